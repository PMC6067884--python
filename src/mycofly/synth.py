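"""Synthetic-data generators for the infection time-course pipeline.

Everything the pipeline consumes can be generated here with known ground
truth: mixed host/pathogen/contaminant read pools whose pathogen fraction
rises from near zero early in infection to dominant in cadavers, fungal
expression matrices containing the three canonical temporal classes
(titer-tracking; on-in-life/off-in-death; on-only-after-death), activity
monitor traces with circadian-gated deaths under a 12:12 light:dark cycle
and ungated deaths under constant darkness, and genomes with a repeat
planted at a known copy number for probe selection.

Every generator is a pure function of its configuration, including the
seed: identical configs give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import random_seq
from .dam import DamSeries
from .waterfall import (
    ROLE_HOST_TRANSCRIPTOME,
    ROLE_PATHOGEN_ANNOTATED,
    ROLE_PATHOGEN_TRANSCRIPTOME,
    ReferenceSet,
)

#: Reserved schedule key for reads drawn from no reference at all.  These
#: emulate the residual read class (library artifacts, unsequenced taxa)
#: that fails to align anywhere; the study design keeps it under 2%.
JUNK_CATEGORY = "junk"


def default_mixing_schedule() -> dict[str, dict[str, float]]:
    """Per-timepoint read-category proportions.

    The pathogen share is zero at 24 hr, trace at 48 hr, substantial at
    72 hr and dominant in cadavers, mirroring the observed time course in
    which fungal reads are generally not detected until 72 hr after
    exposure.  Each entry sums to 1; 1.5% of reads are unalignable junk.
    """
    return {
        "24": {"host_mrna": 0.855, "host_ncrna": 0.08, "contaminant": 0.05,
               JUNK_CATEGORY: 0.015},
        "48": {"host_mrna": 0.850, "host_ncrna": 0.08, "contaminant": 0.05,
               "pathogen_txome": 0.004, "pathogen_annot": 0.001, JUNK_CATEGORY: 0.015},
        "72": {"host_mrna": 0.655, "host_ncrna": 0.06, "contaminant": 0.04,
               "pathogen_txome": 0.20, "pathogen_annot": 0.03, JUNK_CATEGORY: 0.015},
        "96": {"host_mrna": 0.455, "host_ncrna": 0.04, "contaminant": 0.03,
               "pathogen_txome": 0.38, "pathogen_annot": 0.08, JUNK_CATEGORY: 0.015},
        "cadaver": {"host_mrna": 0.105, "host_ncrna": 0.01, "contaminant": 0.02,
                    "pathogen_txome": 0.70, "pathogen_annot": 0.15, JUNK_CATEGORY: 0.015},
    }


def default_group_sizes() -> dict[str, int]:
    return {"i": 40, "ii": 20, "iii": 20, "background": 20}


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs for every generator.

    Defaults emulate the study design at desk scale: a 42-sample
    whole-fly time course (three controls at each of five daily
    timepoints, 21 exposed flies, six cadavers), a latent fungal titer
    that is logistic in time across 48-96 hr, deaths gated into the five
    hours before the light-to-dark transition under 12:12 LD, ~80%
    mortality between days 4 and 7, and a 3:1 photophase:scotophase
    activity ratio.
    """

    seed: int = 0
    # references / reads
    n_host_transcripts: int = 30
    n_pathogen_transcripts: int = 20
    n_contaminant_seqs: int = 8
    read_length: int = 100
    transcript_length_range: tuple[int, int] = (500, 1500)
    mixing_schedule: dict[str, dict[str, float]] = field(default_factory=default_mixing_schedule)
    # expression time course
    group_sizes: dict[str, int] = field(default_factory=default_group_sizes)
    noise_cv: float = 0.2
    control_leakage: float = 0.0  # no quantitative leakage rate is established; exposed as a knob
    titer_midpoint_hr: float = 72.0
    titer_scale_hr: float = 8.0
    base_tpm: float = 100.0
    # activity monitor
    n_flies: int = 32
    photoperiod: tuple[int, int] | None = (12, 12)  # None means constant darkness (DD)
    death_window_hr: tuple[float, float] = (-5.0, 0.0)
    recording_hr: float = 168.0
    bin_seconds: int = 30
    activity_rates: tuple[float, float] = (0.6, 0.2)  # per-bin Poisson, photo/scoto
    mortality: float = 0.8
    death_days: tuple[int, int] = (4, 7)
    n_spurious: int = 0  # flies given single-count artifact bins >24 hr post-death
    # genome / repeat
    repeat_kmer: str = "ATCGGATTACAGCTTAGC"
    repeat_copies: int = 50
    genome_length: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("n_host_transcripts", "n_pathogen_transcripts", "n_contaminant_seqs",
                     "n_flies", "repeat_copies", "genome_length", "n_spurious"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid transcript_length_range")
        if self.read_length > lo:
            raise ValueError("read_length exceeds the minimum transcript length")
        for label, entry in self.mixing_schedule.items():
            total = sum(entry.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"schedule entry {label!r} sums to {total}, not 1")
            if any(p < 0 for p in entry.values()):
                raise ValueError(f"schedule entry {label!r} has negative proportions")
        wlo, whi = self.death_window_hr
        if not (-24.0 <= wlo <= whi <= 24.0):
            raise ValueError("death_window_hr must lie within [-24, 24] hours")
        if self.photoperiod is not None and sum(self.photoperiod) != 24:
            raise ValueError("LD photoperiod hours must sum to 24")
        if set(self.repeat_kmer) - set("ACGT"):
            raise ValueError("repeat_kmer contains non-ACGT characters")
        if self.repeat_copies * len(self.repeat_kmer) >= self.genome_length:
            raise ValueError("planted repeats would exceed the genome length")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def category_plan(config: SimConfig) -> list[tuple[str, int, str | None]]:
    """Default ordered reference categories with role tags.

    The order is the alignment waterfall order: host transcripts first,
    then contaminants, then the pathogen references.  The annotated
    pathogen set is one fifth the size of the de novo transcriptome,
    reflecting that genome-annotated transcripts capture roughly an order
    of magnitude fewer reads than the assembled transcriptome.
    """
    return [
        ("host_mrna", config.n_host_transcripts, ROLE_HOST_TRANSCRIPTOME),
        ("host_ncrna", max(1, config.n_host_transcripts // 5), None),
        ("contaminant", config.n_contaminant_seqs, None),
        ("pathogen_txome", config.n_pathogen_transcripts, ROLE_PATHOGEN_TRANSCRIPTOME),
        ("pathogen_annot", max(1, config.n_pathogen_transcripts // 5), ROLE_PATHOGEN_ANNOTATED),
    ]


def simulate_references(
    config: SimConfig,
    plan: list[tuple[str, int, str | None]] | None = None,
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Generate reference sequences for every category in waterfall order.

    Returns the ordered :class:`ReferenceSet` and a provenance table
    mapping every sequence id to its category and role.  Sequences are
    uniform-random ACGT, so cross-category substring collisions at read
    length are vanishingly rare.
    """
    if plan is None:
        plan = category_plan(config)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.transcript_length_range
    categories: list[tuple[str, dict[str, str]]] = []
    roles: dict[str, str] = {}
    rows = []
    for name, count, role in plan:
        if count <= 0:
            raise ValueError(f"zero sequences requested for category {name!r}")
        seqs: dict[str, str] = {}
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq_id = f"{name}_{i:04d}"
            seqs[seq_id] = random_seq(rng, length)
            rows.append({"seq_id": seq_id, "category": name, "role": role, "length": length})
        categories.append((name, seqs))
        if role is not None:
            roles[name] = role
    provenance = pd.DataFrame(rows)
    return ReferenceSet(categories=categories, role_tags=roles), provenance


def simulate_reads(
    refset: ReferenceSet,
    proportions: dict[str, float],
    n_reads: int,
    seed: int,
    read_length: int = 100,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Draw labelled reads from a reference set at the given mixture.

    Category counts are multinomial at the stated proportions.  Reads are
    exact substrings of a uniformly chosen sequence from their source
    category (the error-free dialect); ``error_rate`` optionally applies
    uniform substitutions for robustness experiments.  The reserved
    category :data:`JUNK_CATEGORY` yields uniform-random reads from no
    reference.  Returns a frame with read_id, sequence, true_category.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    total = sum(proportions.values())
    if n_reads > 0 and abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total}, not 1")
    known = {name for name, _ in refset.categories}
    for cat in proportions:
        if cat != JUNK_CATEGORY and cat not in known:
            raise KeyError(f"schedule category {cat!r} absent from the reference set")
    if n_reads == 0:
        return pd.DataFrame(columns=["read_id", "sequence", "true_category"])

    rng = np.random.default_rng(seed)
    cats = sorted(proportions)
    counts = rng.multinomial(n_reads, [proportions[c] for c in cats])
    by_cat = dict(refset.categories)
    rows = []
    idx = 0
    for cat, count in zip(cats, counts):
        for _ in range(count):
            read_id = f"read_{idx:07d}"
            if cat == JUNK_CATEGORY:
                seq = random_seq(rng, read_length)
            else:
                ids = sorted(by_cat[cat])
                src = ids[int(rng.integers(len(ids)))]
                ref = by_cat[cat][src]
                if len(ref) < read_length:
                    raise ValueError(f"reference {src} shorter than the read length")
                start = int(rng.integers(len(ref) - read_length + 1))
                seq = ref[start:start + read_length]
            if error_rate > 0:
                seq = _mutate(rng, seq, error_rate)
            rows.append({"read_id": read_id, "sequence": seq, "true_category": cat})
            idx += 1
    return pd.DataFrame(rows)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    for i in hits:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[int(rng.integers(len(choices)))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# expression time course
# ---------------------------------------------------------------------------

#: (treatment, timepoint_hr, n_samples) — the 42-sample whole-fly design.
SAMPLE_PLAN: tuple[tuple[str, int, int], ...] = (
    ("control", 24, 3), ("control", 48, 3), ("control", 72, 3),
    ("control", 96, 3), ("control", 120, 3),
    ("exposed", 24, 6), ("exposed", 48, 6), ("exposed", 72, 6), ("exposed", 96, 3),
    ("cadaver", 96, 3), ("cadaver", 120, 3),
)


def latent_titer(timepoint_hr: float, midpoint: float = 72.0, scale: float = 8.0) -> float:
    """Logistic latent fungal titer, ~0 at 24-48 hr and ~1 by 96 hr."""
    return 1.0 / (1.0 + math.exp(-(timepoint_hr - midpoint) / scale))


def simulate_expression_timecourse(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate the fungal expression matrix over the 42-sample design.

    Group i transcripts scale with the latent titer; Group ii transcripts
    are expressed late in the living host and shut off in cadavers; Group
    iii transcripts switch on only after death; background transcripts
    are expressed at a constant level in every infected sample.  Control
    samples see all fungal transcripts scaled by ``control_leakage``
    (zero by default).  Multiplicative lognormal noise at ``noise_cv``.

    Returns (matrix, meta, truth): a transcripts x samples TPM frame, a
    sample-metadata frame (sample_id, treatment, timepoint_hr, tissue,
    titer_fraction) and a Series of true group labels per transcript.
    """
    sizes = config.group_sizes
    if all(v <= 0 for v in sizes.values()):
        raise ValueError("at least one expression group must be nonempty")
    rng = np.random.default_rng(config.seed)

    meta_rows = []
    for treatment, t, n in SAMPLE_PLAN:
        for i in range(n):
            if treatment == "control":
                titer = 0.0
            elif treatment == "cadaver":
                titer = float(rng.uniform(0.9, 1.0))
            else:
                base = latent_titer(t, config.titer_midpoint_hr, config.titer_scale_hr)
                titer = float(np.clip(base * rng.lognormal(0.0, 0.15), 0.0, 1.0))
            meta_rows.append({
                "sample_id": f"{treatment}_{t:03d}_{i}",
                "treatment": treatment,
                "timepoint_hr": t,
                "tissue": "whole",
                "titer_fraction": titer,
            })
    meta = pd.DataFrame(meta_rows)

    labels: list[str] = []
    ids: list[str] = []
    for group in ("i", "ii", "iii", "background"):
        for j in range(sizes.get(group, 0)):
            ids.append(f"emus_{group}_{j:04d}")
            labels.append(group)
    truth = pd.Series(labels, index=ids, name="group")

    base = rng.lognormal(math.log(config.base_tpm), 0.5, size=len(ids))
    titers = meta["titer_fraction"].to_numpy()
    living = (meta["treatment"] == "exposed").to_numpy()
    cadaver = (meta["treatment"] == "cadaver").to_numpy()
    control = (meta["treatment"] == "control").to_numpy()
    infected = living | cadaver

    profile = np.zeros((len(ids), len(meta)))
    lab = np.asarray(labels)
    profile[lab == "i"] = titers
    profile[lab == "ii"] = np.where(living, titers, 0.0)
    profile[lab == "iii"] = cadaver.astype(float)
    profile[lab == "background"] = infected.astype(float)
    profile[:, control] = config.control_leakage

    values = base[:, None] * profile
    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
        noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=values.shape)
        values = values * noise
    matrix = pd.DataFrame(values, index=ids, columns=meta["sample_id"].tolist())
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# activity monitor
# ---------------------------------------------------------------------------

def simulate_dam(config: SimConfig) -> tuple[list[DamSeries], pd.DataFrame]:
    """Simulate per-fly binned activity with known death times.

    Counts are Poisson with a higher rate during photophase (constant at
    the mean rate under DD).  Dying flies register a guaranteed movement
    in their death bin and none after it.  Under LD, true deaths fall
    inside ``death_window_hr`` relative to the light-to-dark transition
    of their death day; under DD they are uniform over the day.  The
    first ``n_spurious`` dying flies also receive a single count-1
    artifact bin more than 24 hr after death, to exercise the death-call
    correction rule.

    Time zero is lights-on (or subjective lights-on under DD).
    """
    if config.n_flies <= 0:
        raise ValueError("n_flies must be > 0")
    if config.recording_hr < 24:
        raise ValueError("recording must cover at least 24 hr")
    rng = np.random.default_rng(config.seed)
    bins_per_hr = 3600 / config.bin_seconds
    n_bins = int(round(config.recording_hr * bins_per_hr))
    photo_rate, scoto_rate = config.activity_rates

    hours = (np.arange(n_bins) / bins_per_hr) % 24.0
    if config.photoperiod is None:
        rates = np.full(n_bins, (photo_rate + scoto_rate) / 2.0)
        light_hours = 12.0  # subjective photoperiod for projected transitions
    else:
        light_hours = float(config.photoperiod[0])
        rates = np.where(hours < light_hours, photo_rate, scoto_rate)

    day_lo, day_hi = config.death_days
    series: list[DamSeries] = []
    truth_rows = []
    n_spurious_left = config.n_spurious
    for f in range(config.n_flies):
        monitor = f"M{f // 32 + 1:02d}"
        channel = f % 32 + 1
        fly_id = f"{monitor}C{channel:02d}"
        counts = rng.poisson(rates)
        dies = bool(rng.random() < config.mortality)
        death_hr = math.nan
        death_bin = -1
        planted_spurious = 0
        if dies:
            day = int(rng.integers(day_lo, day_hi + 1)) - 1  # day index from 0
            if config.photoperiod is None:
                death_hr = day * 24.0 + float(rng.uniform(0.0, 24.0))
            else:
                offset = float(rng.uniform(*config.death_window_hr))
                death_hr = day * 24.0 + light_hours + offset
            death_bin = min(int(death_hr * bins_per_hr), n_bins - 1)
            counts[death_bin] = max(1, counts[death_bin])
            counts[death_bin + 1:] = 0
            if n_spurious_left > 0:
                art_bin = death_bin + int(25 * bins_per_hr)
                if art_bin < n_bins:
                    counts[art_bin] = 1
                    planted_spurious = 1
                    n_spurious_left -= 1
        series.append(DamSeries(
            fly_id=fly_id, counts=counts, bin_seconds=config.bin_seconds,
            monitor=monitor, channel=channel,
            outcome="dead_fungus" if dies else "alive",
        ))
        truth_rows.append({
            "fly_id": fly_id, "dies": dies, "true_death_hr": death_hr,
            "true_death_bin": death_bin, "n_spurious_planted": planted_spurious,
        })
    return series, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# genome with planted repeat
# ---------------------------------------------------------------------------

def simulate_genome_with_repeat(config: SimConfig) -> tuple[str, list[int]]:
    """Uniform-random genome with ``repeat_copies`` planted occurrences.

    Occurrences are placed at distinct k-aligned slots, which guarantees
    they never overlap.  Returns the sequence and the sorted 0-based
    start positions of the planted copies.
    """
    rng = np.random.default_rng(config.seed)
    genome = list(random_seq(rng, config.genome_length))
    k = len(config.repeat_kmer)
    positions: list[int] = []
    if config.repeat_copies > 0:
        n_slots = config.genome_length // k
        slots = rng.choice(n_slots, size=config.repeat_copies, replace=False)
        positions = sorted(int(s) * k for s in slots)
        for pos in positions:
            genome[pos:pos + k] = config.repeat_kmer
    return "".join(genome), positions
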
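"""De novo transcriptome decontamination filters.

A transcriptome assembled from reads of an infected animal is a mixture
of pathogen transcripts, host transcripts, and sequences from food
microbes and other contaminants.  Decontamination proceeds in stages on
the raw assembly (stage 1):

* **taxon filter** (stage 1 -> 2): remove every transcript with a strong
  homology hit (e-value <= 1e-40, inclusive) to a subject whose taxon
  label is outside an allowed set (e.g. anything that is not fungal or
  an expected co-assembled virus);
* **control-expression filter** (stage 2 -> 3): remove transcripts never
  expressed in any sample, and transcripts for which uninfected control
  samples account for strictly more than 10% of total TPM across all
  samples — genuine pathogen transcripts cannot be expressed in
  uninfected animals.

Separate from the staged filters, transcript regions homologous to the
host genome (e-value strictly below 1e-10) can be masked to N so that
shared/ambiguous sequence attracts no reads, and transcripts absent from
both annotations can be assigned to host or pathogen by exclusive genome
homology.

Homology hits use BLAST outfmt-6 conventions: 1-based inclusive
query coordinates, one row per hit.  Taxon labels are supplied by the
caller as part of each hit (resolving a taxonomy database is out of
scope here and would tie results to a database version).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

TAXON_EVALUE_MAX = 1e-40  # inclusive: "1e-40 or smaller" removes
MASK_EVALUE_MAX = 1e-10   # strict: only hits with e-value < 1e-10 qualify
CONTROL_FRACTION_MAX = 0.10  # strict: removal requires "more than 10%"
MIN_UNANNOTATED_LENGTH = 300  # strict: only transcripts longer than 300 bp kept


@dataclass(frozen=True)
class HomologyHit:
    """One homology hit against a query transcript (1-based inclusive coords)."""

    query_id: str
    subject_id: str
    evalue: float
    query_start: int = 1
    query_end: int = 1
    subject_taxon_label: str = ""

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        if not 1 <= self.query_start <= self.query_end:
            raise ValueError("require 1 <= query_start <= query_end")


@dataclass
class DecontamReport:
    """Outcome of one filtering stage: which ids were removed and why."""

    stage: str
    removed: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    masked_bases: dict[str, int] = field(default_factory=dict)

    def check_conservation(self, input_ids: Iterable[str]) -> None:
        inp = set(input_ids)
        if set(self.removed) | set(self.retained) != inp or set(self.removed) & set(self.retained):
            raise AssertionError(f"stage {self.stage}: removed/retained do not partition the input")


def _check_hits(transcripts: Mapping[str, str], hits: Sequence[HomologyHit]) -> None:
    unknown = {h.query_id for h in hits} - set(transcripts)
    if unknown:
        raise KeyError(f"hits reference unknown transcript ids: {sorted(unknown)[:5]}")


def filter_by_taxon(
    transcripts: Mapping[str, str],
    hits: Sequence[HomologyHit],
    allowed_labels: set[str],
    evalue_max: float = TAXON_EVALUE_MAX,
) -> DecontamReport:
    """Remove transcripts with strong homology to disallowed taxa.

    A transcript is removed iff it has at least one hit with e-value
    <= ``evalue_max`` (inclusive) whose subject taxon label is NOT in
    ``allowed_labels``.  Transcripts with no hits at all are retained —
    absence of homology is not evidence of contamination.
    """
    if not allowed_labels:
        raise ValueError("allowed_labels must be nonempty")
    _check_hits(transcripts, hits)
    flagged = {
        h.query_id
        for h in hits
        if h.evalue <= evalue_max and h.subject_taxon_label not in allowed_labels
    }
    report = DecontamReport(
        stage="taxon",
        removed=sorted(flagged),
        retained=sorted(set(transcripts) - flagged),
    )
    report.check_conservation(transcripts)
    return report


def filter_by_control_expression(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    control_fraction_max: float = CONTROL_FRACTION_MAX,
) -> DecontamReport:
    """Remove unexpressed transcripts and those driven by control samples.

    A transcript is removed iff its TPM sums to zero over all samples, or
    the TPM summed over uninfected control samples exceeds (strictly)
    ``control_fraction_max`` of the TPM summed over all samples.  A
    transcript sitting exactly at the boundary fraction is retained.
    """
    missing = set(matrix.columns) ^ set(meta["sample_id"])
    if missing:
        raise ValueError(f"matrix/meta sample mismatch: {sorted(missing)[:5]}")
    control_ids = meta.loc[meta["treatment"] == "control", "sample_id"]
    total = matrix.sum(axis=1)
    control_sum = matrix[list(control_ids)].sum(axis=1)
    never_expressed = total == 0
    frac = control_sum.where(total > 0, 0.0) / total.where(total > 0, 1.0)
    removed = matrix.index[never_expressed | (frac > control_fraction_max)]
    report = DecontamReport(
        stage="control_expression",
        removed=sorted(removed),
        retained=sorted(set(matrix.index) - set(removed)),
    )
    report.check_conservation(matrix.index)
    return report


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def mask_host_regions(
    transcripts: Mapping[str, str],
    hits: Sequence[HomologyHit],
    evalue_max: float = MASK_EVALUE_MAX,
) -> tuple[dict[str, str], DecontamReport]:
    """Mask host-homologous transcript regions to N.

    Every base inside a hit interval with e-value strictly below
    ``evalue_max`` becomes N; overlapping intervals are merged; sequence
    length and id never change.  Returns the masked sequences and a
    report whose ``masked_bases`` counts masked positions per transcript.
    """
    _check_hits(transcripts, hits)
    by_query: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if h.evalue < evalue_max:
            if h.query_end > len(transcripts[h.query_id]):
                raise ValueError(
                    f"hit interval ({h.query_start}, {h.query_end}) exceeds "
                    f"{h.query_id} length {len(transcripts[h.query_id])}"
                )
            by_query.setdefault(h.query_id, []).append((h.query_start, h.query_end))

    masked: dict[str, str] = {}
    masked_bases: dict[str, int] = {}
    for tid, seq in transcripts.items():
        intervals = merge_intervals(by_query.get(tid, []))
        if not intervals:
            masked[tid] = seq
            masked_bases[tid] = 0
            continue
        chars = list(seq)
        n = 0
        for start, end in intervals:  # 1-based inclusive
            chars[start - 1:end] = "N" * (end - start + 1)
            n += end - start + 1
        masked[tid] = "".join(chars)
        masked_bases[tid] = n
    report = DecontamReport(
        stage="mask", removed=[], retained=sorted(transcripts), masked_bases=masked_bases
    )
    return masked, report


def assign_unannotated(
    transcripts: Mapping[str, str],
    hits_vs_host_genome: Sequence[HomologyHit],
    hits_vs_pathogen_genome: Sequence[HomologyHit],
    min_length: int = MIN_UNANNOTATED_LENGTH,
    evalue_max: float = MASK_EVALUE_MAX,
) -> dict[str, str]:
    """Classify transcripts absent from both annotations by genome homology.

    Transcripts not longer than ``min_length`` are ``dropped_short``.
    The rest are classed ``host_unannotated`` or ``pathogen_unannotated``
    when they have a qualifying hit (e-value strictly below
    ``evalue_max``) to exactly one of the two genomes, and ``unassigned``
    when they hit both or neither.
    """
    host_q = {h.query_id for h in hits_vs_host_genome if h.evalue < evalue_max}
    path_q = {h.query_id for h in hits_vs_pathogen_genome if h.evalue < evalue_max}
    out: dict[str, str] = {}
    for tid, seq in transcripts.items():
        if len(seq) <= min_length:
            out[tid] = "dropped_short"
        elif tid in host_q and tid not in path_q:
            out[tid] = "host_unannotated"
        elif tid in path_q and tid not in host_q:
            out[tid] = "pathogen_unannotated"
        else:
            out[tid] = "unassigned"
    return out


def run_refinement(
    transcripts: Mapping[str, str],
    taxon_hits: Sequence[HomologyHit],
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    allowed_labels: set[str],
    taxon_evalue_max: float = TAXON_EVALUE_MAX,
    control_fraction_max: float = CONTROL_FRACTION_MAX,
) -> tuple[dict[str, str], list[DecontamReport]]:
    """Run the staged refinement: raw assembly -> taxon -> expression filter.

    The taxon filter produces stage 2; the control-expression filter on
    the surviving transcripts produces stage 3.  Returns the retained
    sequences and the ordered stage reports.  Each stage is idempotent:
    re-running a stage on its own output removes nothing.
    """
    if not transcripts:
        return {}, []
    reports = []
    stage2 = filter_by_taxon(transcripts, taxon_hits, allowed_labels, taxon_evalue_max)
    reports.append(stage2)
    surviving = {t: transcripts[t] for t in stage2.retained}

    sub = matrix.loc[[t for t in matrix.index if t in surviving]]
    stage3 = filter_by_control_expression(sub, meta, control_fraction_max)
    # transcripts absent from the expression matrix have no evidence either
    # way and are retained
    no_expression_row = sorted(set(surviving) - set(sub.index))
    stage3.retained = sorted(set(stage3.retained) | set(no_expression_row))
    stage3.check_conservation(surviving)
    reports.append(stage3)
    final = {t: surviving[t] for t in stage3.retained}
    return final, reports
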
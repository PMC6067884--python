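"""Drosophila activity monitor (DAM) parsing and death-time inference.

A DAM records infrared beam breaks per fly in fixed-width bins (30 s
native resolution here).  A fly killed by the fungus stops moving for
good, so its time of last movement — the end of its last nonzero bin —
is a proxy for time of death, accurate to one bin.

Monitors occasionally register spurious single events long after a fly
has died (a cadaver being knocked, electrical noise).  The death call
therefore applies an iterated trailing-gap correction: while the gap
between the last candidate event and the previous event exceeds
``max_gap_hr`` (default 24 hr), the candidate is discarded as an
artifact.  Iterating (rather than a single pass) lets stacked artifacts
collapse onto the true last movement; the number of discarded events is
reported for audit.

Death offsets are expressed in signed hours relative to the light-to-
dark transition ("sunset"): a fly that stops moving 2 hr before sunset
has offset -2.  Under constant darkness the offsets are computed against
projected subjective transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_CHANNELS = 32
_N_META_COLUMNS = 10  # record index, date, time, status, six padding fields
_DATE_FORMAT = "%d %b %y"
_TIME_FORMAT = "%H:%M:%S"


class NoMovementError(ValueError):
    """A series with no nonzero bins has no last movement to call."""


@dataclass
class DamSeries:
    """Binned beam-break counts for one fly (one monitor channel)."""

    fly_id: str
    counts: np.ndarray
    bin_seconds: int = 30
    start: datetime | None = None
    monitor: str = "M01"
    channel: int = 1
    outcome: str | None = None  # alive | dead_fungus | dead_other, when known

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("activity counts must be >= 0")
        if not 1 <= self.channel <= N_CHANNELS:
            raise ValueError(f"channel must be 1..{N_CHANNELS}")

    @property
    def duration_hr(self) -> float:
        return len(self.counts) * self.bin_seconds / 3600.0

    def bin_end_hr(self, index: int) -> float:
        """End time of a bin, in hours from recording start."""
        return (index + 1) * self.bin_seconds / 3600.0


@dataclass(frozen=True)
class PhotoperiodSpec:
    """Light regime of the recording.

    ``lights_on_hr`` anchors the phase: hours from recording start to
    the first (possibly projected, under DD) lights-on.  For LD the
    light and dark hours must sum to 24.
    """

    regime: str = "LD"  # LD | DD
    light_hours: float = 12.0
    dark_hours: float = 12.0
    lights_on_hr: float | None = 0.0

    def __post_init__(self) -> None:
        if self.regime not in ("LD", "DD"):
            raise ValueError("regime must be 'LD' or 'DD'")
        if self.light_hours + self.dark_hours != 24.0:
            raise ValueError("light + dark hours must sum to 24")


@dataclass(frozen=True)
class DeathCall:
    """Inferred time of last movement for one fly."""

    fly_id: str
    last_movement_bin: int
    last_movement_hr: float  # end of the surviving candidate bin
    n_events_discarded: int = 0

    @property
    def corrected(self) -> bool:
        return self.n_events_discarded > 0


# ---------------------------------------------------------------------------
# TriKinetics monitor file dialect
# ---------------------------------------------------------------------------

def write_dam_file(
    path: str | Path,
    counts: np.ndarray,
    start: datetime | None = None,
    bin_seconds: int = 30,
    status: Sequence[int] | None = None,
) -> None:
    """Write a monitor file: one row per bin, 10 metadata + 32 count columns.

    ``counts`` is (n_bins, 32).  ``status`` optionally overrides the
    per-row status field (1 = valid reading).
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2 or counts.shape[1] != N_CHANNELS:
        raise ValueError(f"counts must be (n_bins, {N_CHANNELS})")
    if start is None:
        start = datetime(2016, 1, 4, 8, 0, 0)
    lines = []
    for i, row in enumerate(counts):
        stamp = start + timedelta(seconds=i * bin_seconds)
        st = 1 if status is None else int(status[i])
        meta = [str(i + 1), stamp.strftime(_DATE_FORMAT), stamp.strftime(_TIME_FORMAT),
                str(st)] + ["0"] * (_N_META_COLUMNS - 4)
        lines.append("\t".join(meta + [str(c) for c in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def parse_dam_file(path: str | Path, bin_seconds: int = 30) -> list[DamSeries]:
    """Parse a TriKinetics-dialect monitor file into 32 per-channel series.

    Rows whose status field is not 1 are excluded from the counts and
    tallied in a warning.  Rows with the wrong column count or
    non-monotone timestamps abort parsing with the offending line number.
    """
    path = Path(path)
    monitor = path.stem
    rows: list[list[int]] = []
    last_stamp: datetime | None = None
    first_stamp: datetime | None = None
    n_flagged = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _N_META_COLUMNS + N_CHANNELS:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {_N_META_COLUMNS + N_CHANNELS} "
                    f"columns, found {len(fields)}"
                )
            try:
                stamp = datetime.strptime(f"{fields[1]} {fields[2]}",
                                          f"{_DATE_FORMAT} {_TIME_FORMAT}")
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: bad timestamp") from exc
            if last_stamp is not None and stamp <= last_stamp:
                raise ValueError(f"{path.name}:{lineno}: timestamps are not increasing")
            last_stamp = stamp
            if first_stamp is None:
                first_stamp = stamp
            if int(fields[3]) != 1:
                n_flagged += 1
                continue
            try:
                rows.append([int(v) for v in fields[_N_META_COLUMNS:]])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-integer count") from exc
    if n_flagged:
        warnings.warn(f"{path.name}: excluded {n_flagged} status-flagged row(s)",
                      stacklevel=2)
    matrix = np.array(rows, dtype=int).reshape(-1, N_CHANNELS)
    return [
        DamSeries(
            fly_id=f"{monitor}C{ch + 1:02d}", counts=matrix[:, ch],
            bin_seconds=bin_seconds, start=first_stamp, monitor=monitor, channel=ch + 1,
        )
        for ch in range(N_CHANNELS)
    ]


# ---------------------------------------------------------------------------
# death calling
# ---------------------------------------------------------------------------

def call_last_movement(series: DamSeries, max_gap_hr: float = 24.0) -> DeathCall:
    """Infer the time of last movement with the trailing-gap correction.

    The candidate is the last nonzero bin; while the event-to-event gap
    between the candidate and the previous nonzero bin exceeds
    ``max_gap_hr``, the candidate is discarded as a spurious signal and
    the rule repeats.  The call reports the end time of the surviving
    bin and the number of events discarded.
    """
    nonzero = np.flatnonzero(series.counts)
    if nonzero.size == 0:
        raise NoMovementError(f"{series.fly_id}: series has no movement at all")
    discarded = 0
    idx = nonzero.size - 1
    while idx > 0:
        gap_hr = (nonzero[idx] - nonzero[idx - 1]) * series.bin_seconds / 3600.0
        if gap_hr > max_gap_hr:
            discarded += 1
            idx -= 1
        else:
            break
    last_bin = int(nonzero[idx])
    return DeathCall(
        fly_id=series.fly_id,
        last_movement_bin=last_bin,
        last_movement_hr=series.bin_end_hr(last_bin),
        n_events_discarded=discarded,
    )


def hours_since_transition(t_hr: float, photoperiod: PhotoperiodSpec) -> float:
    """Hours elapsed since the most recent light-to-dark transition, in [0, 24)."""
    if photoperiod.lights_on_hr is None:
        raise ValueError("photoperiod phase anchor (lights_on_hr) is missing")
    first_transition = photoperiod.lights_on_hr + photoperiod.light_hours
    return (t_hr - first_transition) % 24.0


def death_offset(call: DeathCall, photoperiod: PhotoperiodSpec) -> float:
    """Signed hours relative to the nearest light-to-dark transition.

    Deaths during photophase map to negative offsets (a fly stopping 2 hr
    before sunset has offset -2); deaths in scotophase map to positive
    offsets.  Under DD the transitions are projected subjective ones.
    """
    d = hours_since_transition(call.last_movement_hr, photoperiod)
    return d if d <= photoperiod.dark_hours else d - 24.0


def bin_activity(series: DamSeries, width_minutes: float) -> DamSeries:
    """Rebin counts into wider windows; total counts are conserved.

    The window must be a whole multiple of the native bin.  A trailing
    partial window is kept (summed) so no counts are lost.
    """
    width_s = width_minutes * 60.0
    factor = width_s / series.bin_seconds
    if factor != int(factor) or factor < 1:
        raise ValueError("window must be a positive multiple of the native bin width")
    factor = int(factor)
    n = len(series.counts)
    pad = (-n) % factor
    padded = np.concatenate([series.counts, np.zeros(pad, dtype=int)])
    rebinned = padded.reshape(-1, factor).sum(axis=1)
    return DamSeries(
        fly_id=series.fly_id, counts=rebinned, bin_seconds=int(width_s),
        start=series.start, monitor=series.monitor, channel=series.channel,
        outcome=series.outcome,
    )


@dataclass
class CohortSummary:
    """Death-timing and activity summary for a cohort of monitored flies."""

    survival: pd.DataFrame          # day, mean cumulative death fraction, sd over monitors
    offsets: pd.Series              # signed death offsets, one per dead fly
    ks_statistic: float             # KS of hours-since-transition vs uniform(0, 24)
    ks_pvalue: float
    activity_profile: pd.DataFrame = field(default_factory=pd.DataFrame)


def cohort_summary(
    calls: Sequence[DeathCall],
    series: Sequence[DamSeries],
    photoperiod: PhotoperiodSpec,
    profile_bin_minutes: float = 30.0,
) -> CohortSummary:
    """Summarize death timing across a cohort.

    ``calls`` holds one call per fly that died; ``series`` the full
    cohort (dead and surviving), each with its outcome label.  Produces
    the per-day cumulative death fraction (mean and SD over monitors,
    which stand in for replicate vials), the death-offset distribution,
    a KS test of the offsets against a uniform 24 hr distribution
    (rejected for circadian-gated deaths under LD, not rejected for the
    sporadic deaths seen under constant darkness), and mean +/- SD
    rebinned activity profiles per outcome group.
    """
    if not series:
        raise ValueError("empty cohort")
    by_fly = {s.fly_id: s for s in series}
    dead_ids = {c.fly_id for c in calls}

    # survival: cumulative fraction of flies dead by the end of each day
    death_day = {c.fly_id: int(c.last_movement_hr // 24.0) + 1 for c in calls}
    n_days = int(np.ceil(max(s.duration_hr for s in series) / 24.0))
    monitors = sorted({s.monitor for s in series})
    per_monitor = np.zeros((len(monitors), n_days))
    for mi, monitor in enumerate(monitors):
        flies = [s.fly_id for s in series if s.monitor == monitor]
        for day in range(1, n_days + 1):
            dead = sum(1 for f in flies if f in dead_ids and death_day[f] <= day)
            per_monitor[mi, day - 1] = dead / len(flies)
    survival = pd.DataFrame({
        "day": np.arange(1, n_days + 1),
        "cumulative_death_fraction": per_monitor.mean(axis=0),
        "sd": per_monitor.std(axis=0, ddof=0),
    })

    offsets = pd.Series(
        {c.fly_id: death_offset(c, photoperiod) for c in calls}, name="offset_hr"
    )
    if len(calls):
        d = np.array([hours_since_transition(c.last_movement_hr, photoperiod) for c in calls])
        ks = stats.kstest(d, stats.uniform(loc=0, scale=24).cdf)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = float("nan"), float("nan")

    profiles = {}
    outcomes = sorted({s.outcome or "unknown" for s in series})
    for outcome in outcomes:
        group = [bin_activity(s, profile_bin_minutes).counts
                 for s in series if (s.outcome or "unknown") == outcome]
        width = max(len(g) for g in group)
        arr = np.full((len(group), width), np.nan)
        for i, g in enumerate(group):
            arr[i, :len(g)] = g
        profiles[f"{outcome}_mean"] = np.nanmean(arr, axis=0)
        profiles[f"{outcome}_sd"] = np.nanstd(arr, axis=0, ddof=0)
    activity = pd.DataFrame(profiles)
    return CohortSummary(
        survival=survival, offsets=offsets,
        ks_statistic=ks_stat, ks_pvalue=ks_p, activity_profile=activity,
    )
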
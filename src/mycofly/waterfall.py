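"""Sequential multi-reference read partitioning ("alignment waterfall").

Dual RNA-seq samples from an infected host contain reads from the host,
the pathogen, and assorted contaminants.  To get a full accounting of
reads and a conservative estimate of pathogen abundance, reads are
aligned sequentially to an ordered list of references — host transcripts
first, then contaminants, then the pathogen references — with only reads
that failed to align to every previous reference used as input to the
next.  A read is therefore assigned to the FIRST category that matches
it; reads matching nothing are the residual ``unaligned`` class.

The fungal-titer proxy is the fraction of pathogen-aligned reads among
reads aligned to either the pathogen references or the host
transcriptome, which tracks fungal load across the infection.

Alignment itself is behind a contract (:class:`AlignerContract`): any
callable mapping (reads, reference sequences) to matched/unmatched read
id sets can be plugged in, so output from external aligners can drive
the same bookkeeping.  The shipped matcher is exact-substring with
reverse-complement awareness, sufficient for error-free reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from ._seq import revcomp

ROLE_HOST_TRANSCRIPTOME = "host_transcriptome"
ROLE_PATHOGEN_TRANSCRIPTOME = "pathogen_transcriptome"
ROLE_PATHOGEN_ANNOTATED = "pathogen_annotated"

UNALIGNED = "unaligned"

#: (reads: mapping id->sequence, references: mapping id->sequence)
#: -> (matched ids, unmatched ids); the two sets must partition the input.
AlignerContract = Callable[[Mapping[str, str], Mapping[str, str]], tuple[set, set]]


class AlignerContractError(RuntimeError):
    """An aligner returned sets that do not partition its input reads."""

    def __init__(self, message: str, offending_ids: set[str]):
        super().__init__(f"{message}: {sorted(offending_ids)[:10]}")
        self.offending_ids = offending_ids


class TiterUndefinedError(ZeroDivisionError):
    """No reads aligned to either host or pathogen transcriptome references."""


@dataclass
class ReferenceSet:
    """Ordered references with category labels and role tags.

    ``categories`` is an ordered list of (label, id->sequence mapping);
    the order IS the waterfall order.  ``role_tags`` marks which
    categories act as the host transcriptome, the pathogen transcriptome
    and the pathogen annotated-transcript set for the titer proxy.
    """

    categories: list[tuple[str, dict[str, str]]]
    role_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [name for name, _ in self.categories]
        if len(labels) != len(set(labels)):
            raise ValueError("category labels must be unique")
        unknown = set(self.role_tags) - set(labels)
        if unknown:
            raise ValueError(f"role tags for unknown categories: {sorted(unknown)}")

    @property
    def order(self) -> list[str]:
        return [name for name, _ in self.categories]

    def with_role(self, role: str) -> list[str]:
        return [cat for cat, r in self.role_tags.items() if r == role]


@dataclass
class ReadPartition:
    """Per-sample read counts by category, plus the unaligned residual."""

    sample_id: str
    counts: dict[str, int]
    unaligned: int

    def __post_init__(self) -> None:
        if self.unaligned < 0 or any(c < 0 for c in self.counts.values()):
            raise ValueError("read counts must be >= 0")

    @property
    def total(self) -> int:
        return self.unaligned + sum(self.counts.values())


@dataclass(frozen=True)
class TiterProxy:
    """Pathogen read fraction among pathogen + host-transcriptome reads."""

    sample_id: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("titer fraction must lie in [0, 1]")


def builtin_exact_aligner(min_match: int = 1) -> AlignerContract:
    """Exact-substring matcher honouring both strands.

    A read matches a reference set iff it occurs as an exact substring of
    any reference sequence or of its reverse complement.  Reads shorter
    than ``min_match`` never match.  This is the test stand-in for the
    external aligners a production run would plug in through the same
    contract.
    """
    if min_match < 1:
        raise ValueError("min_match must be >= 1")

    def align(reads: Mapping[str, str], references: Mapping[str, str]) -> tuple[set, set]:
        # One concatenated haystack per strand; '#' separators prevent
        # spurious matches spanning two references.
        fwd = "#".join(references.values())
        rev = revcomp(fwd)
        matched, unmatched = set(), set()
        for read_id, seq in reads.items():
            if len(seq) >= min_match and (seq in fwd or seq in rev):
                matched.add(read_id)
            else:
                unmatched.add(read_id)
        return matched, unmatched

    return align


def partition_reads(
    reads: Mapping[str, str] | pd.DataFrame,
    refset: ReferenceSet,
    aligner: AlignerContract,
    sample_id: str = "sample",
) -> tuple[ReadPartition, pd.DataFrame]:
    """Assign each read to the first matching category in waterfall order.

    ``reads`` may be an id->sequence mapping or a frame with ``read_id``
    and ``sequence`` columns.  Returns the partition and a per-read
    assignment table (read_id, category) in which unmatched reads carry
    the ``unaligned`` label.  An aligner whose matched/unmatched sets do
    not partition its input aborts the run with the offending read ids.
    """
    if isinstance(reads, pd.DataFrame):
        if reads["read_id"].duplicated().any():
            raise ValueError("read ids must be unique")
        remaining = dict(zip(reads["read_id"], reads["sequence"]))
    else:
        remaining = dict(reads)

    assignment: dict[str, str] = {}
    counts: dict[str, int] = {}
    for category, sequences in refset.categories:
        if not remaining:
            counts[category] = 0
            continue
        matched, unmatched = aligner(remaining, sequences)
        in_ids = set(remaining)
        overlap = matched & unmatched
        stray = (matched | unmatched) ^ in_ids
        if overlap or stray:
            raise AlignerContractError(
                f"aligner broke the partition contract on category {category!r}",
                overlap | stray,
            )
        for read_id in matched:
            assignment[read_id] = category
        counts[category] = len(matched)
        remaining = {r: remaining[r] for r in remaining if r in unmatched}

    for read_id in remaining:
        assignment[read_id] = UNALIGNED
    partition = ReadPartition(sample_id=sample_id, counts=counts, unaligned=len(remaining))
    table = pd.DataFrame(
        {"read_id": list(assignment), "category": list(assignment.values())}
    ).sort_values("read_id", ignore_index=True)
    return partition, table


def compute_titer_proxy(partition: ReadPartition, refset: ReferenceSet) -> TiterProxy:
    """Pathogen/(pathogen + host transcriptome) read fraction.

    The numerator pools the pathogen de novo transcriptome and annotated
    transcript categories; the denominator adds only the host
    transcriptome (mRNA) category — host ncRNA/genome alignments are
    excluded by default, matching how the read proportions are defined.
    """
    host_cats = refset.with_role(ROLE_HOST_TRANSCRIPTOME)
    path_cats = (refset.with_role(ROLE_PATHOGEN_TRANSCRIPTOME)
                 + refset.with_role(ROLE_PATHOGEN_ANNOTATED))
    if not host_cats or not path_cats:
        raise ValueError("role tags must identify at least one host and one pathogen category")
    host = sum(partition.counts.get(c, 0) for c in host_cats)
    pathogen = sum(partition.counts.get(c, 0) for c in path_cats)
    denom = host + pathogen
    if denom == 0:
        raise TiterUndefinedError(
            f"sample {partition.sample_id!r}: no reads aligned to host or pathogen references"
        )
    return TiterProxy(sample_id=partition.sample_id, fraction=pathogen / denom)


def accounting_report(partitions: Sequence[ReadPartition]) -> pd.DataFrame:
    """Per-sample read fractions by category, including the unaligned class.

    Fractions in each row sum to 1.  Serializable directly to TSV/JSON.
    """
    rows = []
    for p in partitions:
        total = p.total
        row: dict[str, float | str] = {"sample_id": p.sample_id}
        for category, count in p.counts.items():
            row[category] = count / total if total else 0.0
        row[UNALIGNED] = p.unaligned / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)
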
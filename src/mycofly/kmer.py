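"""Canonical k-mer counting and repeat-probe selection.

A short DNA FISH probe against a high-copy genomic repeat gives a
bright, pathogen-specific signal; the probe target is simply the most
abundant k-mer (k = 18 for a standard oligo probe) in the genome.
Because genomic DNA is double-stranded, a k-mer and its reverse
complement are the same target: counting is canonical (each window
contributes to the lexicographically smaller of the window and its
reverse complement).  Windows containing ambiguous bases are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

from ._seq import revcomp


@dataclass(frozen=True)
class KmerResult:
    """A canonical k-mer and its strand-collapsed genome-wide count."""

    kmer: str
    count: int
    k: int
    positions: tuple[tuple[str, int, str], ...] | None = None  # (contig, 0-based, strand)

    def __post_init__(self) -> None:
        if len(self.kmer) != self.k:
            raise ValueError("kmer length does not match k")
        if self.count < 1:
            raise ValueError("a reported k-mer must occur at least once")
        if self.kmer > revcomp(self.kmer):
            raise ValueError("kmer must be in canonical (lexicographically smaller) form")


def canonical(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _contig_windows(seq: str, k: int, rc: str | None = None) -> Iterator[tuple[int, str, str]]:
    """Yield (offset, canonical k-mer, strand) for N-free windows of one contig."""
    if rc is None:
        rc = revcomp(seq)
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i:i + k]
        if "N" in fwd:
            continue
        rev = rc[n - i - k:n - i]
        if fwd <= rev:
            yield i, fwd, "+"
        else:
            yield i, rev, "-"


def count_kmers(
    genome: Mapping[str, str] | str,
    k: int,
    chunk_size: int | None = None,
) -> dict[str, int]:
    """Canonical k-mer counts over every contig of a genome.

    Each N-free length-k window contributes one count to its canonical
    form.  ``chunk_size`` enables the memory-bounded streaming mode, in
    which each contig is processed in overlapping chunks; the result is
    identical to the in-memory mode.
    """
    if isinstance(genome, str):
        genome = {"contig_1": genome}
    if k < 1:
        raise ValueError("k must be >= 1")
    if genome and k > max(len(s) for s in genome.values()):
        raise ValueError("k exceeds the longest contig")
    counts: dict[str, int] = {}
    for seq in genome.values():
        seq = seq.upper()
        if chunk_size is None:
            for _i, kmer, _s in _contig_windows(seq, k):
                counts[kmer] = counts.get(kmer, 0) + 1
        else:
            if chunk_size < k:
                raise ValueError("chunk_size must be >= k")
            # overlap chunks by k-1 so every window is seen exactly once
            for start in range(0, max(len(seq) - k + 1, 1), chunk_size - k + 1):
                chunk = seq[start:start + chunk_size]
                if len(chunk) < k:
                    break
                for _i, kmer, _s in _contig_windows(chunk, k):
                    counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def most_abundant_kmer(
    genome: Mapping[str, str] | str,
    k: int,
    top_n: int = 1,
    with_positions: bool = False,
) -> list[KmerResult]:
    """The ``top_n`` most abundant canonical k-mers, with deterministic ties.

    Results are sorted by descending count, ties broken lexicographically
    by canonical k-mer.  With ``with_positions`` every occurrence is
    reported as (contig, 0-based offset, strand).
    """
    if isinstance(genome, str):
        genome = {"contig_1": genome}
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    counts = count_kmers(genome, k)
    if not counts:
        raise ValueError("no N-free windows of length k")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    wanted = {kmer for kmer, _ in ranked}
    positions: dict[str, list[tuple[str, int, str]]] = {kmer: [] for kmer in wanted}
    if with_positions:
        for contig, seq in genome.items():
            for i, kmer, strand in _contig_windows(seq.upper(), k):
                if kmer in wanted:
                    positions[kmer].append((contig, i, strand))
    return [
        KmerResult(
            kmer=kmer, count=count, k=k,
            positions=tuple(positions[kmer]) if with_positions else None,
        )
        for kmer, count in ranked
    ]


def probe_report(result: KmerResult, genome: Mapping[str, str] | str) -> dict:
    """Summary statistics supporting probe selection for a candidate k-mer.

    Reports the total count, the per-contig occurrence distribution, the
    GC fraction and the Wallace-rule melting temperature estimate
    Tm = 2(A+T) + 4(G+C) degrees C (a rough screen, not a nearest-
    neighbour calculation).
    """
    if isinstance(genome, str):
        genome = {"contig_1": genome}
    per_contig: dict[str, int] = {}
    for contig, seq in genome.items():
        n = 0
        for _i, kmer, _s in _contig_windows(seq.upper(), result.k):
            if kmer == result.kmer:
                n += 1
        if n:
            per_contig[contig] = n
    gc = sum(result.kmer.count(b) for b in "GC")
    at = result.k - gc
    return {
        "kmer": result.kmer,
        "count": result.count,
        "per_contig": per_contig,
        "gc_fraction": gc / result.k,
        "tm_wallace_c": 2 * at + 4 * gc,
    }
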
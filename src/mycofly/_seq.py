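"""Small shared sequence helpers (reverse complement, random sequence, FASTA I/O)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform-random ACGT string of the given length."""
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


def write_fasta(path: str | Path, records: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seq_records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
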
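"""Small sequence helpers shared across modules: reverse complement,
k-mer iteration, and plain-text FASTA/FASTQ round-trips (Biopython-backed
parsing, byte-stable writing)."""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield all k-mers of `seq` that are pure ACGT (N breaks extraction)."""
    n = len(seq)
    for i in range(n - k + 1):
        km = seq[i : i + k]
        if set(km) <= {"A", "C", "G", "T"}:
            yield km


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, list[int]]]:
    """FASTQ (Phred+33) -> list of (id, bases, quality scores)."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(reads: Iterable[tuple[str, str, list[int]]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq, quals in reads:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{name}\n{seq}\n+\n{qstr}\n")
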
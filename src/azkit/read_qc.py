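"""Raw-read quality control.

A read is retained when strictly more than `frac_threshold` of its bases
have Phred quality strictly above `q_threshold` (default: more than 70%
of bases with Q > 20 — the strict reading of the filtering rule; a read
sitting exactly on either boundary fails). Adapter trimming is exact and
end-anchored only: the longest adapter (or reverse-complement) match at
either end of the read is removed, from sequence and qualities alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import revcomp


@dataclass
class QualityRead:
    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"{self.id}: {len(self.bases)} bases vs {len(self.quals)} quality scores")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class QCReport:
    total_reads: int
    hq_reads: int
    hq_read_pct: float
    hq_base_pct: float
    mean_read_length: float

    def to_tsv(self) -> str:
        head = "total_reads\thq_reads\thq_read_pct\thq_base_pct\tmean_read_length"
        row = f"{self.total_reads}\t{self.hq_reads}\t{self.hq_read_pct:.2f}\t{self.hq_base_pct:.2f}\t{self.mean_read_length:.2f}"
        return head + "\n" + row + "\n"


def trim_adapters(read: QualityRead, adapters: Sequence[str]) -> QualityRead:
    """Remove the longest exact end-anchored adapter match (adapter or its
    reverse complement) from each end; a no-match is a no-op."""
    variants = []
    for a in adapters:
        if not a:
            raise ValueError("empty adapter string")
        a = a.upper()
        variants.extend((a, revcomp(a)))
    bases, quals = read.bases, list(read.quals)
    lead = max((len(a) for a in variants if bases.startswith(a)), default=0)
    if lead:
        bases, quals = bases[lead:], quals[lead:]
    tail = max((len(a) for a in variants if a and bases.endswith(a)), default=0)
    if tail:
        bases, quals = bases[:-tail], quals[:-tail]
    return QualityRead(read.id, bases, quals)


def passes_quality(read: QualityRead, q_threshold: int = 20, frac_threshold: float = 0.70) -> bool:
    """True iff (#bases with Q > q_threshold) / length > frac_threshold,
    both inequalities strict. An empty read fails."""
    n = len(read)
    if n == 0:
        return False
    good = sum(1 for q in read.quals if q > q_threshold)
    return good / n > frac_threshold


def filter_reads(
    reads: Iterable[QualityRead], q_threshold: int = 20, frac_threshold: float = 0.70
) -> list[QualityRead]:
    return [r for r in reads if passes_quality(r, q_threshold, frac_threshold)]


def filter_pairs(
    r1: Sequence[QualityRead],
    r2: Sequence[QualityRead],
    q_threshold: int = 20,
    frac_threshold: float = 0.70,
) -> tuple[list[QualityRead], list[QualityRead]]:
    """Synchronized pair filtering: if either mate fails, both are dropped."""
    if len(r1) != len(r2):
        raise ValueError("mate files out of sync")
    keep1, keep2 = [], []
    for a, b in zip(r1, r2):
        if passes_quality(a, q_threshold, frac_threshold) and passes_quality(b, q_threshold, frac_threshold):
            keep1.append(a)
            keep2.append(b)
    return keep1, keep2


def qc_summary(
    reads: Sequence[QualityRead],
    filtered: Sequence[QualityRead],
    q_threshold: int = 20,
) -> QCReport:
    """Tally the filtering outcome. hq_base_pct is the fraction of ALL
    input bases with Q > q_threshold (the base-level analogue of the read
    rule; the source material reports it without defining the formula, so
    this interpretation is documented). Percentages to 2 decimals."""
    total = len(reads)
    if total == 0:
        raise ValueError("no reads to summarize")
    hq = len(filtered)
    total_bases = sum(len(r) for r in reads)
    good_bases = sum(sum(1 for q in r.quals if q > q_threshold) for r in reads)
    mean_len = sum(len(r) for r in filtered) / hq if hq else 0.0
    return QCReport(
        total_reads=total,
        hq_reads=hq,
        hq_read_pct=round(100.0 * hq / total, 2),
        hq_base_pct=round(100.0 * good_bases / total_bases, 2) if total_bases else 0.0,
        mean_read_length=round(mean_len, 2),
    )
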
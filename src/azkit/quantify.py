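"""Read-to-transcript assignment and the enrichment statistic.

The mapper is a lightweight exact-seed pseudo-aligner (a contract-level
stand-in for a short-read aligner): k-mer seeds at a few fixed offsets
nominate (transcript, position, strand) candidates, each verified by
ungapped comparison allowing at most `max_mismatch` substitutions. A
read is assigned to at most one transcript — fewest mismatches, with a
deterministic lexicographic tie-break.

Expression per transcript and condition is summarized as
    enrichment = average read depth x coverage
where coverage is the fraction of bases covered at depth >= 1 and the
average depth is taken over covered bases (the reading under which the
product does not double-penalize partial coverage; averaging over all
bases is available via `depth_over="all"`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import revcomp


@dataclass
class Assignment:
    read_id: str
    transcript_id: str
    pos: int  # 0-based on the transcript forward strand
    strand: str
    mismatches: int
    read_len: int


@dataclass
class Pileup:
    transcript_id: str
    depth: np.ndarray  # per-base coverage counts
    n_reads: int


@dataclass
class EnrichmentRecord:
    transcript_id: str
    condition: str
    avg_depth: float
    coverage: float  # fraction in [0, 1]
    enrichment: float


def _hamming_at(read: str, tseq: str, pos: int, cap: int) -> int | None:
    """Mismatch count of `read` vs transcript window at `pos`; None if the
    read does not fit or exceeds `cap` mismatches."""
    if pos < 0 or pos + len(read) > len(tseq):
        return None
    mm = 0
    window = tseq[pos : pos + len(read)]
    for a, b in zip(read, window):
        if a != b:
            mm += 1
            if mm > cap:
                return None
    return mm


def map_reads(
    reads: Sequence[tuple[str, str]],
    transcripts: dict[str, str],
    seed_k: int = 21,
    max_mismatch: int = 3,
) -> tuple[list[Assignment], int]:
    """Assign each (read_id, bases) to at most one transcript.

    Returns (assignments, n_unassigned); assigned + unassigned equals the
    number of input reads.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in transcripts.items():
        for i in range(len(seq) - seed_k + 1):
            km = seq[i : i + seed_k]
            if "N" not in km:
                index.setdefault(km, []).append((tid, i))

    assignments: list[Assignment] = []
    unassigned = 0
    for rid, bases in reads:
        bases = bases.upper()
        n = len(bases)
        best: tuple[int, str, int, str] | None = None  # (mm, tid, pos, strand)
        seen: set[tuple[str, int, str]] = set()
        offsets = sorted({0, max(0, (n - seed_k) // 2), max(0, n - seed_k)})
        for strand in ("+", "-"):
            q = bases if strand == "+" else revcomp(bases)
            for off in offsets:
                km = q[off : off + seed_k]
                if len(km) < seed_k:
                    continue
                for tid, i in index.get(km, ()):  # candidate alignment start
                    pos = i - off
                    key = (tid, pos, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    mm = _hamming_at(q, transcripts[tid], pos, max_mismatch)
                    if mm is None:
                        continue
                    cand = (mm, tid, pos, strand)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            unassigned += 1
        else:
            mm, tid, pos, strand = best
            assignments.append(Assignment(rid, tid, pos, strand, mm, n))
    return assignments, unassigned


def pileups(assignments: Sequence[Assignment], transcripts: dict[str, str]) -> dict[str, Pileup]:
    """Per-base depth for every transcript (zero arrays where unmapped)."""
    depth = {tid: np.zeros(len(seq), dtype=np.int64) for tid, seq in transcripts.items()}
    nreads: dict[str, int] = {tid: 0 for tid in transcripts}
    for a in assignments:
        depth[a.transcript_id][a.pos : a.pos + a.read_len] += 1
        nreads[a.transcript_id] += 1
    return {tid: Pileup(tid, depth[tid], nreads[tid]) for tid in transcripts}


def enrichment(pileup: Pileup, condition: str = "", depth_over: str = "covered") -> EnrichmentRecord:
    """Enrichment = average read depth x coverage for one pileup."""
    L = len(pileup.depth)
    if L == 0:
        raise ValueError(f"zero-length transcript {pileup.transcript_id}")
    covered = pileup.depth > 0
    n_cov = int(covered.sum())
    coverage = n_cov / L
    if n_cov == 0:
        avg = 0.0
    elif depth_over == "covered":
        avg = float(pileup.depth[covered].mean())
    elif depth_over == "all":
        avg = float(pileup.depth.mean())
    else:
        raise ValueError(f"unknown depth_over mode: {depth_over!r}")
    return EnrichmentRecord(pileup.transcript_id, condition, avg, coverage, avg * coverage)


def quantify(
    reads: Sequence[tuple[str, str]],
    transcripts: dict[str, str],
    condition: str,
    seed_k: int = 21,
    max_mismatch: int = 3,
    depth_over: str = "covered",
) -> tuple[list[EnrichmentRecord], list[Assignment], int]:
    """Map reads and compute one EnrichmentRecord per transcript."""
    assignments, unassigned = map_reads(reads, transcripts, seed_k, max_mismatch)
    piles = pileups(assignments, transcripts)
    records = [enrichment(piles[tid], condition, depth_over) for tid in transcripts]
    return records, assignments, unassigned
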
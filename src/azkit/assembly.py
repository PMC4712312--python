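"""Minimal de Bruijn unitig assembler with an odd-k sweep.

This is a contract-level stand-in for a Velvet/Oases-style assembler at
desk scale: k-mers are counted canonically, those below a multiplicity
floor are dropped as presumed sequencing errors (floor 2 by default, the
usual denoising choice), edges come from observed (k+1)-mers, and the
output is the set of maximal non-branching paths (unitigs), reported in
a deterministic canonical orientation (the lexicographically smaller of
the strand pair). No scaffolding, bubble popping or isoform resolution.

The sweep assembles at each requested odd k and selects the k with the
highest percentage of assembled reads (a read counts as assembled when
every one of its k-mers survives into a retained unitig), breaking ties
by larger N50 and then smaller k.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import canonical, iter_kmers, revcomp


@dataclass
class Contig:
    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AssemblyStats:
    k: int
    n_reads_assembled: int
    pct_reads_assembled: float
    n_contigs: int
    max_len: int
    min_len: int
    mean_len: float
    total_len: int
    n_gt_100: int
    n_gt_500: int
    n_gt_1k: int
    n_gt_10k: int
    n_gt_1m: int
    n50: int
    non_atgc_count: int
    non_atgc_pct: float

    HEADER = (
        "k\tn_reads_assembled\tpct_reads_assembled\tn_contigs\tmax_len\tmin_len\t"
        "mean_len\ttotal_len\tn_gt_100\tn_gt_500\tn_gt_1k\tn_gt_10k\tn_gt_1m\t"
        "n50\tnon_atgc_count\tnon_atgc_pct"
    )

    def to_row(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.k,
                self.n_reads_assembled,
                f"{self.pct_reads_assembled:.4f}",
                self.n_contigs,
                self.max_len,
                self.min_len,
                f"{self.mean_len:.2f}",
                self.total_len,
                self.n_gt_100,
                self.n_gt_500,
                self.n_gt_1k,
                self.n_gt_10k,
                self.n_gt_1m,
                self.n50,
                self.non_atgc_count,
                f"{self.non_atgc_pct:.6g}",
            )
        )


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L sum to at least half the
    total assembly length (descending cumulative scan)."""
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    cum = 0
    for L in ordered:
        cum += L
        if cum >= half:
            return L
    raise AssertionError("unreachable")


def _check_k(k: int, reads: Sequence[str]) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    max_len = max((len(r) for r in reads), default=0)
    if k > max_len:
        raise ValueError(f"k={k} exceeds the longest read ({max_len} bp)")


def build_unitigs(reads: Sequence[str], k: int, min_count: int = 2) -> list[Contig]:
    """Assemble reads into unitigs of the canonical k-mer de Bruijn graph.

    k-mers with canonical multiplicity below `min_count` are dropped;
    edges require an observed (k+1)-mer whose two constituent k-mers both
    survive. Returns contigs sorted by (length desc, sequence) with
    deterministic ids; every contig is at least k bp.
    """
    reads = [r.upper() for r in reads]
    _check_k(k, reads)

    counts: Counter[str] = Counter()
    for r in reads:
        for km in iter_kmers(r, k):
            counts[canonical(km)] += 1
    retained = {km for km, c in counts.items() if c >= min_count}
    if not retained:
        return []

    succ: dict[str, set[str]] = {}
    pred: dict[str, set[str]] = {}
    nodes: set[str] = set()
    for km in retained:
        nodes.add(km)
        nodes.add(revcomp(km))

    # edges by (k-1)-overlap between surviving nodes: reads overlapping by
    # k-1 merge, matching the de Bruijn graph contract
    for a in nodes:
        suffix = a[1:]
        for c in "ACGT":
            b = suffix + c
            if b in nodes:
                succ.setdefault(a, set()).add(b)
                pred.setdefault(b, set()).add(a)

    def outdeg(n: str) -> int:
        return len(succ.get(n, ()))

    def indeg(n: str) -> int:
        return len(pred.get(n, ()))

    seqs: set[str] = set()
    visited: set[str] = set()

    def walk(start: str) -> str:
        path = [start]
        cur = start
        while outdeg(cur) == 1:
            nxt = next(iter(succ[cur]))
            if indeg(nxt) != 1 or nxt == start:
                break
            path.append(nxt)
            cur = nxt
        visited.update(path)
        return path[0] + "".join(p[-1] for p in path[1:])

    starts = sorted(n for n in nodes if indeg(n) != 1 or (pred.get(n) and outdeg(next(iter(pred[n]))) != 1))
    for s in starts:
        seq = walk(s)
        seqs.add(min(seq, revcomp(seq)))

    # leftover perfect cycles
    for n in sorted(nodes - visited):
        if n in visited:
            continue
        seq = walk(n)
        seqs.add(min(seq, revcomp(seq)))

    ordered = sorted(seqs, key=lambda s: (-len(s), s))
    return [Contig(f"contig_{i:05d}", s) for i, s in enumerate(ordered)]


def reads_assembled(reads: Sequence[str], contigs: Sequence[Contig], k: int) -> int:
    """Count reads all of whose k-mers survive into the retained unitigs.
    Reads shorter than k (or with no valid k-mer) do not count."""
    contig_kmers: set[str] = set()
    for c in contigs:
        for km in iter_kmers(c.seq, k):
            contig_kmers.add(canonical(km))
    n = 0
    for r in reads:
        kms = [canonical(km) for km in iter_kmers(r.upper(), k)]
        if kms and all(km in contig_kmers for km in kms):
            n += 1
    return n


def assembly_stats(contigs: Sequence[Contig], k: int, n_reads: int, n_assembled: int) -> AssemblyStats:
    lengths = [c.length for c in contigs]
    total = sum(lengths)
    non_atgc = sum(sum(1 for b in c.seq if b not in "ACGT") for c in contigs)
    return AssemblyStats(
        k=k,
        n_reads_assembled=n_assembled,
        pct_reads_assembled=100.0 * n_assembled / n_reads if n_reads else 0.0,
        n_contigs=len(contigs),
        max_len=max(lengths) if lengths else 0,
        min_len=min(lengths) if lengths else 0,
        mean_len=total / len(lengths) if lengths else 0.0,
        total_len=total,
        n_gt_100=sum(1 for L in lengths if L > 100),
        n_gt_500=sum(1 for L in lengths if L > 500),
        n_gt_1k=sum(1 for L in lengths if L > 1000),
        n_gt_10k=sum(1 for L in lengths if L > 10_000),
        n_gt_1m=sum(1 for L in lengths if L > 1_000_000),
        n50=n50(lengths) if lengths else 0,
        non_atgc_count=non_atgc,
        # reported as count/total-length, matching the convention of the
        # assembly-statistics table this panel mirrors
        non_atgc_pct=non_atgc / total if total else 0.0,
    )


def kmer_sweep(
    reads: Sequence[str], k_values: Iterable[int], min_count: int = 2
) -> tuple[list[AssemblyStats], int, dict[int, list[Contig]]]:
    """Assemble at each odd k; return (stats per k, selected k, contigs
    per k). Selection: max pct_reads_assembled, ties by larger N50, then
    smaller k."""
    reads = list(reads)
    if not reads:
        raise ValueError("empty read stream")
    k_values = sorted(set(k_values))
    if not k_values:
        raise ValueError("no k values supplied")
    stats: list[AssemblyStats] = []
    per_k: dict[int, list[Contig]] = {}
    for k in k_values:
        contigs = build_unitigs(reads, k, min_count)
        per_k[k] = contigs
        stats.append(assembly_stats(contigs, k, len(reads), reads_assembled(reads, contigs, k)))
    best = max(stats, key=lambda s: (s.pct_reads_assembled, s.n50, -s.k))
    return stats, best.k, per_k
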
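"""Nucleotide similarity search and the novel-transcript cascade.

The search is a desk-scale local aligner with the classic seed-and-extend
contract: exact k-mer seeds on both strands, then banded local dynamic
programming (affine gaps, Gotoh recurrence) around the seeded diagonal.
Hits report percent identity (matches / alignment columns, the BLAST
convention) and query coverage (aligned query span / query length), the
two quantities the annotation rule thresholds.

The cascade assigns every transcript exactly one of {known, novel,
excluded}, walking the annotation order used when the abscission-zone
array content was assembled: primary (tomato-like) reference first, then
cross-species references, then contaminant screens, and finally the
<10%-query-coverage filter of surviving candidates against everything
already called known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._seq import iter_kmers, revcomp

log = logging.getLogger(__name__)

#: seed size shared by the aligner and the simulator's novelty screen
DEFAULT_SEED_K = 13

NEG_INF = float("-inf")


@dataclass
class ScoringScheme:
    """Alignment scoring. A gap of length L costs -(open + (L-1)*extend)
    with the open penalty charged on the first gapped base."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    band: int = 32  # max deviation from the seeded diagonal


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    aln_len: int
    matches: int
    mismatches: int
    gaps: int  # gap columns in the alignment
    identity_pct: float
    q_cov_pct: float
    strand: str  # '+' or '-'
    score: int
    q_start: int  # 0-based, on the forward query
    q_end: int  # exclusive
    s_start: int
    s_end: int

    def to_tabular(self) -> str:
        """12-column tab layout (outfmt-6 dialect); evalue slot carries 0,
        bitscore slot carries the raw DP score."""
        return "\t".join(
            str(x)
            for x in (
                self.query_id,
                self.subject_id,
                f"{self.identity_pct:.2f}",
                self.aln_len,
                self.mismatches,
                self.gaps,
                self.q_start + 1,
                self.q_end,
                self.s_start + 1,
                self.s_end,
                0,
                self.score,
            )
        )


@dataclass
class CascadeLabel:
    transcript_id: str
    label: str  # known | novel | excluded
    evidence: int  # deciding step: 2, 3, 5, 7 or 9


class SubjectIndex:
    """Exact k-mer index over a set of subject sequences (forward strand;
    the query is searched on both strands instead)."""

    def __init__(self, subjects: dict[str, str], seed_k: int = DEFAULT_SEED_K):
        self.subjects = dict(subjects)
        self.seed_k = seed_k
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in self.subjects.items():
            for i in range(len(seq) - seed_k + 1):
                km = seq[i : i + seed_k]
                if "N" in km:
                    continue
                self.kmers.setdefault(km, []).append((sid, i))

    def __len__(self) -> int:
        return len(self.subjects)


def _banded_local(q: str, s: str, dlo: int, dhi: int, sc: ScoringScheme):
    """Local affine-gap DP restricted to diagonals dlo <= (i - j) <= dhi
    (1-based i over query, j over subject). Returns (score, i, j, H, E, F)
    with full score matrices for traceback, or None if no positive cell."""
    n, m = len(q), len(s)
    W = dhi - dlo + 1

    # matrices stored band-relative: column index c = (i - j) - dlo
    H = [[NEG_INF] * W for _ in range(n + 1)]
    E = [[NEG_INF] * W for _ in range(n + 1)]
    F = [[NEG_INF] * W for _ in range(n + 1)]

    match, mismatch = sc.match, sc.mismatch
    go, ge = sc.gap_open, sc.gap_extend

    best = 0
    bi = bj = 0
    for i in range(0, n + 1):
        Hi, Ei, Fi = H[i], E[i], F[i]
        jlo = max(0, i - dhi)
        jhi = min(m, i - dlo)
        if jlo > jhi:
            continue
        Hp = H[i - 1] if i else None
        Fp = F[i - 1] if i else None
        qi = q[i - 1] if i else ""
        for j in range(jlo, jhi + 1):
            c = i - j - dlo
            if i == 0 or j == 0:
                Hi[c] = 0.0
                continue
            # E: gap in query (consume subject, move left => diagonal c+1)
            e = NEG_INF
            if c + 1 < W:
                hl, el = Hi[c + 1], Ei[c + 1]
                e = max(hl + go, el + ge)
            Ei[c] = e
            # F: gap in subject (consume query, move up => same j, c-1 in prev row)
            f = NEG_INF
            if c - 1 >= 0:
                hu, fu = Hp[c - 1], Fp[c - 1]
                f = max(hu + go, fu + ge)
            Fi[c] = f
            diag = Hp[c] + (match if qi == s[j - 1] else mismatch)
            h = diag
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0.0
            Hi[c] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    return best, bi, bj, H, E, F


def _traceback(q: str, s: str, dlo: int, bi: int, bj: int, H, E, F, sc: ScoringScheme):
    """Recover match/mismatch/gap counts and spans from the DP matrices."""
    matches = mismatches = gaps = 0
    i, j = bi, bj
    state = "H"
    go, ge = sc.gap_open, sc.gap_extend
    while i > 0 and j > 0:
        c = i - j - dlo
        if state == "H":
            h = H[i][c]
            if h == 0:
                break
            diag = H[i - 1][c] + (sc.match if q[i - 1] == s[j - 1] else sc.mismatch)
            if h == diag:
                if q[i - 1] == s[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif h == E[i][c]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query: consume subject
            gaps += 1
            c1 = c + 1
            if E[i][c] == H[i][c1] + go:
                state = "H"
            j -= 1
        else:  # F: gap in subject: consume query
            gaps += 1
            if F[i][c] == H[i - 1][c - 1] + go:
                state = "H"
            i -= 1
    return matches, mismatches, gaps, i, j  # (i, j) = start (0-based, inclusive)


def align_pair(
    query: str,
    subject: str,
    diagonals: tuple[int, int] | None = None,
    scoring: ScoringScheme | None = None,
):
    """Align one query/subject pair with banded (or, if `diagonals` is
    None, full) local DP. Returns the raw alignment summary or None."""
    sc = scoring or ScoringScheme()
    n, m = len(query), len(subject)
    if diagonals is None:
        dlo, dhi = -m, n
    else:
        dlo, dhi = diagonals
        dlo, dhi = max(dlo, -m), min(dhi, n)
    res = _banded_local(query, subject, dlo, dhi, sc)
    if res is None:
        return None
    score, bi, bj, H, E, F = res
    matches, mismatches, gaps, i0, j0 = _traceback(query, subject, dlo, bi, bj, H, E, F, sc)
    return {
        "score": int(score),
        "matches": matches,
        "mismatches": mismatches,
        "gaps": gaps,
        "q_start": i0,
        "q_end": bi,
        "s_start": j0,
        "s_end": bj,
    }


def search(
    query: str,
    index: SubjectIndex,
    query_id: str = "query",
    scoring: ScoringScheme | None = None,
) -> list[AlignmentHit]:
    """Seed-and-extend search of `query` against an indexed subject set.

    One hit is reported per (subject, strand) that seeds, extended by
    banded local DP around the seeded diagonal range. Hits are sorted by
    (q_cov_pct, identity_pct) descending with subject_id as the final,
    deterministic tie-break. An empty index yields an empty list.
    """
    sc = scoring or ScoringScheme()
    k = index.seed_k
    qlen = len(query)
    if qlen < k or not index.subjects:
        return []
    hits: list[AlignmentHit] = []
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        # seed diagonals per subject
        diags: dict[str, list[int]] = {}
        for i in range(qlen - k + 1):
            km = q[i : i + k]
            for sid, j in index.kmers.get(km, ()):  # noqa: B905
                diags.setdefault(sid, []).append(i - j)
        for sid, ds in diags.items():
            s = index.subjects[sid]
            dlo, dhi = min(ds) - sc.band, max(ds) + sc.band
            # guard against absurdly wide bands from repeat seeds
            if dhi - dlo > max(qlen, len(s)):
                # centre on the modal diagonal instead
                mode = max(set(ds), key=lambda d: (ds.count(d), -d))
                dlo, dhi = mode - sc.band, mode + sc.band
            aln = align_pair(q, s, (dlo, dhi), sc)
            if aln is None:
                continue
            aln_len = aln["matches"] + aln["mismatches"] + aln["gaps"]
            if aln_len == 0:
                continue
            q_span = aln["q_end"] - aln["q_start"]
            if strand == "+":
                q_start, q_end = aln["q_start"], aln["q_end"]
            else:  # report on forward-query coordinates
                q_start, q_end = qlen - aln["q_end"], qlen - aln["q_start"]
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=sid,
                    aln_len=aln_len,
                    matches=aln["matches"],
                    mismatches=aln["mismatches"],
                    gaps=aln["gaps"],
                    identity_pct=100.0 * aln["matches"] / aln_len,
                    q_cov_pct=100.0 * q_span / qlen,
                    strand=strand,
                    score=aln["score"],
                    q_start=q_start,
                    q_end=q_end,
                    s_start=aln["s_start"],
                    s_end=aln["s_end"],
                )
            )
    hits.sort(key=lambda h: (-h.q_cov_pct, -h.identity_pct, h.subject_id, h.strand))
    return hits


def is_annotated(hits: list[AlignmentHit], id_thresh: float = 50.0, cov_thresh: float = 70.0) -> bool:
    """Annotation rule: ANY hit with identity and query coverage strictly
    above the thresholds (the "more than 50% identity and 70% query
    coverage" criterion, taken literally)."""
    return any(h.identity_pct > id_thresh and h.q_cov_pct > cov_thresh for h in hits)


def best_query_coverage(hits: list[AlignmentHit]) -> float:
    return max((h.q_cov_pct for h in hits), default=0.0)


def run_cascade(
    transcripts: dict[str, str],
    primary_ref: dict[str, str],
    secondary_refs: list[dict[str, str]] | None = None,
    contaminant_refs: list[dict[str, str]] | None = None,
    seed_k: int = DEFAULT_SEED_K,
    id_thresh: float = 50.0,
    cov_thresh: float = 70.0,
    novel_cov_thresh: float = 10.0,
    scoring: ScoringScheme | None = None,
) -> list[CascadeLabel]:
    """Assign each transcript exactly one {known, novel, excluded} label.

    Step order (evidence number recorded on each label):
      2. annotated against the primary reference            -> known
      3. annotated against any secondary reference          -> known
      5. matches a contaminant reference                    -> excluded
      7. matches a secondary reference on the rescreen      -> known
      9. best query coverage vs the union of known
         transcripts < novel_cov_thresh                     -> novel,
         otherwise excluded (neither annotated nor novel).
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    secondary_refs = secondary_refs or []
    contaminant_refs = contaminant_refs or []
    sc = scoring or ScoringScheme()

    idx_primary = SubjectIndex(primary_ref, seed_k)
    merged_secondary: dict[str, str] = {}
    for ref in secondary_refs:
        merged_secondary.update(ref)
    idx_secondary = SubjectIndex(merged_secondary, seed_k)
    merged_contaminant: dict[str, str] = {}
    for ref in contaminant_refs:
        merged_contaminant.update(ref)
    idx_contaminant = SubjectIndex(merged_contaminant, seed_k)

    labels: dict[str, CascadeLabel] = {}
    candidates: list[str] = []
    for tid in transcripts:
        seq = transcripts[tid]
        if is_annotated(search(seq, idx_primary, tid, sc), id_thresh, cov_thresh):
            labels[tid] = CascadeLabel(tid, "known", 2)
        elif is_annotated(search(seq, idx_secondary, tid, sc), id_thresh, cov_thresh):
            labels[tid] = CascadeLabel(tid, "known", 3)
        else:
            candidates.append(tid)

    survivors: list[str] = []
    for tid in candidates:
        seq = transcripts[tid]
        if is_annotated(search(seq, idx_contaminant, tid, sc), id_thresh, cov_thresh):
            labels[tid] = CascadeLabel(tid, "excluded", 5)
        elif is_annotated(search(seq, idx_secondary, tid, sc), id_thresh, cov_thresh):
            labels[tid] = CascadeLabel(tid, "known", 7)
        else:
            survivors.append(tid)

    known_seqs = {tid: transcripts[tid] for tid, lab in labels.items() if lab.label == "known"}
    idx_known = SubjectIndex(known_seqs, seed_k)
    for tid in survivors:
        cov = best_query_coverage(search(transcripts[tid], idx_known, tid, sc))
        if cov < novel_cov_thresh:
            labels[tid] = CascadeLabel(tid, "novel", 9)
        else:
            labels[tid] = CascadeLabel(tid, "excluded", 9)

    return [labels[tid] for tid in transcripts]
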
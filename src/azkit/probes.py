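"""AZ-array probe design, specificity screening and layout accounting.

Probes are 60-mer windows (shorter only when the transcript itself is
shorter, never below 28 bp) taken at deterministic, maximally spread
positions, in both sense and antisense orientation; the per-category
multiplicity (annotated 1+1, novel 2+2, ...) is an AllocationPolicy.

Specificity screening follows the published criteria read strictly: a
qualifying alignment has length 31-60 bp, at most 2 mismatches ("<3")
and at most 1 gap ("<2"); a probe with exactly one qualifying hit that
is its own source transcript is `specific`, two or more qualifying hits
make it `cross_hyb`, anything else (including probes shorter than 28 bp)
is `rejected`.

Array layout: exact-duplicate probe sequences are removed (first kept,
deterministic order), mandatory content (designed + technical-QC +
vendor + controls) must fit the feature capacity, and the remaining
spots are filled by duplicating specific probes round-robin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from ._seq import revcomp
from .homology import ScoringScheme, SubjectIndex, search

log = logging.getLogger(__name__)

PROBE_LEN = 60
MIN_PROBE_LEN = 28


@dataclass
class Probe:
    probe_id: str
    transcript_id: str
    orientation: str  # sense | antisense
    seq: str
    start: int  # window start on the source transcript, 0-based
    probe_class: str = "unclassified"


@dataclass
class AllocationPolicy:
    """category -> (sense probes, antisense probes) per transcript."""

    per_category: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "annotated": (1, 1),
            "novel": (2, 2),
            "cross_species": (1, 1),
            "legacy": (1, 1),
            "technical_qc": (2, 2),
        }
    )

    def counts(self, category: str) -> tuple[int, int]:
        try:
            return self.per_category[category]
        except KeyError:
            raise KeyError(f"no probe allocation for category {category!r}") from None

    def probes_per_transcript(self, category: str) -> int:
        s, a = self.counts(category)
        return s + a


@dataclass
class ArrayLayout:
    designed_probes: int
    qc_probes: int
    vendor_probes: int
    filler_duplicates: int
    control_features: int

    @property
    def total_probes(self) -> int:
        return self.designed_probes + self.qc_probes + self.vendor_probes + self.filler_duplicates

    @property
    def total_features(self) -> int:
        return self.total_probes + self.control_features

    def to_dict(self) -> dict[str, int]:
        return {
            "designed_probes": self.designed_probes,
            "qc_probes": self.qc_probes,
            "vendor_probes": self.vendor_probes,
            "filler_duplicates": self.filler_duplicates,
            "total_probes": self.total_probes,
            "control_features": self.control_features,
            "total_features": self.total_features,
        }


def _spread_starts(span: int, n: int) -> list[int]:
    """n deterministic, maximally spread window starts over [0, span]."""
    if n <= 0:
        return []
    if n == 1:
        return [span // 2]
    return [round(i * span / (n - 1)) for i in range(n)]


def generate_candidates(
    transcript_id: str,
    seq: str,
    category: str,
    policy: AllocationPolicy | None = None,
    probe_len: int = PROBE_LEN,
    min_len: int = MIN_PROBE_LEN,
) -> list[Probe]:
    """Candidate probes for one transcript under the category's policy.
    Transcripts shorter than `min_len` yield no probes (logged shortfall,
    the zero-probe path for repeat/vector-style filtering)."""
    policy = policy or AllocationPolicy()
    seq = seq.upper()
    L = len(seq)
    if L < min_len:
        log.warning("no probes designed for %s (%d bp < %d bp minimum)", transcript_id, L, min_len)
        return []
    w = min(probe_len, L)
    n_sense, n_anti = policy.counts(category)
    probes = []
    for start in _spread_starts(L - w, n_sense):
        window = seq[start : start + w]
        probes.append(Probe(f"{transcript_id}|s|{start}", transcript_id, "sense", window, start))
    for start in _spread_starts(L - w, n_anti):
        window = seq[start : start + w]
        probes.append(Probe(f"{transcript_id}|a|{start}", transcript_id, "antisense", revcomp(window), start))
    return probes


def classify_probe(
    probe: Probe,
    index: SubjectIndex,
    max_mismatch: int = 2,
    max_gaps: int = 1,
    min_aln: int = 31,
    max_aln: int = 60,
    scoring: ScoringScheme | None = None,
) -> str:
    """Classify one probe against the indexed transcript set.

    A qualifying hit has alignment length in [min_aln, max_aln], at most
    `max_mismatch` mismatches and `max_gaps` gap columns. Exactly one
    qualifying hit that is the source transcript -> specific; two or more
    qualifying hits -> cross_hyb; otherwise rejected. A probe with no hit
    at all on its declared source transcript is an integrity error.
    """
    if len(probe.seq) < MIN_PROBE_LEN:
        probe.probe_class = "rejected"
        return "rejected"
    hits = search(probe.seq, index, probe.probe_id, scoring)
    if not any(h.subject_id == probe.transcript_id for h in hits):
        raise ValueError(f"probe {probe.probe_id} has no hit on its source transcript")
    qualifying = [
        h
        for h in hits
        if min_aln <= h.aln_len <= max_aln and h.mismatches <= max_mismatch and h.gaps <= max_gaps
    ]
    subjects = {h.subject_id for h in qualifying}
    if len(subjects) >= 2:
        cls = "cross_hyb"
    elif len(subjects) == 1 and probe.transcript_id in subjects:
        cls = "specific"
    elif len(subjects) == 1:
        cls = "cross_hyb"  # sole qualifying hit is a non-target
    else:
        cls = "rejected"
    probe.probe_class = cls
    return cls


def design_probes(
    transcripts: dict[str, str],
    categories: dict[str, str],
    policy: AllocationPolicy | None = None,
    screen: bool = True,
    scoring: ScoringScheme | None = None,
) -> list[Probe]:
    """Generate and (optionally) specificity-screen probes for a labeled
    transcript set."""
    policy = policy or AllocationPolicy()
    probes: list[Probe] = []
    for tid, seq in transcripts.items():
        probes.extend(generate_candidates(tid, seq, categories[tid], policy))
    if screen:
        index = SubjectIndex(transcripts)
        for p in probes:
            classify_probe(p, index, scoring=scoring)
    return probes


def layout_accounting(
    designed: int, qc_probes: int, vendor_probes: int, control_features: int, capacity: int
) -> ArrayLayout:
    """Pure feature accounting: remaining capacity after controls and
    mandatory probes becomes filler duplicates."""
    mandatory = designed + qc_probes + vendor_probes + control_features
    if capacity < mandatory:
        raise ValueError(f"capacity {capacity} below mandatory content {mandatory}")
    return ArrayLayout(
        designed_probes=designed,
        qc_probes=qc_probes,
        vendor_probes=vendor_probes,
        filler_duplicates=capacity - mandatory,
        control_features=control_features,
    )


def build_layout(
    probes: Sequence[Probe],
    capacity: int,
    control_features: int,
    vendor_probes: int = 0,
    qc_probes: int = 0,
) -> tuple[ArrayLayout, list[Probe]]:
    """Deduplicate, account, and fill the array.

    Exact duplicate probe sequences are dropped keeping the first in the
    given order; leftover capacity is filled by duplicating specific
    probes round-robin. Returns the layout and the final probe list
    (deduplicated probes followed by filler copies)."""
    seen: set[str] = set()
    deduped: list[Probe] = []
    for p in probes:
        if p.seq not in seen:
            seen.add(p.seq)
            deduped.append(p)
    layout = layout_accounting(len(deduped), qc_probes, vendor_probes, control_features, capacity)
    specific = [p for p in deduped if p.probe_class == "specific"]
    filler: list[Probe] = []
    if layout.filler_duplicates:
        if not specific:
            raise ValueError("no specific probes available to fill remaining spots")
        for i in range(layout.filler_duplicates):
            src = specific[i % len(specific)]
            filler.append(
                Probe(f"{src.probe_id}|fill{i}", src.transcript_id, src.orientation, src.seq, src.start, src.probe_class)
            )
    return layout, deduped + filler


def allocation_summary(
    category_counts: dict[str, int], policy: AllocationPolicy | None = None
) -> dict[str, int]:
    """Per-category probe totals (count x probes-per-transcript, before
    shortfall and redundancy filtering) plus grand totals."""
    policy = policy or AllocationPolicy()
    out: dict[str, int] = {}
    for cat, n in category_counts.items():
        if n < 0:
            raise ValueError(f"negative transcript count for {cat!r}")
        out[cat] = n * policy.probes_per_transcript(cat)
    rnaseq = [c for c in ("annotated", "novel", "cross_species") if c in category_counts]
    out["rnaseq_transcripts"] = sum(category_counts[c] for c in rnaseq)
    out["array_transcripts"] = out["rnaseq_transcripts"] + category_counts.get("legacy", 0)
    out["total_probes"] = sum(
        category_counts[c] * policy.probes_per_transcript(c)
        for c in category_counts
        if c != "technical_qc"
    )
    return out
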
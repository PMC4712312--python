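"""Five-group differential classification on log2(LAZ/FAZ) enrichment.

Transcripts expressed in both conditions fall into Group A (up in LAZ,
log2 ratio > 1), Group B (down, < -1) or Group C (between, boundary
values inclusive so the partition is total); transcripts expressed in
exactly one condition are A1 (LAZ only) or B1 (FAZ only). Display values
round half-away-from-zero to the requested precision, the behavior the
published worked values follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

GROUPS = ("A", "B", "C", "A1", "B1")


@dataclass
class DEGRecord:
    transcript_id: str
    enr_faz: float
    enr_laz: float
    log2_ratio: float | None  # None for A1/B1 (ratio undefined)
    group: str


@dataclass
class GroupSummary:
    counts: dict[str, int]
    total: int  # transcripts expressed in both conditions = |A|+|B|+|C|


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (2.345 -> 2.35, -2.345 -> -2.35)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def log2_ratio(enr_laz: float, enr_faz: float) -> float:
    """log2(LAZ/FAZ); defined only when both enrichments are positive."""
    if enr_laz <= 0 or enr_faz <= 0:
        raise ValueError("log2 ratio undefined when either enrichment is zero")
    return math.log2(enr_laz / enr_faz)


def classify(enr_faz: float, enr_laz: float, lfc: float = 1.0, min_enrichment: float = 0.0) -> str:
    """Group label for one transcript. `min_enrichment` is an optional
    floor below which a condition counts as unexpressed (default 0: only
    true zeros are exclusive). Both-zero input is an error (the
    transcript is absent, not classifiable)."""
    faz = enr_faz if enr_faz > min_enrichment else 0.0
    laz = enr_laz if enr_laz > min_enrichment else 0.0
    if faz == 0 and laz == 0:
        raise ValueError("transcript absent from both conditions")
    if faz == 0:
        return "A1"
    if laz == 0:
        return "B1"
    # product comparisons instead of log2(laz/faz) > lfc: exact at the
    # boundary and exactly antisymmetric under condition swap
    factor = 2.0**lfc
    if laz > faz * factor:
        return "A"
    if laz * factor < faz:
        return "B"
    return "C"


def classify_records(
    faz: Mapping[str, float],
    laz: Mapping[str, float],
    lfc: float = 1.0,
    min_enrichment: float = 0.0,
) -> list[DEGRecord]:
    """Join two per-condition enrichment maps into DEG records; transcripts
    with zero enrichment in both conditions are dropped (absent)."""
    records = []
    for tid in sorted(set(faz) | set(laz)):
        f = faz.get(tid, 0.0)
        z = laz.get(tid, 0.0)
        if f <= min_enrichment and z <= min_enrichment:
            continue
        group = classify(f, z, lfc, min_enrichment)
        ratio = log2_ratio(z, f) if group in ("A", "B", "C") else None
        records.append(DEGRecord(tid, f, z, ratio, group))
    return records


def summarize_groups(records: Sequence[DEGRecord]) -> GroupSummary:
    counts = {g: 0 for g in GROUPS}
    for r in records:
        counts[r.group] += 1
    return GroupSummary(counts, counts["A"] + counts["B"] + counts["C"])


def family_tally(
    records: Sequence[DEGRecord], family_map: Mapping[str, str]
) -> tuple[dict[str, dict[str, int]], int]:
    """Per-group, per-family contingency counts (e.g. transcription-factor
    families over the five groups). Unmapped ids are counted, not tallied;
    mapped + unmapped equals the number of records."""
    tally: dict[str, dict[str, int]] = {g: {} for g in GROUPS}
    unmapped = 0
    for r in records:
        fam = family_map.get(r.transcript_id)
        if fam is None:
            unmapped += 1
            continue
        tally[r.group][fam] = tally[r.group].get(fam, 0) + 1
    return tally, unmapped


def records_to_tsv(records: Sequence[DEGRecord], ndigits: int = 2) -> str:
    """Table-shaped TSV: id, LAZ, FAZ, rounded log2 ratio, group."""
    lines = ["transcript_id\tenr_LAZ\tenr_FAZ\tlog2_ratio\tgroup"]
    for r in records:
        ratio = "" if r.log2_ratio is None else f"{round_half_away(r.log2_ratio, ndigits):.{ndigits}f}"
        lines.append(f"{r.transcript_id}\t{r.enr_laz:.6g}\t{r.enr_faz:.6g}\t{ratio}\t{r.group}")
    return "\n".join(lines) + "\n"
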
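"""qPCR comparative-CT quantification and ontology-term tallies.

Relative expression by the comparative cycle-threshold method:
    dCt   = Ct(gene) - Ct(reference gene), per sample (replicates
            averaged by arithmetic mean before differencing)
    ddCt  = dCt(target sample) - dCt(calibrator sample)
    value = 2 ** -ddCt
The statistic is self-calibrating (target == calibrator gives 1.0) and
invariant under a global shift of every Ct.

Term tallies are plain frequency counts of (category, term) annotations
over a transcript subset — the kind of top-10 molecular function /
biological process / cellular component panel used to profile an
annotation set. No enrichment testing, only counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


@dataclass
class CtTable:
    """Ct measurements: rows of (gene, sample, replicate, ct)."""

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        for sample, grp in self.data.groupby("sample"):
            if self.reference_gene not in set(grp["gene"]):
                raise ValueError(f"reference gene {self.reference_gene!r} missing for sample {sample!r}")

    @classmethod
    def from_csv(cls, path, reference_gene: str) -> "CtTable":
        return cls(pd.read_csv(path), reference_gene)

    def mean_ct(self, gene: str, sample: str) -> float:
        rows = self.data[(self.data["gene"] == gene) & (self.data["sample"] == sample)]
        if rows.empty:
            raise KeyError(f"no Ct for gene {gene!r} in sample {sample!r}")
        return float(rows["ct"].mean())


def ddct(ct: CtTable, gene: str, target_sample: str, calibrator_sample: str) -> float:
    """Relative expression 2^-ddCt of `gene` in target vs calibrator."""
    d_target = ct.mean_ct(gene, target_sample) - ct.mean_ct(ct.reference_gene, target_sample)
    d_cal = ct.mean_ct(gene, calibrator_sample) - ct.mean_ct(ct.reference_gene, calibrator_sample)
    return 2.0 ** -(d_target - d_cal)


@dataclass
class TermTally:
    counts: dict[str, dict[str, int]]  # category -> term -> count
    n_with_term: int  # transcripts in the subset carrying >= 1 term

    def top_k(self, category: str, k: int = 10) -> list[tuple[str, int]]:
        """Top terms by count, alphabetical tie-break (deterministic)."""
        items = self.counts.get(category, {})
        return sorted(items.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def tally_terms(
    annotations: Mapping[str, list[tuple[str, str]]],
    subset: Iterable[str] | None = None,
) -> TermTally:
    """Count (category, term) occurrences over `subset` transcript ids
    (all annotated transcripts when subset is None)."""
    ids = set(subset) if subset is not None else set(annotations)
    counts: dict[str, dict[str, int]] = {}
    n_with = 0
    for tid in ids:
        terms = annotations.get(tid, [])
        if terms:
            n_with += 1
        for category, term in terms:
            cat = counts.setdefault(category, {})
            cat[term] = cat.get(term, 0) + 1
    return TermTally(counts, n_with)


def read_annotations(path) -> dict[str, list[tuple[str, str]]]:
    """3-column TSV (transcript, category, term) -> annotation map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript", "category", "term"])
    out: dict[str, list[tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.transcript, []).append((row.category, row.term))
    return out
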
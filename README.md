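# azkit

A desk-scale, fully tested re-implementation of the computational
pipeline used to build and compare two pooled tomato abscission-zone
(AZ) transcriptomes — the flower-pedicel AZ (FAZ) and the leaf-petiole
AZ (LAZ) — and to turn the result into an AZ-specific oligonucleotide
microarray. It is written for computational biologists who want to
study, test or extend the *logic* of that pipeline (thresholds,
classification rules, probe criteria, accounting) without the deposited
sequencing libraries or the production tools behind it: every external
tool is replaced by a small, contract-equivalent algorithm, and a seeded
synthetic-data generator provides ground truth the real experiment
cannot.

## What it computes

- **Read QC** — keep a read iff strictly more than 70% of bases have
  Phred Q > 20 (strict on both counts); exact end-anchored adapter
  trimming; read/base-level summary statistics.
- **Assembly** — a canonical de Bruijn unitig assembler (multiplicity
  floor 2, no tip/bubble processing) with an odd-k sweep selecting the
  k that maximizes the percentage of assembled reads; N50 and the full
  contig statistics panel.
- **Homology** — seed-and-extend banded local alignment (+1/−2 match/
  mismatch, −3/−1 affine gaps) reporting percent identity and query
  coverage; the annotation rule (identity > 50% AND coverage > 70%);
  the stepwise cascade that partitions transcripts into
  known / novel / excluded, with novelty requiring < 10% query coverage
  against all known transcripts.
- **Quantification** — a k-mer pseudo-mapper and the expression
  statistic `enrichment = average read depth × coverage`.
- **DEG classification** — log2(LAZ/FAZ) five-group scheme:
  A (> 1), B (< −1), C (neutral, boundary inclusive), A1/B1
  (condition-exclusive).
- **Probe design** — sense/antisense ≤60-mers per transcript category
  (annotated 1+1, novel 2+2), specificity screening (alignment length
  31–60, < 3 mismatches, < 2 gaps, single hit on target), redundancy
  filtering and exact array-layout accounting.
- **Validation** — comparative-CT qPCR (2^−ΔΔCt) and ontology-term
  frequency tallies.

See `docs/methods.md` for the model, parameter defaults, and every
place where a definition had to be fixed by interpretation.

## Worked example

Label a synthetic transcript set with the novel-transcript cascade
(`python examples/03_novel_cascade.py`):

```
  step 2:  30 transcripts -> known
  step 3:   3 transcripts -> known
  step 5:   4 transcripts -> excluded
  step 9:   8 transcripts -> novel
truth recovery: 45/45
```

Thirty transcripts annotate against the primary (tomato-like) reference
(step 2), three only against the cross-species references (step 3), four
match the contaminant screen and are excluded (step 5), and eight pass
the < 10%-coverage novelty filter (step 9) — exactly reproducing the
generator's construction.

Probe accounting at published scale
(`python examples/05_probe_array.py`):

```
published-scale: 100276 initial probes for 41315 transcripts; final array 176026 probes / 180880 features
```

i.e. 41,315 array transcripts yield 100,276 category-allocated probes;
after selection, 93,674 + 200 technical-QC + 2,278 vendor probes plus
79,874 filler duplicates give 176,026 probes, and with 4,854 vendor
controls the 4×180K array carries 180,880 features.

The other examples cover simulation+QC, the assembly sweep,
quantification+classification, and ΔΔCt validation. A thin `az-kit`
CLI (subcommands `simulate`, `qc`, `assemble`, `cascade`, `quantify`,
`classify`, `probes`, `ddct`, `go-tally`, `run`) wraps the same
functions for shell use.

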
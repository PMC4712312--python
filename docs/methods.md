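# Methods

`azkit` re-creates, at desk scale, the computational chain used to build
and compare two pooled abscission-zone (AZ) transcriptomes — the tomato
flower-pedicel AZ (FAZ) and leaf-petiole AZ (LAZ) — and to turn the
result into an AZ-specific oligonucleotide microarray. Every stage is a
small, fully specified algorithm with the same *contract* as the
production tool it stands in for (Velvet/Oases, Bowtie, BLAST, vendor
probe pipelines), so that the statistical logic of the study — not the
third-party software — is what the package implements and tests.

## The pipeline model

1. **Read QC.** A read is kept when strictly more than 70% of its bases
   have Phred quality strictly above Q20. Both inequalities are strict:
   a read with exactly 70% qualifying bases, or bases at exactly Q20,
   fails. This is a deliberate literal reading; both thresholds are
   configuration values (`q_threshold`, `frac_threshold`) so the closed
   reading is one flag away. Adapter trimming is exact and end-anchored
   (adapter or its reverse complement at either read end); fuzzy adapter
   matching is out of scope. Pairs are dropped synchronously: if either
   mate fails, both do. The base-level statistic `hq_base_pct` is
   100 · (bases with Q > 20)/(total bases) — the source material reports
   this quantity without defining it, so the formula here is our
   interpretation and is flagged as such.

2. **Assembly.** A canonical k-mer de Bruijn unitig assembler: k-mers
   below a multiplicity floor (default 2) are discarded as presumed
   errors, edges connect surviving k-mers overlapping by k−1, and the
   contigs are the maximal non-branching paths, reported in the
   lexicographically smaller orientation. There is no tip clipping,
   bubble popping, scaffolding or isoform resolution; on error-containing
   reads the retained error k-mers therefore surface as short junk
   unitigs and depress N50 — a documented consequence of floor-only
   denoising, visible in the run report rather than hidden. The odd-k
   sweep assembles at each requested k and selects the k maximizing the
   percentage of assembled reads (a read is assembled when all of its
   k-mers survive into retained unitigs), with larger N50 and then
   smaller k as tie-breaks. N50 is the largest L such that contigs of
   length ≥ L hold at least half the total assembly length.

3. **Homology search.** Seed-and-extend local alignment: exact 13-mer
   seeds on both strands nominate subjects and diagonals; a banded local
   affine-gap DP (match +1, mismatch −2, gap open −3, gap extend −1,
   band ±32 around the seeded diagonal range) produces one hit per
   (subject, strand). Identity is matches/alignment-columns (the BLAST
   convention) and query coverage is aligned-query-span/query-length;
   neither is defined in the source material, so both definitions are
   explicit here and configurable. The annotation rule is: ANY hit with
   identity > 50% and query coverage > 70% (strict). E-value statistics
   and protein-space search are not implemented; the nucleotide path
   carries the whole cascade.

4. **Novel-transcript cascade.** Labels are assigned in a fixed order,
   with the deciding step recorded: annotated against the primary
   (tomato-like) reference → known (step 2); else against the secondary
   (Arabidopsis/tobacco-like) references → known (step 3); else matching
   a contaminant reference → excluded (step 5); else matching secondary
   on the rescreen → known (step 7); surviving candidates are novel only
   if their best query coverage against the union of known transcripts
   is < 10% (step 9), otherwise excluded. The original steps 5–7 operate
   on re-assembled unaligned *reads*; here the cascade consumes
   transcripts/contigs, so those steps are realized at transcript
   granularity (and step 7 is consequently rarely decisive). Candidates
   failing the step-9 coverage screen are neither annotated nor novel;
   labeling them `excluded` keeps the three-way partition total.

5. **Quantification.** A k-mer pseudo-mapper (21-mer seeds at three
   fixed read offsets, both strands, ungapped verification with ≤ 3
   substitutions) assigns each read to at most one transcript — fewest
   mismatches, lexicographic transcript id as the deterministic
   tie-break; mates map independently. Per transcript and condition,
   enrichment = average read depth × coverage, with coverage the
   fraction of bases at depth ≥ 1 and average depth taken over covered
   bases. Averaging over covered bases is the reading under which the
   product form does not double-penalize partial coverage; the
   all-bases alternative is available (`depth_over="all"`). No
   library-size normalization is applied — the enrichment formula, as
   stated, compares raw values.

6. **Five-group classification.** For transcripts expressed in both
   conditions, log2(LAZ/FAZ) > 1 → Group A (up in LAZ), < −1 → Group B,
   otherwise Group C; transcripts expressed exclusively in LAZ or FAZ
   are A1 and B1. The boundary |log2 ratio| = 1 is assigned to C so the
   partition is total (the source leaves exactly ±1 unassigned).
   Internally the comparisons are products (laz > faz·2^lfc), which is
   exact at the boundary and exactly antisymmetric under condition swap.
   Display rounding is half-away-from-zero at the table's precision
   (2 decimals or 1); a few published cells (e.g. −4.11 where the pair
   computes −4.12) imply unrounded upstream values, so numeric tests
   target rows that reproduce under this rule. Group totals count
   A+B+C (both-condition transcripts); A1/B1 are reported separately.

7. **Probe design.** Sense and antisense windows of length
   min(60, transcript length) at deterministic, maximally spread
   positions; transcripts under 28 bp yield no probes (the zero-probe
   path that repeat/vector masking produces in the real pipeline).
   Window placement is our stand-in — the real placement is a vendor
   algorithm. Specificity: a qualifying alignment has length 31–60,
   ≤ 2 mismatches ("<3") and ≤ 1 gap ("<2"); exactly one qualifying
   subject which is the source transcript → specific; two or more
   qualifying subjects → cross-hybridizing; otherwise rejected (note a
   28–30 bp probe can never have a 31-column qualifying alignment — the
   published criteria are internally tight there, and the strict reading
   is kept). Hit multiplicity is counted per distinct subject so that a
   palindromic self-hit on both strands does not masquerade as
   cross-hybridization. Layout: exact-sequence deduplication (first
   kept), then mandatory content (designed + technical-QC + vendor +
   controls) must fit the feature capacity and the remainder is filled
   with round-robin duplicates of specific probes. The accounting
   identities (total probes = designed + QC + vendor + filler; total
   features = probes + controls) are enforced exactly.

8. **Validation statistics.** Comparative-CT: replicate Ct values are
   arithmetically averaged *before* differencing (the aggregation order
   is unstated in the source; mean-then-difference is the common
   convention), ΔCt = Ct(gene) − Ct(reference), ΔΔCt = ΔCt(target) −
   ΔCt(calibrator), relative expression 2^−ΔΔCt. Term tallies are pure
   frequency counts with deterministic alphabetical tie-breaks; no
   enrichment p-values are computed, matching the frequency-chart
   presentation being emulated.

## The synthetic-data generator

The generator is the package's study stand-in, not a test fixture: it
emits the labeled truth a real experiment cannot provide.

- **Study geometry.** Two conditions (FAZ, LAZ), 73 bp paired-end reads
  from fixed-length fragments (default 200 bp; insert-size variation is
  omitted because no stage consumes it), one pooled library per
  condition — mirroring the pooled design being emulated.
- **Transcript classes.** Known transcripts are copied into the primary
  reference; `secondary` transcripts appear only in a cross-species
  reference; contaminants only in the contaminant reference; duplicate
  pairs (default divergence 0.5%) land in the primary reference and
  exist to exercise the cross-hybridization screen. Novel transcripts
  are rejection-sampled random sequences sharing no 13-mer (either
  strand) with any reference — the same seed size the aligner uses — so
  their cascade fate is guaranteed by construction.
- **Expression.** Per transcript, a log-normal baseline (ln-mean 3,
  ln-sd 1) split across conditions by a normal log2 fold change
  (sd 1.5), with probability 0.05 per condition of a point mass at zero
  (exclusive expression). These defaults produce all five DEG groups at
  realistic proportions for a few-hundred-transcript desk study.
- **Reads.** Fragment counts are Poisson with mean
  `read_density · expression · (L − read_length + 1)` (read_density
  0.01 ≈ 20–40× depth at median expression), substitution errors at
  `error_rate` per base, and Phred qualities from a correct/erroneous
  two-level model (Q≈38 vs Q≈12, ±2 jitter). A 6% whole-read
  quality-failure mixture (Q≈15 throughout) emulates the few percent of
  raw reads that the Q20/70% rule removes in the emulated study (~94%
  high-quality reads); setting `p_degraded=0, jitter=0` gives a
  constant-quality model. Zero-expression transcripts yield zero reads;
  transcripts shorter than the read length are skipped with a warning.

What the generator does **not** model: position-dependent quality decay,
indel sequencing errors, splice/isoform structure, strand-specific
chemistry, per-time-point sampling (the pooled mixture is modeled
directly), and GC or coverage bias. Passing tests therefore demonstrate
the correctness of the algorithms under the stated statistical model,
not performance on real Illumina data.

## Numerical and design choices

- Determinism everywhere: one integer seed fixes FASTA/FASTQ bytes;
  every sort and tie-break (contig orientation and naming, hit order,
  mapping ties, probe windows, top-k term ties) is lexicographic or
  otherwise total.
- The aligner's scoring (+1/−2, gaps −3/−1, band 32) was chosen to keep
  the full Smith–Waterman oracle tractable in tests; tests verify the
  banded search agrees with an independent full-DP oracle
  (`Bio.Align.PairwiseAligner`) within 1 identity point on pairs up to
  2 kb.
- Desk-scale problem sizes: the acceptance script simulates ~50
  transcripts (~33k reads) for the pipeline run and 270 transcripts for
  the cascade-recovery check; these sizes were chosen so a complete run
  is a coffee-break computation while still exercising every branch.
- Degenerate inputs fail loudly: empty read streams, zero-length
  transcripts, both-zero enrichment, capacity below mandatory array
  content, missing reference genes and probes with no self-hit all
  raise, rather than propagate, errors.

## Known limitations

- The assembler's floor-only denoising leaves short error unitigs on
  noisy data (no tip clipping), so assembled-read percentages and N50 on
  error-containing simulations are pessimistic relative to a production
  assembler.
- The cascade runs at transcript granularity; the unaligned-read
  re-assembly variant of steps 5–7 is not reproduced.
- Only the nucleotide annotation path exists; protein-space annotation
  is an extension point, not an implementation.
- The probe screen considers exact-window hybridization energetics only
  through the mismatch/gap counts; no melting-temperature model.
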
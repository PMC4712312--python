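"""Synthetic transcriptomes, reference sets and paired-end reads.

The generator emulates the study design downstream stages assume: two
pooled conditions (FAZ, LAZ) sequenced as 73 bp paired-end reads; a
primary (tomato-like) reference holding the known transcripts; secondary
(Arabidopsis/tobacco-like) references holding cross-species-only
transcripts; a contaminant reference; novel transcripts constructed to
share no seed k-mer with any reference, so they survive the homology
cascade by construction; and near-identical duplicate pairs to exercise
the probe cross-hybridization screen.

Expression is drawn per transcript as a log-normal baseline split across
the two conditions by a normal log2 fold change, with a point mass at
zero in each condition for exclusive expression. Read counts follow a
Poisson with mean proportional to expression x (length - read_length + 1)
(the standard shotgun model; it keeps the pileup expectation closed-form).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import revcomp, write_fasta, write_fastq
from .homology import DEFAULT_SEED_K

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class QualityModel:
    """Phred scores for correctly vs erroneously sequenced bases.

    A fraction `p_degraded` of reads is emitted with `q_degraded` base
    quality throughout (a whole-read quality failure, emulating the few
    percent of raw reads that the Q>20/70% rule removes in practice);
    `jitter` is the half-width of the uniform integer spread around each
    mean. Set p_degraded=0 and jitter=0 for a constant-quality model."""

    q_correct: int = 38
    q_error: int = 12
    q_degraded: int = 15
    p_degraded: float = 0.06
    jitter: int = 2


@dataclass
class SimConfig:
    seed: int = 0
    n_known: int = 50
    n_novel: int = 10
    n_contaminant: int = 5
    n_duplicated: int = 0
    n_secondary: int = 0  # transcripts present only in a secondary reference
    length_range: tuple[int, int] = (300, 800)
    read_length: int = 73
    fragment_length: int = 200
    error_rate: float = 0.0
    quality_model: QualityModel = field(default_factory=QualityModel)
    adapter_seq: str | None = None
    adapter_prob: float = 0.05
    # expression model
    expr_log_mean: float = 3.0  # log-normal baseline, natural-log scale
    expr_log_sd: float = 1.0
    lfc_sd: float = 1.5  # sd of the per-transcript log2(LAZ/FAZ)
    p_exclusive: float = 0.05  # per condition, probability of zero expression
    read_density: float = 0.01  # Poisson mean = density * expr * (L - read_len + 1)
    dup_divergence: float = 0.005  # per-base substitution rate between duplicate mates
    seed_k: int = DEFAULT_SEED_K  # novelty screen k (matches the aligner seed)

    def validate(self) -> None:
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError(f"degenerate length_range: {self.length_range}")
        for name in ("n_known", "n_novel", "n_contaminant", "n_duplicated", "n_secondary"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class TruthSet:
    """Ground truth: transcript sequences, category labels, per-condition
    expression, and the reference sets the cascade will see."""

    transcripts: dict[str, str]
    categories: dict[str, str]  # known | novel | contaminant | duplicated | secondary
    expression: dict[str, tuple[float, float]]  # (FAZ, LAZ)
    primary_ref: dict[str, str]
    secondary_ref: dict[str, str]
    contaminant_ref: dict[str, str]

    def expected_label(self, tid: str) -> str:
        """Cascade label implied by construction."""
        cat = self.categories[tid]
        if cat in ("known", "duplicated", "secondary"):
            return "known"
        if cat == "novel":
            return "novel"
        return "excluded"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.transcripts, outdir / "transcripts.fa")
        write_fasta(self.primary_ref, outdir / "primary_ref.fa")
        write_fasta(self.secondary_ref, outdir / "secondary_ref.fa")
        write_fasta(self.contaminant_ref, outdir / "contaminant_ref.fa")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("transcript_id\tcategory\texpr_FAZ\texpr_LAZ\n")
            for tid in self.transcripts:
                faz, laz = self.expression[tid]
                fh.write(f"{tid}\t{self.categories[tid]}\t{faz:.6g}\t{laz:.6g}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _kmer_set(seqs: dict[str, str], k: int) -> set[str]:
    out: set[str] = set()
    for seq in seqs.values():
        for i in range(len(seq) - k + 1):
            out.add(seq[i : i + k])
        rc = revcomp(seq)
        for i in range(len(rc) - k + 1):
            out.add(rc[i : i + k])
    return out


def _draw_expression(rng: np.random.Generator, cfg: SimConfig) -> tuple[float, float]:
    base = float(rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd))
    t = float(rng.normal(0.0, cfg.lfc_sd))
    faz = base * 2.0 ** (-t / 2.0)
    laz = base * 2.0 ** (t / 2.0)
    u = rng.random()
    if u < cfg.p_exclusive:
        faz = 0.0
    elif u < 2 * cfg.p_exclusive:
        laz = 0.0
    return faz, laz


def generate_truth(config: SimConfig) -> TruthSet:
    """Build the labeled transcript set and its reference FASTA contents."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.length_range

    transcripts: dict[str, str] = {}
    categories: dict[str, str] = {}
    primary: dict[str, str] = {}
    secondary: dict[str, str] = {}
    contaminant: dict[str, str] = {}

    def rand_len() -> int:
        return int(rng.integers(lo, hi + 1))

    for i in range(config.n_known):
        tid = f"known_{i:04d}"
        seq = _random_seq(rng, rand_len())
        transcripts[tid] = seq
        categories[tid] = "known"
        primary[f"ref_{tid}"] = seq

    for i in range(config.n_duplicated):
        base = _random_seq(rng, rand_len())
        mate = _mutate(rng, base, config.dup_divergence)
        for suffix, seq in (("a", base), ("b", mate)):
            tid = f"dup_{i:04d}{suffix}"
            transcripts[tid] = seq
            categories[tid] = "duplicated"
            primary[f"ref_{tid}"] = seq

    for i in range(config.n_secondary):
        tid = f"xspecies_{i:04d}"
        seq = _random_seq(rng, rand_len())
        transcripts[tid] = seq
        categories[tid] = "secondary"
        secondary[f"secref_{tid}"] = seq

    for i in range(config.n_contaminant):
        tid = f"contam_{i:04d}"
        seq = _random_seq(rng, rand_len())
        transcripts[tid] = seq
        categories[tid] = "contaminant"
        contaminant[f"cref_{tid}"] = seq

    # novel transcripts: rejection-sample until seed-k-mer-disjoint from
    # every reference (both strands), so they survive the cascade's
    # homology filters by construction
    ref_kmers = _kmer_set({**primary, **secondary, **contaminant}, config.seed_k)
    for i in range(config.n_novel):
        tid = f"novel_{i:04d}"
        for _attempt in range(10_000):
            seq = _random_seq(rng, rand_len())
            kms = {seq[j : j + config.seed_k] for j in range(len(seq) - config.seed_k + 1)}
            if not (kms & ref_kmers):
                break
        else:  # pragma: no cover - astronomically unlikely at desk scale
            raise RuntimeError("could not draw a reference-disjoint novel transcript")
        transcripts[tid] = seq
        categories[tid] = "novel"

    expression = {tid: _draw_expression(rng, config) for tid in transcripts}
    return TruthSet(transcripts, categories, expression, primary, secondary, contaminant)


def simulate_reads(
    truth: TruthSet, config: SimConfig
) -> tuple[list[tuple[str, str, list[int]]], list[tuple[str, str, list[int]]]]:
    """Paired-end reads for the two conditions; returns (FAZ, LAZ) lists of
    (read_id, bases, quality scores), mates interleaved as /1 then /2.

    Read count per transcript is Poisson with mean read_density * expr *
    (L - read_length + 1); zero expression yields zero reads; transcripts
    shorter than the read length are skipped with a logged warning.
    """
    if not truth.transcripts:
        raise ValueError("truth set is empty")
    rng = np.random.default_rng([config.seed, 2])
    qm = config.quality_model
    out: dict[str, list[tuple[str, str, list[int]]]] = {"FAZ": [], "LAZ": []}

    for tid, seq in truth.transcripts.items():
        L = len(seq)
        faz, laz = truth.expression[tid]
        if min(faz, laz) < 0:
            raise ValueError(f"negative expression for {tid}")
        if L < config.read_length:
            if faz > 0 or laz > 0:
                log.warning("transcript %s (%d bp) shorter than read length; skipped", tid, L)
            continue
        frag = min(config.fragment_length, L)
        for cond, expr in (("FAZ", faz), ("LAZ", laz)):
            if expr == 0:
                continue
            mean = config.read_density * expr * (L - config.read_length + 1)
            n_frags = int(rng.poisson(mean))
            for i in range(n_frags):
                start = int(rng.integers(0, L - frag + 1))
                fragment = seq[start : start + frag]
                r1 = fragment[: config.read_length]
                r2 = revcomp(fragment)[: config.read_length]
                for mate, bases in ((1, r1), (2, r2)):
                    bases, quals = _sequence_read(rng, bases, config, qm)
                    out[cond].append((f"{tid}_{cond}_{i}/{mate}", bases, quals))
    return out["FAZ"], out["LAZ"]


def _sequence_read(
    rng: np.random.Generator, template: str, config: SimConfig, qm: QualityModel
) -> tuple[str, list[int]]:
    """Apply the substitution error model and draw per-base qualities;
    optionally prepend an adapter (read-through emulation)."""
    bases = list(template)
    n = len(bases)
    errs = rng.random(n) < config.error_rate
    degraded = rng.random() < qm.p_degraded
    q_good = qm.q_degraded if degraded else qm.q_correct
    quals: list[int] = []
    for i in range(n):
        if errs[i]:
            choices = [b for b in "ACGT" if b != bases[i]]
            bases[i] = choices[rng.integers(0, 3)]
            q = min(qm.q_error, q_good)
        else:
            q = q_good
        if qm.jitter:
            q += int(rng.integers(-qm.jitter, qm.jitter + 1))
        quals.append(max(2, min(41, q)))
    if config.adapter_seq and rng.random() < config.adapter_prob:
        ad = config.adapter_seq
        bases = list(ad) + bases
        quals = [qm.q_correct] * len(ad) + quals
        bases, quals = bases[: config.read_length], quals[: config.read_length]
    return "".join(bases), quals


def write_reads(reads, path) -> None:
    """4-line FASTQ with Phred+33 qualities."""
    write_fastq(reads, path)
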
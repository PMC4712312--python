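"""End-to-end orchestration: simulate -> qc -> assemble -> cascade ->
quantify -> classify -> probes, with serialized per-stage artifacts, a
hash manifest, determinism under a fixed seed, and stage resume.

Glue only: every scientific decision lives in the stage modules; this
module wires them together, writes their tabular outputs, and records a
sha256 manifest so reruns are auditable byte-for-byte. Each stage
consumes only serialized artifacts of the stages before it, which is
what makes `from_stage` resume possible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import assembly, deg, probes, quantify, read_qc, synth
from ._seq import read_fasta, read_fastq, write_fasta, write_fastq
from .homology import CascadeLabel, run_cascade

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "assemble", "cascade", "quantify", "classify", "probes")


@dataclass
class RunConfig:
    """All pipeline thresholds, defaulting to the study's stated values."""

    outdir: str = "az_run"
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    q_threshold: int = 20
    frac_threshold: float = 0.70
    k_values: tuple[int, ...] = (33, 47, 61)
    min_kmer_count: int = 2
    id_thresh: float = 50.0
    cov_thresh: float = 70.0
    novel_cov_thresh: float = 10.0
    lfc: float = 1.0
    map_seed_k: int = 21
    max_mismatch: int = 3
    array_capacity: int = 2000
    control_features: int = 54

    def validate(self) -> None:
        self.sim.validate()
        if not (0 < self.frac_threshold < 1):
            raise ValueError("frac_threshold must be in (0, 1)")
        for name in ("id_thresh", "cov_thresh", "novel_cov_thresh"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must be in (0, 100]")
        if any(k % 2 == 0 for k in self.k_values):
            raise ValueError("all sweep k values must be odd")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["k_values"] = list(self.k_values)
        d["sim"]["length_range"] = list(self.sim.length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim_d = d.pop("sim", {})
        qm = synth.QualityModel(**sim_d.pop("quality_model", {}))
        if "length_range" in sim_d:
            sim_d["length_range"] = tuple(sim_d["length_range"])
        sim = synth.SimConfig(quality_model=qm, **sim_d)
        if "k_values" in d:
            d["k_values"] = tuple(d["k_values"])
        return cls(sim=sim, **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(outdir: Path, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise FileNotFoundError(f"cannot resume: missing intermediate {outdir / name}")


def _load_truth(outdir: Path) -> synth.TruthSet:
    _require(outdir, "transcripts.fa", "primary_ref.fa", "secondary_ref.fa", "contaminant_ref.fa", "truth.tsv")
    categories: dict[str, str] = {}
    expression: dict[str, tuple[float, float]] = {}
    for line in (outdir / "truth.tsv").read_text().splitlines()[1:]:
        tid, cat, faz, laz = line.split("\t")
        categories[tid] = cat
        expression[tid] = (float(faz), float(laz))
    return synth.TruthSet(
        read_fasta(outdir / "transcripts.fa"),
        categories,
        expression,
        read_fasta(outdir / "primary_ref.fa"),
        read_fasta(outdir / "secondary_ref.fa"),
        read_fasta(outdir / "contaminant_ref.fa"),
    )


def _load_labels(outdir: Path) -> list[CascadeLabel]:
    _require(outdir, "cascade.tsv")
    labels = []
    for line in (outdir / "cascade.tsv").read_text().splitlines()[1:]:
        tid, label, step = line.split("\t")
        labels.append(CascadeLabel(tid, label, int(step)))
    return labels


def _load_enrichment(outdir: Path) -> dict[str, dict[str, float]]:
    enr: dict[str, dict[str, float]] = {}
    for cond in ("FAZ", "LAZ"):
        name = f"enrichment_{cond.lower()}.tsv"
        _require(outdir, name)
        enr[cond] = {}
        for line in (outdir / name).read_text().splitlines()[1:]:
            tid, _, _, _, e = line.split("\t")
            enr[cond][tid] = float(e)
    return enr


def run_pipeline(config: RunConfig, from_stage: str | None = None) -> dict:
    """Execute the stages in order and return the run report.

    `from_stage` resumes at the named stage, loading everything earlier
    from the serialized artifacts already in `config.outdir`; the final
    tables are identical to a full run under the same config and seed.
    """
    config.validate()
    if from_stage is not None and from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; stages are {STAGES}")
    start = STAGES.index(from_stage) if from_stage else 0
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def active(stage: str) -> bool:
        return STAGES.index(stage) >= start

    # --- simulate ---------------------------------------------------
    if active("simulate"):
        truth = synth.generate_truth(config.sim)
        truth.write(outdir)
        faz_raw, laz_raw = synth.simulate_reads(truth, config.sim)
        write_fastq(faz_raw, outdir / "faz.fq")
        write_fastq(laz_raw, outdir / "laz.fq")
        report["stages"]["simulate"] = {
            "transcripts": len(truth.transcripts),
            "faz_reads": len(faz_raw),
            "laz_reads": len(laz_raw),
        }
    else:
        truth = _load_truth(outdir)

    # --- qc ---------------------------------------------------------
    if active("qc"):
        _require(outdir, "faz.fq", "laz.fq")
        report["stages"]["qc"] = {}
        for cond in ("FAZ", "LAZ"):
            raw = read_fastq(outdir / f"{cond.lower()}.fq")
            qreads = [read_qc.QualityRead(r, s, q) for r, s, q in raw]
            kept = read_qc.filter_reads(qreads, config.q_threshold, config.frac_threshold)
            rep = read_qc.qc_summary(qreads, kept, config.q_threshold)
            write_fastq([(r.id, r.bases, r.quals) for r in kept], outdir / f"{cond.lower()}.hq.fq")
            (outdir / f"qc_{cond.lower()}.tsv").write_text(rep.to_tsv())
            report["stages"]["qc"][cond] = asdict(rep)

    # --- assemble ----------------------------------------------------
    if active("assemble"):
        _require(outdir, "faz.hq.fq", "laz.hq.fq")
        pooled = [s for f in ("faz.hq.fq", "laz.hq.fq") for _, s, _ in read_fastq(outdir / f)]
        stats, best_k, per_k = assembly.kmer_sweep(pooled, config.k_values, config.min_kmer_count)
        contigs = per_k[best_k]
        write_fasta({c.id: c.seq for c in contigs}, outdir / "contigs.fa")
        (outdir / "assembly_sweep.tsv").write_text(
            assembly.AssemblyStats.HEADER + "\n" + "\n".join(s.to_row() for s in stats) + "\n"
        )
        report["stages"]["assembly"] = {"selected_k": best_k, "n_contigs": len(contigs)}

    # --- cascade -----------------------------------------------------
    if active("cascade"):
        _require(outdir, "contigs.fa")
        contig_seqs = read_fasta(outdir / "contigs.fa")
        labels = run_cascade(
            contig_seqs,
            truth.primary_ref,
            [truth.secondary_ref] if truth.secondary_ref else [],
            [truth.contaminant_ref] if truth.contaminant_ref else [],
            id_thresh=config.id_thresh,
            cov_thresh=config.cov_thresh,
            novel_cov_thresh=config.novel_cov_thresh,
        )
        with open(outdir / "cascade.tsv", "w") as fh:
            fh.write("transcript_id\tlabel\tstep\n")
            for lab in labels:
                fh.write(f"{lab.transcript_id}\t{lab.label}\t{lab.evidence}\n")
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab.label] = counts.get(lab.label, 0) + 1
        report["stages"]["cascade"] = counts

    # --- quantify ----------------------------------------------------
    if active("quantify"):
        _require(outdir, "contigs.fa", "cascade.tsv", "faz.hq.fq", "laz.hq.fq")
        contig_seqs = read_fasta(outdir / "contigs.fa")
        labels = _load_labels(outdir)
        kept_seqs = {l.transcript_id: contig_seqs[l.transcript_id] for l in labels if l.label != "excluded"}
        for cond in ("FAZ", "LAZ"):
            reads_pairs = [(r, s) for r, s, _ in read_fastq(outdir / f"{cond.lower()}.hq.fq")]
            records, _, unassigned = quantify.quantify(
                reads_pairs, kept_seqs, cond, config.map_seed_k, config.max_mismatch
            )
            with open(outdir / f"enrichment_{cond.lower()}.tsv", "w") as fh:
                fh.write("transcript_id\tcondition\tavg_depth\tcoverage\tenrichment\n")
                for r in records:
                    fh.write(
                        f"{r.transcript_id}\t{cond}\t{r.avg_depth:.4f}\t{r.coverage:.4f}\t{r.enrichment:.4f}\n"
                    )
            report["stages"].setdefault("quantify", {})[cond] = {
                "mapped": len(reads_pairs) - unassigned,
                "unassigned": unassigned,
            }

    # --- classify ----------------------------------------------------
    if active("classify"):
        enr = _load_enrichment(outdir)
        records = deg.classify_records(enr["FAZ"], enr["LAZ"], config.lfc)
        (outdir / "deg.tsv").write_text(deg.records_to_tsv(records))
        summary = deg.summarize_groups(records)
        report["stages"]["classify"] = {"counts": summary.counts, "total_both": summary.total}

    # --- probes ------------------------------------------------------
    if active("probes"):
        _require(outdir, "contigs.fa", "cascade.tsv")
        contig_seqs = read_fasta(outdir / "contigs.fa")
        labels = _load_labels(outdir)
        kept_seqs = {l.transcript_id: contig_seqs[l.transcript_id] for l in labels if l.label != "excluded"}
        categories = {
            l.transcript_id: ("novel" if l.label == "novel" else "annotated")
            for l in labels
            if l.label != "excluded"
        }
        probe_list = probes.design_probes(kept_seqs, categories)
        layout, final = probes.build_layout(
            probe_list, capacity=config.array_capacity, control_features=config.control_features
        )
        write_fasta(((p.probe_id, p.seq) for p in final), outdir / "probes.fa")
        (outdir / "array_layout.json").write_text(json.dumps(layout.to_dict(), indent=2) + "\n")
        report["stages"]["probes"] = {
            "candidates": len(probe_list),
            "specific": sum(1 for p in probe_list if p.probe_class == "specific"),
            "cross_hyb": sum(1 for p in probe_list if p.probe_class == "cross_hyb"),
            **layout.to_dict(),
        }

    # --- manifest ----------------------------------------------------
    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "report.json")
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    report["manifest"] = manifest
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
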
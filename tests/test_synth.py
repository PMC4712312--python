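"""Synthetic truth sets and read simulation."""

import numpy as np
import pytest

from azkit._seq import revcomp
from azkit.homology import SubjectIndex, search
from azkit.synth import QualityModel, SimConfig, generate_truth, simulate_reads


def small_cfg(**kw):
    base = dict(seed=7, n_known=10, n_novel=3, n_contaminant=2, n_duplicated=0, length_range=(200, 400))
    base.update(kw)
    return SimConfig(**base)


class TestGenerateTruth:
    def test_exhaustive_labeling_all_known(self):
        truth = generate_truth(small_cfg(n_known=10, n_novel=0, n_contaminant=0))
        assert len(truth.transcripts) == 10
        assert set(truth.categories.values()) == {"known"}
        assert set(truth.primary_ref.values()) == set(truth.transcripts.values())

    def test_category_counts_match_config(self):
        cfg = small_cfg(n_known=5, n_novel=4, n_contaminant=3, n_duplicated=2, n_secondary=1)
        truth = generate_truth(cfg)
        counts = {}
        for c in truth.categories.values():
            counts[c] = counts.get(c, 0) + 1
        assert counts == {"known": 5, "novel": 4, "contaminant": 3, "duplicated": 4, "secondary": 1}
        assert len(truth.transcripts) == 5 + 4 + 3 + 2 * 2 + 1

    def test_novel_absent_from_references(self):
        truth = generate_truth(small_cfg())
        ref_seqs = set(truth.primary_ref.values()) | set(truth.contaminant_ref.values())
        for tid, cat in truth.categories.items():
            if cat == "novel":
                assert truth.transcripts[tid] not in ref_seqs

    def test_determinism_byte_identical(self, tmp_path):
        cfg = small_cfg(seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_truth(cfg).write(d1)
        generate_truth(small_cfg(seed=7)).write(d2)
        for name in ("transcripts.fa", "primary_ref.fa", "contaminant_ref.fa", "truth.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seed_differs(self):
        t1 = generate_truth(small_cfg(seed=1))
        t2 = generate_truth(small_cfg(seed=2))
        assert t1.transcripts != t2.transcripts

    def test_degenerate_length_range_is_an_error(self):
        with pytest.raises(ValueError):
            generate_truth(small_cfg(length_range=(500, 300)))

    def test_duplicate_pairs_are_near_identical(self):
        """Mates must stay above the cross-hybridization screen's mismatch
        tolerance over probe-sized windows, verified with the aligner."""
        truth = generate_truth(small_cfg(n_duplicated=3, n_known=2, n_novel=0, n_contaminant=0))
        for i in range(3):
            a = truth.transcripts[f"dup_{i:04d}a"]
            b = truth.transcripts[f"dup_{i:04d}b"]
            hits = search(a, SubjectIndex({"b": b}), "a")
            assert hits and hits[0].identity_pct > 98.0 and hits[0].q_cov_pct > 95.0


class TestSimulateReads:
    def test_zero_expression_yields_zero_reads(self):
        cfg = small_cfg(n_known=4, n_novel=0, n_contaminant=0)
        truth = generate_truth(cfg)
        tid = next(iter(truth.transcripts))
        truth.expression[tid] = (0.0, 5.0)
        faz, _ = simulate_reads(truth, cfg)
        assert not any(r[0].startswith(tid + "_FAZ") for r in faz)

    def test_error_free_reads_all_pass_qc(self):
        from azkit.read_qc import QualityRead, passes_quality

        cfg = small_cfg(
            error_rate=0.0,
            quality_model=QualityModel(q_correct=40, q_error=40, p_degraded=0.0, jitter=0),
        )
        truth = generate_truth(cfg)
        faz, laz = simulate_reads(truth, cfg)
        assert faz or laz
        for rid, bases, quals in faz + laz:
            assert passes_quality(QualityRead(rid, bases, quals))

    def test_error_free_reads_map_back_exactly(self):
        cfg = small_cfg(error_rate=0.0)
        truth = generate_truth(cfg)
        faz, laz = simulate_reads(truth, cfg)
        for rid, bases, _ in (faz + laz)[:500]:
            tid = rid.rsplit("_", 2)[0]
            src = truth.transcripts[tid]
            assert bases in src or revcomp(bases) in src

    def test_degraded_read_fraction_near_mixture_weight(self):
        """The whole-read quality-failure mixture drives the high-quality
        read fraction to ~(1 - p_degraded)."""
        from azkit.read_qc import QualityRead, filter_reads

        cfg = small_cfg(seed=19, quality_model=QualityModel(p_degraded=0.06))
        truth = generate_truth(cfg)
        faz, laz = simulate_reads(truth, cfg)
        reads = [QualityRead(r, s, q) for r, s, q in faz + laz]
        frac = len(filter_reads(reads)) / len(reads)
        assert 0.90 <= frac <= 0.97

    def test_short_transcript_skipped(self, caplog):
        cfg = small_cfg(n_known=2, n_novel=0, n_contaminant=0, length_range=(200, 200))
        truth = generate_truth(cfg)
        tid = next(iter(truth.transcripts))
        truth.transcripts[tid] = truth.transcripts[tid][:50]  # below read length
        truth.expression[tid] = (5.0, 5.0)
        import logging

        with caplog.at_level(logging.WARNING, logger="azkit.synth"):
            faz, laz = simulate_reads(truth, cfg)
        assert not any(r[0].startswith(tid + "_") for r in faz + laz)
        assert any("shorter than read length" in m for m in caplog.messages)

    def test_pileup_depth_matches_poisson_expectation(self):
        """Mean per-base depth within 3 sigma of the closed form.

        Fragments per transcript are F ~ Poisson(density * e * (L - r + 1));
        each fragment contributes two r-base mates that land fully inside
        the transcript, so summed depth is exactly 2 r F and the mean depth
        is 2 r F / L. The 3-sigma band on F gives the band on mean depth.
        """
        L, r, density, e = 400, 73, 0.05, 20.0
        cfg = SimConfig(
            seed=11, n_known=1, n_novel=0, n_contaminant=0, length_range=(L, L),
            read_density=density, fragment_length=200, error_rate=0.0,
        )
        truth = generate_truth(cfg)
        tid = next(iter(truth.transcripts))
        truth.expression[tid] = (e, 0.0)
        faz, _ = simulate_reads(truth, cfg)
        depth = np.zeros(L)
        seq = truth.transcripts[tid]
        for _, bases, _ in faz:
            fwd = seq.find(bases)
            pos = fwd if fwd >= 0 else seq.find(revcomp(bases))
            assert pos >= 0, "error-free read must map back exactly"
            depth[pos : pos + r] += 1
        assert depth.sum() == len(faz) * r  # reads never overhang
        f_mean = density * e * (L - r + 1)
        n_frags = len(faz) / 2
        assert abs(n_frags - f_mean) < 3 * np.sqrt(f_mean)
        mean_depth_expected = 2 * r * f_mean / L
        assert abs(depth.mean() - mean_depth_expected) < 3 * np.sqrt(f_mean) * 2 * r / L
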
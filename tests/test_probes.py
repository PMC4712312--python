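"""Probe design, specificity screening and array accounting."""

import pytest

from azkit._seq import revcomp
from azkit.homology import SubjectIndex
from azkit.probes import (
    AllocationPolicy,
    allocation_summary,
    build_layout,
    classify_probe,
    design_probes,
    generate_candidates,
    layout_accounting,
)
from conftest import mutate, random_seq


class TestGenerateCandidates:
    def test_60bp_annotated_gives_sense_and_antisense(self, rng):
        t = random_seq(rng, 60)
        probes = generate_candidates("t", t, "annotated")
        assert len(probes) == 2
        sense = next(p for p in probes if p.orientation == "sense")
        anti = next(p for p in probes if p.orientation == "antisense")
        assert sense.seq == t
        assert anti.seq == revcomp(t)

    def test_novel_policy_emits_four_distinct_windows(self, rng):
        t = random_seq(rng, 1000)
        probes = generate_candidates("t", t, "novel")
        assert len(probes) == 4
        assert sum(p.orientation == "sense" for p in probes) == 2
        sense = [p for p in probes if p.orientation == "sense"]
        assert sense[0].seq != sense[1].seq
        # maximally spread: windows at the two extremes
        assert {p.start for p in sense} == {0, 940}

    def test_below_minimum_length_yields_nothing(self, rng):
        assert generate_candidates("t", random_seq(rng, 27), "annotated") == []

    def test_short_transcript_probe_is_whole_transcript(self, rng):
        t = random_seq(rng, 40)
        probes = generate_candidates("t", t, "annotated")
        assert all(len(p.seq) == 40 for p in probes)

    def test_probe_length_bounds(self, rng):
        for L in (28, 59, 60, 61, 500):
            for p in generate_candidates("t", random_seq(rng, L), "novel"):
                assert 28 <= len(p.seq) <= 60


class TestClassifyProbe:
    def test_unique_probe_is_specific(self, rng):
        transcripts = {f"t{i}": random_seq(rng, 300) for i in range(5)}
        index = SubjectIndex(transcripts)
        probes = generate_candidates("t0", transcripts["t0"], "annotated")
        for p in probes:
            assert classify_probe(p, index) == "specific"

    def test_duplicate_window_is_cross_hybridizing(self, rng):
        base = random_seq(rng, 300)
        near = mutate(rng, base, 0.005)  # < 3 mismatches expected per 60-mer
        transcripts = {"dupA": base, "dupB": near, "other": random_seq(rng, 300)}
        index = SubjectIndex(transcripts)
        probes = generate_candidates("dupA", base, "annotated")
        classes = {classify_probe(p, index) for p in probes}
        assert classes == {"cross_hyb"}

    def test_antisense_probe_screens_like_its_sense_partner(self, rng):
        transcripts = {f"t{i}": random_seq(rng, 300) for i in range(4)}
        index = SubjectIndex(transcripts)
        sense, anti = generate_candidates("t1", transcripts["t1"], "annotated")
        assert classify_probe(sense, index) == classify_probe(anti, index)

    def test_foreign_probe_raises_integrity_error(self, rng):
        transcripts = {"t0": random_seq(rng, 300)}
        index = SubjectIndex(transcripts)
        probes = generate_candidates("t0", random_seq(rng, 300), "annotated")
        with pytest.raises(ValueError, match="source transcript"):
            classify_probe(probes[0], index)


class TestAccounting:
    def test_published_per_category_totals(self):
        counts = {"annotated": 31298, "novel": 8823, "cross_species": 838, "legacy": 356}
        out = allocation_summary(counts)
        assert out["annotated"] == 62596
        assert out["novel"] == 35292
        assert out["cross_species"] == 1676
        assert out["legacy"] == 712
        assert out["rnaseq_transcripts"] == 40959
        assert out["array_transcripts"] == 41315
        assert out["total_probes"] == 100276

    def test_empty_category(self):
        assert allocation_summary({"novel": 0})["novel"] == 0

    def test_published_array_layout_chain(self):
        layout = layout_accounting(
            designed=93674, qc_probes=200, vendor_probes=2278, control_features=4854, capacity=180880
        )
        assert layout.designed_probes + layout.qc_probes + layout.vendor_probes == 96152
        assert layout.filler_duplicates == 79874
        assert layout.total_probes == 176026
        assert layout.total_features == 180880

    def test_small_worked_example(self):
        layout = layout_accounting(designed=10, qc_probes=0, vendor_probes=0, control_features=2, capacity=20)
        assert layout.filler_duplicates == 8 and layout.total_features == 20

    def test_capacity_exactly_mandatory(self):
        layout = layout_accounting(designed=10, qc_probes=1, vendor_probes=1, control_features=2, capacity=14)
        assert layout.filler_duplicates == 0

    def test_capacity_too_small_is_an_error(self):
        with pytest.raises(ValueError):
            layout_accounting(designed=10, qc_probes=0, vendor_probes=0, control_features=2, capacity=11)


class TestBuildLayout:
    def test_dedup_fill_and_invariants(self, rng):
        transcripts = {f"t{i}": random_seq(rng, 200) for i in range(6)}
        categories = {tid: "annotated" for tid in transcripts}
        probes = design_probes(transcripts, categories)
        capacity, controls = len(probes) + 10, 3
        layout, final = build_layout(probes, capacity=capacity + controls, control_features=controls)
        assert layout.total_features == capacity + controls
        assert layout.total_probes == layout.designed_probes + layout.filler_duplicates
        assert len(final) == layout.total_probes
        # fillers duplicate specific probes only
        from collections import Counter

        seq_counts = Counter(p.seq for p in final)
        for p in final:
            if seq_counts[p.seq] > 1:
                assert p.probe_class == "specific"

    def test_exact_duplicates_removed_keep_first(self, rng):
        t = random_seq(rng, 60)
        transcripts = {"a": t, "b": t}  # identical transcripts -> identical windows
        probes = design_probes(transcripts, {"a": "annotated", "b": "annotated"}, screen=False)
        for p in probes:
            p.probe_class = "specific"
        layout, final = build_layout(probes, capacity=6, control_features=0)
        assert layout.designed_probes == 2  # one sense + one antisense survive
        assert final[0].transcript_id == "a"
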
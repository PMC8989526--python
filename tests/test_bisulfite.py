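"""Clone alignment, conversion calling, deletion calling, region reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imotifkit import bisulfite, synthetic
from imotifkit.bisulfite import (FIVE_PRIME_CLASSES, SIDE_CLASSES,
                                 ReferenceRegion, align_clone,
                                 call_conversions, call_deletions,
                                 classify_deletion, region_report,
                                 render_alignment, _aligner)
from imotifkit.repeats import RepeatElement, reverse_complement
from imotifkit.synthetic import BisulfiteRates, SimConfig, gen_clone_set


def _element(start, n, seq_id="r"):
    return RepeatElement(seq_id=seq_id, start=start, end=start + 4 * n,
                         c_rich_strand="+", n=n)


class TestAlignClone:
    def test_identity_alignment(self, tccc9_region):
        aln = align_clone(tccc9_region, tccc9_region.sequence)
        assert aln.read_text == tccc9_region.sequence
        assert all(r == q for r, q in aln.columns)

    def test_fully_converted_clone_has_no_gaps(self, tccc9_region):
        clone = tccc9_region.sequence.replace("C", "T")
        aln = align_clone(tccc9_region, clone, mode="bisulfite")
        assert not any("-" in (r, q) for r, q in aln.columns)
        assert all(q == "T" for r, q in aln.columns if r == "C")

    def test_planted_deletion_recovered_at_coordinates(self, tccc9_region):
        s = tccc9_region.elements[0].start
        cs = gen_clone_set(tccc9_region, n_clones=1,
                           rates=BisulfiteRates(0, 0, 0, 0),
                           deletions=[(0, (s - 20, s - 12))],
                           cfg=SimConfig(seed=0))
        aln = align_clone(tccc9_region, cs.clones[0][1])
        events, _ = call_deletions([aln], tccc9_region.elements[0])
        [ev] = events
        # equal-scoring placements can shift a gap within identical flanking
        # bases; the called interval must reproduce the clone when excised
        ref = tccc9_region.sequence
        assert ev.length == 8
        assert ref[:ev.ref_start] + ref[ev.ref_end:] == cs.clones[0][1]
        assert ev.side_class == "UPSTREAM_5P"

    def test_reverse_complement_clone_reoriented(self, tccc9_region):
        aln = align_clone(tccc9_region,
                          reverse_complement(tccc9_region.sequence))
        assert aln.read_text == tccc9_region.sequence

    def test_round_trip_invariant(self, tccc9_region):
        cs = gen_clone_set(tccc9_region, n_clones=5,
                           deletions=[(0, (50, 60)), (2, (120, 130))],
                           cfg=SimConfig(seed=9))
        for cid, seq in cs.clones:
            aln = align_clone(tccc9_region, seq, clone_id=cid)
            assert aln.reference_text == tccc9_region.sequence
            assert aln.read_text == seq

    def test_bisulfite_conversion_scores_as_match(self):
        m = _aligner("bisulfite").substitution_matrix
        assert m["C", "T"] >= m["C", "C"]
        assert _aligner("standard").substitution_matrix["C", "T"] < 0

    def test_empty_clone_rejected(self, tccc9_region):
        with pytest.raises(ValueError):
            align_clone(tccc9_region, "")

    def test_length_ratio_bounds(self, tccc9_region):
        with pytest.raises(ValueError):
            align_clone(tccc9_region, "ACGT" * 3)


class TestCallConversions:
    def test_no_conversions_zero_frequency(self, tccc9_region):
        aln = align_clone(tccc9_region, tccc9_region.sequence)
        stats = call_conversions([aln], element=tccc9_region.elements[0])
        assert stats.frequency == 0.0

    def test_all_converted_unit_frequency(self, tccc9_region):
        clone = tccc9_region.sequence.replace("C", "T")
        aln = align_clone(tccc9_region, clone)
        stats = call_conversions([aln], element=tccc9_region.elements[0])
        assert stats.frequency == 1.0
        assert stats.converted == 27  # (TCCC)9 carries 27 cytosines

    def test_recovers_generating_rate_within_3se(self, tccc9_region):
        rate = 0.374
        n_clones = 200
        cs = gen_clone_set(tccc9_region, n_clones=n_clones,
                           rates=BisulfiteRates(p_cc_plus=rate),
                           cfg=SimConfig(seed=4))
        alns = [align_clone(tccc9_region, seq, clone_id=cid)
                for cid, seq in cs.clones]
        stats = call_conversions(alns, element=tccc9_region.elements[0])
        se = np.sqrt(rate * (1 - rate) / (27 * n_clones))
        assert abs(stats.frequency - rate) < 3 * se

    def test_estimator_unbiased_over_seeds(self, tccc9_region):
        # mean over many small simulations within 3 SE of the true rate
        rate, n_seeds, n_clones = 0.374, 100, 10
        freqs = []
        for seed in range(n_seeds):
            cs = gen_clone_set(tccc9_region, n_clones=n_clones,
                               rates=BisulfiteRates(p_cc_plus=rate),
                               cfg=SimConfig(seed=seed))
            alns = [align_clone(tccc9_region, seq) for _, seq in cs.clones]
            freqs.append(call_conversions(
                alns, element=tccc9_region.elements[0]).frequency)
        se_mean = np.sqrt(rate * (1 - rate) / (27 * n_clones * n_seeds))
        assert abs(np.mean(freqs) - rate) < 3 * se_mean

    def test_manual_count_on_three_clone_toy(self):
        ref = ReferenceRegion(id="toy", sequence="AACCGACCTA",
                              elements=[_element(2, 1, "toy")])
        # positions of C: 2,3,6,7; clones convert different subsets
        clones = ["AACCGACCTA",   # 0 conversions
                  "AATCGATCTA",   # converts C2 and C6
                  "AATTGATTTA"]   # converts all four
        alns = [align_clone(ref, c, clone_id=f"c{i}")
                for i, c in enumerate(clones)]
        stats = call_conversions(alns, scope="region")
        assert (stats.converted, stats.unconverted) == (6, 6)
        assert stats.frequency == 0.5
        assert stats.conversions_per_clone_mean == pytest.approx(2.0)


class TestCallDeletions:
    def test_side_classification_table(self):
        el = _element(100, 9)  # [100, 136)
        cases = [
            ((60, 70), "UPSTREAM_5P"),
            ((40, 49), "OUTSIDE"),
            ((95, 105), "OVERLAP_5P"),
            ((95, 140), "OVERLAP_5P"),   # spans the whole element
            ((110, 120), "INTERNAL"),
            ((130, 140), "OVERLAP_3P"),
            ((140, 150), "DOWNSTREAM_3P"),
            ((190, 200), "OUTSIDE"),
        ]
        for (s, e), expected in cases:
            assert classify_deletion(s, e, el, window=50) == expected, (s, e)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 300), st.integers(1, 60),
           st.integers(10, 80), st.integers(10, 80))
    def test_classes_partition_and_window_moves_only_flank_classes(
            self, start, length, w1, w2):
        el = _element(150, 5)
        end = start + length
        c1 = classify_deletion(start, end, el, window=w1)
        c2 = classify_deletion(start, end, el, window=w2)
        assert c1 in SIDE_CLASSES and c2 in SIDE_CLASSES
        if c1 != c2:
            flank = {"UPSTREAM_5P", "DOWNSTREAM_3P", "OUTSIDE"}
            assert {c1, c2} <= flank

    def test_downstream_event_excluded_from_frequency(self, tccc9_region):
        el = tccc9_region.elements[0]
        cs = gen_clone_set(tccc9_region, n_clones=4,
                           rates=BisulfiteRates(0, 0, 0, 0),
                           deletions=[(0, (el.end + 5, el.end + 15))],
                           cfg=SimConfig(seed=0))
        alns = [align_clone(tccc9_region, seq) for _, seq in cs.clones]
        events, freq = call_deletions(alns, el)
        assert [e.side_class for e in events] == ["DOWNSTREAM_3P"]
        assert freq == 0.0

    def test_overlap_event_reports_overlap_length(self, tccc9_region):
        el = tccc9_region.elements[0]
        cs = gen_clone_set(tccc9_region, n_clones=1,
                           rates=BisulfiteRates(0, 0, 0, 0),
                           deletions=[(0, (el.start - 6, el.start + 4))],
                           cfg=SimConfig(seed=0))
        aln = align_clone(tccc9_region, cs.clones[0][1])
        events, freq = call_deletions([aln], el)
        assert freq == 1.0
        [ev] = events
        assert ev.side_class in FIVE_PRIME_CLASSES
        total = ev.ref_end - ev.ref_start
        assert total == 10
        assert 0 < ev.overlap_length <= total

    def test_planted_five_of_27_gives_185_percent(self, tccc9_region):
        el = tccc9_region.elements[0]
        deletions = [(i, (el.start - 20, el.start - 12)) for i in range(5)]
        cs = gen_clone_set(tccc9_region, n_clones=27, deletions=deletions,
                           cfg=SimConfig(seed=2))
        alns = [align_clone(tccc9_region, seq) for _, seq in cs.clones]
        _, freq = call_deletions(alns, el)
        assert freq == pytest.approx(5 / 27)
        assert round(100 * freq, 1) == 18.5

    def test_min_del_len_filters_single_base_gaps(self, tccc9_region):
        el = tccc9_region.elements[0]
        cs = gen_clone_set(tccc9_region, n_clones=1,
                           rates=BisulfiteRates(0, 0, 0, 0),
                           deletions=[(0, (el.start - 10, el.start - 9))],
                           cfg=SimConfig(seed=0))
        aln = align_clone(tccc9_region, cs.clones[0][1])
        events, _ = call_deletions([aln], el, min_del_len=2)
        assert events == []
        events, _ = call_deletions([aln], el, min_del_len=1)
        assert len(events) == 1


class TestRegionReport:
    def test_identical_clones_all_zero(self, tccc9_region):
        clones = [(f"c{i}", tccc9_region.sequence) for i in range(3)]
        rep = region_report(tccc9_region, clones)
        el = rep.elements[0]
        assert el.conversion.frequency == 0.0
        assert el.deletion_frequency == 0.0

    def test_long_element_exceeds_short_element(self, two_element_region):
        # state-dependent conversion: folded elements react, duplex does not;
        # deletions planted only at the long element
        el5, el9 = sorted(two_element_region.elements, key=lambda e: e.n)
        rates = BisulfiteRates(p_cc_plus=0.374, p_cg_duplex=0.01)
        state_map = synthetic.state_map_for_region(two_element_region)
        for i in range(el5.start, el5.end):
            if two_element_region.sequence[i] == "C":
                state_map[i] = "C_SS"  # weaker structure at the short repeat
        deletions = [(i, (el9.start - 10, el9.start + 2)) for i in range(10)]
        cs = gen_clone_set(two_element_region, n_clones=20, rates=rates,
                           state_map=state_map, deletions=deletions,
                           cfg=SimConfig(seed=12))
        rep = region_report(two_element_region, cs.clones)
        by_n = {e.n: e for e in rep.elements}
        assert by_n[9].conversion.frequency > by_n[5].conversion.frequency
        assert by_n[9].deletion_frequency > by_n[5].deletion_frequency

    def test_report_denominators_match_hand_counts(self):
        ref = ReferenceRegion(id="toy", sequence="AACCGACCTA",
                              elements=[_element(2, 1, "toy")])
        clones = [("a", "AACCGACCTA"), ("b", "AATCGATCTA"),
                  ("c", "AATTGATTTA")]
        rep = region_report(ref, clones)
        conv = rep.region_conversion
        assert conv.converted + conv.unconverted == 12  # 4 C x 3 clones
        assert rep.elements[0].conversion.converted + \
            rep.elements[0].conversion.unconverted == 6

    def test_rendering_marks_conversions_and_deletions(self, tccc9_region):
        el = tccc9_region.elements[0]
        cs = gen_clone_set(tccc9_region, n_clones=2,
                           deletions=[(0, (el.start - 12, el.start - 4))],
                           cfg=SimConfig(seed=1))
        alns = [align_clone(tccc9_region, seq, clone_id=cid)
                for cid, seq in cs.clones]
        text = render_alignment(tccc9_region, alns, width=0)
        assert "Ref." in text
        assert "-" in text and "T" in text and "." in text
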
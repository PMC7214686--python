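"""Poised-region lists, the two classification rules, bins and maps."""

import numpy as np
import pytest

from promdens import (GenomicInterval, PeakSet, TssRecord,
                      assign_expression_bin, classify_by_k4me1,
                      classify_by_k4me3, distance_by_group, joint_distance_map,
                      poised_k4me1, poised_peaks)
from promdens.promoter_states import PromoterStateCall


def _ps(mark, *triples):
    return PeakSet(mark=mark, intervals=tuple(
        GenomicInterval(c, s, e, name=f"{mark}_{i}")
        for i, (c, s, e) in enumerate(triples)))


class TestPoisedPeaks:
    def test_one_bp_overlap_retained(self):
        out = poised_peaks(_ps("H3K4me3", ("chr1", 100, 200)),
                           _ps("H3K27me3", ("chr1", 150, 250)))
        assert [(iv.start, iv.end) for iv in out] == [(100, 200)]

    def test_half_open_abutment_not_overlap(self):
        out = poised_peaks(_ps("H3K4me3", ("chr1", 100, 200)),
                           _ps("H3K27me3", ("chr1", 200, 300)))
        assert len(out) == 0

    def test_multiple_overlaps_reported_once(self):
        out = poised_peaks(_ps("H3K4me3", ("chr1", 100, 200)),
                           _ps("H3K27me3", ("chr1", 90, 120), ("chr1", 150, 160)))
        assert len(out) == 1

    def test_idempotent_subset(self):
        k4 = _ps("H3K4me3", ("chr1", 100, 200), ("chr1", 500, 600))
        k27 = _ps("H3K27me3", ("chr1", 150, 250))
        once = poised_peaks(k4, k27)
        twice = poised_peaks(once, k27)
        assert once.intervals == twice.intervals
        assert set(once.intervals) <= set(k4.intervals)

    def test_poised_k4me1_roles(self):
        out = poised_k4me1(_ps("H3K4me1", ("chr1", 90, 310)),
                           _ps("H3K4me3", ("chr1", 100, 200)))
        assert len(out) == 1
        assert len(poised_k4me1(_ps("H3K4me1", ("chr1", 1000, 1100)),
                                _ps("H3K4me3", ("chr1", 100, 200)))) == 0


class TestClassifyByK4me3:
    TSS = [TssRecord("chr1", 1000, "+", "t")]

    def test_poised_when_nearest_k4me3_bivalent(self):
        calls = classify_by_k4me3(self.TSS, _ps("H3K4me3", ("chr1", 900, 1100)),
                                  _ps("H3K27me3", ("chr1", 1050, 1400)))
        assert calls[0].state == "poised"

    def test_active_when_no_k27me3_anywhere(self):
        calls = classify_by_k4me3(self.TSS, _ps("H3K4me3", ("chr1", 900, 1100)),
                                  PeakSet(mark="H3K27me3", intervals=()))
        assert calls[0].state == "active"

    def test_other_when_no_k4me3_in_window(self):
        calls = classify_by_k4me3(self.TSS, _ps("H3K4me3", ("chr1", 8000, 8100)),
                                  PeakSet(mark="H3K27me3", intervals=()))
        assert calls[0].state == "other"


class TestClassifyByK4me1:
    TSS = [TssRecord("chr1", 1000, "+", "t")]
    K27 = _ps("H3K27me3", ("chr1", 950, 1300))

    def test_poised_takes_precedence_over_active(self):
        # nearest H3K4me1 overlaps the bivalent H3K4me3 even though the
        # nearest H3K4me3 is within 500 bp of the TSS
        calls = classify_by_k4me1(self.TSS,
                                  _ps("H3K4me1", ("chr1", 900, 1150)),
                                  _ps("H3K4me3", ("chr1", 900, 1100)),
                                  self.K27)
        assert calls[0].state == "poised"
        assert abs(calls[0].d_k4me3) <= 500

    def test_active_when_k4me3_center_within_radius(self):
        calls = classify_by_k4me1(self.TSS,
                                  _ps("H3K4me1", ("chr1", 200, 400)),
                                  _ps("H3K4me3", ("chr1", 1200, 1400)),  # center 1300
                                  PeakSet(mark="H3K27me3", intervals=()))
        assert calls[0].state == "active"

    def test_other_when_k4me3_center_beyond_radius(self):
        calls = classify_by_k4me1(self.TSS,
                                  _ps("H3K4me1", ("chr1", 200, 400)),
                                  _ps("H3K4me3", ("chr1", 1700, 1900)),  # center 1800
                                  PeakSet(mark="H3K27me3", intervals=()))
        assert calls[0].state == "other"

    def test_active_calls_respect_radius_invariant(self, default_landscape):
        land = default_landscape
        calls = classify_by_k4me1(land.tss, land.peaks["H3K4me1"],
                                  land.peaks["H3K4me3"], land.peaks["H3K27me3"])
        active = [c for c in calls if c.state == "active"]
        assert active
        assert all(abs(c.d_k4me3) <= 500 for c in active)


class TestExpressionBins:
    @pytest.mark.parametrize("tpm,expected", [
        (0.0, "B1"), (1.0, "B1"), (1.0000001, "B2"), (5.0, "B2"),
        (5.1, "B3"), (10.0, "B3"), (10.000001, "B4"), (1000.0, "B4"),
    ])
    def test_boundaries_inclusive_below(self, tpm, expected):
        assert assign_expression_bin(tpm) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_expression_bin(-0.1)


class TestJointDistanceMap:
    def test_counts_conserve_tss(self):
        tss = [TssRecord("chr1", p, "+", f"t{p}") for p in (1000, 1010, 1020)]
        k1 = _ps("H3K4me1", ("chr1", 960, 1060))
        k3 = _ps("H3K4me3", ("chr1", 960, 1060))
        m = joint_distance_map(tss, k1, k3)
        assert m.counts.sum() == m.n_tss == 3

    def test_window_exclusion(self):
        tss = [TssRecord("chr1", 1000, "+", "a"), TssRecord("chr1", 9000, "+", "b")]
        k1 = _ps("H3K4me1", ("chr1", 960, 1060))
        k3 = _ps("H3K4me3", ("chr1", 960, 1060))
        m = joint_distance_map(tss, k1, k3, window=2000)
        assert m.n_tss == 1

    def test_random_conservation(self, small_landscape):
        land = small_landscape
        m = joint_distance_map(land.tss, land.peaks["H3K4me1"],
                               land.peaks["H3K4me3"])
        both = 0
        from promdens import PeakIndex
        i1, i3 = PeakIndex(land.peaks["H3K4me1"]), PeakIndex(land.peaks["H3K4me3"])
        for t in land.tss:
            if i1.nearest(t, 2000) and i3.nearest(t, 2000):
                both += 1
        assert m.counts.sum() == m.n_tss == both


class TestDistanceByGroup:
    def _call(self, i, state, bin_, d):
        return PromoterStateCall(tss_id=f"t{i}", state=state, rule="by_k4me1",
                                 d_k4me1=d, expression_bin=bin_, tpm=1.0)

    def test_groups_by_bin(self):
        calls = [self._call(0, "active", "B1", 0), self._call(1, "active", "B1", 10),
                 self._call(2, "active", "B4", 400), self._call(3, "active", "B4", -500)]
        rows = {r.expression_bin: r for r in distance_by_group(calls)}
        assert rows["B1"].signed == (0, 10)
        assert rows["B4"].absolute == (400, 500)
        assert rows["B2"].signed == ()  # empty group emitted, not dropped

    def test_state_by_bin_rows(self):
        calls = [self._call(0, "poised", "B1", -50), self._call(1, "other", "B1", 700)]
        rows = distance_by_group(calls, grouping="state_x_expression_bin")
        assert len(rows) == 8  # 2 states x 4 bins, 'other' dropped
        filled = [r for r in rows if r.signed]
        assert len(filled) == 1 and filled[0].state == "poised"

    def test_empty_input(self):
        rows = distance_by_group([])
        assert all(r.signed == () for r in rows)
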
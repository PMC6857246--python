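"""Spanning-read detection, boundary fine-mapping, segmentation, QC."""

import numpy as np
import pytest

import squiggletr as sq
from squiggletr.delineation import Segmentation
from tests.conftest import simulate


def seg_for(sim, refs, locus, model, config=None):
    res = sq.process_read(sim.read, refs, locus, model,
                          config or sq.DelineationConfig())
    return res


class TestDetectSpanning:
    def test_plus_strand_noiseless(self, locus, model6, refs):
        sim = simulate(locus, model6, 10, strand="+", dwell_model="fixed")
        call = sq.detect_spanning(sim.read, refs)
        assert call is not None
        assert call.strand == "+"
        assert call.flank_distance < 0.2

    def test_minus_strand_same_boundaries(self, locus, model6, refs):
        plus = simulate(locus, model6, 10, strand="+", dwell_model="fixed")
        minus = simulate(locus, model6, 10, strand="-", dwell_model="fixed")
        cp = sq.detect_spanning(plus.read, refs)
        cm = sq.detect_spanning(minus.read, refs)
        assert cp.strand == "+" and cm.strand == "-"
        # same molecule geometry: the TR occupies the same span of its own
        # time axis (flank lengths are equal on this locus)
        assert abs(cp.tr_start_sample - cm.tr_start_sample) < 60
        assert abs(cp.tr_end_sample - cm.tr_end_sample) < 60

    def test_single_flank_is_not_spanning(self, locus, model6, refs):
        seq = locus.flank_left + locus.motif  # no right flank
        values = sq.sequence_to_squiggle(seq, model6).values
        read = sq.RawRead(read_id="half", samples=np.repeat(values, 10))
        assert sq.detect_spanning(read, refs) is None

    def test_too_short_read_not_spanning(self, locus, model6, refs):
        read = sq.RawRead(read_id="tiny", samples=np.arange(500.0))
        assert sq.detect_spanning(read, refs) is None


class TestFinemapBoundaries:
    def test_noiseless_boundaries_within_one_dwell(self, locus, model6, refs):
        sim = simulate(locus, model6, 12, dwell_model="fixed", dwell_mean=10)
        call = sq.detect_spanning(sim.read, refs)
        fine = sq.finemap_boundaries(sim.read, call, refs)
        assert not fine.coarse_only
        assert abs(fine.tr_start_sample - sim.tr_start_sample) <= 10
        assert abs(fine.tr_end_sample - sim.tr_end_sample) <= 10

    def test_refinement_is_stable(self, locus, model6, refs):
        # running finemap on an already-refined call moves boundaries by at
        # most one dwell
        sim = simulate(locus, model6, 8, dwell_model="fixed", dwell_mean=10)
        call = sq.detect_spanning(sim.read, refs)
        once = sq.finemap_boundaries(sim.read, call, refs)
        twice = sq.finemap_boundaries(sim.read, once, refs)
        assert abs(twice.tr_start_sample - once.tr_start_sample) <= 10
        assert abs(twice.tr_end_sample - once.tr_end_sample) <= 10


class TestSegmentTr:
    def test_noiseless_twelve_units(self, locus, model6, refs):
        sim = simulate(locus, model6, 12, dwell_model="fixed", dwell_mean=10)
        tr = sim.read.samples[sim.tr_start_sample:sim.tr_end_sample]
        seg = sq.segment_tr(tr, refs[("multi_unit", "+")], refs[("unit", "+")],
                            unit_len_points=len(locus.motif), k=model6.k,
                            dwell_estimate=10.0)
        assert seg.n_units == 12
        truth = np.array(sim.unit_boundaries) - sim.tr_start_sample
        for est, tru in zip(seg.boundaries, truth):
            assert abs(est - tru) <= 10  # within one dwell

    def test_three_units_shorter_than_reference(self, locus, model6, refs):
        sim = simulate(locus, model6, 3, dwell_model="fixed", dwell_mean=10)
        tr = sim.read.samples[sim.tr_start_sample:sim.tr_end_sample]
        seg = sq.segment_tr(tr, refs[("multi_unit", "+")], refs[("unit", "+")],
                            unit_len_points=len(locus.motif), k=model6.k,
                            dwell_estimate=10.0)
        assert seg.n_units == 3

    def test_too_short_signal_flagged(self, locus, model6, refs):
        seg = sq.segment_tr(np.arange(5.0), refs[("multi_unit", "+")],
                            refs[("unit", "+")], unit_len_points=len(locus.motif),
                            k=model6.k)
        assert seg.n_units == 0
        assert "too_short" in seg.flags

    def test_boundaries_partition_signal(self, locus, model6, refs):
        sim = simulate(locus, model6, 9, noise=0.3, seed=4)
        tr = sim.read.samples[sim.tr_start_sample:sim.tr_end_sample]
        seg = sq.segment_tr(tr, refs[("multi_unit", "+")], refs[("unit", "+")],
                            unit_len_points=len(locus.motif), k=model6.k,
                            dwell_estimate=10.0)
        assert seg.boundaries[0] == 0
        assert seg.boundaries[-1] == tr.size
        assert all(b > a for a, b in zip(seg.boundaries[:-1], seg.boundaries[1:]))
        assert sum(u.size for u in seg.unit_signals) == tr.size


class TestQcFilter:
    @staticmethod
    def _seg(mean):
        return Segmentation(read_id=f"r{mean}", strand="+", boundaries=[0, 1],
                            unit_signals=[np.zeros(1)], unit_distances=[mean])

    def test_outlier_discarded_at_hand_computed_cutoff(self):
        segs = [self._seg(1.0) for _ in range(7)] + [self._seg(10.0)]
        kept, discarded, thr = sq.qc_filter(segs)
        # q75 of seven 1s and a 10 is 1.0 (linear interpolation), IQR 0
        assert thr.q75 == 1.0 and thr.iqr == 0.0 and thr.cutoff == 1.0
        assert len(kept) == 7 and len(discarded) == 1
        assert discarded[0].mean_distance == 10.0

    def test_equal_distances_keep_all(self):
        segs = [self._seg(0.4) for _ in range(6)]
        kept, discarded, thr = sq.qc_filter(segs)
        assert len(kept) == 6 and not discarded

    def test_fewer_than_four_reads_keeps_all(self):
        segs = [self._seg(v) for v in (0.1, 5.0, 9.0)]
        kept, discarded, thr = sq.qc_filter(segs)
        assert len(kept) == 3 and thr is None


class TestInvariances:
    def test_strand_symmetry_noiseless(self, locus, model6, refs):
        for n in (5, 11):
            p = seg_for(simulate(locus, model6, n, strand="+",
                                 dwell_model="fixed"), refs, locus, model6)
            m = seg_for(simulate(locus, model6, n, strand="-",
                                 dwell_model="fixed"), refs, locus, model6)
            assert p.segmentation.n_units == m.segmentation.n_units == n

    def test_scale_offset_invariance(self, locus, model6, refs):
        sim = simulate(locus, model6, 8, noise=0.2, seed=6)
        base = seg_for(sim, refs, locus, model6)
        moved = sq.RawRead(read_id="t", samples=sim.read.samples * 7.3 - 55.0)
        same = sq.process_read(moved, refs, locus, model6)
        assert base.call.strand == same.call.strand
        assert base.segmentation.n_units == same.segmentation.n_units
        assert base.segmentation.boundaries == same.segmentation.boundaries

    def test_identity_limit_dwell_one(self, locus, model6, refs):
        config = sq.DelineationConfig(samples_per_kmer=1.0)
        for n in (3, 30, 120):
            sim = simulate(locus, model6, n, dwell_model="fixed", dwell_mean=1)
            res = sq.process_read(sim.read, refs, locus, model6, config)
            assert res.call is not None and res.call.strand == "+"
            assert res.segmentation.n_units == n
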
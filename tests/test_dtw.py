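"""MVM alignment and symmetric DTW, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import squiggletr as sq
from squiggletr.dtw import (
    InfeasibleAlignmentError,
    MvmConstraint,
    mvm_align_skip,
    mvm_cost_banded,
)
from squiggletr.signal_io import NormalizedSignal


# --- independent oracles ---------------------------------------------------

def tile_oracle(ref, sig, elasticity, open_begin=False, open_end=False):
    """Enumerate all dwell tilings: each reference point consumes 1..E
    consecutive samples, dwells cover a contiguous span; every consumed
    sample pays |ref - sig|.  Returns the minimal raw cost (for open ends,
    the minimal average is used to select the span, mirroring the contract)."""
    ref = np.asarray(ref, float)
    sig = np.asarray(sig, float)
    R, S = ref.size, sig.size
    best = None  # (avg, raw)
    starts = range(S) if open_begin else [0]
    for s0 in starts:
        for dwells in itertools.product(range(1, elasticity + 1), repeat=R):
            end = s0 + sum(dwells)
            if end > S:
                continue
            if not open_end and end != S:
                continue
            cost = 0.0
            t = s0
            for i, d in enumerate(dwells):
                for _ in range(d):
                    cost += abs(ref[i] - sig[t])
                    t += 1
            span = end - s0
            key = (cost / span, cost) if (open_begin or open_end) else (cost, cost)
            if best is None or key < best:
                best = key
    return None if best is None else best[1]


def skip_oracle(ref, sig, elasticity, open_begin=False, open_end=False):
    """Enumerate all monotone one-sample-per-point assignments with steps
    of at most E; skipped samples are free."""
    ref = np.asarray(ref, float)
    sig = np.asarray(sig, float)
    R, S = ref.size, sig.size
    best = None
    for combo in itertools.combinations(range(S), R):
        if not open_begin and combo[0] != 0:
            continue
        if not open_end and combo[-1] != S - 1:
            continue
        if any(b - a > elasticity for a, b in zip(combo[:-1], combo[1:])):
            continue
        cost = sum(abs(ref[i] - sig[j]) for i, j in enumerate(combo))
        if best is None or cost < best:
            best = cost
    return best


def _random_pair(rng, max_ref=6, max_sig=10):
    R = rng.integers(1, max_ref + 1)
    S = rng.integers(R, max_sig + 1)
    return rng.normal(0, 1, R), rng.normal(0, 1, S)


class TestMvmOracle:
    @pytest.mark.parametrize("open_begin,open_end", [
        (False, False), (False, True), (True, True),
    ])
    def test_tile_semantics_matches_enumeration(self, open_begin, open_end):
        rng = np.random.default_rng(42)
        for _ in range(60):
            ref, sig = _random_pair(rng, max_ref=4, max_sig=8)
            E = int(rng.integers(1, 4))
            expected = tile_oracle(ref, sig, E, open_begin, open_end)
            try:
                aln = sq.mvm_align(ref, sig, MvmConstraint(E),
                                   open_begin=open_begin, open_end=open_end)
            except InfeasibleAlignmentError:
                assert expected is None
                continue
            assert expected is not None
            assert aln.distance == pytest.approx(expected, abs=1e-9)

    def test_skip_semantics_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            ref, sig = _random_pair(rng, max_ref=5, max_sig=9)
            E = int(rng.integers(1, 4))
            expected = skip_oracle(ref, sig, E, open_begin=True, open_end=True)
            try:
                aln = mvm_align_skip(ref, sig, MvmConstraint(E),
                                     open_begin=True, open_end=True)
            except InfeasibleAlignmentError:
                assert expected is None
                continue
            assert aln.distance == pytest.approx(expected, abs=1e-9)


class TestMvmAlign:
    def test_single_point(self):
        aln = sq.mvm_align([0.0], [0.0])
        assert aln.pairs == [(0, 0)]
        assert aln.distance == 0.0

    def test_self_alignment_is_zero(self):
        x = np.array([0.3, -1.2, 0.8, 2.0, -0.5])
        aln = sq.mvm_align(x, x, MvmConstraint(3))
        assert aln.distance == pytest.approx(0.0, abs=1e-12)
        assert [j for _, j in aln.pairs] == list(range(5))

    def test_two_point_example_frozen(self):
        # oracle-derived: dwells (2, 1) give |1-1| + |0.9-1| + |-1+1| = 0.1
        aln = sq.mvm_align([1.0, -1.0], [1.0, 0.9, -1.0], MvmConstraint(2))
        assert aln.distance == pytest.approx(0.1)
        assert tile_oracle([1.0, -1.0], [1.0, 0.9, -1.0], 2) == pytest.approx(0.1)

    def test_signal_shorter_than_reference(self):
        with pytest.raises(InfeasibleAlignmentError):
            sq.mvm_align([0.0, 1.0, 2.0], [0.0, 1.0])

    def test_closed_ends_with_insufficient_elasticity(self):
        # 2 points cannot tile 5 samples when each may consume at most 2
        with pytest.raises(InfeasibleAlignmentError):
            sq.mvm_align(np.zeros(2), np.zeros(5), MvmConstraint(2))

    def test_monotone_pairs_invariant(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 1, 8)
        sig = np.repeat(ref, 4) + rng.normal(0, 0.1, 32)
        aln = sq.mvm_align(ref, sig, MvmConstraint(10))
        starts = [j for _, j in aln.pairs]
        assert all(b > a for a, b in zip(starts[:-1], starts[1:]))
        assert aln.begin == 0 and aln.end == 31

    def test_noise_does_not_decrease_distance_on_average(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(0, 1, 12)
        clean = np.repeat(ref, 5)
        base, noisy = [], []
        for seed in range(10):
            r2 = np.random.default_rng(seed)
            base.append(sq.mvm_align(ref, clean, MvmConstraint(8)).distance)
            pert = clean + r2.normal(0, 0.4, clean.size)
            noisy.append(sq.mvm_align(ref, pert, MvmConstraint(8)).distance)
        assert np.mean(noisy) > np.mean(base)


class TestBandedCost:
    def test_matches_full_alignment_with_wide_band(self):
        rng = np.random.default_rng(11)
        ref = rng.normal(0, 1, 20)
        sig = np.repeat(ref, 3) + rng.normal(0, 0.2, 60)
        full = sq.mvm_align(ref, sig, MvmConstraint(6)).distance
        banded = mvm_cost_banded(ref, sig, 6, 60)
        assert banded == pytest.approx(full, abs=1e-9)

    def test_infeasible_returns_inf(self):
        assert np.isinf(mvm_cost_banded(np.zeros(2), np.zeros(10), 2, 10))


class TestSubsequenceSearch:
    @staticmethod
    def _windows(chunks):
        out = []
        off = 0
        for c in chunks:
            out.append(NormalizedSignal(z=np.asarray(c, float), offset=off))
            off += len(c)
        return out

    def test_planted_reference_wins(self):
        rng = np.random.default_rng(2)
        ref = sq.znormalize(rng.normal(0, 1, 30)).z
        junk = rng.normal(0, 1, 120)
        planted = np.concatenate([rng.normal(0, 1, 40), ref, rng.normal(0, 1, 50)])
        win = self._windows([junk, planted, junk[::-1]])
        got = sq.subsequence_search(ref, win, MvmConstraint(3))
        assert got is not None
        w, aln = got
        assert w.offset == 120
        assert aln.normalized_distance == pytest.approx(0.0, abs=1e-9)
        assert aln.begin == 40

    def test_tie_breaks_to_earliest_window(self):
        ref = np.array([0.0, 1.0, -1.0, 0.5])
        block = np.concatenate([ref, [2.0, -2.0]])
        win = self._windows([block, block])
        w, _ = sq.subsequence_search(ref, win, MvmConstraint(2))
        assert w.offset == 0

    def test_all_windows_infeasible_returns_none(self):
        ref = np.arange(10.0)
        win = self._windows([[0.0, 1.0]])  # shorter than the reference
        assert sq.subsequence_search(ref, win, MvmConstraint(2)) is None


class TestSymmetricDtw:
    def test_identity(self):
        x = np.array([0.4, -1.0, 2.0])
        assert sq.symmetric_dtw_distance(x, x) == 0.0

    def test_hand_computed_table(self):
        # dp over the 2x2 table with diagonal weight 2:
        # dp00=1, dp01=1, dp10=1, dp11=min(1+2*1, 1+1, 1+1)=2
        assert sq.symmetric_dtw_distance([0.0, 1.0], [1.0, 0.0]) == pytest.approx(2.0)

    @given(st.integers(0, 1000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(1, 12))
        b = rng.normal(0, 1, rng.integers(1, 12))
        assert sq.symmetric_dtw_distance(a, b) == pytest.approx(
            sq.symmetric_dtw_distance(b, a))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            sq.symmetric_dtw_distance([], [1.0])


class TestDistanceMatrix:
    def test_identical_segments_zero_matrix(self):
        x = np.array([0.0, 1.0, 2.0])
        dm = sq.distance_matrix([x, x])
        assert np.array_equal(dm, np.zeros((2, 2)))

    def test_symmetric_and_consistent_with_pairwise(self):
        rng = np.random.default_rng(9)
        segs = [rng.normal(0, 1, rng.integers(4, 10)) for _ in range(4)]
        dm = sq.distance_matrix(segs)
        assert np.array_equal(dm, dm.T)
        assert np.all(np.diag(dm) == 0)
        assert dm[1, 2] == pytest.approx(sq.symmetric_dtw_distance(segs[1], segs[2]))

    def test_needs_two_segments(self):
        with pytest.raises(ValueError):
            sq.distance_matrix([np.arange(3.0)])
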
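from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamigrind import ForceSignal, dtw_distance, estimate_tip, similarity_field, tumble_segment
from lamigrind.estimate import dtw_pairwise, estimate_segments
from lamigrind.force import PredictionBank
from lamigrind.planning import MillingPlan


def naive_dtw(a, b):
    """Independent memoized-recursion DTW oracle (textbook formulation)."""
    a = tuple(float(x) for x in a)
    b = tuple(float(x) for x in b)

    @lru_cache(maxsize=None)
    def c(i, j):
        d = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return d
        best = np.inf
        if i > 0:
            best = min(best, c(i - 1, j))
        if j > 0:
            best = min(best, c(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, c(i - 1, j - 1))
        return d + best

    return c(len(a) - 1, len(b) - 1)


seqs = st.lists(st.floats(-50, 50), min_size=2, max_size=12)


class TestDTW:
    def test_identity_distance_zero(self):
        s = np.array([0.3, 1.7, -2.0, 5.0])
        assert dtw_distance(s, s) == 0.0

    def test_hand_computed_table(self):
        # D is all ones; the warped optimum accumulates 1 + 1 = 2
        assert dtw_distance([0.0, 0.0], [1.0, 1.0]) == pytest.approx(2.0)

    def test_warping_beats_lockstep_on_shifted_ramp(self):
        a = [0.0, 1.0, 2.0]
        b = [1.0, 2.0, 3.0]
        d = dtw_distance(a, b)
        assert d < 3.0  # lockstep sum of |a - b|
        assert d == pytest.approx(naive_dtw(a, b))

    @given(seqs, seqs)
    @settings(max_examples=40, deadline=None)
    def test_symmetry(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_lockstep_upper_bound(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        assert dtw_distance(a, b) <= sum(abs(x - y) for x, y in pairs) + 1e-9

    def test_agrees_with_independent_oracle_on_100_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 16))
            a = rng.normal(scale=10.0, size=n)
            b = rng.normal(scale=10.0, size=n)
            assert dtw_distance(a, b) == pytest.approx(naive_dtw(a, b), abs=1e-9)

    def test_pairwise_matches_scalar(self, rng):
        x = rng.normal(size=(7, 15))
        y = rng.normal(size=(9, 15))
        P = dtw_pairwise(x, y)
        for i in range(7):
            for j in range(9):
                assert P[i, j] == pytest.approx(dtw_distance(x[i], y[j]), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


class TestTumbleSegment:
    def _signal(self, n, fs=20.0):
        return ForceSignal(fs=fs, data=np.arange(n * 4, dtype=float).reshape(n, 4))

    def test_segment_count(self):
        segs = tumble_segment(self._signal(300), ns=15)
        assert len(segs) == 20
        assert all(s.ns == 15 for s in segs)

    def test_physical_span(self):
        segs = tumble_segment(self._signal(300), ns=15, vd=0.5)
        assert segs[0].l == pytest.approx(0.375)

    def test_windows_non_overlapping_and_ordered(self):
        sig = self._signal(60)
        segs = tumble_segment(sig, ns=15)
        rebuilt = np.concatenate([s.data for s in segs])
        assert np.array_equal(rebuilt, sig.data)

    def test_short_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert tumble_segment(self._signal(14), ns=15) == []

    def test_trailing_remainder_dropped(self):
        segs = tumble_segment(self._signal(44), ns=15)
        assert len(segs) == 2


def _toy_bank(sequences):
    """Bank over a 1-layer plan with the given (B, ns, 4) sequences."""
    B, ns, _ = sequences.shape
    plan = MillingPlan(n_layers=1, n_paths_per_layer=1,
                       path_length_mm=B * 0.375,
                       workspace_origin=np.array([0.0, 1.8, 6.0]))
    lands = np.zeros((1, 1, B, 3))
    for k in range(B):
        lands[0, 0, k] = [0.375 * (k + 0.5), 1.8, 6.0 - 0.8]
    return PredictionBank(plan=plan, sequences=sequences[None, None],
                          landmarks=lands, fs=20.0)


class TestSimilarityAndEstimate:
    def test_field_shape_and_sign(self, rng):
        bank = _toy_bank(rng.normal(size=(6, 15, 4)))
        sig = ForceSignal(fs=20.0, data=rng.normal(size=(15, 4)))
        seg = tumble_segment(sig, 15)[0]
        fld = similarity_field(seg, bank, method="dtw")
        assert fld.values.shape == (1, 1, 6)
        assert np.all(fld.values >= 0)
        fld_p = similarity_field(seg, bank, method="pearson")
        assert np.all(np.abs(fld_p.values) <= 4.0 + 1e-9)  # 4 channels in [-1, 1]

    def test_exact_bank_entry_attains_zero_distance(self, rng):
        seqs = rng.normal(size=(6, 15, 4))
        bank = _toy_bank(seqs)
        sig = ForceSignal(fs=20.0, data=seqs[3])
        seg = tumble_segment(sig, 15)[0]
        fld = similarity_field(seg, bank, method="dtw")
        assert fld.values[0, 0, 3] == pytest.approx(0.0, abs=1e-12)
        est = estimate_tip(seg, bank, method="dtw")
        assert (est.index.i, est.index.j, est.index.k) == (1, 1, 4)
        assert np.allclose(est.position, bank.landmarks[0, 0, 3])

    def test_tie_broken_lexicographically(self, rng):
        seqs = rng.normal(size=(6, 15, 4))
        seqs[4] = seqs[1]  # duplicate grid deeper in the bank
        bank = _toy_bank(seqs)
        seg = tumble_segment(ForceSignal(fs=20.0, data=seqs[4]), 15)[0]
        est = estimate_tip(seg, bank, method="dtw")
        assert est.index.k == 2  # first of the tied pair

    def test_single_entry_bank_always_wins(self, rng):
        bank = _toy_bank(rng.normal(size=(1, 15, 4)))
        seg = tumble_segment(ForceSignal(fs=20.0, data=rng.normal(size=(15, 4))), 15)[0]
        est = estimate_tip(seg, bank, method="dtw")
        assert (est.index.i, est.index.j, est.index.k) == (1, 1, 1)

    def test_vanishing_noise_leaves_estimate_unchanged(self, rng):
        seqs = rng.normal(size=(6, 15, 4)) * 5
        bank = _toy_bank(seqs)
        seg0 = tumble_segment(ForceSignal(fs=20.0, data=seqs[2]), 15)[0]
        ref = estimate_tip(seg0, bank).index
        noisy = seqs[2] + rng.normal(size=(15, 4)) * 1e-9
        seg1 = tumble_segment(ForceSignal(fs=20.0, data=noisy), 15)[0]
        assert estimate_tip(seg1, bank).index == ref

    def test_constant_sequence_under_pearson_scores_zero(self, rng):
        seqs = rng.normal(size=(4, 15, 4))
        seqs[2] = 1.0  # constant bank entry: correlation undefined -> 0
        bank = _toy_bank(seqs)
        seg = tumble_segment(ForceSignal(fs=20.0, data=rng.normal(size=(15, 4))), 15)[0]
        fld = similarity_field(seg, bank, method="pearson", presmooth=0)
        assert fld.values[0, 0, 2] == pytest.approx(0.0)

    def test_search_window_restricts_candidates(self, rng):
        seqs = rng.normal(size=(6, 15, 4))
        bank = _toy_bank(seqs)
        # the true best entry is k=4, but a (0-layer, 0-path) window around
        # the scheduled indices cannot move off the scheduled path/layer
        seg = tumble_segment(ForceSignal(fs=20.0, data=seqs[3]), 15)[0]
        ests = estimate_segments([seg], bank, scheduled=[(1, 1)], window=(0, 0))
        assert ests[0].index.k == 4  # grid axis stays unbounded

    def test_mismatched_segment_length_rejected(self, rng):
        bank = _toy_bank(rng.normal(size=(4, 15, 4)))
        sig = ForceSignal(fs=20.0, data=rng.normal(size=(12, 4)))
        seg = tumble_segment(sig, 12)[0]
        with pytest.raises(ValueError):
            similarity_field(seg, bank)
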
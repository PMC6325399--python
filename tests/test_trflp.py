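"""Size filtering, iterative true-peak calling, binning, standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rumenprof import (
    PeakTable,
    bin_fragments,
    detect_true_peaks,
    filter_by_size,
    standardize,
)
from conftest import brute_force_true_peaks


def table(sizes, heights, sid="S1"):
    return PeakTable(sid, np.asarray(sizes, float), np.asarray(heights, float))


class TestFilterBySize:
    def test_bounds_inclusive(self):
        t = table([26.9, 27.0, 300.0, 520.0, 520.1], [1, 2, 3, 4, 5])
        out = filter_by_size(t)
        assert out.sizes.tolist() == [27.0, 300.0, 520.0]
        assert out.heights.tolist() == [2.0, 3.0, 4.0]

    def test_empty_and_identity(self):
        assert len(filter_by_size(table([], []))) == 0
        t = table([100, 200], [1, 2])
        out = filter_by_size(t)
        assert out.sizes.tolist() == t.sizes.tolist()

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            filter_by_size(table([100], [1]), min_bp=520, max_bp=27)


class TestDetectTruePeaks:
    def test_hand_trace_single_dominant(self, small_peak_table):
        # iteration 1: sd = sqrt((500^2 + 20*25)/21) ~ 109.2, threshold ~ 327.6
        tps = detect_true_peaks(small_peak_table)
        assert tps.n_true == 1
        assert tps.true_heights.tolist() == [500.0]
        assert tps.n_iterations == 2
        assert tps.final_sd == pytest.approx(5.0)
        sd1 = np.sqrt((500.0**2 + 20 * 25.0) / 21)
        assert sd1 == pytest.approx(109.2, abs=0.1)

    def test_equal_heights_never_true(self):
        tps = detect_true_peaks(table(np.arange(1, 31), np.full(30, 7.0)))
        assert tps.n_true == 0
        assert tps.final_sd == pytest.approx(7.0)

    def test_two_dominant_within_two_iterations(self):
        heights = [400.0, 350.0] + [2.0] * 30
        sizes = np.arange(1, 33, dtype=float)
        tps = detect_true_peaks(table(sizes, heights))
        assert set(tps.true_heights) == {400.0, 350.0}
        assert tps.n_iterations <= 3  # declaring rounds + terminating round
        assert tps.true_mask[:2].all()
        assert brute_force_true_peaks(heights) == set(np.flatnonzero(tps.true_mask))

    def test_empty_input(self):
        tps = detect_true_peaks(table([], []))
        assert tps.n_true == 0 and tps.n_iterations == 0

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(300):
            n = rng.integers(1, 60)
            heights = np.abs(rng.normal(0, 50, n)) + 1e-6
            boosted = rng.random(n) < 0.1
            heights[boosted] += rng.uniform(500, 5000, boosted.sum())
            tps = detect_true_peaks(table(np.arange(1, n + 1, dtype=float), heights))
            assert set(np.flatnonzero(tps.true_mask)) == brute_force_true_peaks(heights)

    def test_monotone_in_k_sd(self, rng):
        heights = np.abs(rng.normal(0, 50, 80)) + 1e-6
        heights[:6] += rng.uniform(300, 3000, 6)
        t = table(np.arange(1, 81, dtype=float), heights)
        counts = [detect_true_peaks(t, k_sd=k).n_true for k in (1.5, 2, 2.5, 3, 4, 6)]
        assert counts == sorted(counts, reverse=True)

    @settings(derandomize=True, max_examples=40)
    @given(
        heights=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=40),
        scale=st.floats(0.01, 1e3),
    )
    def test_scale_and_order_invariance(self, heights, scale):
        h = np.asarray(heights)
        sizes = np.arange(1, len(h) + 1, dtype=float)
        base = detect_true_peaks(table(sizes, h)).true_mask
        scaled = detect_true_peaks(table(sizes, h * scale)).true_mask
        assert (base == scaled).all()
        perm = np.random.default_rng(0).permutation(len(h))
        permuted = detect_true_peaks(table(sizes[perm], h[perm])).true_mask
        assert set(sizes[perm][permuted]) == set(sizes[base])


class TestBinning:
    def test_cross_sample_bin_with_mean_representative(self):
        a = detect_true_peaks(table([100.1], [50.0], "A"), k_sd=0)
        b = detect_true_peaks(table([100.4], [80.0], "B"), k_sd=0)
        m = bin_fragments([a, b], tolerance_bp=0.5)
        assert m.values.shape == (1, 2)
        assert m.representatives[0] == pytest.approx(100.25)
        assert m.values[0].tolist() == [50.0, 80.0]

    def test_gap_beyond_tolerance_splits(self):
        a = detect_true_peaks(table([100.0, 100.6], [5.0, 6.0], "A"), k_sd=0)
        m = bin_fragments([a], tolerance_bp=0.5)
        assert m.values.shape[0] == 2

    def test_within_sample_heights_summed(self):
        a = detect_true_peaks(table([200.0, 200.3], [10.0, 5.0], "A"), k_sd=0)
        m = bin_fragments([a], tolerance_bp=0.5)
        assert m.values.shape[0] == 1
        assert m.values[0, 0] == pytest.approx(15.0)

    def test_chaining_is_single_pass_on_sorted_lengths(self):
        # 100.0-100.4-100.8: consecutive gaps within tolerance chain into one bin
        a = detect_true_peaks(table([100.0, 100.4, 100.8], [1.0, 1.0, 1.0], "A"), k_sd=0)
        m = bin_fragments([a], tolerance_bp=0.5)
        assert m.values.shape[0] == 1
        assert m.representatives[0] == pytest.approx(100.4)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            bin_fragments([], tolerance_bp=-0.1)

    def test_binning_conserves_per_sample_height(self, rng):
        sets = []
        for sid in "ABC":
            n = 12
            sizes = np.sort(rng.uniform(27, 520, n))
            heights = rng.uniform(10, 100, n)
            sets.append(detect_true_peaks(table(sizes, heights, sid), k_sd=0))
        m = bin_fragments(sets)
        for j, tps in enumerate(sets):
            assert m.values[:, j].sum() == pytest.approx(tps.true_heights.sum())


class TestStandardize:
    def test_columns_sum_to_one(self):
        a = detect_true_peaks(table([100.0, 200.0, 300.0], [50, 80, 70], "A"), k_sd=0)
        s = standardize(bin_fragments([a]))
        assert s.values[:, 0].tolist() == pytest.approx([0.25, 0.40, 0.35])
        assert s.standardized

    def test_single_bin_column(self):
        a = detect_true_peaks(table([100.0], [9.0], "A"), k_sd=0)
        s = standardize(bin_fragments([a]))
        assert s.values[0, 0] == 1.0

    def test_zero_column_flagged(self):
        a = detect_true_peaks(table([100.0], [9.0], "A"), k_sd=0)
        b = detect_true_peaks(table([], []), k_sd=0)  # no peaks at all
        b = type(b)("B", b.sizes, b.heights, b.true_mask, 0, float("nan"))
        s = standardize(bin_fragments([a, b]))
        assert s.zero_samples == ["B"]
        assert (s.values[:, 1] == 0).all()

    def test_double_standardize_rejected(self):
        a = detect_true_peaks(table([100.0], [9.0], "A"), k_sd=0)
        s = standardize(bin_fragments([a]))
        with pytest.raises(ValueError):
            standardize(s)
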
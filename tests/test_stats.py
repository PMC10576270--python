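from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromrecall.core import TagLibrary
from chromrecall.stats import (
    MotifRecord,
    fold_change_screen,
    mann_whitney_u,
    motif_filter,
    moving_average_density,
    pileup_profile,
    zscore_rows,
)

from .conftest import make_peak


class TestZscoreRows:
    def test_worked_row(self):
        z = zscore_rows(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z, [[-1.0, 0.0, 1.0]])

    def test_constant_row_maps_to_zeros(self):
        z = zscore_rows(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(z[0], [0.0, 0.0, 0.0])

    def test_rows_standardized(self, rng):
        z = zscore_rows(rng.normal(size=(50, 4)))
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(st.integers(-1000, 1000), min_size=3, max_size=8),
        st.floats(0.01, 100),
        st.floats(-1e3, 1e3),
    )
    def test_location_scale_invariance(self, row, a, b):
        x = np.array([row], dtype=float)
        np.testing.assert_allclose(zscore_rows(a * x + b), zscore_rows(x), atol=1e-6)

    def test_dataframe_round_trips_labels(self):
        df = pd.DataFrame([[1.0, 3.0]], index=["p"], columns=["a", "b"])
        z = zscore_rows(df)
        assert list(z.index) == ["p"] and list(z.columns) == ["a", "b"]

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            zscore_rows(np.ones((3, 1)))


def mann_whitney_oracle(x, y):
    """O(n^2) U plus exact two-sided p by full enumeration of assignments."""
    x, y = list(x), list(y)
    u = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    pooled = x + y
    n, m = len(x), len(y)
    center = n * m / 2
    us = []
    for idx in combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in set(idx)]
        us.append(sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys))
    p = sum(abs(u_ - center) >= abs(u - center) - 1e-12 for u_ in us) / len(us)
    return u, p


class TestMannWhitney:
    def test_worked_case(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.U == 0
        assert res.p == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_samples_give_central_u(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.U == pytest.approx(4.5)  # n*m/2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_u_matches_pair_count_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            u, _ = mann_whitney_oracle(x, y)
            assert mann_whitney_u(x, y).U == pytest.approx(u)

    def test_exact_p_matches_enumeration(self, rng):
        """Exact two-sided p equals full enumeration for small no-tie draws."""
        for _ in range(200):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 11 - n))
            pooled = rng.permutation(np.arange(n + m, dtype=float) + 1)
            x, y = pooled[:n], pooled[n:]
            u, p = mann_whitney_oracle(x, y)
            res = mann_whitney_u(x, y)
            assert res.method == "exact"
            assert res.U == pytest.approx(u)
            assert res.p == pytest.approx(p)

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney_u([1, 1, 2], [1, 3, 4])
        assert res.method == "asymptotic"
        assert 0 < res.p <= 1

    def test_large_samples_use_asymptotic(self, rng):
        res = mann_whitney_u(rng.normal(size=50), rng.normal(1, size=50))
        assert res.method == "asymptotic"
        assert res.p < 0.05


class TestPileupProfile:
    def lib(self, sites, name="lib"):
        return TagLibrary(name, {"chr1": sites}, 10_000_000)

    def test_all_tags_at_summit_fill_central_bin(self):
        peak = make_peak("chr1", 900, 1100, summit=1000)
        prof = pileup_profile([peak], self.lib([1000] * 10), halfwidth=100, bin_size=50)
        assert prof.loc[0] == pytest.approx(10 / 50)
        assert prof.drop(0).eq(0).all()

    def test_uniform_tags_flat_profile(self):
        peak = make_peak("chr1", 900, 1100, summit=1000)
        prof = pileup_profile([peak], self.lib(list(range(900, 1100))), 100, 50)
        np.testing.assert_allclose(prof.to_numpy(), 1.0)  # one tag per base, scale 1

    def test_mirrored_tags_give_mirrored_profile(self):
        peak = make_peak("chr1", 900, 1100, summit=1000)
        # mirror pairs reflect about the summit boundary: d <-> -d-1
        sites = [1000 + d for d in (-81, 80, -31, 30, -11, 10)]
        prof = pileup_profile([peak], self.lib(sites), 100, 20)
        np.testing.assert_allclose(prof.to_numpy(), prof.to_numpy()[::-1])

    def test_matches_per_peak_loop_oracle(self, rng):
        peaks = [
            make_peak("chr1", s, s + 400, summit=s + 200, name=f"p{i}")
            for i, s in enumerate(rng.integers(2000, 400_000, size=100))
        ]
        lib = self.lib(sorted(int(v) for v in rng.integers(0, 401_000, size=20_000)))
        halfwidth, bin_size = 200, 25
        prof = pileup_profile(peaks, lib, halfwidth, bin_size)
        sites = lib.sites("chr1")
        expected = np.zeros(2 * halfwidth // bin_size)
        for p in peaks:
            for b in range(expected.size):
                lo = p.summit - halfwidth + b * bin_size
                cnt = np.searchsorted(sites, lo + bin_size) - np.searchsorted(sites, lo)
                expected[b] += cnt * lib.scale / bin_size
        np.testing.assert_allclose(prof.to_numpy(), expected / len(peaks))

    def test_halfwidth_must_tile_bins(self):
        with pytest.raises(ValueError):
            pileup_profile([make_peak("chr1", 0, 100)], self.lib([]), 100, 33)


class TestMovingAverage:
    def test_edge_clipped_window(self):
        out = moving_average_density([1, 2, 3, 4, 5], 3)
        np.testing.assert_allclose(out, [1.5, 2, 3, 4, 4.5])

    def test_window_one_is_identity(self, rng):
        v = rng.normal(size=20)
        np.testing.assert_array_equal(moving_average_density(v, 1), v)

    def test_matches_naive_loop(self, rng):
        v = rng.normal(size=200)
        w = 51
        out = moving_average_density(v, w)
        half = w // 2
        expected = [
            np.mean(v[max(0, i - half) : min(len(v), i + half + 1)])
            for i in range(len(v))
        ]
        np.testing.assert_allclose(out, expected)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_zero_window_rejected(self, window):
        with pytest.raises(ValueError):
            moving_average_density([1, 2, 3], window)

    def test_window_longer_than_input_rejected(self):
        with pytest.raises(ValueError):
            moving_average_density([1, 2, 3], 5)


class TestFoldChangeScreen:
    def series(self, d):
        return pd.Series(d)

    def test_kept_when_ratio_exceeds_one(self):
        a = self.series({"g": 10.0})
        b = self.series({"g": 4.0})
        assert fold_change_screen(a, b) == ["g"]  # (10+1)/(4+1) = 2.2

    def test_equal_expression_not_kept(self):
        a = self.series({"g": 7.0})
        assert fold_change_screen(a, a.copy()) == []

    def test_toy_table_matches_hand_enumeration(self):
        a = self.series({"g1": 10, "g2": 4, "g3": 0, "g4": 9, "g5": 100, "g6": 3})
        b = self.series({"g1": 4, "g2": 10, "g3": 0, "g4": 9, "g5": 10, "g6": 2})
        # hand-computed (x+1)/(y+1): g1 2.2, g2 0.45, g3 1, g4 1, g5 9.18, g6 4/3
        assert fold_change_screen(a, b) == ["g1", "g5", "g6"]

    def test_log2_mode(self):
        a = self.series({"g1": 10, "g2": 4})
        b = self.series({"g1": 4, "g2": 3})
        # log2(11/5)=1.14 > 1; log2(5/4)=0.32 < 1
        assert fold_change_screen(a, b, fc_threshold=1.0, log2=True) == ["g1"]

    def test_idempotent_on_survivors(self):
        a = self.series({"g1": 10.0, "g2": 1.0, "g3": 50.0})
        b = self.series({"g1": 2.0, "g2": 5.0, "g3": 10.0})
        kept = fold_change_screen(a, b)
        again = fold_change_screen(a.loc[kept], b.loc[kept])
        assert again == kept

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            fold_change_screen(self.series({"g": -1.0}), self.series({"g": 1.0}))

    def test_roster_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fold_change_screen(self.series({"g1": 1.0}), self.series({"g2": 1.0}))


class TestMotifFilter:
    def test_rule_table(self):
        records = [
            MotifRecord("kept_ratio3", 0.005, 15, 5),
            MotifRecord("dropped_p", 0.02, 15, 5),
            MotifRecord("dropped_ratio", 0.005, 6, 5),
            MotifRecord("kept_inf", 0.001, 3, 0),
            MotifRecord("dropped_absent", 0.001, 0, 0),
            MotifRecord("dropped_boundary_p", 0.01, 15, 5),
            MotifRecord("dropped_boundary_ratio", 0.005, 7.5, 5),
        ]
        kept = [r.name for r in motif_filter(records)]
        assert kept == ["kept_ratio3", "kept_inf"]

    def test_idempotent(self):
        records = [MotifRecord("a", 0.001, 30, 5), MotifRecord("b", 0.5, 30, 5)]
        once = motif_filter(records)
        assert motif_filter(once) == once

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            MotifRecord("bad", 0.0, 10, 5)
        with pytest.raises(ValueError):
            MotifRecord("bad", 0.5, 120, 5)
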
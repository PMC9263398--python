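"""Dynamic metrics (ALFF, mALFF, mdALFF, seed dFC) against independent
brute-force oracles and their invariance properties."""

import numpy as np
import pandas as pd
import pytest

from dynconn.atlas import ParcellationAtlas
from dynconn.cohort import RoiTimeSeries
from dynconn.metrics import (WindowSpec, aggregate_units_to_roi, compute_alff,
                             compute_dfc_seed, compute_mdalff, make_windows,
                             normalize_malff)

TR = 2.5


# ---------------------------------------------------------------------------
# independent oracles (no shared code with the implementation)
# ---------------------------------------------------------------------------

def alff_oracle(x, tr, low, high):
    """O(N^2) DFT: explicit exponential sums, one-sided amplitude scaling."""
    x = np.asarray(x, float)
    N = len(x)
    total = 0.0
    count = 0
    for k in range(N // 2 + 1):
        f = k / (N * tr)
        if low - 1e-12 <= f <= high + 1e-12:
            re = sum(x[t] * np.cos(2 * np.pi * k * t / N) for t in range(N))
            im = sum(-x[t] * np.sin(2 * np.pi * k * t / N) for t in range(N))
            mag = np.hypot(re, im)
            scale = 1.0 / N if (k == 0 or (N % 2 == 0 and k == N // 2)) else 2.0 / N
            total += scale * mag
            count += 1
    return total / count


class TestWindows:
    def test_published_window_arithmetic(self):
        """200 volumes - 10 trimmed with 50/10 windows -> exactly 15 windows,
        first [0, 50), last [140, 190)."""
        wins = make_windows(190, WindowSpec(50, 10))
        assert len(wins) == 15
        assert wins[0] == (0, 50)
        assert wins[-1] == (140, 190)

    def test_single_window(self):
        assert make_windows(50, WindowSpec(50, 10)) == [(0, 50)]

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_windows(49, WindowSpec(50, 10))

    @pytest.mark.parametrize("T,length,step", [(190, 50, 10), (100, 30, 7),
                                               (64, 64, 1)])
    def test_count_formula(self, T, length, step):
        wins = make_windows(T, WindowSpec(length, step))
        assert len(wins) == (T - length) // step + 1
        assert all(b - a == length for a, b in wins)
        assert wins[-1][1] <= T


class TestAlff:
    def test_zero_signal(self):
        assert compute_alff(np.zeros(190), TR) == 0.0

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=190)
        assert compute_alff(3.7 * x, TR) == pytest.approx(
            3.7 * compute_alff(x, TR), rel=1e-12)

    def test_sinusoid_closed_form(self):
        """A 0.04 Hz amplitude-2 sinusoid lands on DFT bin 19 of a 190-sample
        series; with 34 bins in 0.01-0.08 Hz the ALFF is exactly 2/34."""
        t = np.arange(190) * TR
        x = 2.0 * np.sin(2 * np.pi * 0.04 * t)
        assert compute_alff(x, TR, (0.01, 0.08)) == pytest.approx(2.0 / 34, rel=1e-10)

    def test_matches_bruteforce_dft_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            T = int(rng.integers(40, 120))
            x = rng.normal(size=T)
            got = compute_alff(x, TR, (0.01, 0.08))
            want = alff_oracle(x, TR, 0.01, 0.08)
            assert got == pytest.approx(want, rel=1e-10)

    def test_no_bin_in_band_reports_grid(self):
        with pytest.raises(ValueError, match="bin"):
            compute_alff(np.ones(20), TR, (0.001, 0.002))


class TestMalff:
    def test_uniform_alff_gives_ones(self):
        np.testing.assert_allclose(normalize_malff(np.full(7, 5.0)), 1.0)

    def test_two_unit_example(self):
        np.testing.assert_allclose(normalize_malff(np.array([1.0, 3.0])),
                                   [0.5, 1.5])

    def test_mask_mean_is_one(self):
        rng = np.random.default_rng(2)
        alff = rng.uniform(0.5, 2.0, size=273)
        assert normalize_malff(alff).mean() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_global_mean(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_malff(np.zeros(5))


class TestAggregation:
    def test_identity_with_one_unit_per_roi(self):
        vals = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            aggregate_units_to_roi(vals, [1, 2, 3], np.array([1, 2, 3])), vals)

    def test_mean_within_roi(self):
        out = aggregate_units_to_roi(np.array([1.0, 2.0, 3.0]),
                                     [5, 5, 5], np.array([5]))
        assert out[0] == pytest.approx(2.0)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(3)
        units = rng.normal(size=60)
        mapping = rng.integers(1, 8, size=60)
        roi_ids = np.arange(1, 8)
        got = aggregate_units_to_roi(units, mapping, roi_ids)
        for i, roi in enumerate(roi_ids):
            sel = units[mapping == roi]
            if sel.size:
                assert got[i] == pytest.approx(sel.mean(), rel=1e-12)
            else:
                assert np.isnan(got[i])


def _toy_atlas(n):
    return ParcellationAtlas(pd.DataFrame({
        "roi_id": np.arange(1, n + 1),
        "network": ["NetA" if i % 2 else "NetB" for i in range(n)],
        "anatomy": [f"r{i}" for i in range(n)],
        "hemisphere": ["left"] * n,
        "x": np.zeros(n), "y": np.zeros(n), "z": np.zeros(n),
    }))


class TestMdalff:
    def test_stationary_sinusoids_mean_one_var_tiny(self):
        """Equal-amplitude stationary signals in every ROI: window-wise
        normalisation forces mdALFF_mean = 1 and near-zero variance."""
        atlas = _toy_atlas(5)
        t = np.arange(190) * TR
        data = np.vstack([np.sin(2 * np.pi * 0.04 * t + p)
                          for p in np.linspace(0, 3, 5)])
        series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        out = compute_mdalff(series, atlas, WindowSpec(50, 10))
        np.testing.assert_allclose(out["mdalff_mean"], 1.0, atol=1e-6)
        assert (out["mdalff_var"] < 1e-3).all()

    def test_envelope_doubling_maximises_variance(self):
        """Doubling one ROI's amplitude in half of the scan makes its
        across-window variance strictly the largest."""
        atlas = _toy_atlas(6)
        rng = np.random.default_rng(4)
        data = rng.normal(size=(6, 190))
        env = np.ones(190)
        env[95:] = 2.0
        data[3] *= env
        series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        out = compute_mdalff(series, atlas, WindowSpec(50, 10))
        assert out["mdalff_var"].idxmax() == 3

    def test_single_window_variance_zero(self):
        atlas = _toy_atlas(4)
        data = np.random.default_rng(5).normal(size=(4, 50))
        series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        out = compute_mdalff(series, atlas, WindowSpec(50, 10))
        assert (out["mdalff_var"] == 0).all()

    def test_scale_invariance(self):
        """A common multiplicative factor on every unit leaves mALFF-based
        metrics unchanged to 1e-10."""
        atlas = _toy_atlas(5)
        data = np.random.default_rng(6).normal(size=(5, 190))
        s1 = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        s2 = RoiTimeSeries("s", 41.7 * data, TR, unit_roi_ids=atlas.roi_ids)
        a = compute_mdalff(s1, atlas)
        b = compute_mdalff(s2, atlas)
        np.testing.assert_allclose(a["mdalff_mean"], b["mdalff_mean"], atol=1e-10)
        np.testing.assert_allclose(a["mdalff_var"], b["mdalff_var"], atol=1e-10)

    def test_window_consistency(self):
        """Externally recomputing mean/variance from per-window mALFF values
        reproduces the table exactly."""
        atlas = _toy_atlas(4)
        data = np.random.default_rng(7).normal(size=(4, 100))
        series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        spec = WindowSpec(30, 10)
        out = compute_mdalff(series, atlas, spec)
        per_window = []
        for a, b in make_windows(100, spec):
            alff = np.array([compute_alff(data[u, a:b], TR) for u in range(4)])
            per_window.append(alff / alff.mean())
        per_window = np.array(per_window)            # (n_win, units)
        np.testing.assert_allclose(out["mdalff_mean"], per_window.mean(0),
                                   rtol=1e-12)
        np.testing.assert_allclose(out["mdalff_var"],
                                   per_window.var(0, ddof=1), rtol=1e-12)


class TestDfc:
    def _atlas_series(self, n=4, T=190, seed=8):
        atlas = _toy_atlas(n)
        data = np.random.default_rng(seed).normal(size=(n, T))
        return atlas, data

    def test_identical_target_saturates(self):
        atlas, data = self._atlas_series()
        data[1] = data[0]
        series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        out = compute_dfc_seed(series, 1, atlas, WindowSpec(50, 10))
        row = out[out["target_roi"] == 2].iloc[0]
        assert row["dfc_mean"] == pytest.approx(np.arctanh(1 - 1e-7), rel=1e-9)
        assert row["dfc_var"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_target(self):
        atlas, data = self._atlas_series()
        data[2] = -data[0]
        series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        out = compute_dfc_seed(series, 1, atlas, WindowSpec(50, 10))
        row = out[out["target_roi"] == 3].iloc[0]
        assert row["dfc_mean"] == pytest.approx(-np.arctanh(1 - 1e-7), rel=1e-9)

    def test_seed_excluded_from_targets(self):
        atlas, data = self._atlas_series()
        series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        out = compute_dfc_seed(series, 2, atlas, WindowSpec(50, 10))
        assert 2 not in set(out["target_roi"])
        assert len(out) == 3

    def test_white_noise_levels(self):
        """Independent white-noise pairs: near-zero mean coupling and a
        Fisher-Z variance on the order of 1/(L-3), checked as a Monte-Carlo
        average over 100 seed/target draws."""
        rng = np.random.default_rng(9)
        atlas = _toy_atlas(2)
        means, varis = [], []
        for _ in range(100):
            data = rng.normal(size=(2, 190))
            series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
            out = compute_dfc_seed(series, 1, atlas, WindowSpec(50, 10))
            means.append(out["dfc_mean"].iloc[0])
            varis.append(out["dfc_var"].iloc[0])
        c = 1.0 / (50 - 3)
        assert abs(np.mean(means)) < 0.15
        assert 0.1 * c <= np.mean(varis) <= 10 * c

    def test_affine_invariance(self):
        """Pearson property: affine rescaling of either ROI's series leaves
        the dFC table unchanged."""
        atlas, data = self._atlas_series()
        s1 = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        data2 = data.copy()
        data2[0] = 5.0 * data2[0] - 3.0
        data2[2] = -2.0 * data2[2] + 1.0   # sign flip allowed: r flips sign
        s2 = RoiTimeSeries("s", data2, TR, unit_roi_ids=atlas.roi_ids)
        a = compute_dfc_seed(s1, 1, atlas, WindowSpec(50, 10))
        b = compute_dfc_seed(s2, 1, atlas, WindowSpec(50, 10))
        np.testing.assert_allclose(b[b.target_roi == 2]["dfc_mean"],
                                   a[a.target_roi == 2]["dfc_mean"], atol=1e-10)
        np.testing.assert_allclose(b[b.target_roi == 3]["dfc_mean"],
                                   -a[a.target_roi == 3]["dfc_mean"], atol=1e-10)

    def test_zero_variance_window_reported(self):
        atlas, data = self._atlas_series()
        data[1, :] = 7.0
        series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        with pytest.raises(ValueError, match="zero-variance"):
            compute_dfc_seed(series, 1, atlas, WindowSpec(50, 10))


class TestBruteForceEquivalence:
    """Full mdALFF and dFC tables on a 5-ROI, 70-timepoint toy cohort against
    a straight-line reimplementation sharing no code with the package."""

    def _naive_tables(self, data, tr, length, step, low, high, seed_pos):
        T = data.shape[1]
        starts = []
        s = 0
        while s + length <= T:
            starts.append(s)
            s += step
        malff_rows = []
        z_rows = []
        for a in starts:
            seg = data[:, a:a + length]
            alff = np.array([alff_oracle(seg[u], tr, low, high)
                             for u in range(data.shape[0])])
            malff_rows.append(alff / alff.mean())
            zs = []
            for u in range(data.shape[0]):
                x, y = seg[seed_pos], seg[u]
                r = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
                r = max(min(r, 1 - 1e-7), -1 + 1e-7)
                zs.append(np.arctanh(r))
            z_rows.append(zs)
        malff = np.array(malff_rows)
        z = np.array(z_rows)
        return (malff.mean(0), malff.var(0, ddof=1),
                z.mean(0), z.var(0, ddof=1))

    def test_tables_match_to_1e10(self):
        atlas = _toy_atlas(5)
        rng = np.random.default_rng(10)
        data = rng.normal(size=(5, 70))
        series = RoiTimeSeries("s", data, TR, unit_roi_ids=atlas.roi_ids)
        spec = WindowSpec(20, 10)
        md = compute_mdalff(series, atlas, spec, band=(0.01, 0.08))
        dfc = compute_dfc_seed(series, 3, atlas, spec)
        m_mean, m_var, z_mean, z_var = self._naive_tables(
            data, TR, 20, 10, 0.01, 0.08, seed_pos=2)
        np.testing.assert_allclose(md["mdalff_mean"], m_mean, rtol=1e-10)
        np.testing.assert_allclose(md["mdalff_var"], m_var, rtol=1e-10)
        targets = dfc["target_roi"].to_numpy()
        keep = [i for i in range(5) if i != 2]
        np.testing.assert_allclose(dfc["dfc_mean"], z_mean[keep], rtol=1e-10)
        np.testing.assert_allclose(dfc["dfc_var"], z_var[keep], atol=1e-10)
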
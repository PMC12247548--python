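import functools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiocohere import (HrTrace, bivariate_coherence, dtw_coherence,
                          dtw_distance, lag_map, match_condition_lengths,
                          xcorr_max)
from cardiocohere.cardiac import zscore


def brute_force_dtw(a, b):
    """Memoized recursive DTW oracle: unbanded, squared cost, sqrt at the end."""
    a = tuple(float(v) for v in a)
    b = tuple(float(v) for v in b)

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 and j == 0:
            return 0.0
        if i == 0 or j == 0:
            return float("inf")
        cost = (a[i - 1] - b[j - 1]) ** 2
        return cost + min(rec(i - 1, j - 1), rec(i - 1, j), rec(i, j - 1))

    return np.sqrt(rec(len(a), len(b)))


def _hr(values, tr=0.7, lag=6.0):
    return HrTrace(zscore(values), tr, applied_lag_s=lag, z_normalized=True)


class TestMatchConditionLengths:
    def test_head_of_longer_dropped(self):
        a, b = match_condition_lengths(np.arange(686), np.arange(471))
        assert len(a) == len(b) == 471
        assert a[0] == 215  # first 215 samples of the longer removed

    def test_equal_lengths_unchanged(self):
        a, b = match_condition_lengths(np.arange(5), np.arange(5) + 10)
        np.testing.assert_array_equal(a, np.arange(5))

    def test_degenerate_single_sample(self):
        a, b = match_condition_lengths(np.arange(9), np.array([3.0]))
        assert len(a) == len(b) == 1
        assert a[0] == 8


class TestBivariateCoherence:
    def test_identity_clipped(self, rng):
        v = rng.normal(size=100)
        hr = _hr(v)
        rec = bivariate_coherence(hr, zscore(v))
        assert rec.value == pytest.approx(np.arctanh(1 - 1e-7), abs=1e-9)
        assert rec.value > 8

    def test_orthogonal_series_near_zero(self, rng):
        x = rng.normal(size=400)
        x -= x.mean()
        y = rng.normal(size=400)
        y -= x * (x @ y) / (x @ x)  # orthogonal to the centered x
        rec = bivariate_coherence(_hr(x), y)
        assert abs(rec.value) < 1e-10

    def test_half_correlation_closed_form(self, rng):
        x = zscore(rng.normal(size=500))
        e = rng.normal(size=500)
        e = zscore(e - x * (x @ e) / (x @ x))
        y = 0.5 * x + np.sqrt(1 - 0.25) * e
        rec = bivariate_coherence(_hr(x), y)
        assert rec.value == pytest.approx(np.arctanh(0.5), abs=1e-9)
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        z1 = bivariate_coherence(_hr(x), y).value
        z2 = bivariate_coherence(_hr(x), 3.0 * y - 7.0).value
        assert z1 == pytest.approx(z2, abs=1e-10)

    def test_constant_input_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            bivariate_coherence(_hr(rng.normal(size=50)), np.ones(50))


class TestDtwDistance:
    def test_identical_series_zero(self, rng):
        v = rng.normal(size=40)
        assert dtw_distance(v, v, 14) == 0.0

    def test_toy_pair_zero(self):
        # path (1,1)(2,1)(3,2)(3,3) has zero accumulated cost
        assert dtw_distance([0, 0, 1], [0, 1, 1], 1) == 0.0

    def test_toy_pair_sqrt2(self):
        for band in (0, 1, 5):
            assert dtw_distance([0, 1], [1, 0], band) == pytest.approx(
                np.sqrt(2), abs=1e-12)

    def test_symmetric(self, rng):
        a, b = rng.normal(size=(2, 25))
        assert dtw_distance(a, b, 5) == pytest.approx(dtw_distance(b, a, 5),
                                                      abs=1e-12)

    def test_zero_iff_identical(self, rng):
        a = rng.normal(size=20)
        b = a.copy()
        b[7] += 1e-3
        assert dtw_distance(a, b, 14) > 0

    def test_band_monotonicity(self, rng):
        a, b = rng.normal(size=(2, 60))
        dists = [dtw_distance(a, b, band) for band in (0, 2, 5, 10, 30, 60)]
        assert all(d1 >= d2 - 1e-12 for d1, d2 in zip(dists, dists[1:]))

    def test_band_zero_is_pointwise_distance(self, rng):
        a, b = rng.normal(size=(2, 30))
        assert dtw_distance(a, b, 0) == pytest.approx(
            np.linalg.norm(a - b), abs=1e-12)

    def test_band_narrower_than_length_gap_rejected(self):
        with pytest.raises(ValueError, match="band"):
            dtw_distance(np.zeros(10), np.zeros(3), 2)

    @settings(deadline=None, max_examples=80)
    @given(st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, n, seed):
        r = np.random.default_rng(seed)
        a = r.integers(-1, 2, n).astype(float)
        b = r.integers(-1, 2, n).astype(float)
        assert dtw_distance(a, b, None) == pytest.approx(
            brute_force_dtw(a, b), abs=1e-12)

    def test_dtw_coherence_requires_equal_lengths(self, rng):
        hr = _hr(rng.normal(size=50))
        with pytest.raises(ValueError, match="match_condition_lengths"):
            dtw_coherence(hr, rng.normal(size=40))


class TestXcorrMax:
    def test_self_recovery_at_seven_trs(self, rng):
        base = np.cumsum(rng.normal(size=200))  # smooth-ish random walk
        hr = _hr(base)
        neural = np.empty_like(hr.values)
        neural[7:] = hr.values[:-7]
        neural[:7] = hr.values[0]
        rec = xcorr_max(hr, neural)
        assert rec.lag_s_at_max == pytest.approx(6.0 + 7 * 0.7, abs=1e-9)
        assert np.tanh(rec.value) > 0.95

    def test_value_at_least_bivariate_at_nominal_lag(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.normal(size=150)
            y = r.normal(size=150)
            hr = _hr(x)
            z_nominal = bivariate_coherence(hr, y).value
            z_max = xcorr_max(hr, y).value
            assert z_max >= z_nominal - 1e-12

    def test_no_positive_peak_flagged(self):
        ramp = np.linspace(0, 1, 60)
        hr = _hr(ramp)
        rec = xcorr_max(hr, -ramp)
        assert rec.value == 0.0
        assert rec.flags == "no_positive_peak"
        assert rec.lag_s_at_max is None

    def test_selection_bias_on_white_noise(self):
        # maximizing over lags inflates the null: mean max-z is positive
        zs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            hr = _hr(r.normal(size=120))
            zs.append(xcorr_max(hr, r.normal(size=120)).value)
        assert np.mean(zs) > 0.05

    def test_min_overlap_guard(self, rng):
        hr = _hr(rng.normal(size=35))
        with pytest.raises(ValueError, match="overlap"):
            xcorr_max(hr, rng.normal(size=35), min_overlap=40)


@pytest.fixture(scope="module")
def blob_run():
    import cardiocohere as cc
    from cardiocohere.cardiac import _legendre_design
    cfg = cc.SimConfig(seed=3, duration_s={"control": 200.0},
                       volume_grid=(10, 10, 10))
    bpm, latent = cc.simulate_hr(cfg, 0, "control")
    n_vols = cfg.n_vols("control")
    vol, blob = cc.simulate_volume(cfg, latent, bpm.sample_times,
                                   "control", 0)
    order = cc.auto_polort_order(n_vols * cfg.tr_s)
    resid = cc.residualize(vol, _legendre_design(n_vols, order))
    hr = cc.prepare_hr(bpm, cfg.tr_s, n_vols, 6.0)
    return cc.lag_map(resid, hr), blob


class TestLagMap:
    def test_blob_voxels_elevated_over_background(self, blob_run):
        lm, blob = blob_run
        bg = lm.z[~blob.data & lm.brain_mask]
        assert lm.z[blob.data].mean() > bg.mean() + 0.2

    def test_blob_lag_recovered(self, blob_run):
        lm, blob = blob_run
        in_blob = lm.lag_s[blob.data]
        assert abs(np.nanmedian(in_blob) - 6.0) <= 0.7  # within 1 TR

    def test_lags_within_search_range(self, blob_run):
        lm, _ = blob_run
        finite = lm.lag_s[np.isfinite(lm.lag_s)]
        assert finite.min() >= lm.search_lags_s.min() - 1e-9
        assert finite.max() <= lm.search_lags_s.max() + 1e-9

    def test_deterministic(self, blob_run):
        import cardiocohere as cc
        from cardiocohere.cardiac import _legendre_design
        cfg = cc.SimConfig(seed=3, duration_s={"control": 200.0},
                           volume_grid=(10, 10, 10))
        bpm, latent = cc.simulate_hr(cfg, 0, "control")
        n_vols = cfg.n_vols("control")
        vol, _ = cc.simulate_volume(cfg, latent, bpm.sample_times,
                                    "control", 0)
        resid = cc.residualize(
            vol, _legendre_design(n_vols, cc.auto_polort_order(n_vols * 0.7)))
        hr = cc.prepare_hr(bpm, cfg.tr_s, n_vols, 6.0)
        lm2 = cc.lag_map(resid, hr)
        np.testing.assert_array_equal(lm2.z, blob_run[0].z)
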
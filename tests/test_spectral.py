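import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from helpers import run_from_series

from falff.io import AmplitudeMap
from falff.spectral import (
    BandSpec,
    alff_map,
    band_power,
    build_confound_matrix,
    falff_map,
    gbold_beta_map,
    normalize_map,
    regress_confounds,
    tsnr_map,
)

BAND = BandSpec(0.008, 0.1)


def ideal_bandpass_rms(x, tr, band):
    """Oracle: zero all out-of-band bins, invert, take the time-domain RMS."""
    x = np.asarray(x, float)
    n = x.shape[-1]
    spec = np.fft.rfft(x - x.mean(axis=-1, keepdims=True), axis=-1)
    freqs = np.fft.rfftfreq(n, tr)
    keep = (freqs >= band.low) & (freqs <= band.high)
    spec[..., ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=n, axis=-1)
    return np.sqrt((filtered ** 2).mean(axis=-1))


class TestConfoundMatrix:
    def test_full_rank_gives_orthogonal_components(self, rng):
        motion = rng.normal(size=(100, 6))
        cm = build_confound_matrix(motion, rng.normal(size=100), rng.normal(size=100), 6)
        assert cm.n_components == 6
        gram = cm.components.T @ cm.components
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()
        np.testing.assert_allclose(cm.components.mean(axis=0), 0.0, atol=1e-10)

    def test_duplicate_columns_reduce_rank(self, rng, caplog):
        base = rng.normal(size=(50, 3))
        motion = np.hstack([base, base])  # rank 3 motion block
        csf = base[:, 0].copy()
        wm = base[:, 1].copy()
        with caplog.at_level("WARNING"):
            cm = build_confound_matrix(motion, csf, wm, 6)
        assert cm.n_components == 3
        assert any("rank" in r.message for r in caplog.records)

    def test_explained_variance_nonincreasing(self, rng):
        cm = build_confound_matrix(
            rng.normal(size=(80, 6)), rng.normal(size=80), rng.normal(size=80), 6
        )
        assert (np.diff(cm.explained_variance) <= 1e-12).all()


class TestRegressConfounds:
    def test_series_equal_to_confound_becomes_flat(self, rng):
        motion = rng.normal(size=(60, 6))
        cm = build_confound_matrix(motion, rng.normal(size=60), rng.normal(size=60), 6)
        series = 3.0 * cm.components[:, 0] + 7.0
        run = run_from_series(series)
        out = regress_confounds(run, cm)
        resid = out.data[0, 0, 0]
        assert resid.std() < 1e-10
        assert resid.mean() == pytest.approx(7.0, abs=1e-9)  # mean re-added

    def test_residuals_orthogonal_to_confounds(self, rng):
        motion = rng.normal(size=(60, 6))
        cm = build_confound_matrix(motion, rng.normal(size=60), rng.normal(size=60), 6)
        run = run_from_series(rng.normal(size=(5, 60)))
        out = regress_confounds(run, cm)
        resid = out.data.reshape(5, 60) - out.data.reshape(5, 60).mean(axis=1, keepdims=True)
        for j in range(cm.n_components):
            col = cm.components[:, j]
            dots = np.abs(resid @ col)
            assert dots.max() <= 1e-8 * np.linalg.norm(col) * np.linalg.norm(resid, axis=1).max()

    def test_zero_components_is_identity(self, rng):
        run = run_from_series(rng.normal(size=(3, 40)))
        cm = build_confound_matrix(None, None, None, 6)
        out = regress_confounds(run, cm)
        np.testing.assert_array_equal(out.data, run.data)


class TestAlff:
    def test_pure_in_band_sinusoid_rms(self):
        n, tr, amp, freq = 1000, 0.8, 2.5, 0.05
        t = np.arange(n) * tr
        run = run_from_series(amp * np.sin(2 * np.pi * freq * t) + 50.0, tr)
        alff = alff_map(run, BAND).values[0, 0, 0]
        assert alff == pytest.approx(amp / np.sqrt(2), rel=1e-9)

    def test_degree_one_homogeneity(self, rng):
        x = rng.normal(size=(4, 240))
        a1 = alff_map(run_from_series(x), BAND).values.ravel()
        a2 = alff_map(run_from_series(2.0 * x), BAND).values.ravel()
        np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-12)

    def test_matches_time_domain_bandpass_oracle(self, rng):
        x = rng.normal(size=(50, 300))
        run = run_from_series(x, 0.72)
        alff = alff_map(run, BAND).values.ravel()
        oracle = ideal_bandpass_rms(x, 0.72, BAND)
        np.testing.assert_allclose(alff, oracle, rtol=1e-10)

    def test_empty_band_raises_with_bin_count(self):
        run = run_from_series(np.random.default_rng(0).normal(size=20), tr=0.8)
        with pytest.raises(ValueError, match="bins"):
            band_power(run.data.reshape(1, -1), 0.8, BandSpec(0.0101, 0.0102))

    def test_out_of_band_drift_leaves_alff_lowers_falff(self, rng):
        n, tr = 480, 0.8
        x = rng.normal(size=(20, n))
        # exactly 2 cycles over the window: on-bin at 0.0052 Hz, below the band
        drift = 5.0 * np.sin(2 * np.pi * 2 * np.arange(n) / n)
        a0 = alff_map(run_from_series(x, tr), BAND).values.ravel()
        a1 = alff_map(run_from_series(x + drift, tr), BAND).values.ravel()
        f0 = falff_map(run_from_series(x, tr), BAND).values.ravel()
        f1 = falff_map(run_from_series(x + drift, tr), BAND).values.ravel()
        np.testing.assert_allclose(a0, a1, rtol=1e-8)
        assert (f1 < f0).all()


class TestFalff:
    def test_all_power_in_band_gives_one(self, rng):
        n, tr = 400, 0.8
        freqs = np.fft.rfftfreq(n, tr)
        spec = np.zeros(len(freqs), complex)
        sel = (freqs >= 0.01) & (freqs <= 0.09)
        spec[sel] = rng.normal(size=sel.sum()) + 1j * rng.normal(size=sel.sum())
        x = np.fft.irfft(spec, n)
        val = falff_map(run_from_series(x, tr), BAND).values[0, 0, 0]
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_out_of_band_sinusoid_gives_zero(self):
        n, tr = 200, 0.8
        x = np.sin(2 * np.pi * 0.3 * np.arange(n) * tr)  # 0.3 Hz, above band
        val = falff_map(run_from_series(x, tr), BAND).values[0, 0, 0]
        assert val < 1e-6

    def test_white_noise_expectation_flat_spectrum(self, rng):
        # flat spectrum: band power fraction ~ band width / Nyquist
        n, tr = 480, 0.8
        x = rng.normal(size=(200, n))
        vals = falff_map(run_from_series(x, tr), BAND).values.ravel()
        expected = np.sqrt(0.092 / 0.625)
        assert vals.mean() == pytest.approx(expected, abs=0.02)

    @pytest.mark.parametrize(
        "series",
        [
            np.zeros(100),                                   # constant
            np.eye(1, 100, 50).ravel() * 100,                # single spike
            np.linspace(0, 10, 100),                         # pure drift
        ],
        ids=["constant", "spike", "drift"],
    )
    def test_bounds_on_adversarial_inputs(self, series):
        val = falff_map(run_from_series(series, 0.8), BAND).values[0, 0, 0]
        assert 0.0 <= val <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        x=hnp.arrays(np.float64, (64,), elements=st.floats(-1e3, 1e3)),
        scale=st.floats(1e-3, 1e3),
    )
    def test_bounded_and_scale_invariant(self, x, scale):
        v0 = falff_map(run_from_series(x, 0.8), BAND).values[0, 0, 0]
        v1 = falff_map(run_from_series(scale * x, 0.8), BAND).values[0, 0, 0]
        assert 0.0 <= v0 <= 1.0
        if np.std(x) > 1e-6:
            assert v1 == pytest.approx(v0, rel=1e-9, abs=1e-12)


class TestTsnr:
    def test_known_mean_and_sd(self):
        x = np.array([90.0, 110.0] * 50)  # mean 100, sd ~10.05 (ddof=1)
        run = run_from_series(x)
        val = tsnr_map(run).values[0, 0, 0]
        assert val == pytest.approx(100.0 / x.std(ddof=1), rel=1e-12)

    def test_constant_series_gives_sentinel(self):
        run = run_from_series(np.full(30, 7.0))
        assert np.isposinf(tsnr_map(run).values[0, 0, 0])

    def test_monte_carlo_convergence(self, rng):
        c, sigma = 100.0, 4.0
        x = c + sigma * rng.normal(size=(100, 4000))
        vals = tsnr_map(run_from_series(x)).values.ravel()
        assert vals.mean() == pytest.approx(c / sigma, rel=0.02)


class TestNormalize:
    def test_uniform_map_becomes_ones(self):
        amap = AmplitudeMap(np.full((4, 4, 4), 3.3), metric="ALFF")
        out = normalize_map(amap, np.ones((4, 4, 4), bool))
        np.testing.assert_allclose(out.values, 1.0)
        assert out.normalized

    def test_two_values_split_around_one(self):
        vals = np.ones((4, 4, 4))
        vals[:2] = 1.0
        vals[2:] = 3.0
        out = normalize_map(AmplitudeMap(vals, metric="fALFF"), np.ones((4, 4, 4), bool))
        assert set(np.round(np.unique(out.values), 10)) == {0.5, 1.5}

    def test_idempotent(self, rng):
        vals = rng.uniform(0.5, 2.0, (5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        once = normalize_map(AmplitudeMap(vals, metric="ALFF"), mask)
        twice = normalize_map(once, mask)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_nonpositive_mean_rejected(self):
        amap = AmplitudeMap(np.zeros((3, 3, 3)), metric="ALFF")
        with pytest.raises(ValueError, match="normalize"):
            normalize_map(amap, np.ones((3, 3, 3), bool))


class TestGboldBeta:
    def _run_with_global(self, rng, slope, n_vox=200, t=2000):
        g = rng.normal(size=t)
        data = np.empty((n_vox, t))
        data[: n_vox // 2] = g + 0.01 * rng.normal(size=(n_vox // 2, t))
        data[n_vox // 2:] = slope * g + rng.normal(size=(n_vox - n_vox // 2, t))
        return run_from_series(data)

    def test_recovers_planted_slope(self, rng):
        run = self._run_with_global(rng, slope=2.0)
        # global signal here is ~ (1 + slope)/2 * g; regress a pure 2g voxel
        g = run.data[run.brain_mask].mean(axis=0)
        scale = np.polyfit(g - g.mean(), run.data[150, 0, 0] - run.data[150, 0, 0].mean(), 1)[0]
        betas = gbold_beta_map(run).values.ravel()
        assert betas[150] == pytest.approx(scale, rel=1e-9)
        assert betas[150] == pytest.approx(2.0 / ((1 + 2.0) / 2), rel=0.1)

    def test_independent_voxel_beta_near_zero(self, rng):
        # global signal dominated by a shared component; one voxel carries
        # only idiosyncratic noise, so its slope on gBOLD is ~ its 1/51
        # own-share of the mean
        t = 5000
        shared = rng.normal(size=t)
        g_part = shared + 0.1 * rng.normal(size=(50, t))
        indep = rng.normal(size=(1, t))
        run = run_from_series(np.vstack([g_part, indep]))
        beta = gbold_beta_map(run).values.ravel()[-1]
        assert abs(beta) < 0.06

    def test_invariant_to_constant_voxel_offset(self, rng):
        x = rng.normal(size=(10, 300))
        b0 = gbold_beta_map(run_from_series(x)).values.ravel()
        x2 = x.copy()
        x2[3] += 100.0
        b1 = gbold_beta_map(run_from_series(x2)).values.ravel()
        assert b1[3] == pytest.approx(b0[3], abs=1e-9)

    def test_constant_global_signal_rejected(self):
        run = run_from_series(np.full((4, 50), 3.0))
        with pytest.raises(ValueError, match="constant global"):
            gbold_beta_map(run)
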
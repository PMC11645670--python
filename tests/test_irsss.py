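"""IR solvation-shell spectroscopy: baseline, subtraction, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrashell.irsss import (
    BASELINE_WINDOWS,
    baseline_correct,
    estimate_noise_sigma,
    find_scaling_coefficient,
    normalize_band,
    run_sss,
    solute_correlated,
)
from hydrashell.spectra import Spectrum, resample
from hydrashell.synthetic import SyntheticSpectrumModel, gen_spectrum_pair

from oracles import grid_scan_coefficient

GRID = np.arange(1000.0, 4000.5, 1.0)


def _spec(y, **kw):
    return Spectrum(GRID, np.asarray(y, dtype=float), **kw)


def _bumpy(rng):
    y = 0.3 * np.exp(-0.5 * ((GRID - 1650) / 60) ** 2) + 0.8 * np.exp(
        -0.5 * ((GRID - 3300) / 180) ** 2
    )
    return y + 0.02 * rng.standard_normal(GRID.shape) * 0.0  # deterministic base


class TestBaseline:
    def test_straight_line_maps_to_zero(self):
        out = baseline_correct(_spec(0.02 - 4e-6 * GRID))
        assert np.abs(out.intensities).max() <= 1e-12

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        a=st.floats(-1e-4, 1e-4, allow_nan=False),
        b=st.floats(-0.05, 0.05, allow_nan=False),
    )
    def test_added_line_is_annihilated(self, a, b):
        rng = np.random.default_rng(0)
        base = _bumpy(rng)
        plain = baseline_correct(_spec(base))
        shifted = baseline_correct(_spec(base + a * GRID + b))
        np.testing.assert_allclose(
            shifted.intensities, plain.intensities, atol=1e-12, rtol=0
        )

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        once = baseline_correct(_spec(_bumpy(rng)))
        twice = baseline_correct(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_window_means_vanish_after_correction(self):
        rng = np.random.default_rng(2)
        out = baseline_correct(_spec(_bumpy(rng) + 3e-6 * GRID - 0.01))
        for lo, hi in BASELINE_WINDOWS["protein_L"]:
            m = out.window_mask(lo, hi)
            assert abs(out.intensities[m].mean()) < 1e-12

    def test_lysozyme_windows_also_supported(self):
        lo, hi = BASELINE_WINDOWS["lysozyme"]
        out = baseline_correct(_spec(0.5 - 1e-4 * GRID), lo, hi)
        assert np.abs(out.intensities).max() <= 1e-10

    def test_window_validation(self):
        spec = _spec(np.ones_like(GRID))
        with pytest.raises(ValueError, match="overlap"):
            baseline_correct(spec, (2000.0, 3000.0), (2500.0, 3500.0))
        with pytest.raises(ValueError, match="grid points|outside"):
            baseline_correct(spec, (2000.0, 2010.0), (4100.0, 4200.0))


class TestScalingCoefficient:
    def test_self_subtraction_gives_one(self):
        rng = np.random.default_rng(3)
        s = _spec(_bumpy(rng) + 0.01)
        assert find_scaling_coefficient(s, s, tolerance=0.0) == pytest.approx(1.0)

    def test_pure_scaling_recovers_the_volume_coefficient(self):
        # mirrors the 1%-solute -> 0.99 illustration, with c = 0.8
        rng = np.random.default_rng(4)
        r = _spec(_bumpy(rng) + 0.01)
        s = _spec(0.8 * r.intensities)
        assert find_scaling_coefficient(s, r, tolerance=0.0) == pytest.approx(0.8)

    def test_zero_touching_synthetic_pair(self):
        model = SyntheticSpectrumModel(
            noise_sigma=0.0, baseline_slope=0.0, baseline_intercept=0.0, seed=0
        )
        sample, reference, truth = gen_spectrum_pair(model)
        c = find_scaling_coefficient(sample, reference, tolerance=0.0)
        assert abs(c - truth["c_true"]) < 1e-3

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_grid_scan(self, seed):
        model = SyntheticSpectrumModel(seed=seed)
        sample, reference, _ = gen_spectrum_pair(model)
        region = (1020.0, 3980.0)
        tol = 3e-3
        mine = find_scaling_coefficient(
            sample, reference, region=region, tolerance=tol,
            smooth_points=7, reference_floor=0.15,
        )
        ref = grid_scan_coefficient(
            sample, reference, region, tol, smooth_points=7, reference_floor=0.15
        )
        assert abs(mine - ref) <= 2e-4

    def test_monotone_in_tolerance(self):
        model = SyntheticSpectrumModel(seed=5)
        sample, reference, _ = gen_spectrum_pair(model)
        tols = [0.0, 1e-4, 1e-3, 5e-3, 2e-2]
        cs = [
            find_scaling_coefficient(sample, reference, tolerance=t) for t in tols
        ]
        assert all(a <= b + 1e-12 for a, b in zip(cs, cs[1:]))

    def test_grid_mismatch_and_unbounded_errors(self):
        rng = np.random.default_rng(6)
        s = _spec(_bumpy(rng))
        other = Spectrum(GRID[::2], s.intensities[::2])
        with pytest.raises(ValueError, match="resample"):
            find_scaling_coefficient(s, other)
        zero_ref = _spec(np.zeros_like(GRID))
        with pytest.raises(ValueError, match="unbounded"):
            find_scaling_coefficient(s, zero_ref, tolerance=0.0)


class TestSoluteCorrelated:
    def test_zero_coefficient_is_identity(self):
        rng = np.random.default_rng(7)
        s = _spec(_bumpy(rng))
        out = solute_correlated(s, _spec(np.ones_like(GRID)), 0.0)
        np.testing.assert_array_equal(out.intensities, s.intensities)
        assert out.role == "solute_correlated"

    def test_constructed_algebra(self):
        rng = np.random.default_rng(8)
        r = _spec(_bumpy(rng) + 0.05)
        sc = np.exp(-0.5 * ((GRID - 1540) / 20) ** 2)
        s = _spec(0.9 * r.intensities + sc)
        out = solute_correlated(s, r, 0.9)
        np.testing.assert_allclose(out.intensities, sc, atol=1e-12)

    def test_least_non_negative_property(self):
        model = SyntheticSpectrumModel(
            noise_sigma=0.0, baseline_slope=0.0, baseline_intercept=0.0, seed=9
        )
        sample, reference, _ = gen_spectrum_pair(model)
        tol = 1e-6
        c = find_scaling_coefficient(sample, reference, tolerance=tol)
        out = solute_correlated(sample, reference, c)
        region = sample.window_mask(1020.0, 3980.0)
        assert out.intensities[region].min() >= -tol - 1e-12


class TestNormalizeBand:
    def test_unit_band_integral_is_fixed_point(self):
        y = np.exp(-0.5 * ((GRID - 1525) / 10) ** 2)
        s = _spec(y)
        s_unit = normalize_band(s)
        again = normalize_band(s_unit)
        np.testing.assert_allclose(again.intensities, s_unit.intensities, rtol=1e-12)
        assert s_unit.band_integral(1500.1, 1550.0) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(k=st.floats(1e-6, 1e6, allow_nan=False))
    def test_scale_invariance(self, k):
        y = np.exp(-0.5 * ((GRID - 1525) / 10) ** 2) + 0.1
        a = normalize_band(_spec(y))
        b = normalize_band(_spec(k * y))
        np.testing.assert_allclose(b.intensities, a.intensities, rtol=1e-9)

    def test_non_positive_band_rejected(self):
        with pytest.raises(ValueError, match="normalization undefined"):
            normalize_band(_spec(np.zeros_like(GRID)))


class TestRunSSS:
    def test_noise_free_pipeline_inverts_exactly(self):
        model = SyntheticSpectrumModel(noise_sigma=0.0, seed=0)
        sample, reference, truth = gen_spectrum_pair(model)
        res = run_sss(sample, reference, tolerance=0.0)
        truth_norm = normalize_band(truth["sc_spectrum"])
        rms = np.sqrt(np.mean((res.spectrum.intensities - truth_norm.intensities) ** 2))
        assert rms < 1e-9
        assert res.coefficient == pytest.approx(truth["c_true"], abs=1e-6)

    def test_monte_carlo_recovery_at_snr_100(self):
        """c within 2% and normalized SC RMS below 5% of peak over 20 seeds."""
        worst_c, worst_rms = 0.0, 0.0
        for seed in range(20):
            sample, reference, truth = gen_spectrum_pair(SyntheticSpectrumModel(seed=seed))
            res = run_sss(sample, reference)
            truth_norm = normalize_band(truth["sc_spectrum"])
            rel = abs(res.coefficient - truth["c_true"]) / truth["c_true"]
            rms = np.sqrt(
                np.mean((res.spectrum.intensities - truth_norm.intensities) ** 2)
            ) / truth_norm.intensities.max()
            worst_c, worst_rms = max(worst_c, rel), max(worst_rms, rms)
        assert worst_c < 0.02
        assert worst_rms < 0.05

    def test_discriminates_sc_differences_from_noise(self):
        """Replicate extractions differ less than a genuinely shifted OH band."""
        def extract(sc_bands, seed):
            model = SyntheticSpectrumModel(sc_bands=sc_bands, seed=seed)
            sample, reference, _ = gen_spectrum_pair(model)
            return run_sss(sample, reference).spectrum

        base_bands = SyntheticSpectrumModel().sc_bands
        shifted_bands = tuple(
            (c + 120.0, w, a) if c > 2000 else (c, w, a) for c, w, a in base_bands
        )
        a1 = extract(base_bands, 30)
        a2 = extract(base_bands, 31)
        b1 = extract(shifted_bands, 32)
        within = np.sqrt(np.mean((a1.intensities - a2.intensities) ** 2))
        between = np.sqrt(np.mean((a1.intensities - b1.intensities) ** 2))
        assert within < between

    def test_concentration_mismatch_warns_but_runs(self):
        s, r, _ = gen_spectrum_pair(SyntheticSpectrumModel(seed=33))
        r_mismatch = Spectrum(
            r.wavenumbers, r.intensities, concentration=2.0, role="reference"
        )
        with pytest.warns(UserWarning, match="mol/L"):
            res = run_sss(s, r_mismatch)
        assert res.coefficient > 0


def test_noise_sigma_estimate_tracks_truth():
    rng = np.random.default_rng(11)
    sigma = 3e-3
    y = 0.5 * np.exp(-0.5 * ((GRID - 3300) / 200) ** 2) + rng.normal(0, sigma, GRID.shape)
    est = estimate_noise_sigma(Spectrum(GRID, y))
    assert 0.5 * sigma < est < 1.5 * sigma


def test_resample_recovers_linear_segments():
    coarse = Spectrum(np.array([1000.0, 2000.0, 3000.0]), np.array([0.0, 1.0, 0.0]))
    fine = resample(coarse, np.array([1000.0, 1500.0, 2500.0, 3000.0]))
    np.testing.assert_allclose(fine.intensities, [0.0, 0.5, 0.5, 0.0])
    with pytest.raises(ValueError, match="beyond"):
        resample(coarse, np.array([900.0, 1500.0]))
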
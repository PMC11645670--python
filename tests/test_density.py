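"""Density accumulation, difference algebra and region integrals."""

import numpy as np
import pytest

from hydrashell.density import (
    DEFAULT_COS_EDGES,
    DEFAULT_D_EDGES,
    DensityDifference,
    GeometryDensity,
    Region,
    accumulate_density,
    density_difference,
    double_difference,
    read_density_csv,
    region_summary,
    write_density_csv,
)
from hydrashell.hbonds import HBondSample


def _samples(d, c, population="SHELL_ALL"):
    return [HBondSample(float(x), float(y), population) for x, y in zip(d, c)]


def _random_density(rng, molality=2.0, population="SHELL_ALL", n=4000):
    d = rng.uniform(2.35, 3.45, n)
    c = rng.uniform(-0.99, -0.01, n)
    return accumulate_density(_samples(d, c, population), molality=molality)


class TestAccumulate:
    def test_point_mass_occupies_one_bin(self):
        p = accumulate_density(_samples([2.70] * 50, [-0.99] * 50), molality=2.0)
        assert np.count_nonzero(p.density) == 1
        assert p.integral() == pytest.approx(1.0, abs=1e-12)
        assert p.overflow == 0

    def test_empty_and_mixed_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accumulate_density([], molality=0.15)
        mixed = _samples([2.7], [-0.9], "WW1") + _samples([2.7], [-0.9], "BULK")
        with pytest.raises(ValueError, match="mixed"):
            accumulate_density(mixed, molality=0.15)

    def test_out_of_grid_samples_are_tallied_not_dropped(self):
        samples = _samples([2.7, 2.7, 2.7, 3.0], [-0.9, -0.9, 0.5, -0.9])
        p = accumulate_density(samples, molality=2.0)
        assert p.overflow == 1
        assert p.n_samples == 4
        assert p.integral() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_samples_within_binomial_envelope(self):
        """Uniform draws land in every bin at its binomial expectation.

        The envelope is the 4-sigma level with a Bonferroni adjustment for
        the 1920 simultaneous bins (a per-bin 4-sigma check is expected to
        fail by chance in roughly one bin per ten runs).
        """
        from scipy.stats import norm

        rng = np.random.default_rng(12)
        n = 100_000
        d = rng.uniform(DEFAULT_D_EDGES[0], DEFAULT_D_EDGES[-1], n)
        c = rng.uniform(DEFAULT_COS_EDGES[0], DEFAULT_COS_EDGES[-1], n)
        p = accumulate_density(_samples(d, c), molality=2.0)
        areas = np.outer(np.diff(p.d_edges), np.diff(p.cos_edges))
        counts = p.density * areas * (n - p.overflow)
        prob = 1.0 / counts.size
        sd = np.sqrt(n * prob * (1 - prob))
        z_fw = norm.isf(norm.sf(4.0) / counts.size)
        assert np.all(np.abs(counts - n * prob) <= z_fw * sd)
        # and the per-bin 4-sigma violations stay at their expected rarity
        assert np.sum(np.abs(counts - n * prob) > 4 * sd) <= 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_density_always_integrates_to_one(self, seed):
        rng = np.random.default_rng(seed)
        p = _random_density(rng, n=int(rng.integers(10, 5000)))
        assert abs(p.integral() - 1.0) <= 1e-9


class TestDifferences:
    def test_identity_gives_zero_grid(self):
        rng = np.random.default_rng(0)
        p = _random_density(rng)
        dp = density_difference(p, p)
        assert np.all(dp.values == 0.0)
        assert dp.order == 1

    def test_constructed_sign_pattern(self):
        p_x = accumulate_density(_samples([2.6] * 10, [-0.99] * 10), molality=2.0)
        p_ref = accumulate_density(
            _samples([2.9] * 10, [-0.99] * 10, "BULK"), molality=2.0
        )
        dp = density_difference(p_x, p_ref)
        assert dp.integral() == pytest.approx(0.0, abs=1e-12)
        pos = dp.values[dp.values > 0]
        neg = dp.values[dp.values < 0]
        assert len(pos) == 1 and len(neg) == 1
        assert np.count_nonzero(dp.values) == 2

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_density(rng)
        b = _random_density(rng, population="BULK")
        ab = density_difference(a, b)
        ba = density_difference(b, a)
        np.testing.assert_array_equal(ab.values, -ba.values)

    def test_molality_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        a = _random_density(rng, molality=2.0)
        b = _random_density(rng, molality=0.15, population="BULK")
        with pytest.raises(ValueError, match="molality"):
            density_difference(a, b)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        a = _random_density(rng)
        coarse = accumulate_density(
            _samples(rng.uniform(2.4, 3.4, 100), rng.uniform(-0.9, -0.1, 100), "BULK"),
            d_edges=np.linspace(2.3, 3.5, 13),
            cos_edges=np.linspace(-1, 0, 11),
            molality=2.0,
        )
        with pytest.raises(ValueError, match="grid"):
            density_difference(a, coarse)

    def test_double_difference_equals_four_density_algebra(self):
        rng = np.random.default_rng(3)
        p_hi_x = _random_density(rng, molality=2.0)
        p_hi_b = _random_density(rng, molality=2.0, population="BULK")
        p_lo_x = _random_density(rng, molality=0.15)
        p_lo_b = _random_density(rng, molality=0.15, population="BULK")
        ddp = double_difference(
            density_difference(p_hi_x, p_hi_b), density_difference(p_lo_x, p_lo_b)
        )
        direct = (p_hi_x.density - p_hi_b.density) - (p_lo_x.density - p_lo_b.density)
        np.testing.assert_array_equal(ddp.values, direct)
        assert ddp.order == 2
        assert abs(ddp.integral()) <= 1e-9

    def test_double_difference_ordering_and_population_checks(self):
        rng = np.random.default_rng(4)
        hi = density_difference(
            _random_density(rng, molality=2.0), _random_density(rng, 2.0, "BULK")
        )
        lo = density_difference(
            _random_density(rng, molality=0.15), _random_density(rng, 0.15, "BULK")
        )
        # equal perturbation at both concentrations -> identically zero ddp
        lo_same = DensityDifference(
            d_edges=hi.d_edges,
            cos_edges=hi.cos_edges,
            values=hi.values.copy(),
            minuend_tag=(0.15, hi.minuend_tag[1]),
            subtrahend_tag=(0.15, "BULK"),
        )
        assert np.all(double_difference(hi, lo_same).values == 0.0)
        with pytest.raises(ValueError, match="molality"):
            double_difference(lo, hi)
        lo_ww = density_difference(
            _random_density(rng, 0.15, "WW1"), _random_density(rng, 0.15, "BULK")
        )
        with pytest.raises(ValueError, match="population"):
            double_difference(hi, lo_ww)


class TestRegions:
    def test_zero_difference_gives_zero_integrals(self):
        rng = np.random.default_rng(5)
        p = _random_density(rng)
        out = region_summary(density_difference(p, p))
        assert out == {"VERY_STRONG": 0.0, "MODERATE": 0.0}

    def test_constructed_masses(self):
        p_x = accumulate_density(_samples([2.6] * 10, [-0.5] * 10), molality=2.0)
        p_ref = accumulate_density(
            _samples([3.0] * 10, [-0.9] * 10, "BULK"), molality=2.0
        )
        out = region_summary(density_difference(p_x, p_ref))
        assert out["VERY_STRONG"] == pytest.approx(1.0, abs=1e-9)
        assert out["MODERATE"] == pytest.approx(-1.0, abs=1e-9)

    def test_exhaustive_partition_conserves_total(self):
        rng = np.random.default_rng(6)
        dp = density_difference(
            _random_density(rng), _random_density(rng, population="BULK")
        )
        quadrants = (
            Region("a", d_max=2.8, cos_max=-0.5),
            Region("b", d_max=2.8, cos_min=-0.5),
            Region("c", d_min=2.8, cos_max=-0.5),
            Region("d", d_min=2.8, cos_min=-0.5),
        )
        out = region_summary(dp, quadrants)
        assert sum(out.values()) == pytest.approx(0.0, abs=1e-9)

    def test_empty_region_rejected(self):
        rng = np.random.default_rng(7)
        dp = density_difference(
            _random_density(rng), _random_density(rng, population="BULK")
        )
        with pytest.raises(ValueError, match="no bins"):
            region_summary(dp, (Region("void", d_min=5.0),))


def test_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    p = _random_density(rng)
    write_density_csv(p, tmp_path / "p.csv")
    back = read_density_csv(tmp_path / "p.csv")
    assert isinstance(back, GeometryDensity)
    np.testing.assert_array_equal(back.density, p.density)
    assert back.molality == p.molality and back.population == p.population
    dp = density_difference(p, _random_density(rng, population="BULK"))
    write_density_csv(dp, tmp_path / "dp.csv")
    back_dp = read_density_csv(tmp_path / "dp.csv")
    assert isinstance(back_dp, DensityDifference)
    np.testing.assert_array_equal(back_dp.values, dp.values)
    assert back_dp.order == 1 and tuple(back_dp.minuend_tag) == dp.minuend_tag
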
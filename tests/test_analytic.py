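"""Analytical density families: Gaussian, collisional, convolution, mixture."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import pdtbind as pb
from pdtbind.analytic import WEIGHT_TOL

from conftest import pure_gaussian


WATER_COLL = pb.CollisionParams(5.77e-3, 3.9, 3.9, 2.5)
WATER_GAUSS = pb.GaussianParams(2.41, 3.46)


class TestGaussianDensity:
    def test_peak_value(self):
        g = WATER_GAUSS
        assert pb.gaussian_density(g.mean_u0, g) == pytest.approx(
            1.0 / (g.sigma * np.sqrt(2 * np.pi))
        )
        # numeric value of the water-coupling background peak
        assert pb.gaussian_density(2.41, g) == pytest.approx(0.1153, abs=5e-5)

    @given(st.floats(-50, 50), st.floats(0.1, 20), st.floats(0, 30))
    @settings(deadline=None)
    def test_symmetry_about_mean(self, mean, sigma, delta):
        g = pb.GaussianParams(mean, sigma)
        assert pb.gaussian_density(mean + delta, g) == pytest.approx(
            pb.gaussian_density(mean - delta, g), rel=1e-12
        )

    def test_rejects_nonfinite_argument(self):
        with pytest.raises(ValueError):
            pb.gaussian_density(np.nan, WATER_GAUSS)
        with pytest.raises(ValueError):
            pb.GaussianParams(0.0, -1.0)


class TestCollisionDensity:
    def test_zero_below_support(self):
        assert pb.collision_density(-1.0, WATER_COLL) == 0.0
        assert pb.collision_cdf(-5.0, WATER_COLL) == 0.0
        assert pb.collision_cdf(0.0, WATER_COLL) == 0.0

    def test_vanishes_at_origin_for_nl_above_one(self):
        # the max-statistics bracket vanishes at u = 0 because x(0) = xc
        assert pb.collision_density(0.0, WATER_COLL) == 0.0
        finite_nl1 = pb.collision_density(0.0, pb.CollisionParams(0.5, 2.0, 1.0, 1.0))
        assert finite_nl1 > 0.0

    def test_cdf_is_antiderivative_of_density(self):
        # central differences of the closed-form CDF reproduce the density
        for u in [0.5, 2.0, 10.0, 100.0, 1e4]:
            h = 1e-5 * max(u, 1.0)
            fd = (pb.collision_cdf(u + h, WATER_COLL) - pb.collision_cdf(u - h, WATER_COLL)) / (2 * h)
            assert fd == pytest.approx(pb.collision_density(u, WATER_COLL), rel=1e-6)

    def test_cdf_monotone_and_normalized(self):
        u = np.logspace(-3, 16, 200)
        cdf = pb.collision_cdf(u, WATER_COLL)
        assert np.all(np.diff(cdf) >= 0)
        # the survival decays like u**-1/4: unit mass is only approached at
        # astronomically large energies
        assert pb.collision_cdf(1e15 * WATER_COLL.epsilon, WATER_COLL) == pytest.approx(
            1.0, abs=1e-3
        )

    def test_cdf_interval_matches_quadrature_of_density(self):
        lo, hi = 1.0, 30.0
        val, err = integrate.quad(lambda t: pb.collision_density(t, WATER_COLL), lo, hi)
        diff = pb.collision_cdf(hi, WATER_COLL) - pb.collision_cdf(lo, WATER_COLL)
        assert diff == pytest.approx(val, rel=1e-6)

    def test_normalization_by_quantile_substitution(self):
        # int F du == int_0^1 dq == 1 exactly; check the quantile inverse
        q = np.linspace(1e-9, 1 - 1e-12, 1001)
        u = pb.collision_quantile(q, WATER_COLL)
        assert np.all(np.diff(u) > 0)
        np.testing.assert_allclose(pb.collision_cdf(u, WATER_COLL), q, rtol=1e-9, atol=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            pb.CollisionParams(0.5, -1.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            pb.CollisionParams(0.5, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            pb.CollisionParams(1.5, 1.0, 1.0, 2.0)


class TestConvolution:
    def test_gauss_hermite_matches_quantile_route_in_bulk(self):
        # the fast 19-node rule is accurate near the density peak and carries
        # only a small mass-weighted error overall (its tails are approximate)
        u = np.linspace(-10, 60, 281)
        gh = pb.convolved_collision_density(u, WATER_GAUSS, WATER_COLL, nodes=19)
        hi = pb.convolved_collision_density(u, WATER_GAUSS, WATER_COLL, nodes=4000, method="quantile")
        peak = hi > 0.7 * hi.max()
        np.testing.assert_allclose(gh[peak], hi[peak], rtol=1e-3)
        assert np.trapezoid(np.abs(gh - hi), u) < 2e-3

    def test_quantile_route_matches_dense_grid_oracle(self):
        # independent oracle: direct discrete convolution on a dense grid
        u = np.linspace(-10, 55, 66)
        t = np.linspace(0, 6000, 1200001)
        F = pb.collision_density(t, WATER_COLL)
        oracle = np.array(
            [np.trapezoid(F * pb.gaussian_density(ui - t, WATER_GAUSS), t) for ui in u]
        )
        ours = pb.convolved_collision_density(u, WATER_GAUSS, WATER_COLL, nodes=4000, method="quantile")
        mask = oracle > 1e-12
        np.testing.assert_allclose(ours[mask], oracle[mask], rtol=1e-3)

    def test_gaussian_mass_transfer(self):
        # convolution leaves total mass at 1: integrate in the quantile form
        u = np.linspace(-40, 0, 11)
        v = pb.convolved_collision_density(u, WATER_GAUSS, WATER_COLL, nodes=200, method="quantile")
        assert np.all(v >= 0)

    def test_rejects_too_few_nodes(self):
        with pytest.raises(ValueError):
            pb.convolved_collision_density(0.0, WATER_GAUSS, WATER_COLL, nodes=3)


class TestMixture:
    def test_no_collision_limit_is_gaussian(self):
        model = pure_gaussian(2.41, 3.46)
        u = np.linspace(-15, 20, 101)
        np.testing.assert_allclose(
            pb.p0_density(u, model), pb.gaussian_density(u, WATER_GAUSS), rtol=1e-14
        )

    def test_all_collision_limit_is_convolution(self):
        mode = pb.ModelMode(1.0, WATER_GAUSS, pb.CollisionParams(0.0, 3.9, 3.9, 2.5))
        model = pb.CouplingModel([mode])
        u = np.linspace(-5, 40, 46)
        np.testing.assert_allclose(
            pb.p0_density(u, model),
            pb.convolved_collision_density(u, WATER_GAUSS, mode.collision),
            rtol=1e-14,
        )

    def test_mixture_degeneracy(self):
        one = pb.CouplingModel([pb.ModelMode(1.0, WATER_GAUSS, WATER_COLL)])
        two = pb.CouplingModel(
            [
                pb.ModelMode(0.3, WATER_GAUSS, WATER_COLL),
                pb.ModelMode(0.7, WATER_GAUSS, WATER_COLL),
            ]
        )
        u = np.linspace(-10, 40, 51)
        np.testing.assert_allclose(pb.p0_density(u, two), pb.p0_density(u, one), rtol=1e-12)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            pb.CouplingModel([])
        with pytest.raises(ValueError):
            pb.CouplingModel(
                [
                    pb.ModelMode(0.5, WATER_GAUSS, WATER_COLL),
                    pb.ModelMode(0.4, WATER_GAUSS, WATER_COLL),
                ]
            )
        # weights summing to 1 within the documented tolerance are accepted
        pb.CouplingModel(
            [
                pb.ModelMode(0.5, WATER_GAUSS, WATER_COLL),
                pb.ModelMode(0.5 + 0.5 * WEIGHT_TOL, WATER_GAUSS, WATER_COLL),
            ]
        )

    def test_single_mode_moments(self, gaussian_model):
        # the b=1 single-mode model has exactly the background mean/variance
        u = np.linspace(2.41 - 40, 2.41 + 40, 20001)
        d = pb.p0_density(u, gaussian_model)
        mean = np.trapezoid(u * d, u)
        var = np.trapezoid((u - mean) ** 2 * d, u)
        assert mean == pytest.approx(2.41, abs=1e-8)
        assert var == pytest.approx(3.46**2, abs=1e-6)
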
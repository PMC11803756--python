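"""UWHAM reweighting, kernel diagnostics, likelihood, and fitting."""

import numpy as np
import pytest

import pdtbind as pb
from pdtbind.samples import SampleSet, StateSamples

from conftest import pure_gaussian


@pytest.fixture(scope="module")
def gaussian_dataset(thermo, wide_sc):
    """Synthetic pure-Gaussian multi-state dataset (small, for module tests)."""
    model = pure_gaussian(2.41, 3.46)
    sched = pb.linear_schedule(11, wide_sc)
    return model, pb.generate_dataset(pb.SimSpec(model, sched, 2000, seed=101), thermo)


class TestUWHAM:
    def test_identical_states_give_zero_df_and_uniform_weights(self, thermo, wide_sc):
        rng = np.random.default_rng(0)
        u = rng.normal(0.0, 2.0, 500)
        pt = pb.SchedulePoint(0.0, 0.0, 0.0)
        # two states at the same schedule point (the decoupled one, so the
        # lam=0 weights are uniform as well)
        ss = SampleSet(
            [StateSamples(0, pt, u), StateSamples(1, pt, u.copy())], wide_sc
        )
        res = pb.uwham_weights(ss, thermo)
        assert res.f[1] - res.f[0] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.w0, 1.0 / res.w0.size, rtol=1e-10)

    def test_recovers_gaussian_free_energy(self, gaussian_dataset, thermo):
        model, ds = gaussian_dataset
        res = pb.uwham_weights(ds, thermo)
        dg = thermo.kt * res.f[-1]
        truth = 2.41 - thermo.beta * 3.46**2 / 2
        se = thermo.kt * pb.uwham_stderr(ds, thermo, n_boot=10, seed=3, result=res)[-1]
        assert abs(dg - truth) < 3 * se

    def test_permutation_invariance(self, thermo, wide_sc):
        rng = np.random.default_rng(4)
        states = [
            StateSamples(k, pb.SchedulePoint(l, l, l), rng.normal(-3 * l, 2.0, 400))
            for k, l in enumerate([0.0, 0.5, 1.0])
        ]
        ss = SampleSet(states, wide_sc)
        res = pb.uwham_weights(ss, thermo)
        shuffled = SampleSet(
            [StateSamples(st.state_index, st.point, rng.permutation(st.u_sc))
             for st in states],
            wide_sc,
        )
        res2 = pb.uwham_weights(shuffled, thermo)
        np.testing.assert_allclose(res2.f, res.f, atol=1e-12)

    def test_requires_two_states(self, thermo, wide_sc):
        ss = SampleSet([StateSamples(0, pb.SchedulePoint(0, 0, 0), np.zeros(5))], wide_sc)
        with pytest.raises(ValueError):
            pb.uwham_weights(ss, thermo)

    def test_poor_overlap_warns_in_metadata(self, thermo, wide_sc):
        rng = np.random.default_rng(9)
        # two distant states with no lam=0 anchor: weights concentrate
        states = [
            StateSamples(0, pb.SchedulePoint(0.9, 0.9, 0.9), rng.normal(-60, 1.0, 300)),
            StateSamples(1, pb.SchedulePoint(1.0, 1.0, 1.0), rng.normal(-65, 1.0, 300)),
        ]
        res = pb.uwham_weights(SampleSet(states, wide_sc), thermo, ess_floor=250.0)
        assert res.warnings


class TestKernelEstimates:
    def test_single_sample_is_unit_bump(self, thermo, wide_sc):
        pt = pb.SchedulePoint(0.0, 0.0, 0.0)
        ss = SampleSet(
            [StateSamples(0, pt, np.array([1.5])),
             StateSamples(1, pb.SchedulePoint(1.0, 1.0, 1.0), np.array([1.5]))],
            wide_sc,
        )
        res = pb.uwham_weights(ss, thermo)
        grid = np.linspace(-5, 8, 1001)
        _, dens = pb.kernel_p0_estimate(ss, res, bandwidth=1.0, grid=grid)
        # mixture of two identical unit kernels at 1.5
        np.testing.assert_allclose(
            dens, pb.gaussian_density(grid, pb.GaussianParams(1.5, 1.0)), rtol=1e-8
        )
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_lambda_function_linear_for_gaussian_data(self, gaussian_dataset, thermo):
        model, ds = gaussian_dataset
        res = pb.uwham_weights(ds, thermo)
        grid = np.linspace(-6, 10, 321)
        _, lam = pb.kernel_lambda_function(ds, res, 1.0, grid, thermo)
        ok = np.isfinite(lam)
        slope, intercept = np.polyfit(grid[ok], lam[ok], 1)
        # kernel smoothing widens the apparent variance by the bandwidth^2
        expected = -thermo.kt / (3.46**2 + 1.0**2)
        assert slope == pytest.approx(expected, rel=0.1)

    def test_translation_equivariance(self, thermo, wide_sc):
        rng = np.random.default_rng(12)
        pts = [pb.SchedulePoint(0, 0, 0), pb.SchedulePoint(0.5, 0.5, 0.5)]
        base = [rng.normal(0, 2.0, 500), rng.normal(-2, 2.0, 500)]
        shift = 7.0
        grid = np.linspace(-8, 8, 161)
        ss = SampleSet([StateSamples(k, p, u) for k, (p, u) in enumerate(zip(pts, base))], wide_sc)
        # shifting every sample translates the lambda-function horizontally
        ss_s = SampleSet(
            [StateSamples(k, p, u + shift) for k, (p, u) in enumerate(zip(pts, base))],
            wide_sc,
        )
        w = pb.uwham_weights(ss, thermo)
        w_s = pb.uwham_weights(ss_s, thermo)
        _, lam = pb.kernel_lambda_function(ss, w, 1.0, grid, thermo)
        _, lam_s = pb.kernel_lambda_function(ss_s, w_s, 1.0, grid + shift, thermo)
        ok = np.isfinite(lam) & np.isfinite(lam_s)
        np.testing.assert_allclose(lam_s[ok], lam[ok], atol=2e-3)

    def test_matches_finite_differences_of_log_density(self, gaussian_dataset, thermo):
        model, ds = gaussian_dataset
        res = pb.uwham_weights(ds, thermo)
        grid = np.linspace(-4, 8, 25)
        h = 1e-5
        _, lam = pb.kernel_lambda_function(ds, res, 1.0, grid, thermo)
        _, d_plus = pb.kernel_p0_estimate(ds, res, 1.0, grid + h)
        _, d_minus = pb.kernel_p0_estimate(ds, res, 1.0, grid - h)
        fd = thermo.kt * (np.log(d_plus) - np.log(d_minus)) / (2 * h)
        np.testing.assert_allclose(lam, fd, rtol=1e-6)

    def test_rejects_bad_bandwidth(self, gaussian_dataset, thermo):
        model, ds = gaussian_dataset
        res = pb.uwham_weights(ds, thermo)
        with pytest.raises(ValueError):
            pb.kernel_p0_estimate(ds, res, bandwidth=0.0)


class TestLikelihood:
    def test_reduces_to_gaussian_nll_at_lambda_zero(self, thermo, wide_sc):
        rng = np.random.default_rng(21)
        u = rng.normal(2.41, 3.46, 3000)
        ss = SampleSet(
            [StateSamples(0, pb.SchedulePoint(0, 0, 0), u),
             StateSamples(1, pb.SchedulePoint(0.1, 0.1, 0.1), rng.normal(0.4, 3.46, 10))],
            wide_sc,
        )
        model = pure_gaussian(2.41, 3.46)
        # restrict to the lam=0 state: closed-form Gaussian cost
        ss0 = SampleSet(
            [StateSamples(0, pb.SchedulePoint(0, 0, 0), u),
             StateSamples(1, pb.SchedulePoint(0, 0, 0), u[:1])],
            wide_sc,
        )
        got = pb.negative_log_likelihood(model, ss0, thermo)
        z = (np.concatenate([u, u[:1]]) - 2.41) / 3.46
        expected = np.sum(np.log(3.46 * np.sqrt(2 * np.pi)) + 0.5 * z**2)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_additivity_of_duplicate_sample(self, thermo, wide_sc):
        rng = np.random.default_rng(22)
        u = rng.normal(0, 3.0, 200)
        pt0, pt1 = pb.SchedulePoint(0, 0, 0), pb.SchedulePoint(1, 1, 1)
        model = pure_gaussian(0.0, 3.0)
        base = SampleSet(
            [StateSamples(0, pt0, u), StateSamples(1, pt1, rng.normal(-15, 3, 200))],
            wide_sc,
        )
        extra = SampleSet(
            [StateSamples(0, pt0, np.append(u, u[7])), StateSamples(1, pt1, base.states[1].u_sc)],
            wide_sc,
        )
        c0 = pb.negative_log_likelihood(model, base, thermo)
        c1 = pb.negative_log_likelihood(model, extra, thermo)
        # the added term is -log p_0(u_7)
        k0 = pb.k_lambda(model, pt0, wide_sc, thermo)
        per = -np.log(pb.p0_density(u[7], model) / k0)
        assert c1 - c0 == pytest.approx(per, rel=1e-6)

    def test_finite_for_zero_density_sample(self, thermo, wide_sc):
        model = pure_gaussian(0.0, 0.5)
        ss = SampleSet(
            [StateSamples(0, pb.SchedulePoint(0, 0, 0), np.array([0.0, 400.0])),
             StateSamples(1, pb.SchedulePoint(1, 1, 1), np.array([0.0]))],
            wide_sc,
        )
        val = pb.negative_log_likelihood(model, ss, thermo)
        assert np.isfinite(val)

    def test_truth_beats_perturbations(self, thermo, wide_sc):
        # the expected per-sample cost is minimized at the generating model
        model = pure_gaussian(2.41, 3.46)
        sched = pb.linear_schedule(5, wide_sc)
        ds = pb.generate_dataset(pb.SimSpec(model, sched, 2000, seed=55), thermo)
        c_true = pb.negative_log_likelihood(model, ds, thermo)
        rng = np.random.default_rng(56)
        for _ in range(8):
            pert = pure_gaussian(2.41 + rng.normal(0, 0.5), 3.46 * np.exp(rng.normal(0, 0.15)))
            assert pb.negative_log_likelihood(pert, ds, thermo) > c_true


class TestFitModel:
    def test_descent_contract_from_truth(self, gaussian_dataset, thermo):
        model, ds = gaussian_dataset
        cfg = pb.FitConfig(max_iter=50)
        res = pb.fit_model(model, ds, thermo, cfg)
        assert res.cost <= res.cost_initial + 1e-9

    def test_recovers_generating_gaussian(self, gaussian_dataset, thermo):
        model, ds = gaussian_dataset
        init = pure_gaussian(1.0, 2.5)
        res = pb.fit_model(init, ds, thermo, pb.FitConfig())
        m = res.model.modes[0]
        assert m.gaussian.mean_u0 == pytest.approx(2.41, abs=0.15)
        assert m.gaussian.sigma == pytest.approx(3.46, abs=0.1)

    def test_report_serializes(self, gaussian_dataset, thermo):
        model, ds = gaussian_dataset
        res = pb.fit_model(model, ds, thermo, pb.FitConfig(max_iter=5))
        d = res.to_dict()
        assert {"cost", "converged", "parameters", "seed"} <= set(d)
        assert len(d["parameters"]) == 1


class TestInitializer:
    def test_pure_gaussian_within_twenty_percent(self, gaussian_dataset, thermo):
        model, ds = gaussian_dataset
        init = pb.initialize_from_diagnostics(ds, mode_count=1, th=thermo)
        g = init.modes[0].gaussian
        assert abs(g.mean_u0 - 2.41) < 0.2 * max(abs(2.41), 3.46)
        assert abs(g.sigma - 3.46) < 0.2 * 3.46
        assert init.modes[0].collision.b_no_collision > 0.5

    def test_dominant_mode_on_bimodal_data(self, thermo, wide_sc):
        modes = [
            pb.ModelMode(0.75, pb.GaussianParams(-12.0, 1.5), pb.CollisionParams(1, 1, 1, 1)),
            pb.ModelMode(0.25, pb.GaussianParams(5.0, 1.5), pb.CollisionParams(1, 1, 1, 1)),
        ]
        model = pb.CouplingModel(modes)
        sched = pb.linear_schedule(5, wide_sc)
        ds = pb.generate_dataset(pb.SimSpec(model, sched, 2000, seed=77), thermo)
        init = pb.initialize_from_diagnostics(ds, mode_count=1, th=thermo)
        # returns the heavier component's parameters
        assert init.modes[0].gaussian.mean_u0 == pytest.approx(-12.0, abs=1.5)

    def test_output_is_valid_model(self, gaussian_dataset, thermo):
        model, ds = gaussian_dataset
        for k in (1, 2):
            init = pb.initialize_from_diagnostics(ds, mode_count=k, th=thermo)
            assert init.n_modes == k
            assert init.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rejects_tiny_datasets(self, thermo, wide_sc):
        ss = SampleSet(
            [StateSamples(0, pb.SchedulePoint(0, 0, 0), np.zeros(10)),
             StateSamples(1, pb.SchedulePoint(1, 1, 1), np.zeros(10))],
            wide_sc,
        )
        with pytest.raises(ValueError):
            pb.initialize_from_diagnostics(ss, mode_count=1, th=thermo)
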
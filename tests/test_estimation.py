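"""Estimation: weighted cost, local/global fits, confidence intervals."""

import numpy as np
import pytest

from adipoflux import (
    FluxDataset,
    ModelParameters,
    cost,
    fit_local,
    simulate,
)
from adipoflux.estimation import crs_minimize, residuals


@pytest.fixture(scope="module")
def perfect_dataset(truth_params, clean_forcing, clean_cohort):
    """FluxDataset whose means are exactly the model prediction."""
    _, dataset, _ = clean_cohort
    return dataset


class TestCost:
    def test_perfect_fit_zero(self, truth_params, clean_forcing,
                              perfect_dataset):
        assert cost(truth_params, perfect_dataset, clean_forcing) \
            == pytest.approx(0.0, abs=1e-18)

    def test_unit_residuals(self, truth_params, clean_forcing, times):
        """Shifting one series by exactly one sigma at every point adds
        one squared unit per included point."""
        sim = simulate(truth_params, clean_forcing, t_grid=times)
        mu = {s: np.asarray(v, dtype=float) for s, v in sim.fluxes.items()}
        sigma = {s: np.full(7, 0.5) for s in mu}
        mu["tg"] = mu["tg"] + 0.5
        ds = FluxDataset.from_series(times, mu, sigma)
        assert cost(truth_params, ds, clean_forcing) == pytest.approx(7.0)

    def test_zero_sigma_point_excluded(self, truth_params, clean_forcing,
                                       times):
        sim = simulate(truth_params, clean_forcing, t_grid=times)
        mu = {s: np.asarray(v, dtype=float) for s, v in sim.fluxes.items()}
        sigma = {s: np.full(7, 0.5) for s in mu}
        sigma["tg"] = sigma["tg"].copy()
        sigma["tg"][3] = 0.0
        mu["tg"] = mu["tg"] + 0.5
        with pytest.warns(UserWarning):
            ds = FluxDataset.from_series(times, mu, sigma)
        assert cost(truth_params, ds, clean_forcing) == pytest.approx(6.0)

    def test_invariant_under_time_reordering(self, truth_params,
                                             clean_forcing, perfect_dataset):
        """Cost is a sum over points; permuting them changes nothing."""
        ds = perfect_dataset
        perm = np.array([3, 0, 6, 2, 5, 1, 4])
        shifted = ModelParameters.baseline().replace(k_ad=0.012)
        c1 = cost(shifted, ds, clean_forcing)
        ds2 = FluxDataset(
            times=ds.times[perm],
            mu={k: v[perm] for k, v in ds.mu.items()},
            sigma={k: v[perm] for k, v in ds.sigma.items()},
            mask={k: v[perm] for k, v in ds.mask.items()},
            n_subjects=ds.n_subjects)
        # re-sort so the simulation grid is increasing, as required
        order = np.argsort(ds2.times)
        ds2 = FluxDataset(
            times=ds2.times[order],
            mu={k: v[order] for k, v in ds2.mu.items()},
            sigma={k: v[order] for k, v in ds2.sigma.items()},
            mask={k: v[order] for k, v in ds2.mask.items()},
            n_subjects=ds2.n_subjects)
        assert cost(shifted, ds2, clean_forcing) == pytest.approx(c1)

    def test_simulation_failure_infinite(self, clean_forcing,
                                         perfect_dataset):
        # a parameter set with no fasting fixed point cannot simulate
        bad = ModelParameters.baseline().replace(frac_use=1.0, glut4=0.04)
        assert cost(bad, perfect_dataset, clean_forcing) == np.inf


class TestFitLocal:
    def test_fixed_point_of_optimum(self, truth_params, clean_forcing,
                                    perfect_dataset):
        fit = fit_local(truth_params, perfect_dataset, clean_forcing)
        assert fit.cost < 1e-12
        for n, v in fit.params.items():
            assert v == pytest.approx(getattr(truth_params, n), rel=1e-6)

    def test_recovers_truth_from_nearby(self, truth_params, clean_forcing,
                                        perfect_dataset):
        rng = np.random.default_rng(5)
        init = truth_params.replace(**{
            n: getattr(truth_params, n) * rng.uniform(0.9, 1.1)
            for n in ("k_ad", "tau_lpl", "tau_at", "p_gly", "p_nefa",
                      "d_spill")})
        fit = fit_local(init, perfect_dataset, clean_forcing)
        for n in ("k_ad", "tau_lpl", "tau_at", "p_gly", "p_nefa", "d_spill"):
            assert abs(fit.params[n] - getattr(truth_params, n)) \
                / getattr(truth_params, n) < 1e-3, n

    def test_deterministic(self, truth_params, clean_forcing,
                           perfect_dataset):
        init = truth_params.replace(k_ad=0.012)
        f1 = fit_local(init, perfect_dataset, clean_forcing)
        f2 = fit_local(init, perfect_dataset, clean_forcing)
        assert f1.params == f2.params
        assert f1.cost == f2.cost

    def test_optimum_not_worse_than_truth_on_noisy_data(self, noisy_cohort):
        from adipoflux.synthetic import cohort_mean_forcing

        table, dataset, truth = noisy_cohort
        forcing = cohort_mean_forcing(table)
        fit = fit_local(truth, dataset, forcing)
        assert fit.cost <= cost(truth, dataset, forcing) + 1e-9

    def test_ci_contains_estimate_and_respects_fixed(self, truth_params,
                                                     clean_forcing,
                                                     perfect_dataset):
        fit = fit_local(truth_params, perfect_dataset, clean_forcing,
                        fixed={"k_reester": 0.001})
        for n, (lo, hi) in fit.ci95.items():
            assert lo <= fit.params[n] <= hi, n
        assert fit.params["k_reester"] == 0.001


class TestConfidenceIntervals:
    def test_diagonal_jacobian_closed_form(self):
        """With J diagonal and unit residual variance the half-width is
        1.96/|J_kk| (up to the s^2 factor)."""
        from adipoflux.estimation import _ci_from_jac

        jac = np.diag([2.0, 0.5])
        n_obs, k = 10, 2
        cost_value = float(n_obs - k)  # s^2 = 1
        ci, _ = _ci_from_jac(jac, np.array([1.0, 3.0]), ["a", "b"],
                             cost_value, n_obs)
        assert ci["a"][1] - ci["a"][0] == pytest.approx(2 * 1.96 / 2.0)
        assert ci["b"][1] - ci["b"][0] == pytest.approx(2 * 1.96 / 0.5)

    def test_zero_sensitivity_column_infinite(self):
        from adipoflux.estimation import _ci_from_jac

        jac = np.array([[1.0, 0.0], [0.5, 0.0], [0.2, 0.0]])
        with pytest.warns(UserWarning):
            ci, _ = _ci_from_jac(jac, np.array([1.0, 3.0]), ["a", "b"], 1.0, 3)
        assert np.isinf(ci["b"][0]) and np.isinf(ci["b"][1])


class TestCrs:
    def test_deterministic_and_finds_quadratic_minimum(self):
        def f(x):
            return float((x[0] - 1.0) ** 2 + (x[1] - 2.0) ** 2)

        lo, hi = np.zeros(2), np.array([5.0, 5.0])
        p1, c1 = crs_minimize(f, lo, hi, seed=3, max_fevals=3000)
        p2, c2 = crs_minimize(f, lo, hi, seed=3, max_fevals=3000)
        np.testing.assert_array_equal(p1, p2)
        assert c1[0] < 1e-3
        np.testing.assert_allclose(p1[0], [1.0, 2.0], atol=0.05)
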
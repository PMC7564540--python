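import json

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy import stats

from epibalance import (
    ConditionDistribution,
    FitOptions,
    ModelParams,
    chi_square,
    equilibrium_distribution,
    fit_condition,
    reduced_chi_square,
)
from epibalance.fitting import (
    _confidence_from_objective,
    _tangent_basis,
    load_fit_options,
    parameter_confidence,
    write_fit_report,
)
from epibalance.model import _stationary


def exact_condition(params, n_sites, sigma=0.01, condition_id="exact"):
    """A condition whose d equals the model equilibrium exactly."""
    c = equilibrium_distribution(params, n_sites).c
    return ConditionDistribution(
        condition_id=condition_id,
        n_sites=n_sites,
        d=c,
        sigma=np.full(n_sites + 1, sigma),
        n_individuals=3,
    )


class TestChiSquare:
    def test_perfect_fit_is_zero(self):
        d = np.array([0.2, 0.8])
        assert chi_square(d, np.array([0.1, 0.1]), d) == 0.0

    def test_single_class_contribution(self):
        # (0.1 / 0.05)^2 = 4
        l = chi_square(np.array([0.6]), np.array([0.05]), np.array([0.5]))
        assert l == pytest.approx(4.0)

    def test_two_class_arithmetic(self):
        l = chi_square(
            np.array([0.3, 0.7]), np.array([0.05, 0.05]), np.array([0.25, 0.75])
        )
        assert l == pytest.approx(2.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            chi_square(np.zeros(3), np.ones(3), np.zeros(4))

    def test_sigma_floor_caps_small_errors(self):
        # sigma 0 at a class is floored, not a division by zero
        l = chi_square(np.array([0.5, 0.5]), np.array([0.0, 1.0]),
                       np.array([0.501, 0.499]), sigma_floor=1e-3)
        assert np.isfinite(l)


class TestReducedChiSquare:
    def test_six_dof_at_nine_sites(self):
        assert reduced_chi_square(6.0, 9) == pytest.approx(1.0)

    def test_zero(self):
        assert reduced_chi_square(0.0, 9) == 0.0

    def test_insufficient_dof(self):
        with pytest.raises(ValueError, match="raw"):
            reduced_chi_square(1.0, 2)


class TestParameterConfidence:
    def test_quadratic_oracle(self):
        """L quadratic in the tangent coordinates with per-direction scale s
        must yield covariance diag(s^2) in those coordinates: the likelihood
        exp(-L/2) is Gaussian with sd s, so the parameter half-widths are
        sqrt(diag(B diag(s^2) B^T))."""
        B = _tangent_basis()
        theta0 = np.full(4, 0.25)
        s = np.array([0.05, 0.1, 0.2])

        def quad(theta):
            t = B.T @ (np.asarray(theta) - theta0)
            return float(np.sum((t / s) ** 2))

        ci, cov, warn = _confidence_from_objective(quad, theta0, step=1e-4)
        assert not warn
        expected = B @ np.diag(s**2) @ B.T
        assert np.allclose(cov, expected, rtol=1e-4, atol=1e-10)
        for i, name in enumerate(("p", "alpha", "q", "beta")):
            assert ci[name] == pytest.approx(np.sqrt(expected[i, i]), rel=1e-4)

    def test_flat_scale_direction_excluded(self, recovery_params):
        """The pure rescaling direction leaves L untouched; the constrained
        Hessian must still be finite and invertible."""
        cond = exact_condition(recovery_params, 9)
        s2 = np.maximum(cond.sigma, 1e-3) ** 2
        theta = recovery_params.as_array()
        ci, cov, warn = parameter_confidence(theta, cond.d, s2, 9)
        assert not warn
        assert all(np.isfinite(v) and v > 0 for v in ci.values())

    def test_doubling_sigma_doubles_half_widths(self, recovery_params):
        cond = exact_condition(recovery_params, 9, sigma=0.02)
        theta = recovery_params.as_array()
        s2 = cond.sigma**2
        ci1, _, _ = parameter_confidence(theta, cond.d, s2, 9)
        ci2, _, _ = parameter_confidence(theta, cond.d, (2 * cond.sigma) ** 2, 9)
        for name in ci1:
            assert ci2[name] == pytest.approx(2 * ci1[name], rel=1e-6)

    def test_singular_hessian_reports_infinite_widths(self):
        flat = lambda theta: 0.0
        with pytest.warns(RuntimeWarning, match="singular"):
            ci, cov, warn = _confidence_from_objective(flat, np.full(4, 0.25))
        assert warn
        assert all(v == np.inf for v in ci.values())


class TestFitCondition:
    def test_self_consistency_zero_noise(self, recovery_params):
        """Data generated exactly from the model is fitted to L ~ 0 with the
        generating cooperativity ratios recovered."""
        cond = exact_condition(recovery_params, 9)
        fit = fit_condition(cond, FitOptions(seed=7))
        assert fit.converged
        assert fit.l_min <= 1e-8
        assert fit.ratios["alpha_over_p"] == pytest.approx(4.0, rel=1e-3)
        assert fit.ratios["beta_over_q"] == pytest.approx(0.5, rel=1e-3)

    def test_binomial_data_has_no_cooperativity(self):
        cond = exact_condition(ModelParams(0.5, 0, 0.5, 0), 9, condition_id="binom")
        fit = fit_condition(cond, FitOptions(seed=3))
        assert fit.l_min <= 1e-8
        assert fit.ratios["alpha_over_p"] <= fit.ci68["alpha"] / fit.params.p
        assert fit.ratios["beta_over_q"] <= fit.ci68["beta"] / fit.params.q

    def test_gauge_fixed_params_on_simplex(self, recovery_params):
        cond = exact_condition(recovery_params, 9)
        fit = fit_condition(cond, FitOptions(seed=7))
        total = fit.params.p + fit.params.alpha + fit.params.q + fit.params.beta
        assert total == pytest.approx(1.0, abs=1e-12)
        assert abs(fit.model.c.sum() - 1.0) < 1e-12

    def test_insufficient_classes_rejected(self):
        cond = ConditionDistribution("c", 1, np.array([0.4, 0.6]), np.zeros(2), 1)
        with pytest.raises(ValueError, match="classes"):
            fit_condition(cond)

    def test_l_min_matches_fixed_q_gauge_oracle(self, recovery_params, bimodal_params):
        """Independent route: refitting with the gauge q = 1 (three free
        parameters, scipy L-BFGS-B on logs) must reach the same minimum L
        and the same cooperativity ratios as the simplex-gauge fit."""
        for params, cid in ((recovery_params, "a"), (bimodal_params, "b")):
            c_true = equilibrium_distribution(params, 9).c
            rng = np.random.default_rng(5)
            d = c_true + rng.normal(0, 0.01, size=10)
            d = np.clip(d, 1e-6, None)
            d /= d.sum()
            cond = ConditionDistribution(cid, 9, d, np.full(10, 0.01), 3)
            fit = fit_condition(cond, FitOptions(seed=11))

            s2 = np.maximum(cond.sigma, 1e-3) ** 2

            def loss_logs(x):
                p, a, b = np.exp(x)
                c = _stationary(p, a, 1.0, b, 9)
                return float(np.sum((d - c) ** 2 / s2))

            best = np.inf
            best_x = None
            for start_seed in range(8):
                x0 = np.random.default_rng(start_seed).normal(0, 1, 3)
                res = minimize(loss_logs, x0, method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-14, "maxfev": 4000})
                if res.fun < best:
                    best, best_x = res.fun, res.x
            assert fit.l_min == pytest.approx(best, abs=1e-6)
            p_o, a_o, b_o = np.exp(best_x)
            assert fit.ratios["alpha_over_p"] == pytest.approx(a_o / p_o, rel=1e-3)
            assert fit.ratios["beta_over_q"] == pytest.approx(b_o / 1.0, rel=1e-3)

    def test_noise_monotonicity_in_expectation(self, recovery_params):
        """Larger perturbations of model-generated data cannot decrease the
        mean minimised chi-square."""
        c = equilibrium_distribution(recovery_params, 9).c
        sigma = np.full(10, 0.02)
        means = []
        for amp in (0.0, 0.01, 0.03):
            ls = []
            for seed in range(6):
                rng = np.random.default_rng(100 + seed)
                d = np.clip(c + rng.normal(0, amp, 10), 1e-9, None)
                d /= d.sum()
                cond = ConditionDistribution("m", 9, d, sigma, 3)
                ls.append(fit_condition(cond, FitOptions(seed=seed, n_restarts=8)).l_min)
            means.append(np.mean(ls))
        assert means[0] <= means[1] <= means[2]


class TestFitConfigAndReport:
    def test_load_fit_options_yaml(self, tmp_path):
        path = tmp_path / "fit.yaml"
        path.write_text("n_restarts: 4\nsigma_floor: 0.002\nseed: 9\n")
        opts = load_fit_options(path)
        assert opts == FitOptions(n_restarts=4, sigma_floor=0.002, seed=9, tol=1e-10)

    def test_load_fit_options_rejects_unknown_keys(self, tmp_path):
        path = tmp_path / "fit.yaml"
        path.write_text("bogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            load_fit_options(path)

    def test_report_json(self, tmp_path, recovery_params):
        cond = exact_condition(recovery_params, 9)
        opts = FitOptions(seed=7, n_restarts=8)
        fit = fit_condition(cond, opts)
        path = tmp_path / "fit.json"
        write_fit_report(fit, path, opts)
        report = json.loads(path.read_text())
        assert report["condition_id"] == "exact"
        assert report["gauge"].startswith("p + alpha + q + beta")
        assert report["convergence"]["converged"] is True
        assert report["options"]["seed"] == 7
        assert len(report["model_distribution"]) == 10
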
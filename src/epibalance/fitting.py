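"""Chi-square fitting of the equilibrium model to condition distributions.

The objective is

    L(P, alpha, Q, beta) = sum_n (D_n - C_n)^2 / sigma_n^2,

comparing the observed average class frequencies D_n (with standard errors
sigma_n) to the stationary distribution C_n of the cooperative birth-death
model.  Because the stationary law depends only on rate ratios, L has an
exactly flat direction along common rescalings of (P, alpha, Q, beta).  The
fit therefore fixes the gauge P + alpha + Q + beta = 1 and optimises over
the remaining three directions; every scientific output — the fitted
distribution, the minimised L, the reduced chi-square, and the
cooperativity ratios alpha/P and beta/Q — is invariant under this choice.

Confidence intervals use the Gaussian approximation of the likelihood
exp(-L/2) near its maximum: the parameter covariance is the inverse of half
the Hessian of L, evaluated numerically on the gauge-constrained subspace.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import minimize

from .epialleles import ConditionDistribution
from .model import (
    EquilibriumDistribution,
    ModelParams,
    _stationary,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "chi_square",
    "fit_condition",
    "parameter_confidence",
    "reduced_chi_square",
    "load_fit_options",
    "write_fit_report",
]

_PARAM_NAMES = ("p", "alpha", "q", "beta")


@dataclass(frozen=True)
class FitOptions:
    """Configuration of the chi-square fit.

    n_restarts : number of local searches from seeded random starts on the
        constraint simplex (multi-start guards against local minima in the
        bimodal regime).
    tol : agreement required between the two best restarts' L values for
        the fit to be declared converged.
    sigma_floor : lower bound applied to each sigma_n (frequency scale);
        prevents division by zero when replicates coincide at a class.
    seed : seed for the restart draws.
    """

    n_restarts: int = 16
    tol: float = 1e-10
    sigma_floor: float = 1e-3
    seed: int = 0


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting the equilibrium model to one condition."""

    condition_id: str
    params: ModelParams
    model: EquilibriumDistribution
    l_min: float
    reduced_chi2: float
    ci68: dict
    significant_2sigma: dict
    ratios: dict
    converged: bool
    n_restarts_used: int
    hessian_warning: bool = False

    @property
    def ratio_meth(self) -> float:
        """Cooperativity ratio alpha / P for methylation."""
        return self.ratios["alpha_over_p"]

    @property
    def ratio_demeth(self) -> float:
        """Cooperativity ratio beta / Q for demethylation."""
        return self.ratios["beta_over_q"]


def chi_square(
    d: np.ndarray,
    sigma: np.ndarray,
    c: np.ndarray,
    sigma_floor: float = 1e-3,
) -> float:
    """Chi-square distance between observed and model class frequencies.

    Returns sum_n (d[n] - c[n])^2 / max(sigma[n], sigma_floor)^2.
    """
    d = np.asarray(d, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (d.shape == sigma.shape == c.shape):
        raise ValueError("d, sigma and c must have the same length")
    if sigma_floor <= 0:
        raise ValueError("sigma_floor must be positive")
    s = np.maximum(sigma, sigma_floor)
    return float(np.sum((d - c) ** 2 / s**2))


def reduced_chi_square(l_min: float, n_sites: int) -> float:
    """Reduced chi-square L / dof with dof = (N + 1) - 4.

    The four named rate parameters are counted as free even though only
    three directions are identifiable (the scale is gauge-fixed); see the
    package documentation for the convention.
    """
    dof = (n_sites + 1) - 4
    if dof < 1:
        raise ValueError(
            f"dof = (N+1) - 4 = {dof} < 1 for N = {n_sites}; report the raw "
            "chi-square instead of a reduced value"
        )
    return l_min / dof


def _softmax4(z3: np.ndarray) -> np.ndarray:
    """Map three free logits to the open simplex p + alpha + q + beta = 1."""
    z = np.concatenate(([0.0], z3))
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _objective_factory(d, s2, n_sites):
    def objective(z3):
        theta = _softmax4(z3)
        c = _stationary(theta[0], theta[1], theta[2], theta[3], n_sites)
        r = d - c
        return float(np.sum(r * r / s2))

    return objective


def _l_of_params(theta, d, s2, n_sites):
    """L at a raw parameter point; negative components are clipped to zero.

    Used only for finite-difference curvature near the optimum, where a
    step can push a boundary parameter slightly negative.
    """
    t = np.maximum(np.asarray(theta, dtype=float), 0.0)
    if t[2] + t[3] <= 0:
        return np.inf
    c = _stationary(t[0], t[1], t[2], t[3], n_sites)
    r = d - c
    return float(np.sum(r * r / s2))


def fit_condition(
    condition: ConditionDistribution,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the four rate parameters to a condition distribution.

    Minimises the chi-square objective over the non-negative orthant
    intersected with the gauge constraint p + alpha + q + beta = 1, using
    Nelder-Mead from ``options.n_restarts`` seeded random starts on the
    simplex.  The fit is declared converged when the two best restarts
    agree in L within ``options.tol``.

    A failure of every restart yields ``converged=False`` with the best
    point found, not an exception.
    """
    options = options or FitOptions()
    n_sites = condition.n_sites
    if n_sites + 1 < 4:
        raise ValueError(
            f"need at least 4 methylation classes to fit 4 parameters; "
            f"got N = {n_sites} ({n_sites + 1} classes)"
        )
    d = condition.d
    s2 = np.maximum(condition.sigma, options.sigma_floor) ** 2
    objective = _objective_factory(d, s2, n_sites)

    rng = np.random.default_rng(options.seed)
    starts = rng.dirichlet(np.ones(4), size=options.n_restarts)
    results = []
    for start in starts:
        z0 = np.log(np.maximum(start[1:], 1e-12) / max(start[0], 1e-12))
        res = minimize(
            objective,
            z0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-12,
                "fatol": 1e-14,
                "maxfev": 4000,
                "adaptive": False,
            },
        )
        # polish: restart the simplex at the located minimum
        res2 = minimize(
            objective,
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-15, "maxfev": 2000},
        )
        best = res2 if res2.fun <= res.fun else res
        results.append(best)

    results.sort(key=lambda r: r.fun)
    best = results[0]
    converged = (
        len(results) >= 2 and abs(results[1].fun - best.fun) <= options.tol
    ) or len(results) == 1

    theta = _softmax4(best.x)
    params = ModelParams(*theta)
    c = _stationary(*theta, n_sites)
    model = EquilibriumDistribution(n_sites=n_sites, c=c)
    l_min = float(best.fun)
    red = reduced_chi_square(l_min, n_sites)

    ci68, cov, hess_warn = parameter_confidence(theta, d, s2, n_sites)
    significant = {
        name: bool(theta[i] > 2.0 * ci68[name]) if np.isfinite(ci68[name]) else False
        for i, name in enumerate(_PARAM_NAMES)
    }
    ratios = _ratio_intervals(theta, cov)

    return FitResult(
        condition_id=condition.condition_id,
        params=params,
        model=model,
        l_min=l_min,
        reduced_chi2=red,
        ci68=ci68,
        significant_2sigma=significant,
        ratios=ratios,
        converged=bool(converged),
        n_restarts_used=options.n_restarts,
        hessian_warning=hess_warn,
    )


def _tangent_basis() -> np.ndarray:
    """Orthonormal basis (4 x 3) of the sum-zero tangent of the simplex."""
    ones = np.ones((4, 1)) / 2.0
    # complete to an orthonormal basis of R^4, drop the ones-direction
    q, _ = np.linalg.qr(np.hstack([ones, np.eye(4)[:, :3]]))
    return q[:, 1:4]


def _confidence_from_objective(fun, theta: np.ndarray, step: float = 1e-5):
    """Half-widths and covariance from the curvature of an objective.

    ``fun`` maps a 4-parameter point to the chi-square value L.  The
    likelihood is exp(-L/2), so near the minimum the parameter covariance
    is the inverse of half the Hessian of L.  The Hessian is computed by
    central differences along an orthonormal basis of the gauge-constrained
    subspace (sum of parameter increments zero), which excludes the exactly
    flat scale direction.
    """
    theta = np.asarray(theta, dtype=float)
    B = _tangent_basis()
    H = np.empty((3, 3))
    f0 = fun(theta)
    for i in range(3):
        for j in range(i, 3):
            ei, ej = B[:, i] * step, B[:, j] * step
            if i == j:
                f_p = fun(theta + ei)
                f_m = fun(theta - ei)
                H[i, i] = (f_p - 2 * f0 + f_m) / step**2
            else:
                f_pp = fun(theta + ei + ej)
                f_pm = fun(theta + ei - ej)
                f_mp = fun(theta - ei + ej)
                f_mm = fun(theta - ei - ej)
                H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * step**2)

    warn = False
    eigvals = np.linalg.eigvalsh(H)
    if eigvals.min() <= 1e-12 * max(1.0, abs(eigvals).max()):
        warnings.warn(
            "singular Hessian on the gauge-constrained subspace; "
            "confidence half-widths reported as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        warn = True
        cov = np.full((4, 4), np.inf)
        ci = {name: np.inf for name in _PARAM_NAMES}
        return ci, cov, warn

    cov_t = 2.0 * np.linalg.inv(H)  # covariance = inv(Hessian of L / 2)
    cov = B @ cov_t @ B.T
    ci = {
        name: float(np.sqrt(max(cov[i, i], 0.0)))
        for i, name in enumerate(_PARAM_NAMES)
    }
    return ci, cov, warn


def parameter_confidence(
    theta: Sequence[float],
    d: np.ndarray,
    s2: np.ndarray,
    n_sites: int,
    step: float = 1e-5,
):
    """68% half-widths of the gauge-fixed parameters at the fit optimum.

    Returns
    -------
    (ci68, cov, warning) : dict of per-parameter half-widths, the 4x4
        parameter covariance restricted to the constrained subspace, and a
        flag set when the constrained Hessian is singular (half-widths are
        then +inf).
    """
    return _confidence_from_objective(
        lambda th: _l_of_params(th, d, s2, n_sites), np.asarray(theta, float), step
    )


def _ratio_intervals(theta: np.ndarray, cov: np.ndarray) -> dict:
    """Cooperativity ratios alpha/P and beta/Q with propagated 68% widths."""
    p, a, q, b = theta
    out = {}
    tiny = 1e-12
    if p > tiny:
        r1 = a / p
        g = np.array([-a / p**2, 1.0 / p, 0.0, 0.0])
        v = float(g @ cov @ g) if np.isfinite(cov).all() else np.inf
        out["alpha_over_p"] = float(r1)
        out["alpha_over_p_ci68"] = float(np.sqrt(v)) if v >= 0 else np.inf
    else:
        out["alpha_over_p"] = np.inf if a > 0 else 0.0
        out["alpha_over_p_ci68"] = np.inf
    if q > tiny:
        r2 = b / q
        g = np.array([0.0, 0.0, -b / q**2, 1.0 / q])
        v = float(g @ cov @ g) if np.isfinite(cov).all() else np.inf
        out["beta_over_q"] = float(r2)
        out["beta_over_q_ci68"] = float(np.sqrt(v)) if v >= 0 else np.inf
    else:
        out["beta_over_q"] = np.inf if b > 0 else 0.0
        out["beta_over_q_ci68"] = np.inf
    return out


def load_fit_options(path) -> FitOptions:
    """Load fit configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(FitOptions)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown fit options: {sorted(unknown)}")
    return FitOptions(**data)


def write_fit_report(
    fit: FitResult,
    path,
    options: FitOptions | None = None,
) -> None:
    """Write a structured JSON fit report."""
    from . import __version__

    def _num(x):
        return None if x is None else (float(x) if np.isfinite(x) else "inf")

    report = {
        "tool": "epibalance",
        "version": __version__,
        "condition_id": fit.condition_id,
        "gauge": "p + alpha + q + beta = 1",
        "params": {n: getattr(fit.params, n) for n in _PARAM_NAMES},
        "ci68": {k: _num(v) for k, v in fit.ci68.items()},
        "significant_2sigma": fit.significant_2sigma,
        "l_min": fit.l_min,
        "reduced_chi2": fit.reduced_chi2,
        "ratios": {k: _num(v) for k, v in fit.ratios.items()},
        "convergence": {
            "converged": fit.converged,
            "n_restarts_used": fit.n_restarts_used,
            "hessian_warning": fit.hessian_warning,
        },
        "model_distribution": fit.model.c.tolist(),
    }
    if options is not None:
        report["options"] = dataclasses.asdict(options)
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
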
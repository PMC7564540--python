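"""Cooperative birth-death model of methylation classes.

A molecule with N CpG sites and n of them methylated moves between adjacent
classes: each unmethylated site gains methylation at per-site rate
P_n = P + alpha*n and each methylated site loses it at per-site rate
Q_n = Q + beta*(N - n).  P and Q are the configuration-independent rates;
alpha and beta are the cooperative contributions, coupling a site's rate to
the methylation state of the rest of the molecule.

The class-level chain is a birth-death process with upward rate
(N - n) * P_n and downward rate n * Q_n, so its stationary distribution
satisfies detailed balance

    C_n * (N - n) * P_n = C_{n+1} * (n + 1) * Q_{n+1},    n = 0..N-1,

and follows from the one-term recursion implemented here.  Only rate
*ratios* are identified by the stationary law: rescaling all four rates by
a common factor leaves it unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "EquilibriumDistribution",
    "RateProfile",
    "BalancePoints",
    "methylation_rate",
    "demethylation_rate",
    "equilibrium_distribution",
    "class_rate_profile",
    "balance_points",
    "write_equilibrium_distribution",
]


@dataclass(frozen=True)
class ModelParams:
    """Rate parameters of the cooperative methylation/demethylation model.

    Attributes
    ----------
    p : float
        Independent per-site methylation rate (per unit time).
    alpha : float
        Cooperative methylation coefficient (per unit time per methylated
        site on the molecule).
    q : float
        Independent per-site demethylation rate.
    beta : float
        Cooperative demethylation coefficient (per unit time per
        unmethylated site on the molecule).
    """

    p: float
    alpha: float
    q: float
    beta: float

    def __post_init__(self):
        for name in ("p", "alpha", "q", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        # q + beta = 0 is allowed at the type level (useful for absorbing
        # trajectory simulations); computing an equilibrium then raises.

    def scaled(self, k: float) -> "ModelParams":
        """Return a copy with all four rates multiplied by k > 0."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return ModelParams(self.p * k, self.alpha * k, self.q * k, self.beta * k)

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.alpha, self.q, self.beta], dtype=float)


@dataclass(frozen=True)
class EquilibriumDistribution:
    """Stationary class frequencies C_n / C of the birth-death chain."""

    n_sites: int
    c: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        if c.shape != (self.n_sites + 1,):
            raise ValueError("c must have length n_sites + 1")
        if (c < 0).any():
            raise ValueError("equilibrium frequencies must be non-negative")
        if abs(c.sum() - 1.0) > 1e-12:
            raise ValueError("equilibrium frequencies must sum to 1")
        object.__setattr__(self, "c", c)


@dataclass(frozen=True)
class RateProfile:
    """Per-site and per-class transition rates across methylation classes.

    ``p_site[n]`` = P_n for n = 0..N-1 (per-site methylation rate when the
    molecule is in class n); ``q_site[n-1]`` = Q_n for n = 1..N.  ``up`` and
    ``down`` are the class-level total rates (N - n) * P_n and n * Q_n.
    """

    n_sites: int
    p_site: np.ndarray
    q_site: np.ndarray
    up: np.ndarray
    down: np.ndarray


@dataclass(frozen=True)
class BalancePoints:
    """Classes where upward and downward fluxes balance, and the modes of c.

    ``crossings`` lists indices n (0..N-1) where the flux ratio
    r_n = (N - n) P_n / ((n + 1) Q_{n+1}) crosses 1 — the local extrema of
    the stationary distribution.  ``modes`` lists the local maxima of c.
    """

    crossings: tuple
    modes: tuple


def methylation_rate(params: ModelParams, n: int, n_sites: int) -> float:
    """Per-site methylation rate P_n = P + alpha * n for a class-n molecule."""
    if not 0 <= n <= n_sites - 1:
        raise ValueError(f"methylation acts on classes 0..N-1; got n={n}, N={n_sites}")
    return params.p + params.alpha * n


def demethylation_rate(params: ModelParams, n: int, n_sites: int) -> float:
    """Per-site demethylation rate Q_n = Q + beta * (N - n) for class n."""
    if not 1 <= n <= n_sites:
        raise ValueError(f"demethylation acts on classes 1..N; got n={n}, N={n_sites}")
    return params.q + params.beta * (n_sites - n)


def _class_rates(p: float, a: float, q: float, b: float, n_sites: int):
    """Total up/down class rates: up[n] = (N-n)P_n, down[n] = (n+1)Q_{n+1}."""
    n = np.arange(n_sites, dtype=float)
    up = (n_sites - n) * (p + a * n)
    down = (n + 1.0) * (q + b * (n_sites - (n + 1.0)))
    return up, down


def _stationary(p: float, a: float, q: float, b: float, n_sites: int) -> np.ndarray:
    """Stationary class frequencies by the detailed-balance recursion.

    Weights are accumulated in log space so that extreme rate ratios at
    large N cannot overflow; classes unreachable from below (zero upward
    flux at some lower class) carry zero mass.
    """
    up, down = _class_rates(p, a, q, b, n_sites)
    logw = np.full(n_sites + 1, -np.inf)
    logw[0] = 0.0
    cur = 0.0
    for i in range(n_sites):
        if up[i] == 0.0:
            break
        if down[i] == 0.0:
            raise ValueError(
                "absorbing boundary, no finite equilibrium: class "
                f"{i + 1} has zero demethylation rate but nonzero inbound flux"
            )
        cur += math.log(up[i]) - math.log(down[i])
        logw[i + 1] = cur
    w = np.exp(logw - logw.max())
    return w / w.sum()


def equilibrium_distribution(params: ModelParams, n_sites: int) -> EquilibriumDistribution:
    """Stationary methylation-class distribution under detailed balance.

    With alpha = beta = 0 this reduces exactly to Binomial(N, P / (P + Q)):
    sites decouple and each is methylated with probability P / (P + Q).

    Raises
    ------
    ValueError
        If some class has zero demethylation rate but a nonzero upward flux
        feeding it (absorbing boundary: no finite equilibrium exists).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    c = _stationary(params.p, params.alpha, params.q, params.beta, n_sites)
    return EquilibriumDistribution(n_sites=n_sites, c=c)


def class_rate_profile(params: ModelParams, n_sites: int) -> RateProfile:
    """Per-site and total class transition rates for all classes."""
    n_lo = np.arange(n_sites, dtype=float)          # classes 0..N-1 (methylation)
    n_hi = np.arange(1, n_sites + 1, dtype=float)   # classes 1..N (demethylation)
    p_site = params.p + params.alpha * n_lo
    q_site = params.q + params.beta * (n_sites - n_hi)
    up = (n_sites - n_lo) * p_site
    down = n_hi * q_site
    return RateProfile(
        n_sites=n_sites, p_site=p_site, q_site=q_site, up=up, down=down
    )


def balance_points(params: ModelParams, n_sites: int) -> BalancePoints:
    """Locate flux balance points and the modes of the stationary law.

    The ratio r_n = (N - n) P_n / ((n + 1) Q_{n+1}) equals C_{n+1} / C_n, so
    the stationary distribution rises where r_n > 1 and falls where
    r_n < 1; r_n crossing 1 marks a local extremum.  A unimodal profile
    (methylation or demethylation dominating everywhere) yields one mode at
    an end class, while a ratio that falls below 1 and later rises above it
    yields two modes — the bimodal regime.  Plateaus (r_n exactly 1) are
    assigned to the lower class index.
    """
    up, down = _class_rates(params.p, params.alpha, params.q, params.beta, n_sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(down > 0, up / np.where(down > 0, down, 1.0), np.inf)
        r = np.where((up == 0) & (down == 0), 0.0, r)

    # r_n algebraically equal to 1 can land a few ulp off; compare with a
    # relative tolerance so plateaus resolve deterministically
    tol = 1e-9
    above = r > 1.0 + tol
    at_most_one = r <= 1.0 + tol

    crossings = []
    for n in range(n_sites):
        if abs(r[n] - 1.0) <= tol:
            crossings.append(n)
        elif n >= 1 and not abs(r[n - 1] - 1.0) <= tol and (
            (r[n - 1] - 1.0) * (r[n] - 1.0) < 0
        ):
            crossings.append(n)

    modes = []
    for n in range(n_sites + 1):
        left_ok = n == 0 or above[n - 1]
        right_ok = n == n_sites or at_most_one[n]
        if left_ok and right_ok:
            modes.append(n)
    return BalancePoints(crossings=tuple(crossings), modes=tuple(modes))


def write_equilibrium_distribution(dist: EquilibriumDistribution, path) -> None:
    """Write the stationary distribution as TSV with columns n, c."""
    df = pd.DataFrame({"n": np.arange(dist.n_sites + 1), "c": dist.c})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
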
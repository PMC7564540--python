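"""Synthetic epiallele data with the statistical structure the analysis assumes.

Three generators are provided:

* :func:`sample_epialleles` draws molecules directly from the analytic
  stationary class distribution and places the methylated sites uniformly
  at random (the mean-field model is site-exchangeable, so exchangeable
  placement is the unique consistent choice);
* :func:`simulate_trajectory` runs the continuous-time birth-death dynamics
  per molecule (Gillespie algorithm) — the brute-force oracle for the
  detailed-balance stationary law;
* :func:`generate_condition` builds a replicate condition: each simulated
  individual receives its own rate parameters, obtained by multiplying the
  ground truth by lognormal factors (median 1), emulating inter-individual
  parameter fluctuation on top of finite-coverage sampling noise.

All randomness flows from explicit seeds; there is no hidden global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .epialleles import (
    ConditionDistribution,
    EpialleleMatrix,
    average_condition,
    methylation_classes,
)
from .model import ModelParams, _class_rates, equilibrium_distribution

__all__ = [
    "SyntheticConditionSpec",
    "TrajectoryRecord",
    "sample_epialleles",
    "simulate_trajectory",
    "generate_condition",
    "write_ground_truth",
]


@dataclass(frozen=True)
class SyntheticConditionSpec:
    """Ground truth and sampling plan for one simulated condition.

    Defaults mirror the scale of deep bisulfite-amplicon studies: regions
    of N = 9 CpGs, three individuals per condition, 10^4 molecules per
    individual, and 10% relative inter-individual parameter jitter.
    """

    params: ModelParams
    n_sites: int = 9
    n_individuals: int = 3
    reads_per_individual: int = 10_000
    jitter_sd: float = 0.1
    seed: int = 0
    condition_id: str = "synthetic"

    def __post_init__(self):
        if self.reads_per_individual < 1:
            raise ValueError("reads_per_individual must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass(frozen=True)
class TrajectoryRecord:
    """Class occupancy of simulated molecules at requested checkpoints.

    ``states`` has shape (n_checkpoints, n_molecules): the class of each
    molecule at each checkpoint time.  ``occupancy`` is the per-checkpoint
    class histogram normalised to frequencies.
    """

    times: np.ndarray
    states: np.ndarray
    n_sites: int

    @property
    def occupancy(self) -> np.ndarray:
        out = np.empty((len(self.times), self.n_sites + 1))
        for i, row in enumerate(self.states):
            out[i] = np.bincount(row, minlength=self.n_sites + 1) / row.size
        return out


def _place_sites(classes: np.ndarray, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Methylate a uniformly random subset of `classes[i]` of the N sites."""
    n_reads = classes.size
    ranks = np.argsort(rng.random((n_reads, n_sites)), axis=1)
    return (ranks < classes[:, None]).astype(np.uint8)


def sample_epialleles(
    params: ModelParams,
    n_sites: int,
    n_reads: int,
    seed: Union[int, np.random.Generator] = 0,
    sample_id: str = "synthetic",
) -> EpialleleMatrix:
    """Draw an epiallele matrix from the stationary class distribution.

    Each molecule's class is drawn from the analytic equilibrium, then its
    methylated sites are placed uniformly at random.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    eq = equilibrium_distribution(params, n_sites)
    classes = rng.choice(n_sites + 1, size=n_reads, p=eq.c)
    reads = _place_sites(classes, n_sites, rng)
    return EpialleleMatrix(sample_id=sample_id, n_sites=n_sites, reads=reads)


def _advance(state, t, target, up, down, rng):
    """Advance each molecule's Gillespie clock to the target time, in place."""
    n_mol = state.size
    while True:
        total = up[state] + down[state]
        active = (t < target) & (total > 0)
        if not active.any():
            t[t < target] = target
            return
        idx = np.flatnonzero(active)
        rates = total[idx]
        dt = rng.exponential(1.0 / rates)
        t_new = t[idx] + dt
        fires = t_new <= target
        fire_idx = idx[fires]
        t[idx] = np.minimum(t_new, target)
        if fire_idx.size:
            u = rng.random(fire_idx.size)
            go_up = u < up[state[fire_idx]] / (
                up[state[fire_idx]] + down[state[fire_idx]]
            )
            state[fire_idx] += np.where(go_up, 1, -1)


def simulate_trajectory(
    params: ModelParams,
    n_sites: int,
    n_molecules: int,
    horizon: float,
    seed: Union[int, np.random.Generator] = 0,
    checkpoints: Optional[Sequence[float]] = None,
    initial_class: Union[int, str] = 0,
) -> tuple[TrajectoryRecord, EpialleleMatrix]:
    """Continuous-time birth-death simulation of molecule classes.

    A molecule in class n gains methylation at total rate (N - n) * P_n and
    loses it at total rate n * Q_n (each unmethylated site flips at the
    per-site rate P_n, each methylated site at Q_n); waiting times are
    exponential.  Class occupancy is recorded at the requested checkpoint
    times, and the final states are materialised as an epiallele matrix
    with uniform site placement.

    ``initial_class`` may be a class index or "uniform" for a uniform
    random class per molecule.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    up, down_shift = _class_rates(params.p, params.alpha, params.q, params.beta, n_sites)
    # per-class total rates indexed by current class n = 0..N
    up_rate = np.zeros(n_sites + 1)
    up_rate[:n_sites] = up                     # (N - n) P_n for n = 0..N-1
    down_rate = np.zeros(n_sites + 1)
    down_rate[1:] = down_shift                 # n Q_n for n = 1..N

    if checkpoints is None:
        checkpoints = np.array([horizon])
    else:
        checkpoints = np.asarray(sorted(checkpoints), dtype=float)
        if (checkpoints <= 0).any() or checkpoints[-1] > horizon:
            raise ValueError("checkpoints must lie in (0, horizon]")

    if initial_class == "uniform":
        state = rng.integers(0, n_sites + 1, size=n_molecules)
    else:
        if not 0 <= int(initial_class) <= n_sites:
            raise ValueError("initial_class out of range")
        state = np.full(n_molecules, int(initial_class), dtype=np.int64)
    state = state.astype(np.int64)
    t = np.zeros(n_molecules)

    records = np.empty((len(checkpoints), n_molecules), dtype=np.int64)
    for k, target in enumerate(checkpoints):
        _advance(state, t, target, up_rate, down_rate, rng)
        records[k] = state
    if checkpoints[-1] < horizon:
        _advance(state, t, horizon, up_rate, down_rate, rng)

    final = EpialleleMatrix(
        sample_id="trajectory_final",
        n_sites=n_sites,
        reads=_place_sites(state, n_sites, rng),
    )
    record = TrajectoryRecord(times=np.asarray(checkpoints), states=records, n_sites=n_sites)
    return record, final


def _jittered_params(
    params: ModelParams, jitter_sd: float, rng: np.random.Generator, max_retries: int = 100
) -> ModelParams:
    """Multiply each rate by an independent lognormal factor (median 1)."""
    if jitter_sd == 0:
        return params
    sigma_log = np.sqrt(np.log1p(jitter_sd**2))
    base = params.as_array()
    for _ in range(max_retries):
        factors = rng.lognormal(mean=0.0, sigma=sigma_log, size=4)
        cand = base * factors
        if cand[2] + cand[3] > 0:
            return ModelParams(*cand)
    raise ValueError("could not draw valid jittered parameters")


def generate_condition(
    spec: SyntheticConditionSpec,
) -> tuple[list[EpialleleMatrix], ConditionDistribution, dict]:
    """Simulate a replicate condition with inter-individual parameter jitter.

    Each of the m individuals gets jittered rate parameters, an epiallele
    matrix sampled from its own stationary law, and the per-individual
    class distributions are averaged into a ConditionDistribution.  The
    returned ground-truth record holds the generating parameters, the
    per-individual parameters, and the seed.
    """
    rng = np.random.default_rng(spec.seed)
    matrices = []
    per_individual = []
    for i in range(spec.n_individuals):
        ind_params = _jittered_params(spec.params, spec.jitter_sd, rng)
        per_individual.append(ind_params)
        mat = sample_epialleles(
            ind_params,
            spec.n_sites,
            spec.reads_per_individual,
            seed=rng,
            sample_id=f"{spec.condition_id}_ind{i + 1}",
        )
        matrices.append(mat)
    condition = average_condition(
        [methylation_classes(m) for m in matrices], condition_id=spec.condition_id
    )
    truth = {
        "condition_id": spec.condition_id,
        "params": {
            "p": spec.params.p,
            "alpha": spec.params.alpha,
            "q": spec.params.q,
            "beta": spec.params.beta,
        },
        "ratio_meth": spec.params.alpha / spec.params.p if spec.params.p > 0 else None,
        "ratio_demeth": spec.params.beta / spec.params.q if spec.params.q > 0 else None,
        "per_individual_params": [
            {"p": pp.p, "alpha": pp.alpha, "q": pp.q, "beta": pp.beta}
            for pp in per_individual
        ],
        "n_sites": spec.n_sites,
        "n_individuals": spec.n_individuals,
        "reads_per_individual": spec.reads_per_individual,
        "jitter_sd": spec.jitter_sd,
        "seed": spec.seed,
    }
    return matrices, condition, truth


def write_ground_truth(truth: dict, path) -> None:
    """Write the ground-truth sidecar JSON next to generated epiallele files."""
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
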
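"""Fitness estimation for one-missegregation-step neighbors.

Karyotypes adjacent to the frequent set are typically seen in only a
handful of cells, too few for replicator fitting.  Their expected
frequency is instead modeled as mutational flux from the frequent
parents,

    dx_i/dt = sum_{j in S} P(alpha_i | alpha_j) f_j x_j(t) + f_i x_i(t),

where ``P(alpha_i | alpha_j)`` is the probability that one missegregation
converts parent j into neighbor i during a division
(:func:`alfak.karyospace.single_ms_probability`).  The neighbor fitness
``f_i`` is the MAP estimate under a binomial observation model of the
neighbor's counts combined with a Normal prior on the fitness difference
``f_i - f_j`` for each adjacent parent j.  Absence is informative: a
neighbor never observed despite fit parents gets its fitness bounded from
above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .freqfit import FitnessEstimate, FrequentSet, LongitudinalCounts, replicator_solve
from .karyospace import (
    Karyotype,
    TransitionKernel,
    manhattan_distance,
    one_step_neighbors,
    single_ms_probability,
)

__all__ = [
    "NeighborPrior",
    "estimate_prior",
    "neighbor_flux_frequency",
    "fit_neighbor_fitness",
    "fit_all_neighbors",
]


@dataclass(frozen=True)
class NeighborPrior:
    """Normal prior on the parent-to-neighbor fitness difference (per day)."""

    mu_delta: float = 0.0
    sigma_delta: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_delta <= 0:
            raise ValueError(f"sigma_delta must be > 0, got {self.sigma_delta}")


def estimate_prior(
    estimates: Sequence[FitnessEstimate],
    fallback_sigma: Optional[float] = None,
) -> NeighborPrior:
    """Empirical prior from pairwise fitness differences of *adjacent*
    frequent karyotypes.

    Gains and losses are pooled symmetrically (each adjacent pair
    contributes +d and -d), so mu_delta is 0 by construction and
    sigma_delta reflects the typical single-step effect size.  With no
    adjacent pairs, falls back to the SD of all frequent fitness values
    (or ``fallback_sigma``).
    """
    if len(estimates) < 2:
        warnings.warn("fewer than 2 frequent estimates; using default prior", stacklevel=2)
        return NeighborPrior(0.0, fallback_sigma or 0.1)
    diffs: List[float] = []
    for a in range(len(estimates)):
        for b in range(a + 1, len(estimates)):
            if manhattan_distance(estimates[a].karyotype, estimates[b].karyotype) == 1:
                d = estimates[a].f - estimates[b].f
                diffs.extend([d, -d])
    if diffs:
        sigma = float(np.std(diffs, ddof=0))
    else:
        sigma = fallback_sigma if fallback_sigma is not None else float(
            np.std([e.f for e in estimates], ddof=0)
        )
    if sigma <= 0:
        sigma = fallback_sigma or 0.1
    return NeighborPrior(0.0, sigma)


def neighbor_flux_frequency(
    fi: float,
    parents: Sequence[Tuple[float, np.ndarray, float]],
    times: np.ndarray,
    grid_points: int = 201,
) -> np.ndarray:
    """Expected neighbor frequency trajectory under the flux model.

    Parameters
    ----------
    fi
        Candidate fitness of the neighbor.
    parents
        Triples ``(f_j, x_j(times), P(alpha_i | alpha_j))`` with the parent
        trajectory evaluated on ``times``.
    times
        Strictly increasing observation times (days); the neighbor starts
        at frequency 0 at ``times[0]``.

    The linear ODE is solved with an exact exponential integrating factor
    on a dense time grid (trapezoid rule on the influx term).  The state
    and the influx are floored at 0 so that negative net parent rates
    cannot drive the frequency negative.
    """
    times = np.asarray(times, dtype=float)
    if not parents or all(p[2] == 0 for p in parents):
        if not any(p[2] > 0 for p in parents):
            warnings.warn("no parent with positive transition probability; zero flux", stacklevel=2)
        return np.zeros_like(times)

    fj = np.array([p[0] for p in parents])
    xj = np.vstack([np.asarray(p[1], dtype=float) for p in parents])
    pij = np.array([p[2] for p in parents])

    # dense grid; parent trajectories interpolated in log space (they are
    # near-exponential between observations under the replicator model)
    grid = np.linspace(times[0], times[-1], grid_points)
    logxj = np.log(np.maximum(xj, 1e-300))
    xj_g = np.exp(
        np.vstack([np.interp(grid, times, logxj[j]) for j in range(len(parents))])
    )
    influx = np.maximum(pij @ (fj[:, None] * xj_g), 0.0)

    # exact integrating factor between grid nodes, trapezoid on the forcing:
    # x(t+h) = x(t) e^{fi h} + h/2 (g(t) e^{fi h} + g(t+h))
    h = grid[1] - grid[0]
    e = np.exp(fi * h)
    x = np.empty_like(grid)
    x[0] = 0.0
    for m in range(grid.size - 1):
        x[m + 1] = max(x[m] * e + 0.5 * h * (influx[m] * e + influx[m + 1]), 0.0)
    return np.interp(times, grid, x)


def fit_neighbor_fitness(
    data: LongitudinalCounts,
    estimates: Sequence[FitnessEstimate],
    neighbor: Karyotype,
    prior: NeighborPrior,
    kernel: TransitionKernel,
    f_bounds: Tuple[float, float] = (-2.0, 2.0),
) -> FitnessEstimate:
    """MAP fitness of one neighbor karyotype.

    Maximizes over ``f_i`` the binomial log-likelihood of the neighbor's
    observed counts (its expected frequency from
    :func:`neighbor_flux_frequency`) plus one Normal log-prior term on
    ``f_i - f_j`` per adjacent frequent parent.  Observed counts may be
    zero everywhere.
    """
    est_by_k: Dict[Karyotype, FitnessEstimate] = {e.karyotype: e for e in estimates}
    parents_f = [
        e for e in estimates
        if e.stage == "frequent" and manhattan_distance(e.karyotype, neighbor) == 1
    ]
    if not parents_f:
        raise ValueError("neighbor is not adjacent to any frequent karyotype")

    times = data.times
    t0 = times - times[0]
    idx = {k: i for i, k in enumerate(data.karyotypes)}
    n_i = (
        data.counts[idx[neighbor]].astype(float)
        if neighbor in idx
        else np.zeros_like(times)
    )
    N = data.totals.astype(float)

    # parent frequency trajectories from the fitted replicator model
    S_members = [e.karyotype for e in estimates if e.stage == "frequent"]
    fS = np.array([est_by_k[k].f for k in S_members])
    x_first = np.array(
        [data.counts[idx[k], 0] if k in idx else 0 for k in S_members], dtype=float
    )
    x0 = (x_first + 0.5) / (x_first.sum() + 0.5 * len(S_members))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xS = replicator_solve(fS, x0, t0)

    parent_triples = []
    for e in parents_f:
        j = S_members.index(e.karyotype)
        pij = single_ms_probability(e.karyotype, neighbor, kernel)
        parent_triples.append((e.f, xS[j], pij))

    def neg_logpost(fi: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            xhat = neighbor_flux_frequency(fi, parent_triples, times)
        xhat = np.clip(xhat, 1e-12, 1 - 1e-12)
        ll = float(np.sum(stats.binom.logpmf(n_i, N, xhat)))
        lp = float(
            sum(stats.norm.logpdf(fi - e.f, prior.mu_delta, prior.sigma_delta) for e in parents_f)
        )
        return -(ll + lp)

    res = optimize.minimize_scalar(neg_logpost, bounds=f_bounds, method="bounded",
                                   options={"xatol": 1e-6})
    parents = tuple(e.karyotype for e in parents_f)
    return FitnessEstimate(neighbor, float(res.x), stage="neighbor", parents=parents)


def fit_all_neighbors(
    data: LongitudinalCounts,
    S: FrequentSet,
    estimates: Sequence[FitnessEstimate],
    kernel: TransitionKernel,
    prior: Optional[NeighborPrior] = None,
) -> List[FitnessEstimate]:
    """Fit every viable one-step neighbor of the frequent set.

    Returns neighbor-stage estimates only; the anchor set for Kriging is
    the frequent estimates plus these.
    """
    if prior is None:
        prior = estimate_prior(list(estimates))
    neighbors: List[Karyotype] = []
    seen = set(S.members)
    for k in S.members:
        for nb in sorted(one_step_neighbors(k, kernel.max_copy, include_nonviable=False)):
            if nb not in seen:
                seen.add(nb)
                neighbors.append(nb)
    out: List[FitnessEstimate] = []
    for nb in neighbors:
        out.append(fit_neighbor_fitness(data, estimates, nb, prior, kernel))
    return out
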
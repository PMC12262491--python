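"""Quasispecies analysis: transition matrices, steady states, rate screens.

A population spread over the charted region evolves (in the deterministic
large-population limit) as ``dx/dt = W x - (mean growth) x``, where the
growth-mutation matrix W combines karyotype fitness with single-step
missegregation flux.  Each division of state j produces two daughters;
with per-copy missegregation probability p, a daughter equals a
distance-1 neighbor i with probability ``single_ms_probability(j -> i)``
and equals j with the zero-event probability ``(1-p)^N_tot``.  Hence

    W[i, j] = f_j * 2 * P(one missegregation j -> i)        (i != j)
    W[j, j] = f_j * (2 * (1-p)^N_tot - 1)

(the -1 accounts for the parent consumed by the division).  Flux into
out-of-region or inviable states, and all multi-event mass, is explicit
loss — never silently renormalized — making the matrix a conservative
single-step approximation.  The steady state is the normalized leading
(Perron) eigenvector of W; because per-copy missegregation makes
high-ploidy states leak more mass per division, raising p can displace
narrow or high-ploidy fitness peaks (the quasispecies error threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .karyospace import (
    Karyotype,
    TransitionKernel,
    is_viable,
    manhattan_distance,
    one_step_neighbors,
    single_ms_probability,
)

__all__ = [
    "TransitionMatrix",
    "SteadyState",
    "build_transition_matrix",
    "steady_state",
    "rate_screen",
    "RateScreenResult",
    "assign_groups",
]


@dataclass
class TransitionMatrix:
    """Sparse growth-mutation matrix; ``W[i, j]`` is the rate at which
    state j produces state i per unit time."""

    states: List[Karyotype]
    W: sparse.csr_matrix
    loss: np.ndarray  # per-state rate of flux leaving the charted region
    f: np.ndarray  # per-state net growth rate
    p: float

    def __post_init__(self) -> None:
        n = len(self.states)
        if self.W.shape != (n, n):
            raise ValueError("W shape mismatch")

    def dense(self) -> np.ndarray:
        return self.W.toarray()


@dataclass
class SteadyState:
    p: float
    states: List[Karyotype]
    freqs: np.ndarray
    dominant: Karyotype
    mean_fitness: float


def build_transition_matrix(
    fitness: Dict[Karyotype, float], kernel: TransitionKernel
) -> TransitionMatrix:
    """Growth-mutation matrix over a finite charted region.

    ``fitness`` maps every in-region karyotype to its (finite) net growth
    rate; NaN values are rejected.  Only distance-1 transitions are
    represented; multi-event and out-of-region flux is accumulated in the
    per-state ``loss`` vector.
    """
    states = sorted(fitness)
    index = {k: i for i, k in enumerate(states)}
    n = len(states)
    f = np.array([fitness[k] for k in states], dtype=float)
    if np.any(np.isnan(f)):
        bad = [states[i] for i in np.where(np.isnan(f))[0]]
        raise ValueError(f"NaN fitness for states {bad[:3]}...")
    W = sparse.lil_matrix((n, n))
    loss = np.zeros(n)
    for j, kj in enumerate(states):
        n_tot = sum(kj)
        p0 = (1.0 - kernel.p) ** n_tot
        W[j, j] = f[j] * (2.0 * p0 - 1.0)
        outflux = 0.0
        for nb in one_step_neighbors(kj, kernel.max_copy, include_nonviable=True):
            prob = single_ms_probability(kj, nb, kernel)
            if nb in index and is_viable(nb, kernel.max_copy):
                W[index[nb], j] = f[j] * 2.0 * prob
            else:
                outflux += 2.0 * prob
        # multi-event mass: 2*(1 - p0 - sum of all single-event daughter probs)
        single_total = n_tot * kernel.p * (1.0 - kernel.p) ** (n_tot - 1)
        multi = max(1.0 - p0 - single_total, 0.0)
        loss[j] = f[j] * (outflux + 2.0 * multi)
    return TransitionMatrix(states, W.tocsr(), loss, f, kernel.p)


def steady_state(
    tm: TransitionMatrix, tol: float = 1e-10, max_iter: int = 20_000
) -> SteadyState:
    """Leading-eigenvector steady state of the growth-mutation matrix.

    W is shifted by ``c I`` with c large enough to make the matrix
    non-negative (the eigenvectors are unchanged), then power-iterated to
    ``tol`` in the L1 change of the normalized vector; this equals the
    long-time limit of the mean-fitness-corrected linear dynamics.  At
    high missegregation rates the matrix is nearly diagonal and its
    leading eigenvalues cluster, stalling power iteration; a Krylov
    (ARPACK) or dense eigensolver then finishes the job.  A final
    non-convergence raises with a spectral-gap diagnostic.
    """
    W = tm.W
    n = W.shape[0]
    diag = W.diagonal()
    wmax = float(np.abs(W).max()) if W.nnz else 1.0
    shift = max(0.0, -float(diag.min())) + 0.1 * (wmax + 1.0)
    M = (W + shift * sparse.eye(n, format="csr")).tocsr()
    x = np.full(n, 1.0 / n)
    converged = False
    for it in range(max_iter):
        y = M @ x
        s = y.sum()
        if s <= 0:
            raise RuntimeError("power iteration collapsed; matrix not primitive")
        y /= s
        delta = np.abs(y - x).sum()
        x = y
        if delta < tol:
            converged = True
            break
    if not converged:
        try:
            if n <= 1500:
                vals, vecs = np.linalg.eig(M.toarray())
                lead = int(np.argmax(vals.real))
                v = vecs[:, lead].real
            else:
                vals, vecs = sparse.linalg.eigs(M, k=1, which="LM", v0=x, tol=1e-12)
                v = vecs[:, 0].real
            v = np.abs(v)
            if v.sum() <= 0:
                raise RuntimeError("degenerate eigenvector")
            x = v / v.sum()
        except Exception as e:
            gap = _eig_gap(M)
            raise RuntimeError(
                f"steady state did not converge (spectral gap ratio {gap:.3g})"
            ) from e
    dom = int(np.argmax(x))
    # deterministic tie-break: lexicographically smallest karyotype among maxima
    maxima = np.where(np.isclose(x, x[dom], rtol=0, atol=1e-12))[0]
    dom = min(maxima, key=lambda i: tm.states[i])
    return SteadyState(tm.p, tm.states, x, tm.states[dom], float(x @ tm.f))


def _eig_gap(M) -> float:
    if M.shape[0] > 2000:
        return float("nan")
    A = M.toarray() if sparse.issparse(M) else np.asarray(M)
    vals = np.sort(np.abs(np.linalg.eigvals(A)))[::-1]
    return float(vals[1] / vals[0]) if vals.size > 1 else 0.0


@dataclass
class RateScreenResult:
    """Dominance table plus the underlying steady states per rate."""

    table: pd.DataFrame
    steady_states: Dict[float, SteadyState]


def rate_screen(
    fitness: Dict[Karyotype, float],
    p_grid: Sequence[float],
    max_copy: int = 8,
) -> RateScreenResult:
    """Steady states across missegregation rates.

    For each p in the ascending grid: the steady state, its dominant
    karyotype, the Manhattan distance of that dominant from the dominant
    at the lowest rate, and a switch flag when the distance is positive.
    """
    p_grid = list(p_grid)
    if any(b <= a for a, b in zip(p_grid, p_grid[1:])):
        raise ValueError("p_grid must be ascending")
    rows = []
    states_ref: Optional[Karyotype] = None
    freq_table: Dict[float, SteadyState] = {}
    for p in p_grid:
        tm = build_transition_matrix(fitness, TransitionKernel(p=p, max_copy=max_copy))
        ss = steady_state(tm)
        freq_table[p] = ss
        if states_ref is None:
            states_ref = ss.dominant
        d = manhattan_distance(ss.dominant, states_ref)
        rows.append(
            {
                "p": p,
                "dominant": ss.dominant,
                "distance_from_low_rate_dominant": d,
                "switch": bool(d > 0),
                "mean_fitness": ss.mean_fitness,
            }
        )
    return RateScreenResult(pd.DataFrame(rows), freq_table)


def assign_groups(
    screen: RateScreenResult, top_n: int = 400
) -> pd.DataFrame:
    """Classify abundant karyotypes by the sign of their abundance trend in p.

    Among the ``top_n`` karyotypes with the highest maximum steady-state
    abundance over the grid, group "x" collects those whose abundance
    correlates negatively (Spearman) with missegregation rate and group
    "y" those correlating positively; zero-correlation states stay
    unassigned.
    """
    sss = screen.steady_states
    ps = sorted(sss)
    states = sss[ps[0]].states
    freq = np.column_stack([sss[p].freqs for p in ps])  # state x rate
    top = np.argsort(freq.max(axis=1))[::-1][: min(top_n, len(states))]
    rows = []
    for i in top:
        if len(ps) < 2 or np.ptp(freq[i]) == 0:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(ps, freq[i]).statistic)
        group = "x" if rho < 0 else ("y" if rho > 0 else None)
        rows.append(
            {"karyotype": states[i], "rho": rho, "group": group,
             "max_abundance": float(freq[i].max())}
        )
    return pd.DataFrame(rows)
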
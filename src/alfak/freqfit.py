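"""Fitness estimation for frequently observed karyotypes.

Clone frequencies under selection follow the continuous-time replicator
equation

    dx_i/dt = x_i(t) * (f_i - sum_j x_j(t) f_j),

whose solution is the exponential-tilting closed form

    x_i(t) = x_i(0) exp(f_i t) / sum_j x_j(0) exp(f_j t).

Fitness values are net growth rates per day, identifiable from frequency
data only up to an additive constant: the estimates are anchored so that
the abundance-weighted mean fitness of the frequent set at the first
timepoint is zero.  An externally measured absolute population growth rate
can be added afterwards to calibrate the offset.

Fitting proceeds in two stages: a weighted least-squares initialization on
interval log-frequency changes (with per-interval offsets absorbing the
unknown mean-fitness term), followed by joint maximum-likelihood
refinement of fitness values and initial frequencies under the multinomial
sampling model of the observed counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .karyospace import Karyotype, format_karyotype

__all__ = [
    "LongitudinalCounts",
    "FrequentSet",
    "FitnessEstimate",
    "select_frequent",
    "replicator_solve",
    "qp_initialize",
    "refine_mle",
    "bootstrap_fitness",
]


class FitError(RuntimeError):
    pass


@dataclass
class LongitudinalCounts:
    """Per-timepoint karyotype count table.

    ``counts[i, k]`` is the number of cells with karyotype ``karyotypes[i]``
    sampled at time ``times[k]`` (days, strictly increasing).
    """

    karyotypes: List[Karyotype]
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need >= 2 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.counts.shape != (len(self.karyotypes), self.times.size):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.karyotypes)}, {self.times.size})"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("every timepoint must have at least one cell")

    @property
    def n_timepoints(self) -> int:
        return self.times.size

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def frequencies(self) -> np.ndarray:
        return self.counts / self.totals[None, :]

    def subset(self, karyotypes: Sequence[Karyotype]) -> "LongitudinalCounts":
        index = {k: i for i, k in enumerate(self.karyotypes)}
        rows = [index[k] for k in karyotypes]
        return LongitudinalCounts(list(karyotypes), self.times.copy(), self.counts[rows])


@dataclass
class FrequentSet:
    members: List[Karyotype]
    threshold: float

    def __post_init__(self) -> None:
        if not self.members:
            raise FitError("frequent set is empty")


@dataclass
class FitnessEstimate:
    """One karyotype's net growth rate (per day, relative to the anchor).

    ``stage`` records provenance: estimated directly from frequency
    dynamics (``frequent``), via mutational flux (``neighbor``), or by
    landscape interpolation (``interpolated``).
    """

    karyotype: Karyotype
    f: float
    stage: str = "frequent"
    se: Optional[float] = None
    parents: Tuple[Karyotype, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isfinite(self.f):
            raise ValueError(f"non-finite fitness for {format_karyotype(self.karyotype)}")
        if self.stage not in ("frequent", "neighbor", "interpolated"):
            raise ValueError(f"unknown stage {self.stage!r}")


def select_frequent(
    data: LongitudinalCounts,
    threshold: float = 5,
    as_frequency: bool = False,
) -> FrequentSet:
    """Karyotypes whose count (or frequency) reaches ``threshold`` in at
    least one timepoint."""
    values = data.frequencies() if as_frequency else data.counts
    keep = np.any(values >= threshold, axis=1)
    members = [k for k, m in zip(data.karyotypes, keep) if m]
    if not members:
        raise FitError(f"threshold {threshold} excludes every observed karyotype")
    return FrequentSet(members, threshold)


def replicator_solve(
    f: np.ndarray, x0: np.ndarray, times: np.ndarray, strict: bool = False
) -> np.ndarray:
    """Closed-form replicator frequencies; shape (len(x0), len(times)).

    ``times`` are measured from the instant at which ``x0`` holds.  Uses a
    log-sum-exp normalization, so large ``f * t`` products are safe.
    """
    f = np.asarray(f, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(x0 < 0):
        raise ValueError("x0 must be non-negative")
    s = x0.sum()
    if not np.isclose(s, 1.0):
        if strict:
            raise ValueError(f"x0 sums to {s}, expected 1")
        warnings.warn(f"normalizing x0 (sum was {s:.6g})", stacklevel=2)
    with np.errstate(divide="ignore"):
        logx0 = np.where(x0 > 0, np.log(np.maximum(x0 / s, 1e-300)), -np.inf)
    logits = logx0[:, None] + f[:, None] * times[None, :]
    m = logits.max(axis=0, keepdims=True)
    w = np.exp(logits - m)
    return w / w.sum(axis=0, keepdims=True)


def _anchor_shift(f: np.ndarray, x_first: np.ndarray) -> np.ndarray:
    """Shift so the abundance-weighted mean fitness at the first timepoint is 0."""
    w = x_first / x_first.sum()
    return f - float(w @ f)


def qp_initialize(
    data: LongitudinalCounts,
    S: FrequentSet,
    pseudo_count: float = 0.5,
) -> np.ndarray:
    """Least-squares initialization of frequent-karyotype fitness.

    For clone i over interval k the replicator solution gives
    ``d log x_i = (f_i - fbar_k) dt``; the unknown interval means are
    absorbed into free offsets ``c_k``, and the residuals are weighted by
    the harmonic mean of the adjacent counts (intervals where the clone is
    well-sampled at both ends dominate).  Zero counts get a pseudo-count
    before the log.  Returns fitness per day, anchored.
    """
    sub = data.subset(S.members)
    K, T = sub.counts.shape
    if T < 2:
        raise FitError("need >= 2 timepoints for initialization")
    counts = sub.counts.astype(float)
    totals = sub.totals.astype(float)
    freq = (counts + pseudo_count) / (totals + pseudo_count * K)[None, :]
    logx = np.log(freq)
    dt = np.diff(sub.times)

    # unknowns: f (K) then c (T-1)
    rows_a: List[np.ndarray] = []
    rows_y: List[float] = []
    for i in range(K):
        for k in range(T - 1):
            a, b = counts[i, k], counts[i, k + 1]
            w = 2.0 * a * b / (a + b) if (a + b) > 0 else 0.0
            if w <= 0:
                w = pseudo_count  # keep the system well-posed for all-zero intervals
            sw = np.sqrt(w)
            row = np.zeros(K + T - 1)
            row[i] = dt[k] * sw
            row[K + k] = -dt[k] * sw
            rows_a.append(row)
            rows_y.append((logx[i, k + 1] - logx[i, k]) * sw)
    A = np.vstack(rows_a)
    y = np.asarray(rows_y)
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    f = sol[:K]
    return _anchor_shift(f, np.maximum(counts[:, 0], pseudo_count))


def _multinomial_loglik(f: np.ndarray, logits0: np.ndarray, sub: LongitudinalCounts) -> float:
    x0 = np.exp(logits0 - logits0.max())
    x0 /= x0.sum()
    t = sub.times - sub.times[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        xhat = replicator_solve(f, x0, t)
    xhat = np.maximum(xhat, 1e-12)
    return float(np.sum(sub.counts * np.log(xhat)))


def refine_mle(
    data: LongitudinalCounts,
    S: FrequentSet,
    f_init: Optional[np.ndarray] = None,
    fit_x0: bool = True,
    tol: float = 1e-8,
) -> List[FitnessEstimate]:
    """Multinomial maximum-likelihood refinement of frequent fitness.

    Jointly optimizes fitness values and (optionally) the initial
    frequency vector on the simplex, starting from the least-squares
    initialization.  The likelihood is invariant to an additive shift of
    all f, so the optimum is re-anchored afterwards.  Non-convergence is
    flagged with a warning, never silent.
    """
    sub = data.subset(S.members)
    K = len(S.members)
    if f_init is None:
        f_init = qp_initialize(data, S)
    f_init = np.asarray(f_init, dtype=float)
    if not np.all(np.isfinite(f_init)):
        raise FitError("f_init must be finite")

    if K == 1:
        warnings.warn(
            "single-clone data: fitness unidentifiable from frequencies; "
            "returning the anchor value 0",
            stacklevel=2,
        )
        return [FitnessEstimate(S.members[0], 0.0, stage="frequent")]

    freq0 = (sub.counts[:, 0] + 0.5) / (sub.counts[:, 0].sum() + 0.5 * K)
    logits0_init = np.log(freq0)

    if fit_x0:
        def negll(theta: np.ndarray) -> float:
            return -_multinomial_loglik(theta[:K], theta[K:], sub)

        theta0 = np.concatenate([f_init, logits0_init])
    else:
        def negll(theta: np.ndarray) -> float:
            return -_multinomial_loglik(theta, logits0_init, sub)

        theta0 = f_init.copy()

    res = optimize.minimize(negll, theta0, method="L-BFGS-B", options={"ftol": tol, "maxiter": 2000})
    ll_init, ll_opt = -negll(theta0), -res.fun
    if ll_opt < ll_init - 1e-9:  # optimizer must not degrade the start
        res.x, ll_opt = theta0, ll_init
    if not res.success:
        warnings.warn(f"fitness MLE did not fully converge: {res.message}", stacklevel=2)
    f = _anchor_shift(res.x[:K], freq0 * sub.counts[:, 0].sum() + 0.5)
    return [FitnessEstimate(k, float(fi), stage="frequent") for k, fi in zip(S.members, f)]


def bootstrap_fitness(
    data: LongitudinalCounts,
    S: FrequentSet,
    B: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Multinomial bootstrap over cells within each timepoint.

    Returns per-karyotype SE and ``(alpha/2, 1-alpha/2)`` percentile
    intervals of the anchored fitness; reproducible for a fixed seed.
    """
    if B < 1:
        raise FitError(f"need B >= 1 bootstrap replicates, got {B}")
    rng = np.random.default_rng(seed)
    freqs = data.frequencies()
    totals = data.totals
    boots = np.empty((B, len(S.members)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(B):
            counts_b = np.column_stack(
                [rng.multinomial(int(totals[k]), freqs[:, k]) for k in range(data.n_timepoints)]
            )
            # keep timepoints valid: resampling cannot empty a column (totals>0)
            data_b = LongitudinalCounts(list(data.karyotypes), data.times.copy(), counts_b)
            S_b = FrequentSet(list(S.members), S.threshold)
            ests = refine_mle(data_b, S_b)
            boots[b] = [e.f for e in ests]
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return {
        "karyotypes": list(S.members),
        "se": boots.std(axis=0, ddof=1) if B > 1 else np.full(len(S.members), np.nan),
        "ci_low": lo,
        "ci_high": hi,
        "replicates": boots,
    }
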
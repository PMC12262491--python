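"""Gaussian-process (Kriging) interpolation of fitness over the charted region.

The frequent-karyotype and neighbor fitness estimates serve as anchor
points for universal Kriging with a constant mean and a Matérn
covariance with smoothness nu = 3/2,

    C(d) = sigma^2 (1 + sqrt(3) d / rho) exp(-sqrt(3) d / rho) + tau^2 1{d=0},

over Euclidean distance between integer copy-number vectors (Manhattan
available by configuration).  Predictions are deliberately refused
outside the charted region — the set of viable karyotypes within a fixed
number of missegregations (default 2) of the frequent set — because the
anchors carry no information further out.

Model quality is summarized by the CV score, a leave-one-out R^2 over the
frequent-stage anchors: each frequent anchor is dropped *together with
the neighbor anchors derived solely from it* (their fits are functions of
the parent's estimate, so leaving them in would leak), the landscape is
refit, and the left-out fitness is predicted.  A score near 1 means the
local landscape is internally consistent; scores at or below 0 flag fits
no better than predicting the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import linalg, optimize
from scipy.spatial import distance

from .freqfit import FitnessEstimate, FrequentSet, LongitudinalCounts, refine_mle
from .karyospace import Karyotype, TransitionKernel, charted_region, one_step_neighbors

__all__ = [
    "FitnessLandscape",
    "matern32",
    "fit_kriging",
    "cv_score",
    "bootstrap_landscape",
    "delta_f_profile",
    "fit_pipeline",
]


class RegionError(ValueError):
    """Prediction requested outside the charted region."""


def matern32(d: np.ndarray, sigma2: float, rho: float) -> np.ndarray:
    """Matérn covariance with smoothness 3/2 as a function of distance."""
    if sigma2 <= 0 or rho <= 0:
        raise ValueError(f"hyperparameters must be positive (sigma2={sigma2}, rho={rho})")
    d = np.asarray(d, dtype=float)
    s = np.sqrt(3.0) * d / rho
    return sigma2 * (1.0 + s) * np.exp(-s)


def _pairwise_dist(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return distance.cdist(A, B, "euclidean")
    if metric == "manhattan":
        return distance.cdist(A, B, "cityblock")
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class FitnessLandscape:
    """Fitted local fitness landscape.

    Holds the anchor estimates, Matérn hyperparameters, the Cholesky
    factor of ``K + tau^2 I`` used for prediction, and the charted region
    inside which prediction is defined.
    """

    anchors: List[FitnessEstimate]
    sigma2: float
    rho: float
    tau2: float
    region: Set[Karyotype]
    metric: str = "euclidean"
    cv: Optional[float] = None
    _X: np.ndarray = field(default=None, repr=False)
    _cho: Tuple[np.ndarray, bool] = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)
    _mu: float = field(default=0.0, repr=False)

    def predict(self, k: Sequence[int], return_sd: bool = False):
        """Kriging posterior mean (and SD) at karyotype ``k``; refuses
        out-of-region queries."""
        kt = tuple(int(x) for x in k)
        if kt not in self.region:
            raise RegionError(f"karyotype {kt} is outside the charted region")
        x = np.asarray(kt, dtype=float)[None, :]
        kstar = matern32(_pairwise_dist(x, self._X, self.metric)[0], self.sigma2, self.rho)
        mean = float(self._mu + kstar @ self._alpha)
        if not return_sd:
            return mean
        v = linalg.cho_solve(self._cho, kstar)
        var = self.sigma2 + self.tau2 - float(kstar @ v)
        return mean, float(np.sqrt(max(var, 0.0)))

    def predict_many(self, ks: Sequence[Sequence[int]]) -> np.ndarray:
        for k in ks:
            if tuple(int(x) for x in k) not in self.region:
                raise RegionError(f"karyotype {tuple(k)} is outside the charted region")
        X = np.asarray(ks, dtype=float)
        Kst = matern32(_pairwise_dist(X, self._X, self.metric), self.sigma2, self.rho)
        return self._mu + Kst @ self._alpha

    def lut(self) -> Dict[Karyotype, float]:
        """Flat karyotype -> fitness lookup table over the whole region."""
        ks = sorted(self.region)
        vals = self.predict_many(ks)
        return dict(zip(ks, (float(v) for v in vals)))


def _neg_profile_loglik(
    log_params: np.ndarray, D: np.ndarray, y: np.ndarray
) -> float:
    sigma2, rho, tau2 = np.exp(log_params)
    n = y.size
    K = matern32(D, sigma2, rho) + tau2 * np.eye(n)
    try:
        cho = linalg.cho_factor(K, lower=True)
    except linalg.LinAlgError:
        return 1e12
    one = np.ones(n)
    Ki_y = linalg.cho_solve(cho, y)
    Ki_1 = linalg.cho_solve(cho, one)
    mu = float(one @ Ki_y) / float(one @ Ki_1)
    r = y - mu
    Ki_r = linalg.cho_solve(cho, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return 0.5 * (float(r @ Ki_r) + logdet + n * np.log(2 * np.pi))


def fit_kriging(
    anchors: Sequence[FitnessEstimate],
    region: Optional[Set[Karyotype]] = None,
    metric: str = "euclidean",
    hyperparams: Optional[Tuple[float, float, float]] = None,
    n_starts: int = 5,
    seed: int = 0,
    radius: int = 2,
    max_copy: int = 8,
    hyper_subsample: int = 400,
) -> FitnessLandscape:
    """Fit universal Kriging (constant mean) to the anchor estimates.

    Hyperparameters ``(sigma2, rho, tau2)`` are estimated by profile
    maximum likelihood with ``n_starts`` seeded multi-starts (ties broken
    by lowest rho), or fixed if given explicitly.  With ``tau2 = 0`` the
    predictor interpolates the anchors exactly.
    """
    anchors = list(anchors)
    if len(anchors) < 3:
        raise ValueError(f"need >= 3 anchors, got {len(anchors)}")
    seen: Dict[Karyotype, float] = {}
    dups = []
    for a in anchors:
        if a.karyotype in seen and not np.isclose(seen[a.karyotype], a.f):
            dups.append(a.karyotype)
        seen[a.karyotype] = a.f
    if dups:
        raise ValueError(f"duplicate anchors with conflicting fitness: {dups}")

    X = np.asarray([a.karyotype for a in anchors], dtype=float)
    y = np.asarray([a.f for a in anchors], dtype=float)
    D = _pairwise_dist(X, X, metric)

    if hyperparams is not None:
        sigma2, rho, tau2 = hyperparams
    else:
        rng = np.random.default_rng(seed)
        # profile likelihood on a seeded subsample when the anchor set is
        # large; the full system is solved once with the chosen values
        if len(y) > hyper_subsample:
            sub = rng.choice(len(y), hyper_subsample, replace=False)
            D_h, y_h = D[np.ix_(sub, sub)], y[sub]
        else:
            D_h, y_h = D, y
        y_var = max(float(np.var(y_h)), 1e-10)
        off = D_h[D_h > 0]
        d_med = float(np.median(off)) if off.size else 1.0
        best: Tuple[float, float, Tuple[float, float, float]] = (np.inf, np.inf, (y_var, d_med, y_var * 1e-3))
        for s in range(n_starts):
            x0 = np.log(
                [
                    y_var * np.exp(rng.normal(0, 1)),
                    d_med * np.exp(rng.normal(0, 1)),
                    max(y_var * 10 ** rng.uniform(-5, -1), 1e-12),
                ]
            )
            res = optimize.minimize(
                _neg_profile_loglik, x0, args=(D_h, y_h), method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": 300},
            )
            cand = tuple(np.exp(res.x))
            key = (round(res.fun, 6), cand[1])
            if key < (round(best[0], 6), best[1]):
                best = (res.fun, cand[1], cand)
        sigma2, rho, tau2 = best[2]

    n = y.size
    K = matern32(D, sigma2, rho) + tau2 * np.eye(n)
    jitter = 0.0
    while True:
        try:
            cho = linalg.cho_factor(K + jitter * np.eye(n), lower=True)
            break
        except linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0 else jitter * 10
            if jitter > 1e-4:
                raise
    one = np.ones(n)
    Ki_y = linalg.cho_solve(cho, y)
    Ki_1 = linalg.cho_solve(cho, one)
    mu = float(one @ Ki_y) / float(one @ Ki_1)
    alpha = linalg.cho_solve(cho, y - mu)

    if region is None:
        frequent = [a.karyotype for a in anchors if a.stage == "frequent"]
        base = frequent if frequent else [a.karyotype for a in anchors]
        region = charted_region(base, radius=radius, max_copy=max_copy)
        region |= {a.karyotype for a in anchors}

    return FitnessLandscape(
        anchors=anchors, sigma2=float(sigma2), rho=float(rho), tau2=float(tau2),
        region=set(region), metric=metric, _X=X, _cho=cho, _alpha=alpha, _mu=mu,
    )


def predict(landscape: FitnessLandscape, k: Sequence[int], return_sd: bool = False):
    """Module-level alias for :meth:`FitnessLandscape.predict`."""
    return landscape.predict(k, return_sd=return_sd)


def cv_score(
    anchors: Sequence[FitnessEstimate],
    metric: str = "euclidean",
    hyperparams: Optional[Tuple[float, float, float]] = None,
    seed: int = 0,
    return_pairs: bool = False,
):
    """Leave-one-out R^2 of the landscape on its frequent anchors.

    For each frequent-stage anchor s, the model is refit without s and
    without neighbor anchors whose *only* frequent parent is s, and f(s)
    is predicted.  Score = 1 - SS_res / SS_tot over the (predicted,
    estimated) pairs; 1 is perfect, values <= 0 mean no better than the
    mean.  Hyperparameters are estimated once on the full anchor set and
    held fixed across folds.
    """
    anchors = list(anchors)
    freq = [a for a in anchors if a.stage == "frequent"]
    if len(freq) < 3:
        raise ValueError(f"CV score undefined with {len(freq)} frequent anchors (< 3)")

    if hyperparams is None:
        full = fit_kriging(anchors, metric=metric, seed=seed)
        hyperparams = (full.sigma2, full.rho, full.tau2)

    preds, obs = [], []
    for s in freq:
        keep = []
        for a in anchors:
            if a.karyotype == s.karyotype and a.stage == "frequent":
                continue
            if a.stage == "neighbor" and a.parents and set(a.parents) == {s.karyotype}:
                continue
            keep.append(a)
        if len(keep) < 3:
            continue
        sub = fit_kriging(keep, metric=metric, hyperparams=hyperparams,
                          region={s.karyotype} | {a.karyotype for a in keep})
        preds.append(sub.predict(s.karyotype))
        obs.append(s.f)
    preds_a, obs_a = np.asarray(preds), np.asarray(obs)
    ss_res = float(np.sum((obs_a - preds_a) ** 2))
    ss_tot = float(np.sum((obs_a - obs_a.mean()) ** 2))
    score = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    if return_pairs:
        r = float(np.corrcoef(preds_a, obs_a)[0, 1]) if preds_a.size > 2 else np.nan
        return score, {"predicted": preds_a, "estimated": obs_a, "pearson_r": r}
    return score


def delta_f_profile(
    landscape: FitnessLandscape, k: Sequence[int]
) -> np.ndarray:
    """44-vector of single-missegregation fitness effects at karyotype k.

    Ordered chr1-loss, chr1-gain, chr2-loss, ..., chr22-gain; entries whose
    neighbor falls outside the charted region (or below 1 copy) are NaN.
    """
    kt = tuple(int(x) for x in k)
    if kt not in landscape.region:
        raise RegionError(f"karyotype {kt} is outside the charted region")
    f0 = landscape.predict(kt)
    out = np.full(2 * len(kt), np.nan)
    for c in range(len(kt)):
        for j, step in enumerate((-1, +1)):
            nb = kt[:c] + (kt[c] + step,) + kt[c + 1 :]
            if nb[c] >= 0 and nb in landscape.region:
                out[2 * c + j] = landscape.predict(nb) - f0
    return out


def fit_pipeline(
    data: LongitudinalCounts,
    kernel: TransitionKernel,
    threshold: float = 5,
    metric: str = "euclidean",
    radius: int = 2,
    seed: int = 0,
    compute_cv: bool = True,
) -> FitnessLandscape:
    """Full inference pipeline: frequent fit -> neighbor fit -> Kriging.

    Convenience wrapper used by forecasting, the bootstrap, and the CLI.
    """
    from .freqfit import select_frequent
    from .nnfit import estimate_prior, fit_all_neighbors

    S = select_frequent(data, threshold=threshold)
    freq_est = refine_mle(data, S)
    prior = estimate_prior(freq_est)
    nb_est = fit_all_neighbors(data, S, freq_est, kernel, prior)
    anchors = freq_est + nb_est
    land = fit_kriging(anchors, metric=metric, seed=seed, radius=radius,
                       max_copy=kernel.max_copy)
    if compute_cv:
        try:
            land.cv = cv_score(anchors, metric=metric,
                               hyperparams=(land.sigma2, land.rho, land.tau2))
        except ValueError:
            land.cv = None
    return land


def bootstrap_landscape(
    data: LongitudinalCounts,
    kernel: TransitionKernel,
    B: int = 50,
    seed: int = 0,
    threshold: float = 5,
    karyotypes: Optional[Sequence[Karyotype]] = None,
    alpha: float = 0.05,
) -> dict:
    """Percentile prediction intervals from refitting the whole pipeline on
    cell-resampled data (multinomial within each timepoint)."""
    if B < 1:
        raise ValueError(f"need B >= 1, got {B}")
    rng = np.random.default_rng(seed)
    freqs = data.frequencies()
    totals = data.totals
    base = fit_pipeline(data, kernel, threshold=threshold, compute_cv=False)
    if karyotypes is None:
        karyotypes = sorted(base.region)
    karyotypes = [tuple(int(x) for x in k) for k in karyotypes]
    samples = np.full((B, len(karyotypes)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(B):
            counts_b = np.column_stack(
                [rng.multinomial(int(totals[t]), freqs[:, t]) for t in range(data.n_timepoints)]
            )
            data_b = LongitudinalCounts(list(data.karyotypes), data.times.copy(), counts_b)
            try:
                land_b = fit_pipeline(data_b, kernel, threshold=threshold, compute_cv=False)
            except Exception:
                continue
            for j, k in enumerate(karyotypes):
                if k in land_b.region:
                    samples[b, j] = land_b.predict(k)
    lo = np.nanpercentile(samples, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(samples, 100 * (1 - alpha / 2), axis=0)
    return {"karyotypes": karyotypes, "low": lo, "high": hi, "samples": samples}
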
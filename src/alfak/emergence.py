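"""Prediction of novel karyotype emergence.

Given a landscape trained on data up to a sample S0, each in-region
karyotype absent from S0 is a candidate for emergence in the next sample
St.  Candidates are described by distance features d1..d5 — the
abundance-weighted fraction of the S0 population exactly 1..5
missegregations away — plus the interpolated fitness f, and the
probability of emergence is modeled with binomial logistic regression

    logit P(novel) = b0 + bf * f + sum_i b_i * d_i,

with per-coefficient Wald z-tests.  Features must never see data past
S0 (no look-ahead); the landscape passed in must therefore be trained on
the history ending at S0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .evaluation import PopulationState
from .karyospace import Karyotype, manhattan_distance
from .landscape import FitnessLandscape

__all__ = [
    "EmergenceDataset",
    "build_emergence_features",
    "fit_emergence_model",
    "emergence_screen",
]

MAX_FEATURE_DISTANCE = 5
FEATURES = ["f"] + [f"d{i}" for i in range(1, MAX_FEATURE_DISTANCE + 1)]


@dataclass
class EmergenceDataset:
    """One row per candidate karyotype: d1..d5, fitness f, emerged label."""

    table: pd.DataFrame  # columns: karyotype, d1..d5, f, emerged

    def __post_init__(self) -> None:
        for c in FEATURES + ["emerged"]:
            if c not in self.table.columns:
                raise ValueError(f"missing column {c}")
        d_cols = self.table[[f"d{i}" for i in range(1, 6)]].to_numpy()
        if np.any(d_cols < 0) or np.any(d_cols.sum(axis=1) > 1 + 1e-9):
            raise ValueError("distance fractions must be in [0,1] and sum to <= 1")


def build_emergence_features(
    landscape: FitnessLandscape,
    s0: PopulationState,
    st: PopulationState,
    train_end_time: Optional[float] = None,
    s0_time: Optional[float] = None,
    weighted: bool = True,
) -> EmergenceDataset:
    """Assemble the emergence design matrix.

    Candidates are in-region karyotypes absent from S0.  ``d_i`` is the
    fraction of the S0 population (abundance-weighted by default;
    ``weighted=False`` counts distinct karyotypes) exactly i
    missegregations from the candidate; the label marks presence in St.
    If both times are supplied, training data extending past S0 raises a
    contract error (look-ahead guard).
    """
    if not st.freqs:
        raise ValueError("St sample is empty")
    if train_end_time is not None and s0_time is not None and train_end_time > s0_time:
        raise ValueError(
            f"look-ahead: landscape trained to t={train_end_time} but S0 is at t={s0_time}"
        )
    s0_ks = list(s0.freqs)
    if weighted:
        s0_w = np.array([s0.freqs[k] for k in s0_ks])
    else:
        s0_w = np.full(len(s0_ks), 1.0 / len(s0_ks))
    rows: List[dict] = []
    s0_set = set(s0_ks)
    for k in sorted(landscape.region):
        if k in s0_set:
            continue
        d = np.array([manhattan_distance(k, q) for q in s0_ks])
        feats = {
            f"d{i}": float(s0_w[d == i].sum()) for i in range(1, MAX_FEATURE_DISTANCE + 1)
        }
        rows.append(
            {
                "karyotype": k,
                **feats,
                "f": landscape.predict(k),
                "emerged": int(k in st.freqs),
            }
        )
    return EmergenceDataset(pd.DataFrame(rows))


def fit_emergence_model(
    ds: EmergenceDataset, l2_fallback: float = 1.0
) -> pd.DataFrame:
    """Logistic regression of emergence on fitness and distance features.

    Returns a coefficient table (term, coef, se, wald_z, wald_p,
    significant at P < 0.05, penalized flag).  Constant features are
    dropped (their coefficient reported as NaN).  On perfect separation
    or non-convergence the fit falls back to a small L2 penalty and is
    flagged ``penalized``.
    """
    ycol = ds.table["emerged"].to_numpy()
    if len(np.unique(ycol)) < 2:
        raise ValueError("both emerged and non-emerged labels are required")
    usable = [c for c in FEATURES if ds.table[c].nunique() > 1]
    X = sm.add_constant(ds.table[usable].to_numpy())
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(ycol, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False) or np.any(
                ~np.isfinite(fit.bse)
            ):
                raise np.linalg.LinAlgError
        except Exception:
            penalized = True
            fit = _l2_logit(ycol, X, l2_fallback)
    coefs = np.asarray(fit.params)
    ses = np.asarray(fit.bse)
    z = coefs / ses
    from scipy import stats as _st

    p = 2 * _st.norm.sf(np.abs(z))
    terms = ["const"] + usable
    rows = []
    for i, t in enumerate(terms):
        rows.append(
            {
                "term": t,
                "coef": coefs[i],
                "se": ses[i],
                "wald_z": z[i],
                "wald_p": p[i],
                "significant": bool(p[i] < 0.05),
                "penalized": penalized,
            }
        )
    for c in FEATURES:
        if c not in usable:
            rows.append(
                {
                    "term": c, "coef": np.nan, "se": np.nan, "wald_z": np.nan,
                    "wald_p": np.nan, "significant": False, "penalized": penalized,
                }
            )
    return pd.DataFrame(rows)


class _L2Fit:
    def __init__(self, params: np.ndarray, bse: np.ndarray):
        self.params = params
        self.bse = bse


def _l2_logit(y: np.ndarray, X: np.ndarray, alpha: float) -> _L2Fit:
    """Ridge-penalized logistic fallback for separated designs (penalty on
    all terms except the intercept); SEs from the penalized Hessian."""
    from scipy import optimize as _opt

    n, d = X.shape
    pen = np.ones(d) * alpha
    pen[0] = 0.0

    def negll(b: np.ndarray) -> float:
        eta = X @ b
        return float(np.sum(np.logaddexp(0, eta)) - y @ eta + 0.5 * np.sum(pen * b**2))

    def grad(b: np.ndarray) -> np.ndarray:
        mu = 1.0 / (1.0 + np.exp(-(X @ b)))
        return X.T @ (mu - y) + pen * b

    res = _opt.minimize(negll, np.zeros(d), jac=grad, method="L-BFGS-B")
    mu = 1.0 / (1.0 + np.exp(-(X @ res.x)))
    W = mu * (1 - mu)
    H = X.T @ (X * W[:, None]) + np.diag(pen)
    cov = np.linalg.inv(H)
    return _L2Fit(res.x, np.sqrt(np.diag(cov)))


def emergence_screen(
    lineage_fits: Sequence[EmergenceDataset],
) -> pd.DataFrame:
    """Per-lineage significance summary across fitted emergence models.

    One row per lineage with a significance flag for each predictor plus
    the most significant (lowest Wald p) predictor.  Lineage retention
    (positive CV score, >= 3 passages, one fit per terminal passage) is
    the caller's responsibility when assembling ``lineage_fits``.
    """
    rows = []
    for i, ds in enumerate(lineage_fits):
        try:
            tab = fit_emergence_model(ds).set_index("term")
        except ValueError:
            continue
        feats = [t for t in FEATURES if t in tab.index and np.isfinite(tab.loc[t, "wald_p"])]
        row: Dict[str, object] = {"lineage": i}
        for t in FEATURES:
            row[f"sig_{t}"] = bool(tab.loc[t, "significant"]) if t in tab.index else False
        row["most_significant"] = (
            min(feats, key=lambda t: tab.loc[t, "wald_p"]) if feats else None
        )
        rows.append(row)
    cols = ["lineage"] + [f"sig_{t}" for t in FEATURES] + ["most_significant"]
    return pd.DataFrame(rows, columns=cols)
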
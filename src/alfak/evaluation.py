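"""Forecast-evaluation metrics and landscape-topology statistics.

Includes: the angle metric between population mean-karyotype change
vectors with its Monte-Carlo random-direction null; exact 1-Wasserstein
distance between karyotype frequency distributions (Manhattan ground
metric, transportation LP); the static no-evolution baseline comparison;
the abundance-overlap coefficient; randomized selection of
non-overlapping passage trajectories for bootstrap independence;
Fisher-z profile correlations; whole-genome-doubling (WGD)
classification; exponential-saturation fits of aneuploidy accumulation;
and a permutation Kolmogorov-Smirnov test on per-fit mean fitness
effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import optimize, stats
from scipy.optimize import linprog

from .karyospace import Karyotype, manhattan_distance

__all__ = [
    "PopulationState",
    "angle_metric",
    "angle_null_test",
    "random_angle_sample",
    "wasserstein_distance",
    "baseline_comparison",
    "overlap_coefficient",
    "select_nonoverlapping_trajectories",
    "profile_correlation",
    "classify_wgd",
    "fit_saturation",
    "permutation_ks",
]


@dataclass
class PopulationState:
    """Karyotype frequency distribution at one timepoint."""

    freqs: Dict[Karyotype, float]

    def __post_init__(self) -> None:
        tot = sum(self.freqs.values())
        if tot <= 0:
            raise ValueError("empty population state")
        if not math.isclose(tot, 1.0, rel_tol=1e-9):
            self.freqs = {k: v / tot for k, v in self.freqs.items()}

    @classmethod
    def from_counts(cls, counts: Dict[Karyotype, int]) -> "PopulationState":
        tot = sum(counts.values())
        return cls({k: v / tot for k, v in counts.items() if v > 0})

    def mean_karyotype(self) -> np.ndarray:
        ks = list(self.freqs)
        X = np.asarray(ks, dtype=float)
        w = np.asarray([self.freqs[k] for k in ks])
        return w @ X


def angle_metric(observed_change: np.ndarray, predicted_change: np.ndarray) -> float:
    """Angle in degrees between two karyotype-space change vectors, in
    [0, 180]; invariant to positive rescaling of either vector."""
    a = np.asarray(observed_change, dtype=float)
    b = np.asarray(predicted_change, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for a zero-norm change vector")
    c = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def random_angle_sample(
    n: int, rng: np.random.Generator, dim: int = 22
) -> np.ndarray:
    """Angles between independent uniform random unit vectors in ``dim``
    dimensions (sampled as normalized Gaussian vectors)."""
    a = rng.normal(size=(n, dim))
    b = rng.normal(size=(n, dim))
    cos = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def angle_null_test(
    per_unit_angles: Sequence[Sequence[float]],
    n_iter: int = 10_000,
    seed: int = 0,
    sidedness: str = "one",
    dim: int = 22,
) -> Dict[str, float]:
    """Monte-Carlo test of directional consistency.

    The statistic T is the median of per-unit median angles.  The null
    resamples angles between independent random unit vectors in ``dim``
    dimensions, matched to each unit's sample size.  One-sided p is the
    fraction of null T* <= T (smaller angles = more aligned than chance);
    two-sided doubles the smaller tail.
    """
    if not per_unit_angles or any(len(u) == 0 for u in per_unit_angles):
        raise ValueError("every unit must contribute at least one angle")
    rng = np.random.default_rng(seed)
    T = float(np.median([np.median(u) for u in per_unit_angles]))
    sizes = [len(u) for u in per_unit_angles]
    null = np.empty(n_iter)
    for it in range(n_iter):
        meds = [np.median(random_angle_sample(m, rng, dim)) for m in sizes]
        null[it] = np.median(meds)
    p_low = float((1 + np.sum(null <= T)) / (1 + n_iter))
    p_high = float((1 + np.sum(null >= T)) / (1 + n_iter))
    if sidedness == "one":
        p = p_low
    elif sidedness == "two":
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        raise ValueError("sidedness must be 'one' or 'two'")
    return {"T": T, "p": p, "null_median": float(np.median(null))}


def wasserstein_distance(a: PopulationState, b: PopulationState) -> float:
    """Exact 1-Wasserstein distance with Manhattan ground metric.

    Solved as a transportation linear program on the union support
    (HiGHS); supports in this setting are small (tens to hundreds of
    karyotypes).
    """
    support = sorted(set(a.freqs) | set(b.freqs))
    wa = np.array([a.freqs.get(k, 0.0) for k in support])
    wb = np.array([b.freqs.get(k, 0.0) for k in support])
    if np.allclose(wa, wb):
        return 0.0
    n = len(support)
    C = np.array(
        [[manhattan_distance(x, y) for y in support] for x in support], dtype=float
    )
    # transport plan T >= 0, row sums wa, col sums wb
    A_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros(n * n)
        row[i * n : (i + 1) * n] = 1.0
        A_eq.append(row)
        b_eq.append(wa[i])
    for j in range(n):
        col = np.zeros(n * n)
        col[j::n] = 1.0
        A_eq.append(col)
        b_eq.append(wb[j])
    res = linprog(C.ravel(), A_eq=np.vstack(A_eq), b_eq=np.asarray(b_eq),
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def baseline_comparison(
    predicted: PopulationState,
    observed_future: PopulationState,
    last_observed: PopulationState,
    metric=wasserstein_distance,
) -> Dict[str, float]:
    """Does the forecast beat the static no-evolution baseline?

    The baseline predicts the future state to equal the last observed
    state.  For distance-like metrics, the forecast wins iff its distance
    to the observed future is *strictly* smaller; ties lose.
    """
    d_pred = metric(predicted, observed_future)
    d_base = metric(last_observed, observed_future)
    return {
        "predicted": float(d_pred),
        "baseline": float(d_base),
        "beats_baseline": bool(d_pred < d_base),
    }


def overlap_coefficient(a: PopulationState, b: PopulationState) -> float:
    """Abundance overlap: sum over karyotypes of min frequency; 1 iff
    identical distributions, 0 iff disjoint supports."""
    support = set(a.freqs) | set(b.freqs)
    return float(sum(min(a.freqs.get(k, 0.0), b.freqs.get(k, 0.0)) for k in support))


def select_nonoverlapping_trajectories(
    graph: nx.DiGraph, seed: int = 0
) -> List[List]:
    """Randomized maximal set of node-disjoint root-to-leaf passage paths.

    Roots (in-degree 0) are visited in random order; from each unclaimed
    root a path is grown by repeatedly choosing a random unclaimed child
    until none remains.  No passage appears in two selected trajectories.
    """
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("lineage graph must be a DAG")
    rng = np.random.default_rng(seed)
    used: set = set()
    roots = [n for n in graph.nodes if graph.in_degree(n) == 0]
    rng.shuffle(roots)
    out: List[List] = []
    for r in roots:
        if r in used:
            continue
        path = [r]
        used.add(r)
        node = r
        while True:
            children = [c for c in graph.successors(node) if c not in used]
            if not children:
                break
            node = children[int(rng.integers(len(children)))]
            path.append(node)
            used.add(node)
        out.append(path)
    return out


def profile_correlation(
    p1: np.ndarray, p2: np.ndarray, z_cap: float = 6.0
) -> float:
    """Fisher-z transformed Pearson correlation between two fitness-effect
    profiles, over their shared non-missing entries (>= 3 required)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    mask = np.isfinite(p1) & np.isfinite(p2)
    if mask.sum() < 3:
        raise ValueError("need >= 3 shared non-missing entries")
    a, b = p1[mask], p2[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant profile")
    r = float(np.corrcoef(a, b)[0, 1])
    r = np.clip(r, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    return float(np.clip(z, -z_cap, z_cap))


def classify_wgd(k: Sequence[int], tie: str = "high") -> bool:
    """Whole-genome-doubled iff the modal chromosome copy number is >= 3.

    Modal ties are resolved to the higher mode by default (a 2/4 tie
    indicates substantial doubling); ``tie='low'`` flips that.
    """
    vals, counts = np.unique(np.asarray(k, dtype=int), return_counts=True)
    modes = vals[counts == counts.max()]
    mode = modes.max() if tie == "high" else modes.min()
    return bool(mode >= 3)


def fit_saturation(
    t: np.ndarray,
    y: np.ndarray,
    groups: Optional[np.ndarray] = None,
) -> Dict[str, object]:
    """Fit exponential saturation ``y(t) = A (1 - exp(-r t))`` with
    additive group effects on both the asymptote A and the rate r.

    With G groups the parameters are ``A0, dA_2..dA_G, r0, dr_2..dr_G``
    (group 1 is the reference).  Returns estimates, standard errors, and
    Wald z/p for the group contrasts.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if groups is None:
        groups = np.zeros(t.size, dtype=int)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    gi = np.array([labels.index(g) for g in groups])
    G = len(labels)
    for g in range(G):
        if np.sum(gi == g) < 4:
            raise ValueError("need >= 4 points per group")

    def model(theta: np.ndarray) -> np.ndarray:
        A = theta[0] + np.concatenate([[0.0], theta[1:G]])[gi]
        r = theta[G] + np.concatenate([[0.0], theta[G + 1 :]])[gi]
        return A * (1.0 - np.exp(-np.abs(r) * t))

    def resid(theta: np.ndarray) -> np.ndarray:
        return model(theta) - y

    A0 = max(float(np.max(np.abs(y))), 1e-6)
    theta0 = np.concatenate([[A0], np.zeros(G - 1), [0.1], np.zeros(G - 1)])
    sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=10_000)
    dof = max(t.size - sol.x.size, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(sol.x.size, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = sol.x / se
    p = 2 * stats.norm.sf(np.abs(z))
    names = (
        ["A"] + [f"dA[{labels[g]}]" for g in range(1, G)]
        + ["r"] + [f"dr[{labels[g]}]" for g in range(1, G)]
    )
    return {
        "params": dict(zip(names, sol.x)),
        "se": dict(zip(names, se)),
        "wald_z": dict(zip(names, z)),
        "wald_p": dict(zip(names, p)),
        "residual_se": float(np.sqrt(s2)),
        "converged": bool(sol.success),
        "groups": labels,
    }


def permutation_ks(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> Dict[str, float]:
    """Permutation Kolmogorov-Smirnov test on two sets of per-fit means.

    The KS statistic is computed on the observed split; the null permutes
    the group labels among the pooled values.  p = (1 + #{D* >= D}) /
    (1 + n_perm).  Inputs should already be one mean per landscape fit so
    that fits, not karyotypes, are the exchangeable units.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    D = float(stats.ks_2samp(a, b, method="asymp").statistic)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        Dstar = stats.ks_2samp(perm[: a.size], perm[a.size :], method="asymp").statistic
        if Dstar >= D - 1e-15:
            count += 1
    return {"D": D, "p": float((1 + count) / (1 + n_perm)), "n_perm": n_perm}
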
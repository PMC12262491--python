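"""Agent-based simulation of karyotype evolution under missegregation.

Cells carry integer karyotypes and divide stochastically at a
karyotype-specific net rate (fitness).  Time advances in fixed steps of
``dt`` days; a cell divides during a step with probability
``1 - exp(-(basal + f) dt)`` (Bernoulli thinning of the continuous-time
division process, converging to it as dt -> 0).  Divisions draw daughters
from the per-copy missegregation kernel
(:func:`alfak.karyospace.division_kernel` semantics, implemented here in
aggregated form over karyotype classes); daughters with any chromosome at
0 copies or above the viability cap are removed.  Fitness is a *net*
growth rate — explicit death is folded into f, with the basal rate
setting the absolute division tempo.

Serial passaging emulates cell culture: when the census reaches ``Nmax``
the population is binomially diluted to a fraction ``dilution`` and a
pseudo-sequencing snapshot of ``sample_size`` cells is drawn without
replacement (multivariate hypergeometric).

Ground-truth fitness comes either from a Gaussian-random-field (GRF)
landscape — a superposition of random planar sinusoids with tunable
correlation wavelength lambda — or from a lookup table exported by a
fitted landscape (forecast mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .freqfit import LongitudinalCounts
from .karyospace import (
    N_AUTOSOMES,
    Karyotype,
    TransitionKernel,
    is_viable,
)

__all__ = ["GRFLandscape", "ABMConfig", "SimResult", "run_abm", "forecast"]


@dataclass
class GRFLandscape:
    """Stationary Gaussian-random-field fitness landscape.

    ``f(k) = mean + (amplitude / sqrt(J)) * sum_j sin(w_j . k + phi_j)``
    with J random planar waves: directions uniform on the sphere, scaled
    to ``|w_j| = 2 pi / wavelength``, phases uniform on ``[0, 2 pi)``.
    Larger wavelength gives smoother terrain (correlation length grows
    with lambda); evaluation is deterministic given the seed.
    """

    wavelength: float = 1.0
    n_components: int = 100
    amplitude: float = 1.0
    mean_fitness: float = 0.0
    seed: int = 0
    n_chrom: int = N_AUTOSOMES
    _W: np.ndarray = field(default=None, repr=False)
    _phi: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.n_components < 1:
            raise ValueError("need >= 1 wave component")
        rng = np.random.default_rng(self.seed)
        dirs = rng.normal(size=(self.n_components, self.n_chrom))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        self._W = dirs * (2.0 * np.pi / self.wavelength)
        self._phi = rng.uniform(0.0, 2.0 * np.pi, size=self.n_components)

    def __call__(self, k: Sequence[int]) -> float:
        x = np.asarray(k, dtype=float)
        return float(
            self.mean_fitness
            + self.amplitude / np.sqrt(self.n_components) * np.sum(np.sin(self._W @ x + self._phi))
        )

    def evaluate_many(self, ks: np.ndarray) -> np.ndarray:
        ks = np.asarray(ks, dtype=float)
        return self.mean_fitness + self.amplitude / np.sqrt(self.n_components) * np.sin(
            ks @ self._W.T + self._phi
        ).sum(axis=1)


def grf_evaluate(grf: GRFLandscape, k: Sequence[int]) -> float:
    return grf(k)


@dataclass
class ABMConfig:
    """Simulation parameters (days as the time unit).

    ``fitness`` maps a karyotype to its net growth rate; callables (GRF)
    and dicts (LUT export) both work.  ``lut_penalty`` is the fitness
    assigned to karyotypes absent from a LUT.
    """

    p: float = 1e-3
    Nmax: int = 10_000
    dilution: float = 0.1
    dt: float = 0.1
    duration: float = 300.0
    sample_size: int = 500
    basal_rate: float = 1.0
    max_copy: int = 8
    seed: int = 0
    lut_penalty: float = -1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution < 1.0):
            raise ValueError("dilution must be in (0, 1)")
        if self.Nmax < 10:
            raise ValueError("Nmax must be >= 10")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class SimResult:
    """Population trajectory plus pseudo-sequencing snapshots."""

    passage_times: List[float]
    snapshots: List[Dict[Karyotype, int]]
    census: List[Tuple[float, int]]
    extinct: bool = False
    truth: Dict[Karyotype, float] = field(default_factory=dict)

    def to_counts(
        self, first: int = 0, last: Optional[int] = None
    ) -> LongitudinalCounts:
        """Assemble snapshots ``[first:last]`` into a LongitudinalCounts table."""
        snaps = self.snapshots[first:last]
        times = self.passage_times[first:last]
        karyotypes = sorted({k for s in snaps for k in s})
        counts = np.array(
            [[s.get(k, 0) for s in snaps] for k in karyotypes], dtype=int
        )
        return LongitudinalCounts(karyotypes, np.asarray(times, dtype=float), counts)


def _fitness_fn(source, penalty: float) -> Callable[[Karyotype], float]:
    if callable(source):
        return source
    if isinstance(source, dict):
        return lambda k: source.get(k, penalty)
    raise TypeError("fitness source must be callable or a karyotype->fitness dict")


def _divide_class(
    k: Karyotype,
    n_div: int,
    p: float,
    max_copy: int,
    rng: np.random.Generator,
    add: Callable[[Karyotype, int], None],
) -> None:
    """Process ``n_div`` divisions of karyotype class ``k``.

    Each division runs the per-copy Bernoulli missegregation kernel.  The
    overwhelmingly common no-event divisions are batched: the number of
    divisions with at least one missegregating copy is binomial with
    success probability ``1 - (1-p)^N_tot``; only those are simulated
    copy-by-copy (conditioned on >= 1 event by inverse-CDF truncation).
    """
    n_tot = sum(k)
    p_any = 1.0 - (1.0 - p) ** n_tot
    n_event = rng.binomial(n_div, p_any) if p_any > 0 else 0
    add(k, 2 * (n_div - n_event))
    if n_event == 0:
        return
    copies = np.repeat(np.arange(len(k)), k)  # one entry per chromosome copy
    for _ in range(n_event):
        # number of missegregating copies, conditional on >= 1
        u = rng.random() * p_any
        m, cdf = 0, 0.0
        pm = (1.0 - p) ** n_tot  # P(exactly 0), then recurrence for m+1
        while True:
            pm = pm * (n_tot - m) / (m + 1) * (p / (1.0 - p))
            cdf += pm
            m += 1
            if u <= cdf or m >= n_tot:
                break
        events = rng.choice(copies, size=m, replace=False)
        d1 = list(k)
        d2 = list(k)
        for c in events:
            if rng.random() < 0.5:
                d1[c] += 1
                d2[c] -= 1
            else:
                d1[c] -= 1
                d2[c] += 1
        for d in (tuple(d1), tuple(d2)):
            if is_viable(d, max_copy):
                add(d, 1)


def run_abm(
    config: ABMConfig,
    fitness_source,
    initial: Optional[Dict[Karyotype, int]] = None,
    n_passages: Optional[int] = None,
    record_truth: bool = True,
) -> SimResult:
    """Run the serial-passaging ABM.

    The default founder population is ``Nmax * dilution`` clonal diploid
    cells.  Stops after ``duration`` days, after ``n_passages`` passages
    if given, or on extinction (flagged).  Passage 0 (the founder state)
    is not recorded; snapshots are taken at each dilution event.
    """
    rng = np.random.default_rng(config.seed)
    fit = _fitness_fn(fitness_source, config.lut_penalty)
    if initial is None:
        initial = {(2,) * N_AUTOSOMES: int(config.Nmax * config.dilution)}
    pop: Dict[Karyotype, int] = {k: int(n) for k, n in initial.items() if n > 0}
    fcache: Dict[Karyotype, float] = {}

    def f_of(k: Karyotype) -> float:
        if k not in fcache:
            fcache[k] = float(fit(k))
        return fcache[k]

    passage_times: List[float] = []
    snapshots: List[Dict[Karyotype, int]] = []
    census: List[Tuple[float, int]] = [(0.0, sum(pop.values()))]
    t = 0.0
    extinct = False
    while t < config.duration - 1e-9:
        t += config.dt
        newborn: Dict[Karyotype, int] = {}

        def add(k: Karyotype, n: int) -> None:
            if n:
                newborn[k] = newborn.get(k, 0) + n

        for k in list(pop.keys()):
            n = pop[k]
            rate = config.basal_rate + f_of(k)
            if rate <= 0:
                continue
            q = 1.0 - np.exp(-rate * config.dt)
            n_div = rng.binomial(n, q)
            if n_div == 0:
                continue
            pop[k] = n - n_div
            _divide_class(k, n_div, config.p, config.max_copy, rng, add)
        for k, n in newborn.items():
            pop[k] = pop.get(k, 0) + n
        pop = {k: n for k, n in pop.items() if n > 0}
        total = sum(pop.values())
        census.append((t, total))
        if total == 0:
            extinct = True
            break
        if total >= config.Nmax:
            ks = list(pop.keys())
            ns = np.array([pop[k] for k in ks])
            kept = rng.binomial(ns, config.dilution)
            pop = {k: int(n) for k, n in zip(ks, kept) if n > 0}
            if not pop:
                extinct = True
                break
            # pseudo-sequencing sample before carrying the diluted flask on
            ks2 = list(pop.keys())
            ns2 = np.array([pop[k] for k in ks2])
            m = min(config.sample_size, int(ns2.sum()))
            drawn = rng.multivariate_hypergeometric(ns2, m)
            snapshots.append({k: int(c) for k, c in zip(ks2, drawn) if c > 0})
            passage_times.append(t)
            census.append((t, int(ns2.sum())))
            if n_passages is not None and len(passage_times) >= n_passages:
                break

    truth: Dict[Karyotype, float] = {}
    if record_truth:
        observed = {k for s in snapshots for k in s}
        truth = {k: f_of(k) for k in observed}
    if extinct:
        warnings.warn("population went extinct; truncated result", stacklevel=2)
    return SimResult(passage_times, snapshots, census, extinct=extinct, truth=truth)


def forecast(
    landscape,
    initial_snapshot: Dict[Karyotype, int],
    config: ABMConfig,
    horizons: Sequence[float],
    n_replicates: int = 20,
) -> Dict[float, Dict[Karyotype, float]]:
    """Forecast future karyotype distributions from a fitted landscape.

    Seeds the ABM from the last observed snapshot (scaled up to the
    post-dilution census), runs ``n_replicates`` replicate simulations
    with the landscape's LUT as fitness source, and returns the
    replicate-averaged frequency distribution at each requested horizon
    (days after the initial snapshot).  Horizon 0 returns the initial
    sample distribution itself.
    """
    lut = landscape.lut()
    in_region = [k for k in initial_snapshot if k in lut]
    if not in_region:
        raise ValueError("no initial karyotype falls inside the charted region")

    total0 = sum(initial_snapshot.values())
    scale = max(1, int(config.Nmax * config.dilution) // max(total0, 1))
    seed_pop = {k: n * scale for k, n in initial_snapshot.items()}

    out: Dict[float, Dict[Karyotype, float]] = {}
    max_h = max(horizons)
    for h in horizons:
        if h == 0:
            out[0.0] = {k: n / total0 for k, n in initial_snapshot.items()}
    agg: Dict[float, Dict[Karyotype, float]] = {float(h): {} for h in horizons if h > 0}
    for r in range(n_replicates):
        cfg = ABMConfig(**{**config.__dict__, "seed": config.seed + 1000 + r,
                           "duration": max_h + config.dt})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_abm(cfg, lut, initial=dict(seed_pop), record_truth=False)
        for h in agg:
            # nearest recorded passage at or before the horizon; fall back to census-free state
            snap = None
            for pt, s in zip(res.passage_times, res.snapshots):
                if pt <= h + 1e-9:
                    snap = s
            if snap is None:
                snap = seed_pop
            tot = sum(snap.values())
            for k, n in snap.items():
                agg[h][k] = agg[h].get(k, 0.0) + n / tot / n_replicates
    out.update(agg)
    return out
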
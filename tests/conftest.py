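"""Shared fixtures: small seeded synthetic datasets and fitted pipelines.

Everything is generated programmatically at test time; expensive objects
(ABM runs, fitted landscapes) are session-scoped so multiple tests share
one computation.
"""

import warnings

import numpy as np
import pytest
from hypothesis import settings

from alfak.abm_sim import ABMConfig, GRFLandscape, run_abm
from alfak.freqfit import (
    FrequentSet,
    LongitudinalCounts,
    refine_mle,
    replicator_solve,
    select_frequent,
)
from alfak.karyospace import DIPLOID, TransitionKernel

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


def make_replicator_counts(
    f_true, x0, times, n_cells=2000, seed=0, karyotypes=None
) -> LongitudinalCounts:
    """Multinomial samples from exact replicator frequencies."""
    rng = np.random.default_rng(seed)
    f_true = np.asarray(f_true, float)
    x0 = np.asarray(x0, float)
    times = np.asarray(times, float)
    X = replicator_solve(f_true, x0, times - times[0])
    counts = np.column_stack([rng.multinomial(n_cells, X[:, k]) for k in range(times.size)])
    if karyotypes is None:
        karyotypes = default_karyotypes(len(f_true))
    return LongitudinalCounts(karyotypes, times, counts)


def default_karyotypes(n):
    """n distinct near-diploid karyotypes (diploid plus single-chromosome CNAs)."""
    ks = [DIPLOID]
    c = 0
    while len(ks) < n:
        for delta in (1, -1, 2):
            k = list(DIPLOID)
            k[c] += delta
            ks.append(tuple(k))
            if len(ks) == n:
                break
        c += 1
    return ks[:n]


@pytest.fixture(scope="session")
def three_clone_counts():
    return make_replicator_counts(
        [0.2, 0.0, -0.1], [0.2, 0.5, 0.3], np.arange(0, 25, 5.0), seed=2
    )


@pytest.fixture(scope="session")
def three_clone_fit(three_clone_counts):
    S = select_frequent(three_clone_counts, 5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = refine_mle(three_clone_counts, S)
    return S, est


@pytest.fixture(scope="session")
def abm_grf_run():
    """One smooth-GRF ABM run with ground truth, shared across tests."""
    cfg = ABMConfig(p=1e-3, Nmax=6000, seed=11)
    grf = GRFLandscape(wavelength=2.0, amplitude=0.3, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_abm(cfg, grf, n_passages=7)
    return res, grf


@pytest.fixture(scope="session")
def abm_landscape(abm_grf_run):
    """Pipeline fit on the first six passages of the shared ABM run."""
    from alfak.landscape import fit_pipeline

    res, grf = abm_grf_run
    data = res.to_counts(0, 6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        land = fit_pipeline(data, TransitionKernel(p=1e-3), threshold=5, seed=0,
                            compute_cv=False)
    return land, res, grf
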
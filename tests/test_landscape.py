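"""Kriging interpolation, CV scoring, and fitness-effect profiles."""

import numpy as np
import pytest
from scipy import linalg

from alfak.freqfit import FitnessEstimate
from alfak.karyospace import DIPLOID, charted_region
from alfak.landscape import (
    FitnessLandscape,
    RegionError,
    bootstrap_landscape,
    cv_score,
    delta_f_profile,
    fit_kriging,
    matern32,
)
from conftest import default_karyotypes


class TestMatern32:
    def test_value_at_zero_is_sigma2(self):
        assert matern32(0.0, 2.5, 1.0) == pytest.approx(2.5)

    def test_decay_to_zero(self):
        assert matern32(1e4, 1.0, 1.0) < 1e-10

    def test_value_at_range(self):
        # d = rho: sigma2 * (1 + sqrt(3)) * exp(-sqrt(3))
        want = (1 + np.sqrt(3)) * np.exp(-np.sqrt(3))
        assert matern32(2.0, 1.0, 2.0) == pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(0.4834, abs=5e-5)

    def test_monotone_nonincreasing(self):
        d = np.linspace(0, 10, 200)
        v = matern32(d, 1.3, 0.7)
        assert np.all(np.diff(v) <= 0)

    def test_rejects_nonpositive_hyperparameters(self):
        with pytest.raises(ValueError):
            matern32(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            matern32(1.0, 1.0, -2.0)


def _grid_anchors(weights=(0.1, -0.05), lo=1, hi=7):
    """Exactly linear fitness over a dense 2-chromosome grid."""
    return [
        FitnessEstimate((a, b) + (2,) * 20, weights[0] * a + weights[1] * b,
                        stage="frequent")
        for a in range(lo, hi)
        for b in range(lo, hi)
    ]


def _linear_anchors(n=40, seed=0, weights=None):
    """Anchors lying exactly on a linear fitness function of copy number."""
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = rng.normal(0, 0.05, 22)
    ks = set()
    while len(ks) < n:
        k = tuple(int(c) for c in rng.integers(1, 5, 22))
        ks.add(k)
    ks = sorted(ks)
    return (
        [FitnessEstimate(k, float(np.dot(weights, k)), stage="frequent") for k in ks],
        weights,
    )


class TestKriging:
    def test_exact_interpolation_at_anchors_with_zero_nugget(self):
        anchors, _ = _linear_anchors(30)
        land = fit_kriging(anchors, hyperparams=(1.0, 5.0, 0.0),
                           region={a.karyotype for a in anchors})
        for a in anchors[:10]:
            assert land.predict(a.karyotype) == pytest.approx(a.f, abs=1e-8)

    def test_linear_landscape_interpolates_held_out_points(self):
        # dense grid on two active chromosomes; in the long-range limit the
        # Matérn-3/2 kernel with a free constant mean reproduces linear trends
        anchors = _grid_anchors()
        held = anchors[::7]
        train = [a for a in anchors if a not in held]
        region = {a.karyotype for a in anchors}
        land = fit_kriging(train, region=region, hyperparams=(1.0, 3e4, 0.0))
        errs = [abs(land.predict(a.karyotype) - a.f) for a in held]
        assert max(errs) < 1e-5

    def test_prediction_matches_dense_solve_oracle(self):
        anchors, _ = _linear_anchors(25, seed=2)
        s2, rho, t2 = 0.8, 4.0, 1e-3
        land = fit_kriging(anchors, hyperparams=(s2, rho, t2),
                           region=charted_region([a.karyotype for a in anchors], 1))
        X = np.array([a.karyotype for a in anchors], float)
        y = np.array([a.f for a in anchors])
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(2))
        K = matern32(D, s2, rho) + t2 * np.eye(len(y))
        one = np.ones(len(y))
        Ki = np.linalg.inv(K)
        mu = (one @ Ki @ y) / (one @ Ki @ one)
        query = tuple(np.array(anchors[0].karyotype) + np.eye(22, dtype=int)[3])
        d = np.sqrt(((X - np.array(query)) ** 2).sum(1))
        kstar = matern32(d, s2, rho)
        want = mu + kstar @ Ki @ (y - mu)
        assert land.predict(query) == pytest.approx(want, abs=1e-10)

    def test_constant_anchor_values_give_constant_prediction(self):
        ks = default_karyotypes(6)
        anchors = [FitnessEstimate(k, 0.42, stage="frequent") for k in ks]
        land = fit_kriging(anchors, hyperparams=(1.0, 3.0, 0.0))
        for k in list(land.region)[:20]:
            assert land.predict(k) == pytest.approx(0.42, abs=1e-8)

    def test_duplicate_conflicting_anchors_rejected(self):
        ks = default_karyotypes(3)
        anchors = [FitnessEstimate(k, 0.1, stage="frequent") for k in ks]
        anchors.append(FitnessEstimate(ks[0], 0.9, stage="frequent"))
        with pytest.raises(ValueError, match="duplicate"):
            fit_kriging(anchors, hyperparams=(1, 1, 0))

    def test_out_of_region_prediction_refused(self):
        anchors, _ = _linear_anchors(10)
        land = fit_kriging(anchors, region={a.karyotype for a in anchors},
                           hyperparams=(1, 3, 0))
        with pytest.raises(RegionError):
            land.predict((8,) * 22)

    def test_prediction_invariant_to_anchor_ordering(self):
        anchors, _ = _linear_anchors(20, seed=3)
        region = charted_region([a.karyotype for a in anchors], 1)
        land1 = fit_kriging(anchors, region=region, hyperparams=(0.5, 3.0, 1e-4))
        land2 = fit_kriging(anchors[::-1], region=region, hyperparams=(0.5, 3.0, 1e-4))
        q = sorted(region)[5]
        assert land1.predict(q) == pytest.approx(land2.predict(q), abs=1e-10)

    def test_symmetric_midpoint_between_equal_anchors(self):
        a = (2,) * 22
        b = (2, 2, 4) + (2,) * 19
        mid = (2, 2, 3) + (2,) * 19
        far = (5, 5, 5) + (2,) * 19  # third anchor to satisfy the minimum
        anchors = [
            FitnessEstimate(a, 1.0, stage="frequent"),
            FitnessEstimate(b, 1.0, stage="frequent"),
            FitnessEstimate(far, 0.0, stage="frequent"),
        ]
        land = fit_kriging(anchors, region={a, b, mid, far}, hyperparams=(1, 2, 0))
        swapped = fit_kriging(anchors[1::-1] + anchors[2:], region={a, b, mid, far},
                              hyperparams=(1, 2, 0))
        assert land.predict(mid) == pytest.approx(swapped.predict(mid), abs=1e-10)


class TestCVScore:
    def test_smooth_landscape_scores_high(self):
        anchors = _grid_anchors()
        assert cv_score(anchors, hyperparams=(1.0, 30.0, 1e-8)) > 0.95

    def test_iid_noise_scores_at_or_below_zero_in_expectation(self):
        scores = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ks = set()
            while len(ks) < 25:
                ks.add(tuple(int(c) for c in rng.integers(1, 5, 22)))
            anchors = [
                FitnessEstimate(k, float(rng.normal()), stage="frequent")
                for k in sorted(ks)
            ]
            scores.append(cv_score(anchors, hyperparams=(1.0, 3.0, 1e-6)))
        assert np.mean(scores) <= 0.0

    def test_requires_three_frequent_anchors(self):
        ks = default_karyotypes(4)
        anchors = [FitnessEstimate(k, 0.1, stage="neighbor", parents=(ks[0],)) for k in ks[1:]]
        anchors.append(FitnessEstimate(ks[0], 0.1, stage="frequent"))
        with pytest.raises(ValueError, match="frequent"):
            cv_score(anchors)

    def test_solely_derived_neighbors_are_held_out_with_parent(self):
        # neighbors tied only to the left-out parent must not leak its value
        parent = DIPLOID
        other1 = (4, 4) + (2,) * 20
        other2 = (2, 2, 4, 4) + (2,) * 18
        other3 = (2, 2, 2, 2, 4, 4) + (2,) * 16
        nb = (3,) + (2,) * 21
        anchors = [
            FitnessEstimate(parent, 5.0, stage="frequent"),
            FitnessEstimate(other1, 0.0, stage="frequent"),
            FitnessEstimate(other2, 0.0, stage="frequent"),
            FitnessEstimate(other3, 0.0, stage="frequent"),
            FitnessEstimate(nb, 5.0, stage="neighbor", parents=(parent,)),
        ]
        score, pairs = cv_score(anchors, hyperparams=(1.0, 2.0, 1e-6), return_pairs=True)
        i = list(pairs["estimated"]).index(5.0)
        # with the leaking neighbor removed, the fold predicts from the
        # far-away zero anchors: prediction must be far from 5.0
        assert pairs["predicted"][i] < 2.5


class TestDeltaFProfile:
    def test_flat_landscape_gives_zero_profile(self):
        ks = default_karyotypes(5)
        anchors = [FitnessEstimate(k, 0.3, stage="frequent") for k in ks]
        land = fit_kriging(anchors, hyperparams=(1.0, 3.0, 0.0))
        prof = delta_f_profile(land, DIPLOID)
        assert prof.shape == (44,)
        assert np.allclose(prof[np.isfinite(prof)], 0.0, atol=1e-7)

    def test_linear_landscape_gives_exact_weights(self):
        # the whole radius-1 ball is anchored, so with zero nugget the
        # interpolator is exact at every profile endpoint
        rng = np.random.default_rng(5)
        w = rng.normal(0, 0.05, 22)
        ball = sorted(charted_region([DIPLOID], 1))
        anchors = [
            FitnessEstimate(k, float(np.dot(w, k)), stage="frequent") for k in ball
        ]
        land = fit_kriging(anchors, region=set(ball), hyperparams=(1.0, 5.0, 0.0))
        prof = delta_f_profile(land, DIPLOID)
        for c in range(22):
            assert prof[2 * c] == pytest.approx(-w[c], abs=1e-7)  # loss
            assert prof[2 * c + 1] == pytest.approx(+w[c], abs=1e-7)  # gain

    def test_out_of_region_rejected(self):
        anchors, _ = _linear_anchors(10)
        land = fit_kriging(anchors, region={a.karyotype for a in anchors},
                           hyperparams=(1, 3, 0))
        with pytest.raises(RegionError):
            delta_f_profile(land, (8,) * 22)


class TestBootstrapLandscape:
    def test_fixed_seed_reproducible(self, three_clone_counts):
        from alfak.karyospace import TransitionKernel

        kern = TransitionKernel(p=1e-3)
        ks = list(three_clone_counts.karyotypes)
        a = bootstrap_landscape(three_clone_counts, kern, B=3, seed=5, karyotypes=ks)
        b = bootstrap_landscape(three_clone_counts, kern, B=3, seed=5, karyotypes=ks)
        assert np.array_equal(a["samples"], b["samples"], equal_nan=True)

    def test_intervals_widen_with_smaller_samples(self):
        from alfak.karyospace import TransitionKernel
        from conftest import make_replicator_counts

        kern = TransitionKernel(p=1e-3)
        widths = []
        for n in (5000, 500):
            data = make_replicator_counts(
                [0.15, 0.0, -0.05], [0.3, 0.4, 0.3], np.arange(0, 25, 5.0),
                n_cells=n, seed=21,
            )
            res = bootstrap_landscape(data, kern, B=12, seed=0,
                                      karyotypes=list(data.karyotypes))
            widths.append(float(np.nanmean(res["high"] - res["low"])))
        assert widths[1] > widths[0]
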
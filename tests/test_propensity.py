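"""Propensity estimators against closed-form and brute-force oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from psadjust import (
    DrawnSample,
    PropensitySpec,
    PropensityVector,
    clip_propensities,
    combine,
    draw_convenience,
    fit_propensity,
    forest_propensity,
    gbm_propensity,
    generate_population,
    internet_population,
    knn_propensity,
    logistic_propensity,
    nb_propensity,
    srswor,
    tree_propensity,
)
from psadjust.exceptions import DegenerateSampleError, InvalidArgumentError

from conftest import COVARIATES, make_binary_sample

FAST_SPECS = [
    PropensitySpec("logistic"),
    PropensitySpec("tree"),
    PropensitySpec("knn", {"k": 5}),
    PropensitySpec("naive_bayes"),
    PropensitySpec("random_forest", {"n_trees": 50}),
    PropensitySpec("gbm", {"n_trees": 50}),
]


def brute_force_knn(X_scaled, z, k):
    """Independent O(n²) oracle: per unit, sort all other units by
    (distance, row index) and average z over the first k."""
    n = len(z)
    out = np.empty(n)
    for i in range(n):
        others = [(np.linalg.norm(X_scaled[i] - X_scaled[j]), j) for j in range(n) if j != i]
        others.sort()
        out[i] = np.mean([z[j] for _, j in others[:k]])
    return out


def brute_force_nb_binary(sample, lam):
    """Hand Bayes computation for one binary covariate with add-λ smoothing."""
    x = sample.covariates["x"].astype(str).to_numpy()
    z = sample.z
    n0, n1 = (z == 0).sum(), (z == 1).sum()
    prior1 = n1 / len(z)
    levels = sorted(set(x))
    out = np.empty(len(z))
    for i, xi in enumerate(x):
        p_x_1 = (((x == xi) & (z == 1)).sum() + lam) / (n1 + lam * len(levels))
        p_x_0 = (((x == xi) & (z == 0)).sum() + lam) / (n0 + lam * len(levels))
        num = prior1 * p_x_1
        den = num + (1 - prior1) * p_x_0
        out[i] = prior1 if den == 0 else num / den
    return out


@pytest.fixture(scope="module")
def identical_rows_sample():
    ref = DrawnSample(pd.DataFrame({"x": ["a"] * 10}), np.ones(10), "reference")
    vol = DrawnSample(pd.DataFrame({"x": ["a"] * 10}), np.ones(10), "volunteer")
    return combine(ref, vol, ["x"])


@pytest.mark.parametrize("spec", FAST_SPECS, ids=lambda s: s.algorithm)
class TestContracts:
    def test_range_and_length(self, mid_sample, spec):
        _, p = fit_propensity(mid_sample, spec)
        assert len(p) == mid_sample.n
        assert np.all(p.values >= 0) and np.all(p.values <= 1)

    def test_deterministic_given_seed(self, mid_sample, spec):
        _, a = fit_propensity(mid_sample, spec)
        _, b = fit_propensity(mid_sample, spec)
        np.testing.assert_array_equal(a.values, b.values)


def test_single_class_sample_rejected(mini_pop):
    ref = srswor(mini_pop, 20, 1)
    sample = combine(
        ref, DrawnSample(ref.rows, np.ones(20), "volunteer"), COVARIATES
    ).subset(np.arange(20))  # keep only the z=0 block
    with pytest.raises(DegenerateSampleError):
        fit_propensity(sample, PropensitySpec("logistic"))


def test_unknown_algorithm_rejected():
    with pytest.raises(InvalidArgumentError):
        PropensitySpec("svm")


class TestNoInformationBaseRate:
    """With identical covariate rows and a balanced sample, the exactly
    solvable models return the base rate 0.5 everywhere; the stochastic
    ensembles land near it."""

    @pytest.mark.parametrize("fit", [logistic_propensity, tree_propensity, nb_propensity])
    def test_exact_base_rate(self, identical_rows_sample, fit):
        p = fit(identical_rows_sample)
        np.testing.assert_allclose(p.values, 0.5, atol=1e-9)

    def test_ensembles_near_base_rate(self, identical_rows_sample):
        p = gbm_propensity(identical_rows_sample, n_trees=50)
        np.testing.assert_allclose(p.values, 0.5, atol=0.05)
        p = forest_propensity(identical_rows_sample, n_trees=200, mtry=1, seed=1)
        np.testing.assert_allclose(p.values.mean(), 0.5, atol=0.15)


class TestLogistic:
    def test_constant_covariate_gives_volunteer_share(self):
        s = make_binary_sample(10, 0, 30, 0)  # x constant
        p = logistic_propensity(s)
        np.testing.assert_allclose(p.values, 0.75, atol=1e-8)

    def test_saturated_two_by_two_equals_cell_fractions(self):
        # z=1: 30 at x=1, 10 at x=0; z=0: 10 at x=1, 30 at x=0
        s = make_binary_sample(30, 10, 10, 30)
        p = logistic_propensity(s)
        x = s.covariates["x"].astype(str).to_numpy()
        np.testing.assert_allclose(p.values[x == "1"], 0.75, atol=1e-6)
        np.testing.assert_allclose(p.values[x == "0"], 0.25, atol=1e-6)

    def test_mean_propensity_equals_volunteer_share(self, mid_sample):
        """The logistic score equation forces mean π̂ = n_vs/n."""
        p = logistic_propensity(mid_sample)
        assert p.values.mean() == pytest.approx(mid_sample.n_vs / mid_sample.n, abs=1e-6)

    def test_age_coefficient_negative_under_age_biased_selection(self, pop50k):
        """Under the decreasing-in-age self-selection scheme the fitted age
        coefficient must be negative."""
        net = internet_population(pop50k)
        ref = srswor(pop50k, 500, 21)
        vol = draw_convenience(net, "logit_linear", 2000, 22)
        s = combine(ref, vol, COVARIATES)
        model, _ = fit_propensity(s, PropensitySpec("logistic"))
        age_ix = list(s.X.columns).index("age")
        assert model.coefficients[age_ix] < 0

    def test_perfect_separation_warns_but_returns(self):
        s = make_binary_sample(20, 0, 0, 20)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            p = logistic_propensity(s)
        assert len(p) == 40
        assert any("converge" in str(w.message) for w in caught)


class TestTree:
    def test_root_only_tree_gives_volunteer_share(self):
        s = make_binary_sample(10, 0, 30, 0)
        p = tree_propensity(s)
        np.testing.assert_allclose(p.values, 0.75)

    def test_pure_volunteer_leaf_gives_one(self):
        s = make_binary_sample(20, 0, 0, 20)
        p = tree_propensity(s, prune_confidence=None, min_node_fraction=0.005)
        x = s.covariates["x"].astype(str).to_numpy()
        np.testing.assert_array_equal(p.values[x == "1"], 1.0)
        np.testing.assert_array_equal(p.values[x == "0"], 0.0)

    def test_stump_matches_leaf_tally_oracle(self):
        s = make_binary_sample(12, 6, 5, 17)
        p = tree_propensity(s, prune_confidence=None, min_node_fraction=0.005)
        x = s.covariates["x"].astype(str).to_numpy()
        z = s.z
        for lvl in ("0", "1"):
            leaf = x == lvl
            np.testing.assert_allclose(p.values[leaf], z[leaf].mean())

    def test_aggressive_pruning_collapses_weak_splits(self, mid_sample):
        full = fit_propensity(
            mid_sample,
            PropensitySpec("tree", {"prune_confidence": None, "min_node_fraction": 0.005}),
        )[0]
        pruned = fit_propensity(
            mid_sample,
            PropensitySpec("tree", {"prune_confidence": 0.1, "min_node_fraction": 0.005}),
        )[0]
        assert pruned.n_effective_leaves <= full.n_effective_leaves


class TestForest:
    def test_single_tree_votes_are_binary(self, mid_sample):
        p = forest_propensity(mid_sample, n_trees=1, mtry=2, seed=0)
        assert set(np.unique(p.values)).issubset({0.0, 1.0})

    def test_five_trees_vote_fractions(self, mid_sample):
        p = forest_propensity(mid_sample, n_trees=5, mtry=2, seed=0)
        np.testing.assert_allclose(p.values * 5, np.round(p.values * 5), atol=1e-12)

    def test_separable_cells_get_unanimous_votes(self):
        s = make_binary_sample(20, 0, 0, 20)
        p = forest_propensity(s, n_trees=25, mtry=1, seed=3)
        x = s.covariates["x"].astype(str).to_numpy()
        assert p.values[x == "1"].min() > 0.9
        assert p.values[x == "0"].max() < 0.1


class TestKNN:
    def test_two_distant_clusters(self):
        """Volunteers clustered at 0..3, reference at 10..13: with k=3 every
        unit's nearest others are its own cluster."""
        ref = DrawnSample(
            pd.DataFrame({"pos": [10.0, 11.0, 12.0, 13.0]}), np.ones(4), "reference"
        )
        vol = DrawnSample(
            pd.DataFrame({"pos": [0.0, 1.0, 2.0, 3.0]}), np.ones(4), "volunteer"
        )
        s = combine(ref, vol, ["pos"])
        p = knn_propensity(s, k=3)
        np.testing.assert_array_equal(p.values[s.z == 1], 1.0)
        np.testing.assert_array_equal(p.values[s.z == 0], 0.0)

    def test_k_equals_n_minus_one_counts_all_others(self):
        s = make_binary_sample(4, 2, 1, 5)
        p = knn_propensity(s, k=s.n - 1)
        expect = np.where(s.z == 1, (s.n_vs - 1) / (s.n - 1), s.n_vs / (s.n - 1))
        np.testing.assert_allclose(p.values, expect)

    def test_k_too_large_rejected(self):
        s = make_binary_sample(3, 3, 3, 3)
        with pytest.raises(InvalidArgumentError):
            knn_propensity(s, k=12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        n_ref, n_vol = 7, 9
        ref = DrawnSample(
            pd.DataFrame({"a": rng.normal(size=n_ref), "b": rng.choice(["u", "v"], n_ref)}),
            np.ones(n_ref),
            "reference",
        )
        vol = DrawnSample(
            pd.DataFrame({"a": rng.normal(size=n_vol), "b": rng.choice(["u", "v"], n_vol)}),
            np.ones(n_vol),
            "volunteer",
        )
        s = combine(ref, vol, ["a", "b"])
        for k in (1, 4, 9):
            model, p = fit_propensity(s, PropensitySpec("knn", {"k": k}))
            oracle = brute_force_knn(model.train_scaled, s.z, k)
            np.testing.assert_allclose(p.values, oracle)


class TestNaiveBayes:
    def test_hand_bayes_single_binary_covariate(self):
        # z=1: 6 at x=1, 4 at x=0; z=0: 2 at x=1, 8 at x=0; λ=0
        s = make_binary_sample(8, 2, 4, 6)
        p = nb_propensity(s, laplace=0)
        x = s.covariates["x"].astype(str).to_numpy()
        np.testing.assert_allclose(p.values[x == "1"], 0.75, atol=1e-12)
        np.testing.assert_allclose(
            p.values[x == "0"], (0.5 * 0.4) / (0.5 * 0.4 + 0.5 * 0.8), atol=1e-12
        )

    @pytest.mark.parametrize("lam", [0, 1, 5])
    def test_covariate_independent_of_z(self, lam):
        # same x split in both classes -> likelihood ratio 1 -> prior
        s = make_binary_sample(5, 5, 5, 5)
        p = nb_propensity(s, laplace=lam)
        np.testing.assert_allclose(p.values, 0.5, atol=1e-12)

    def test_large_smoothing_flattens_to_prior(self):
        s = make_binary_sample(8, 2, 4, 6)
        p = nb_propensity(s, laplace=1e9)
        np.testing.assert_allclose(p.values, 0.5, atol=1e-6)

    def test_gaussian_numeric_conditionals_separate_clusters(self):
        ref = DrawnSample(pd.DataFrame({"pos": np.linspace(9, 11, 8)}), np.ones(8), "reference")
        vol = DrawnSample(pd.DataFrame({"pos": np.linspace(-1, 1, 8)}), np.ones(8), "volunteer")
        s = combine(ref, vol, ["pos"])
        p = nb_propensity(s, laplace=1)
        assert p.values[s.z == 1].min() > 0.99
        assert p.values[s.z == 0].max() < 0.01


class TestGBM:
    def test_zero_trees_is_null_model(self, mid_sample):
        p = gbm_propensity(mid_sample, n_trees=0)
        np.testing.assert_allclose(p.values, mid_sample.n_vs / mid_sample.n)

    def test_training_deviance_non_increasing_with_full_sample_fitting(self, mid_sample):
        spec = PropensitySpec(
            "gbm",
            {"interaction_depth": 3, "learning_rate": 0.1, "n_trees": 50, "subsample": 1.0},
            seed=0,
        )
        model, _ = fit_propensity(mid_sample, spec)
        devs = model.staged_train_deviance(mid_sample)
        assert np.all(np.diff(devs) <= 1e-12)

    def test_separable_cells_reach_extreme_propensities(self):
        s = make_binary_sample(20, 0, 0, 20)
        p = gbm_propensity(s, interaction_depth=2, learning_rate=0.5, n_trees=100)
        x = s.covariates["x"].astype(str).to_numpy()
        assert p.values[x == "1"].min() > 0.9
        assert p.values[x == "0"].max() < 0.1

    def test_nonpositive_learning_rate_rejected(self, mid_sample):
        with pytest.raises(InvalidArgumentError):
            gbm_propensity(mid_sample, learning_rate=0.0)


class TestClipping:
    def test_formula_endpoints_and_fixed_point(self):
        p = PropensityVector(np.array([0.0, 0.5, 1.0]))
        c = clip_propensities(p)
        np.testing.assert_allclose(c.values, [0.5 / 1001, 0.5, 1000.5 / 1001])
        assert c.clipped

    def test_monotone_and_interior(self):
        vals = np.linspace(0, 1, 101)
        c = clip_propensities(PropensityVector(vals))
        assert np.all(np.diff(c.values) > 0)
        assert c.values.min() > 0 and c.values.max() < 1

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PropensityVector(np.array([-0.1, 0.5]))
        with pytest.raises(InvalidArgumentError):
            PropensityVector(np.array([0.5, 1.2]))


def test_all_algorithms_discriminate_under_informative_selection(pop50k):
    """With age-driven self-selection, every algorithm assigns higher mean
    propensity to volunteer units than to reference units."""
    net = internet_population(pop50k)
    ref = srswor(pop50k, 500, 31)
    vol = draw_convenience(net, "logit_linear", 2000, 32)
    s = combine(ref, vol, COVARIATES)
    specs = [
        PropensitySpec("logistic"),
        PropensitySpec("tree"),
        PropensitySpec("knn", {"k": 13}),
        PropensitySpec("naive_bayes"),
        PropensitySpec("random_forest", {"n_trees": 100}, seed=1),
        PropensitySpec("gbm", seed=1),
    ]
    vol_mask = s.volunteer_mask()
    for spec in specs:
        _, p = fit_propensity(s, spec)
        assert p.values[vol_mask].mean() > p.values[~vol_mask].mean(), spec.algorithm
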
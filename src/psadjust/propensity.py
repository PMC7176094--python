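"""Participation-propensity estimation on the combined sample.

Six algorithm families estimate π̂(x) = P(z = 1 | x), the probability that a
unit of the stacked reference+volunteer sample is a volunteer:

* ``logistic`` — unpenalised logistic regression (maximum likelihood);
* ``tree`` — a single classification tree; π̂ is the volunteer fraction of
  the terminal node, after an optional C4.5-style pessimistic-pruning pass;
* ``random_forest`` — π̂ is the fraction of bootstrap trees whose terminal
  node is majority-volunteer (vote fraction, not averaged leaf fractions);
* ``knn`` — volunteer fraction among the k nearest other units;
* ``naive_bayes`` — Bayes formula with class-conditional independence,
  add-λ smoothing on categorical covariates and Gaussian numeric densities;
* ``gbm`` — stagewise gradient boosting of shallow trees on the Bernoulli
  deviance; π̂ is the logistic transform of the additive score.

Raw propensities live in [0, 1]; :func:`clip_propensities` maps them to
(0, 1) via (1000·x + 0.5)/1001 so inverse-odds weights stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import beta as _beta_dist
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .exceptions import DegenerateSampleError, InvalidArgumentError
from .sampling import CombinedSample

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "PropensitySpec",
    "PropensityVector",
    "FittedPropensityModel",
    "fit_propensity",
    "logistic_propensity",
    "tree_propensity",
    "forest_propensity",
    "knn_propensity",
    "nb_propensity",
    "gbm_propensity",
    "clip_propensities",
]

ALGORITHMS = ("logistic", "tree", "knn", "naive_bayes", "random_forest", "gbm")

# Hyperparameter grids searched by cross-validated tuning.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic": {},
    "tree": {
        "impurity": ["entropy", "gini"],
        "prune_confidence": [0.1, 0.25, 0.5],
        "min_node_fraction": [0.005, 0.01, 0.05],
    },
    "knn": {"k": [3, 5, 7, 9, 11, 13]},
    "naive_bayes": {"laplace": [0, 1, 2, 5, 10]},
    "random_forest": {"n_trees": [500], "mtry": [1, 2, 4]},
    "gbm": {
        "interaction_depth": [4, 6, 8],
        "learning_rate": [0.1, 0.01, 0.001],
    },
}

_DEFAULT_HP: dict[str, dict[str, Any]] = {
    "logistic": {},
    "tree": {"impurity": "entropy", "prune_confidence": 0.25, "min_node_fraction": 0.01},
    "knn": {"k": 5},
    "naive_bayes": {"laplace": 1},
    "random_forest": {"n_trees": 500, "mtry": "sqrt"},
    "gbm": {"interaction_depth": 6, "learning_rate": 0.1, "n_trees": 100},
}


@dataclass(frozen=True)
class PropensitySpec:
    """An algorithm choice with hyperparameters and a fitting seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise InvalidArgumentError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )

    def resolved_hyperparameters(self) -> dict[str, Any]:
        hp = dict(_DEFAULT_HP[self.algorithm])
        hp.update(self.hyperparameters)
        return hp

    def __hash__(self) -> int:  # hyperparameters dict is small and flat
        return hash((self.algorithm, tuple(sorted(self.hyperparameters.items())), self.seed))


@dataclass
class PropensityVector:
    """Estimated propensities aligned with the combined-sample rows."""

    values: np.ndarray
    clipped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = (0.0, 1.0)
        if np.any(self.values < lo) or np.any(self.values > hi):
            raise InvalidArgumentError("propensities must lie in [0, 1]")
        if self.clipped and (np.any(self.values <= 0) or np.any(self.values >= 1)):
            raise InvalidArgumentError("clipped propensities must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.values)


def clip_propensities(p: PropensityVector) -> PropensityVector:
    """Map propensities into (0, 1) via (1000·x + 0.5)/1001."""
    return PropensityVector((1000.0 * p.values + 0.5) / 1001.0, clipped=True)


class FittedPropensityModel:
    """Base class: a fitted model that can score new covariate rows."""

    def __init__(self, spec: PropensitySpec, encoder):
        self.spec = spec
        self.encoder = encoder

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError


def _check_sample(sample: CombinedSample) -> None:
    if sample.n_vs == 0 or sample.n_rs == 0:
        raise DegenerateSampleError(
            "combined sample must contain both volunteer (z=1) and reference (z=0) units"
        )


def _seed_int(seed) -> int:
    return int(np.random.default_rng(seed).integers(2**31 - 1))


# ---------------------------------------------------------------------------
# Logistic regression


class LogisticPropensityModel(FittedPropensityModel):
    def __init__(self, spec, encoder, clf):
        super().__init__(spec, encoder)
        self.clf = clf

    @property
    def coefficients(self) -> np.ndarray:
        return self.clf.coef_[0]

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        X = self.encoder.transform(covariates).to_numpy()
        col = int(np.flatnonzero(self.clf.classes_ == 1)[0])
        return self.clf.predict_proba(X)[:, col]


def _fit_logistic(sample: CombinedSample, spec: PropensitySpec) -> LogisticPropensityModel:
    clf = LogisticRegression(
        penalty=None, solver="lbfgs", max_iter=1000, tol=1e-10
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(sample.X.to_numpy(), sample.z)
    hit_cap = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    # diverging coefficients are the practical signature of (quasi-)separation
    if hit_cap or np.abs(clf.coef_).max() > 15:
        warnings.warn(
            "logistic propensity fit did not converge to finite coefficients "
            "(possible perfect separation); returning the capped-iteration fit",
            stacklevel=3,
        )
    return LogisticPropensityModel(spec, sample.encoder, clf)


# ---------------------------------------------------------------------------
# Single classification tree with pessimistic pruning


def _pessimistic_errors(n_vol, n_tot, confidence):
    """C4.5-style predicted error of a node classified by its majority class.

    Uses the Clopper–Pearson upper confidence bound of the binomial error
    rate at level ``1 - confidence``; smaller confidence values prune more.
    ``confidence=None`` disables the pessimistic correction (resubstitution
    error).
    """
    e = np.minimum(n_vol, n_tot - n_vol).astype(float)
    if confidence is None:
        return e
    out = np.empty_like(e)
    for i, (ei, ni) in enumerate(zip(e, n_tot)):
        if ni <= 0:
            out[i] = 0.0
        elif ei >= ni:
            out[i] = float(ni)
        else:
            out[i] = ni * _beta_dist.ppf(1.0 - confidence, ei + 1.0, ni - ei)
    return out


class TreePropensityModel(FittedPropensityModel):
    def __init__(self, spec, encoder, clf, leaf_to_effective, node_propensity):
        super().__init__(spec, encoder)
        self.clf = clf
        self._leaf_to_effective = leaf_to_effective
        self._node_propensity = node_propensity

    @property
    def n_effective_leaves(self) -> int:
        return len(set(self._leaf_to_effective.values()))

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        X = self.encoder.transform(covariates).to_numpy()
        leaves = self.clf.apply(X)
        eff = np.array([self._leaf_to_effective[int(l)] for l in leaves])
        return self._node_propensity[eff]


def _fit_tree(sample: CombinedSample, spec: PropensitySpec) -> TreePropensityModel:
    hp = spec.resolved_hyperparameters()
    n = sample.n
    min_leaf = max(1, int(np.ceil(hp["min_node_fraction"] * n)))
    clf = DecisionTreeClassifier(
        criterion=hp["impurity"],
        min_samples_leaf=min_leaf,
        random_state=_seed_int(spec.seed),
    )
    Xm = sample.X.to_numpy()
    clf.fit(Xm, sample.z)

    # per-node volunteer/total counts from the training sample itself
    path = clf.decision_path(Xm)
    n_tot = np.asarray(path.sum(axis=0)).ravel()
    n_vol = np.asarray(path[sample.z == 1].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        node_prop = np.where(n_tot > 0, n_vol / np.maximum(n_tot, 1), sample.n_vs / n)

    pess = _pessimistic_errors(n_vol, n_tot, hp["prune_confidence"])
    left, right = clf.tree_.children_left, clf.tree_.children_right
    leaf_to_effective: dict[int, int] = {}

    def prune(node: int) -> tuple[float, list[int]]:
        if left[node] == -1:
            leaf_to_effective[node] = node
            return pess[node], [node]
        err_l, leaves_l = prune(left[node])
        err_r, leaves_r = prune(right[node])
        leaves = leaves_l + leaves_r
        subtree_err = err_l + err_r
        if pess[node] <= subtree_err:
            for leaf in leaves:
                leaf_to_effective[leaf] = node
            return pess[node], leaves
        return subtree_err, leaves

    prune(0)
    return TreePropensityModel(spec, sample.encoder, clf, leaf_to_effective, node_prop)


# ---------------------------------------------------------------------------
# Random forest (majority-vote fraction across trees)


class ForestPropensityModel(FittedPropensityModel):
    def __init__(self, spec, encoder, rf):
        super().__init__(spec, encoder)
        self.rf = rf

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        X = self.encoder.transform(covariates).to_numpy()
        col = int(np.flatnonzero(self.rf.classes_ == 1)[0])
        votes = np.zeros(len(X))
        for est in self.rf.estimators_:
            votes += est.predict_proba(X)[:, col] >= 0.5
        return votes / len(self.rf.estimators_)


def _fit_forest(sample: CombinedSample, spec: PropensitySpec) -> ForestPropensityModel:
    hp = spec.resolved_hyperparameters()
    mtry = hp["mtry"]
    if isinstance(mtry, (int, np.integer)):
        mtry = min(int(mtry), sample.X.shape[1])
    rf = RandomForestClassifier(
        n_estimators=int(hp["n_trees"]),
        max_features=mtry,
        bootstrap=True,
        random_state=_seed_int(spec.seed),
        n_jobs=1,
    )
    rf.fit(sample.X.to_numpy(), sample.z)
    return ForestPropensityModel(spec, sample.encoder, rf)


# ---------------------------------------------------------------------------
# k nearest neighbours


class KNNPropensityModel(FittedPropensityModel):
    """Volunteer fraction among the k nearest units.

    Numeric covariates are min-max scaled to [0, 1] (scale frozen at fit
    time); one-hot dummies enter unscaled; the metric is Euclidean. When
    scoring the training sample itself each unit is excluded from its own
    neighbourhood. Distance ties at the k-th neighbour are broken by lowest
    row index so exactly k neighbours count.
    """

    def __init__(self, spec, encoder, train_scaled, z, k, num_cols, num_min, num_range):
        super().__init__(spec, encoder)
        self.train_scaled = train_scaled
        self.z = z
        self.k = k
        self._num_cols = num_cols
        self._num_min = num_min
        self._num_range = num_range

    def _scale(self, X: pd.DataFrame) -> np.ndarray:
        M = X.to_numpy(dtype=float).copy()
        if self._num_cols.size:
            M[:, self._num_cols] = (
                M[:, self._num_cols] - self._num_min
            ) / self._num_range
        return M

    def _vote(self, Q: np.ndarray, exclude_diagonal: bool) -> np.ndarray:
        D = cdist(Q, self.train_scaled)
        if exclude_diagonal:
            np.fill_diagonal(D, np.inf)
        # stable argsort breaks distance ties by lowest training-row index
        order = np.argsort(D, axis=1, kind="stable")[:, : self.k]
        return self.z[order].mean(axis=1)

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        return self._vote(self._scale(self.encoder.transform(covariates)), False)


def _fit_knn(sample: CombinedSample, spec: PropensitySpec) -> KNNPropensityModel:
    hp = spec.resolved_hyperparameters()
    k = int(hp["k"])
    if k >= sample.n:
        raise InvalidArgumentError(f"k must be <= n - 1 = {sample.n - 1}, got {k}")
    num_cols = np.array(
        [i for i, c in enumerate(sample.X.columns) if c in sample.encoder.numeric_columns],
        dtype=int,
    )
    M = sample.X.to_numpy(dtype=float)
    if num_cols.size:
        mins = M[:, num_cols].min(axis=0)
        ranges = M[:, num_cols].max(axis=0) - mins
        ranges[ranges == 0] = 1.0
    else:
        mins = np.empty(0)
        ranges = np.empty(0)
    model = KNNPropensityModel(
        spec, sample.encoder, None, sample.z, k, num_cols, mins, ranges
    )
    model.train_scaled = model._scale(sample.X)
    return model


# ---------------------------------------------------------------------------
# Naive Bayes (categorical add-λ conditionals, Gaussian numeric conditionals)


class NaiveBayesPropensityModel(FittedPropensityModel):
    def __init__(self, spec, encoder, log_prior, cat_tables, gauss_params):
        super().__init__(spec, encoder)
        self.log_prior = log_prior  # shape (2,)
        self.cat_tables = cat_tables  # col -> {level: (logp0, logp1)}
        self.gauss_params = gauss_params  # col -> ((mu0, sd0), (mu1, sd1))

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        n = len(covariates)
        log_lik = np.tile(self.log_prior, (n, 1))
        for col, table in self.cat_tables.items():
            vals = covariates[col].astype(str).to_numpy()
            for cls in (0, 1):
                log_lik[:, cls] += np.array(
                    [table.get(v, (-np.inf, -np.inf))[cls] for v in vals]
                )
        for col, ((mu0, sd0), (mu1, sd1)) in self.gauss_params.items():
            x = covariates[col].to_numpy(dtype=float)
            log_lik[:, 0] += -0.5 * ((x - mu0) / sd0) ** 2 - np.log(sd0)
            log_lik[:, 1] += -0.5 * ((x - mu1) / sd1) ** 2 - np.log(sd1)
        # normalise in log space; if both joints vanish fall back to the prior
        out = np.empty(n)
        both_zero = np.isneginf(log_lik).all(axis=1)
        m = np.max(log_lik, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            expd = np.exp(log_lik - np.where(np.isneginf(m), 0.0, m))
        out = expd[:, 1] / expd.sum(axis=1)
        out[both_zero] = np.exp(self.log_prior[1])
        return out


def _fit_naive_bayes(sample: CombinedSample, spec: PropensitySpec) -> NaiveBayesPropensityModel:
    hp = spec.resolved_hyperparameters()
    lam = float(hp["laplace"])
    if lam < 0:
        raise InvalidArgumentError(f"laplace must be >= 0, got {lam}")
    z = sample.z
    n0, n1 = int((z == 0).sum()), int((z == 1).sum())
    log_prior = np.log(np.array([n0, n1]) / sample.n)

    cat_tables: dict[str, dict[str, tuple[float, float]]] = {}
    gauss_params: dict[str, tuple] = {}
    with np.errstate(divide="ignore"):
        for col in sample.covariates.columns:
            if col in sample.encoder.categorical_levels:
                levels = sample.encoder.categorical_levels[col]
                vals = sample.covariates[col].astype(str).to_numpy()
                table = {}
                for lvl in levels:
                    c0 = int(((vals == lvl) & (z == 0)).sum())
                    c1 = int(((vals == lvl) & (z == 1)).sum())
                    p0 = (c0 + lam) / (n0 + lam * len(levels))
                    p1 = (c1 + lam) / (n1 + lam * len(levels))
                    table[lvl] = (float(np.log(p0)), float(np.log(p1)))
                cat_tables[col] = table
            else:
                x = sample.covariates[col].to_numpy(dtype=float)
                params = []
                for cls in (0, 1):
                    xc = x[z == cls]
                    mu = float(xc.mean())
                    sd = float(xc.std(ddof=1)) if len(xc) > 1 else 0.0
                    if sd <= 0:
                        sd = max(1e-9, 1e-9 * abs(mu))
                    params.append((mu, sd))
                gauss_params[col] = tuple(params)
    return NaiveBayesPropensityModel(spec, sample.encoder, log_prior, cat_tables, gauss_params)


# ---------------------------------------------------------------------------
# Gradient boosting


class GBMPropensityModel(FittedPropensityModel):
    def __init__(self, spec, encoder, gb, null_rate=None):
        super().__init__(spec, encoder)
        self.gb = gb
        self.null_rate = null_rate

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        X = self.encoder.transform(covariates).to_numpy()
        if self.gb is None:
            return np.full(len(X), self.null_rate)
        col = int(np.flatnonzero(self.gb.classes_ == 1)[0])
        return self.gb.predict_proba(X)[:, col]

    def staged_train_deviance(self, sample: CombinedSample) -> np.ndarray:
        """Mean Bernoulli deviance on the training sample after each stage."""
        X = sample.X.to_numpy()
        z = sample.z
        col = int(np.flatnonzero(self.gb.classes_ == 1)[0])
        devs = []
        for proba in self.gb.staged_predict_proba(X):
            p = np.clip(proba[:, col], 1e-15, 1 - 1e-15)
            devs.append(float(-2 * np.mean(z * np.log(p) + (1 - z) * np.log(1 - p))))
        return np.array(devs)


def _fit_gbm(sample: CombinedSample, spec: PropensitySpec) -> GBMPropensityModel:
    hp = spec.resolved_hyperparameters()
    n_trees = int(hp.get("n_trees", 100))
    if n_trees == 0:
        # null additive model: the intercept log-odds alone
        return GBMPropensityModel(spec, sample.encoder, None, sample.n_vs / sample.n)
    if hp["learning_rate"] <= 0:
        raise InvalidArgumentError("learning_rate must be > 0")
    gb = GradientBoostingClassifier(
        n_estimators=n_trees,
        learning_rate=float(hp["learning_rate"]),
        max_depth=int(hp["interaction_depth"]),
        subsample=float(hp.get("subsample", 0.5)),
        random_state=_seed_int(spec.seed),
    )
    gb.fit(sample.X.to_numpy(), sample.z)
    return GBMPropensityModel(spec, sample.encoder, gb)


# ---------------------------------------------------------------------------
# Dispatch and convenience wrappers

_FITTERS = {
    "logistic": _fit_logistic,
    "tree": _fit_tree,
    "knn": _fit_knn,
    "naive_bayes": _fit_naive_bayes,
    "random_forest": _fit_forest,
    "gbm": _fit_gbm,
}


def fit_propensity(
    sample: CombinedSample, spec: PropensitySpec
) -> tuple[FittedPropensityModel, PropensityVector]:
    """Fit one propensity model and return it with in-sample propensities.

    Deterministic given ``(sample, spec)`` including ``spec.seed``. Raises
    :class:`DegenerateSampleError` if z has a single class.
    """
    _check_sample(sample)
    model = _FITTERS[spec.algorithm](sample, spec)
    if isinstance(model, KNNPropensityModel):
        values = model._vote(model.train_scaled, exclude_diagonal=True)
    else:
        values = model.predict(sample.covariates)
    return model, PropensityVector(np.clip(values, 0.0, 1.0))


def _wrap(algorithm: str, sample: CombinedSample, seed=0, **hp) -> PropensityVector:
    spec = PropensitySpec(algorithm, hp, seed=seed)
    return fit_propensity(sample, spec)[1]


def logistic_propensity(sample: CombinedSample) -> PropensityVector:
    """Maximum-likelihood logistic propensities (intercept included)."""
    return _wrap("logistic", sample)


def tree_propensity(
    sample: CombinedSample,
    impurity: str = "entropy",
    prune_confidence: float | None = 0.25,
    min_node_fraction: float = 0.01,
    seed: int = 0,
) -> PropensityVector:
    """Terminal-node volunteer fractions of one pruned classification tree."""
    return _wrap(
        "tree",
        sample,
        seed=seed,
        impurity=impurity,
        prune_confidence=prune_confidence,
        min_node_fraction=min_node_fraction,
    )


def forest_propensity(
    sample: CombinedSample, n_trees: int = 500, mtry=2, seed: int = 0
) -> PropensityVector:
    """Majority-vote fraction over a bootstrap forest."""
    return _wrap("random_forest", sample, seed=seed, n_trees=n_trees, mtry=mtry)


def knn_propensity(sample: CombinedSample, k: int = 5) -> PropensityVector:
    """Volunteer fraction among each unit's k nearest other units."""
    return _wrap("knn", sample, k=k)


def nb_propensity(sample: CombinedSample, laplace: float = 1) -> PropensityVector:
    """Naive-Bayes posterior P(z=1 | x) with add-λ smoothing."""
    return _wrap("naive_bayes", sample, laplace=laplace)


def gbm_propensity(
    sample: CombinedSample,
    interaction_depth: int = 6,
    learning_rate: float = 0.1,
    n_trees: int = 100,
    seed: int = 0,
) -> PropensityVector:
    """Gradient-boosted propensities on the Bernoulli deviance."""
    return _wrap(
        "gbm",
        sample,
        seed=seed,
        interaction_depth=interaction_depth,
        learning_rate=learning_rate,
        n_trees=n_trees,
    )
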
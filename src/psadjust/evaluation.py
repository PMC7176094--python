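"""Replicated Monte-Carlo evaluation of PSA estimators.

One scenario fixes a selection scheme, sample sizes and an estimator (or
several), generates the finite population once, and repeats the draw →
fit → weight → estimate cycle. For each party the summary reports

    Bias = (1/M) Σ_m p̂_m − p        (p is the finite-population truth)
    MSE  = Σ_m (p̂_m − p̄̂)² / (M−1) + Bias²

i.e. the sample variance of the M replicated estimates (divisor M−1) plus
the squared bias, alongside the unadjusted volunteer-mean counterparts.

Hyperparameter tuning follows repeated stratified k-fold cross-validation
of the propensity log-loss on the combined sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import InvalidArgumentError
from .population import (
    PARTIES,
    generate_population,
    internet_population,
    true_proportion,
)
from .propensity import (
    DEFAULT_GRIDS,
    PropensitySpec,
    clip_propensities,
    fit_propensity,
)
from .sampling import CombinedSample, combine, draw_convenience, srswor
from .weighting import (
    hajek_weights,
    ht_class_weights,
    stratify_by_propensity,
    weighted_proportion,
)

__all__ = [
    "bias",
    "mse",
    "ScenarioConfig",
    "ReplicationResult",
    "run_scenario",
    "log_loss",
    "expand_grid",
    "TuneResult",
    "tune_cv",
]

DEFAULT_COVARIATES = ("age", "gender", "nationality", "education")


def bias(estimates, truth: float) -> float:
    """Mean of the replicated estimates minus the population truth."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise InvalidArgumentError("estimates must be non-empty")
    return float(estimates.mean() - truth)


def mse(estimates, truth: float) -> float:
    """Sample variance (divisor M−1) of the estimates plus squared bias."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise InvalidArgumentError("mse needs at least two replicated estimates")
    b = bias(estimates, truth)
    return float(estimates.var(ddof=1) + b * b)


@dataclass
class ScenarioConfig:
    """One Monte-Carlo study configuration."""

    scheme: str = "srswor"
    n_vs: int = 1000
    n_rs: int = 500
    n_pop: int = 50_000
    reps: int = 500
    estimators: list[PropensitySpec] = field(
        default_factory=lambda: [PropensitySpec("logistic")]
    )
    weighting: str = "hajek"
    n_classes: int = 5
    parties: tuple[str, ...] = PARTIES
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise InvalidArgumentError("reps must be >= 1")
        if self.weighting not in ("hajek", "ht_class"):
            raise InvalidArgumentError(f"unknown weighting {self.weighting!r}")
        if isinstance(self.estimators, PropensitySpec):
            self.estimators = [self.estimators]


def _estimator_label(spec: PropensitySpec) -> str:
    if not spec.hyperparameters:
        return spec.algorithm
    hp = ",".join(f"{k}={v}" for k, v in sorted(spec.hyperparameters.items()))
    return f"{spec.algorithm}({hp})"


@dataclass
class ReplicationResult:
    """Per-replication estimates plus bias/MSE summaries."""

    config: ScenarioConfig
    truth: dict[str, float]
    estimates: pd.DataFrame  # columns: rep, estimator, party, estimate
    unadjusted: pd.DataFrame  # columns: rep, party, estimate

    def summary(self) -> pd.DataFrame:
        """Long-format bias/MSE table, one row per (estimator, party)."""
        rows = []
        unadj = {
            party: g["estimate"].to_numpy()
            for party, g in self.unadjusted.groupby("party")
        }
        for (est, party), g in self.estimates.groupby(["estimator", "party"]):
            e = g["estimate"].to_numpy()
            t = self.truth[party]
            rows.append(
                {
                    "scheme": self.config.scheme,
                    "estimator": est,
                    "n_vs": self.config.n_vs,
                    "party": party,
                    "mean_estimate": float(e.mean()),
                    "bias": bias(e, t) if e.size else np.nan,
                    "mse": mse(e, t) if e.size > 1 else np.nan,
                    "unadjusted_bias": bias(unadj[party], t),
                    "unadjusted_mse": mse(unadj[party], t)
                    if unadj[party].size > 1
                    else np.nan,
                    "truth": t,
                }
            )
        return pd.DataFrame(rows).sort_values(["estimator", "party"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


def _estimate_once(
    sample: CombinedSample,
    spec: PropensitySpec,
    weighting: str,
    n_classes: int,
    parties,
) -> dict[str, float]:
    _, p = fit_propensity(sample, spec)
    vol = sample.volunteer_mask()
    if weighting == "hajek":
        p_vol = p.values[vol]
        if np.any(p_vol <= 0) or np.any(p_vol >= 1):
            p = clip_propensities(p)
            p_vol = p.values[vol]
        weights = hajek_weights(p_vol)
    else:
        classes = stratify_by_propensity(sample, p, n_classes)
        weights = ht_class_weights(sample, classes)
    out = {}
    for party in parties:
        y = sample.extra.loc[vol, f"vote_{party}"].to_numpy(dtype=float)
        out[party] = weighted_proportion(y, weights)
    return out


def run_scenario(config: ScenarioConfig, population: pd.DataFrame | None = None) -> ReplicationResult:
    """Run one replicated scenario study.

    The population is generated once (or supplied) and held fixed; each
    replication redraws the reference sample from the full population and
    the convenience sample from its internet subpopulation. Estimator fits
    inside a replication share that replication's samples, so algorithm
    comparisons are paired. Fully reproducible from ``master_seed``.
    """
    root = np.random.SeedSequence(config.master_seed)
    pop_ss, rep_root = root.spawn(2)
    if population is None:
        pop_seed = int(np.random.default_rng(pop_ss).integers(2**31 - 1))
        population = generate_population(config.n_pop, pop_seed)
    truth = {party: true_proportion(population, party) for party in config.parties}
    internet = internet_population(population)

    est_rows, unadj_rows = [], []
    rep_seeds = rep_root.spawn(config.reps)
    for m, rep_ss in enumerate(rep_seeds):
        ref_ss, conv_ss, fit_ss = rep_ss.spawn(3)
        reference = srswor(population, config.n_rs, ref_ss)
        volunteer = draw_convenience(internet, config.scheme, config.n_vs, conv_ss)
        sample = combine(reference, volunteer, list(config.covariates))
        vol = sample.volunteer_mask()
        for party in config.parties:
            y = sample.extra.loc[vol, f"vote_{party}"].to_numpy(dtype=float)
            unadj_rows.append({"rep": m, "party": party, "estimate": float(y.mean())})
        fit_streams = fit_ss.spawn(len(config.estimators))
        for spec, stream in zip(config.estimators, fit_streams):
            seeded = PropensitySpec(
                spec.algorithm,
                spec.hyperparameters,
                seed=int(np.random.default_rng(stream).integers(2**31 - 1)),
            )
            try:
                ests = _estimate_once(
                    sample, seeded, config.weighting, config.n_classes, config.parties
                )
            except Exception as exc:
                raise RuntimeError(
                    f"replication {m}, estimator {_estimator_label(spec)} failed"
                ) from exc
            for party, value in ests.items():
                est_rows.append(
                    {
                        "rep": m,
                        "estimator": _estimator_label(spec),
                        "party": party,
                        "estimate": value,
                    }
                )
    return ReplicationResult(
        config,
        truth,
        pd.DataFrame(est_rows),
        pd.DataFrame(unadj_rows),
    )


# ---------------------------------------------------------------------------
# Cross-validated hyperparameter tuning


def log_loss(z, p) -> float:
    """Mean negative Bernoulli log-likelihood, propensities clipped away
    from 0 and 1 at 1e-15."""
    z = np.asarray(z, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-15, 1 - 1e-15)
    return float(-np.mean(z * np.log(p) + (1 - z) * np.log(1 - p)))


def expand_grid(algorithm: str, grid: dict[str, list] | None = None, seed: int = 0):
    """All hyperparameter combinations of an algorithm's tuning grid."""
    grid = DEFAULT_GRIDS[algorithm] if grid is None else grid
    if not grid:
        return [PropensitySpec(algorithm, seed=seed)]
    keys = list(grid)
    return [
        PropensitySpec(algorithm, dict(zip(keys, combo)), seed=seed)
        for combo in itertools.product(*(grid[k] for k in keys))
    ]


@dataclass
class TuneResult:
    best: PropensitySpec
    best_loss: float
    losses: pd.DataFrame  # columns: estimator, log_loss


def tune_cv(
    sample: CombinedSample,
    grid: list[PropensitySpec],
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> TuneResult:
    """Pick the grid point with the lowest repeated-CV propensity log-loss.

    Stratified k-fold on z, repeated with reshuffled folds; the reported
    loss is the mean over repeats of the pooled out-of-fold log-loss. Ties
    are broken by grid order.
    """
    if not grid:
        raise InvalidArgumentError("hyperparameter grid is empty")
    if sample.n < folds:
        raise InvalidArgumentError("fewer units than CV folds")
    fold_seeds = np.random.default_rng(seed).integers(2**31 - 1, size=repeats)
    splits = []  # shared across grid points: paired comparison
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(fold_seeds[r]))
        splits.append(list(skf.split(sample.X, sample.z)))

    rows = []
    losses = []
    for spec in grid:
        repeat_losses = []
        for split in splits:
            oof = np.empty(sample.n)
            for train_idx, test_idx in split:
                model, _ = fit_propensity(sample.subset(train_idx), spec)
                oof[test_idx] = model.predict(
                    sample.covariates.iloc[test_idx]
                )
            repeat_losses.append(log_loss(sample.z, oof))
        mean_loss = float(np.mean(repeat_losses))
        losses.append(mean_loss)
        rows.append({"estimator": _estimator_label(spec), "log_loss": mean_loss})
    best_i = int(np.argmin(losses))
    return TuneResult(grid[best_i], losses[best_i], pd.DataFrame(rows))
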
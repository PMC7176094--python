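"""Drawing the reference and volunteer samples and stacking them.

The reference sample is a probability sample (SRSWOR) from the full
population, carrying design weights N/n_rs. The volunteer (convenience)
sample is drawn from the internet subpopulation either uniformly or with
age-driven self-selection probabilities

    logit_linear:  π(age) = 1 / (1 + exp(-1 + 0.05·age))
    logit_sine:    π(age) = 1 / (1 + exp(1 - sin(age / 20)))

and carries design weights 1. Both are stacked into a :class:`CombinedSample`
with the membership indicator z (1 = volunteer) on which propensity models
are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, SchemaError

__all__ = [
    "DrawnSample",
    "CombinedSample",
    "CovariateEncoder",
    "srswor",
    "selection_probability",
    "draw_convenience",
    "combine",
]

SELECTION_SCHEMES = ("srswor", "logit_linear", "logit_sine")


@dataclass
class DrawnSample:
    """A sample of rows with per-unit design weights.

    ``label`` is ``"reference"`` (weights N/n under SRSWOR) or
    ``"volunteer"`` (weights 1).
    """

    rows: pd.DataFrame
    design_weights: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.design_weights = np.asarray(self.design_weights, dtype=float)
        if len(self.rows) != len(self.design_weights):
            raise InvalidArgumentError("rows and design_weights lengths differ")
        if np.any(self.design_weights <= 0):
            raise InvalidArgumentError("design weights must be positive")
        if self.label not in ("reference", "volunteer"):
            raise InvalidArgumentError(f"unknown sample label {self.label!r}")

    def __len__(self) -> int:
        return len(self.rows)


class CovariateEncoder:
    """One-hot encoding with a frozen, sorted category order.

    Categorical columns expand to one dummy per level (levels sorted, fixed at
    fit time); numeric columns pass through. ``transform`` produces the same
    column layout for any subset of rows, which keeps train/test matrices
    aligned during cross-validation.
    """

    def __init__(self, frame: pd.DataFrame):
        self.numeric_columns: list[str] = []
        self.categorical_levels: dict[str, list[str]] = {}
        for col in frame.columns:
            if pd.api.types.is_numeric_dtype(frame[col]) and not pd.api.types.is_bool_dtype(
                frame[col]
            ):
                self.numeric_columns.append(col)
            else:
                levels = sorted(pd.unique(frame[col].astype(str)))
                self.categorical_levels[col] = levels
        self.columns: list[str] = []
        for col in frame.columns:
            if col in self.categorical_levels:
                self.columns.extend(
                    f"{col}={lvl}" for lvl in self.categorical_levels[col]
                )
            else:
                self.columns.append(col)

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        parts: dict[str, np.ndarray] = {}
        for col in self.categorical_levels:
            if col not in frame.columns:
                raise SchemaError(f"missing covariate column {col!r}")
            vals = frame[col].astype(str).to_numpy()
            for lvl in self.categorical_levels[col]:
                parts[f"{col}={lvl}"] = (vals == lvl).astype(float)
        for col in self.numeric_columns:
            if col not in frame.columns:
                raise SchemaError(f"missing covariate column {col!r}")
            parts[col] = frame[col].to_numpy(dtype=float)
        return pd.DataFrame(parts, index=frame.index)[self.columns]


@dataclass
class CombinedSample:
    """Stacked reference + volunteer units for propensity modelling.

    ``covariates`` is the raw covariate frame (reference rows first), ``X``
    the one-hot encoded matrix, ``z`` the membership indicator (1 for
    volunteer rows) and ``d`` the base design weights carried over from the
    two samples.
    """

    covariates: pd.DataFrame
    X: pd.DataFrame
    z: np.ndarray
    d: np.ndarray
    encoder: CovariateEncoder
    extra: pd.DataFrame = field(default=None, repr=False)  # non-covariate columns

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=int)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.covariates)
        if not (len(self.X) == len(self.z) == len(self.d) == n):
            raise InvalidArgumentError("combined sample components have unequal length")
        if not np.isin(self.z, (0, 1)).all():
            raise InvalidArgumentError("z must be binary")

    @property
    def n(self) -> int:
        return len(self.z)

    @property
    def n_vs(self) -> int:
        return int(self.z.sum())

    @property
    def n_rs(self) -> int:
        return int(self.n - self.z.sum())

    def volunteer_mask(self) -> np.ndarray:
        return self.z == 1

    def subset(self, idx) -> "CombinedSample":
        """Row subset sharing this sample's fitted encoder (for CV splits)."""
        idx = np.asarray(idx)
        return CombinedSample(
            self.covariates.iloc[idx].reset_index(drop=True),
            self.X.iloc[idx].reset_index(drop=True),
            self.z[idx],
            self.d[idx],
            self.encoder,
            None if self.extra is None else self.extra.iloc[idx].reset_index(drop=True),
        )


def srswor(table: pd.DataFrame, n: int, seed) -> DrawnSample:
    """Simple random sample without replacement, labelled as reference.

    Each of the ``len(table)`` rows has inclusion probability n/N, so the
    design weight is N/n for every drawn unit.
    """
    size = len(table)
    if not 1 <= n <= size:
        raise InvalidArgumentError(f"need 1 <= n <= {size}, got n={n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(size, size=n, replace=False)
    rows = table.iloc[np.sort(idx)].reset_index(drop=True)
    return DrawnSample(rows, np.full(n, size / n), "reference")


def selection_probability(age, scheme: str) -> np.ndarray:
    """Self-selection probability of an internet user as a function of age."""
    age = np.asarray(age, dtype=float)
    if scheme == "logit_linear":
        return 1.0 / (1.0 + np.exp(-1.0 + 0.05 * age))
    if scheme == "logit_sine":
        return 1.0 / (1.0 + np.exp(1.0 - np.sin(age / 20.0)))
    raise InvalidArgumentError(f"unknown selection scheme {scheme!r}")


def draw_convenience(
    internet_table: pd.DataFrame, scheme: str, n_vs: int, seed
) -> DrawnSample:
    """Draw the volunteer sample of fixed size n_vs from the internet pool.

    ``srswor`` draws uniformly. The two logit schemes draw without
    replacement with per-step selection probability proportional to the
    unit's self-selection probability π(age) among the units still in the
    pool (implemented with exponential sampling keys, which realises exactly
    that sequential scheme). Volunteer design weights are all 1.
    """
    size = len(internet_table)
    if not 1 <= n_vs <= size:
        raise InvalidArgumentError(f"need 1 <= n_vs <= {size}, got n_vs={n_vs}")
    if scheme not in SELECTION_SCHEMES:
        raise InvalidArgumentError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    if scheme == "srswor":
        idx = rng.choice(size, size=n_vs, replace=False)
    else:
        pi = selection_probability(internet_table["age"].to_numpy(), scheme)
        keys = rng.exponential(size=size) / pi
        idx = np.argpartition(keys, n_vs - 1)[:n_vs]
    rows = internet_table.iloc[np.sort(idx)].reset_index(drop=True)
    return DrawnSample(rows, np.ones(n_vs), "volunteer")


def combine(
    reference: DrawnSample,
    volunteer: DrawnSample,
    covariate_names: list[str],
) -> CombinedSample:
    """Stack the two samples into the propensity-modelling dataset.

    Reference rows come first with z = 0, then volunteer rows with z = 1.
    Base design weights are carried over unchanged; they play no role in
    propensity fitting and enter only the class-weighting adjustment.
    """
    if len(volunteer) == 0 or len(reference) == 0:
        raise InvalidArgumentError("both samples must be non-empty")
    if {reference.label, volunteer.label} != {"reference", "volunteer"}:
        raise InvalidArgumentError("expected one reference and one volunteer sample")
    for name, sample in (("reference", reference), ("volunteer", volunteer)):
        missing = [c for c in covariate_names if c not in sample.rows.columns]
        if missing:
            raise SchemaError(f"{name} sample missing covariate columns: {missing}")

    stacked = pd.concat(
        [reference.rows, volunteer.rows], ignore_index=True
    )
    covariates = stacked[covariate_names].reset_index(drop=True)
    extra = stacked.drop(columns=covariate_names)
    encoder = CovariateEncoder(covariates)
    X = encoder.transform(covariates)
    z = np.concatenate(
        [np.zeros(len(reference), dtype=int), np.ones(len(volunteer), dtype=int)]
    )
    d = np.concatenate([reference.design_weights, volunteer.design_weights])
    return CombinedSample(covariates, X, z, d, encoder, extra)
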
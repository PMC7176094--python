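"""Synthetic voter population with an internet-access selection structure.

The generator builds a finite population of ``n_pop`` adults whose age follows
a scaled Beta(2, 3) distribution (``age = 82x + 18``), together with gender,
nationality, education, internet access and three binary voting intentions.
The three parties encode three selection mechanisms with respect to an
internet-only volunteer sample:

* Party 1 depends only on gender, which is independent of internet access
  (missing completely at random, MCAR);
* Party 2 depends on age, which drives internet access (missing at random
  given covariates, MAR);
* Party 3 depends on internet access itself (not missing at random, NMAR).

Age strata are ``<35``, ``35–65`` (inclusive both ends) and ``>65``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyDomainError, InvalidArgumentError

__all__ = [
    "generate_population",
    "age_stratum",
    "true_proportion",
    "internet_population",
    "expected_internet_count",
    "stratum_masses",
    "save_population",
    "load_population",
    "COLUMNS",
    "PARTIES",
]

COLUMNS = [
    "age",
    "gender",
    "nationality",
    "education",
    "internet",
    "vote_p1",
    "vote_p2",
    "vote_p3",
]
PARTIES = ("p1", "p2", "p3")

AGE_MIN, AGE_MAX = 18.0, 100.0
_AGE_SCALE = AGE_MAX - AGE_MIN  # 82

# P(non-native | stratum), P(education | stratum), P(internet | nationality, stratum)
_P_NONNATIVE = np.array([0.15, 0.10, 0.025])
_P_EDUCATION = {
    # stratum -> (primary, secondary, higher)
    0: (0.35, 0.20, 0.45),
    1: (0.45, 0.25, 0.30),
    2: (0.80, 0.10, 0.10),
}
_P_INTERNET = {
    "native": np.array([0.90, 0.70, 0.50]),
    "non-native": np.array([0.20, 0.10, 0.00]),
}
_P_VOTE1_FEMALE = 0.20
_P_VOTE2 = np.array([0.0, 0.40, 0.60])
_P_VOTE3_OFFLINE = 0.10
_P_VOTE3_ONLINE = np.array([0.60, 0.40, 0.20])


def age_stratum(age: np.ndarray | pd.Series) -> np.ndarray:
    """Map ages to stratum indices 0 (<35), 1 (35–65), 2 (>65)."""
    age = np.asarray(age, dtype=float)
    return np.where(age < 35, 0, np.where(age <= 65, 1, 2)).astype(np.int64)


def stratum_masses() -> np.ndarray:
    """Analytic stratum probabilities implied by age = 82·Beta(2,3) + 18.

    These are the Beta(2, 3) CDF masses of the intervals split at ages 35
    and 65, i.e. at (35-18)/82 and (65-18)/82 on the unit interval.
    """
    cdf = stats.beta(2, 3).cdf
    lo = cdf((35 - AGE_MIN) / _AGE_SCALE)
    hi = cdf((65 - AGE_MIN) / _AGE_SCALE)
    return np.array([lo, hi - lo, 1.0 - hi])


def expected_internet_count(n_pop: int = 50_000) -> float:
    """Analytic expectation of the internet-subpopulation size.

    Sums P(stratum) · P(internet | nationality, stratum) over the joint
    nationality × stratum distribution; for n_pop = 50,000 this is ≈ 31,877.
    """
    mass = stratum_masses()
    p_net = (1 - _P_NONNATIVE) * _P_INTERNET["native"] + _P_NONNATIVE * _P_INTERNET[
        "non-native"
    ]
    return float(n_pop * np.sum(mass * p_net))


def generate_population(n_pop: int, seed: int) -> pd.DataFrame:
    """Generate the finite voter population.

    Parameters
    ----------
    n_pop : int
        Population size (the study uses 50,000).
    seed : int
        RNG seed; identical ``(n_pop, seed)`` yields an identical table.

    Returns
    -------
    pandas.DataFrame
        Columns ``age`` (float), ``gender``, ``nationality``, ``education``
        (categories) and boolean ``internet``, ``vote_p1``, ``vote_p2``,
        ``vote_p3``.
    """
    if n_pop < 1:
        raise InvalidArgumentError(f"n_pop must be >= 1, got {n_pop}")
    rng = np.random.default_rng(seed)

    age = _AGE_SCALE * rng.beta(2.0, 3.0, size=n_pop) + AGE_MIN
    stratum = age_stratum(age)

    nationality = np.where(
        rng.random(n_pop) < _P_NONNATIVE[stratum], "non-native", "native"
    )
    gender = np.where(rng.random(n_pop) < 0.5, "female", "male")

    edu_u = rng.random(n_pop)
    p_primary = np.array([_P_EDUCATION[s][0] for s in range(3)])[stratum]
    p_secondary = np.array([_P_EDUCATION[s][1] for s in range(3)])[stratum]
    education = np.where(
        edu_u < p_primary,
        "primary",
        np.where(edu_u < p_primary + p_secondary, "secondary", "higher"),
    )

    p_net = np.where(
        nationality == "native",
        _P_INTERNET["native"][stratum],
        _P_INTERNET["non-native"][stratum],
    )
    internet = rng.random(n_pop) < p_net

    vote_p1 = (gender == "female") & (rng.random(n_pop) < _P_VOTE1_FEMALE)
    vote_p2 = rng.random(n_pop) < _P_VOTE2[stratum]
    p3_rate = np.where(internet, _P_VOTE3_ONLINE[stratum], _P_VOTE3_OFFLINE)
    vote_p3 = rng.random(n_pop) < p3_rate

    return pd.DataFrame(
        {
            "age": age,
            "gender": pd.Categorical(gender, categories=["female", "male"]),
            "nationality": pd.Categorical(
                nationality, categories=["native", "non-native"]
            ),
            "education": pd.Categorical(
                education, categories=["higher", "primary", "secondary"]
            ),
            "internet": internet,
            "vote_p1": vote_p1,
            "vote_p2": vote_p2,
            "vote_p3": vote_p3,
        }
    )


def internet_population(pop: pd.DataFrame) -> pd.DataFrame:
    """The subpopulation with internet access (the pool volunteers come from)."""
    return pop.loc[pop["internet"]].reset_index(drop=True)


def true_proportion(
    pop: pd.DataFrame, party: str, domain: str = "all"
) -> float:
    """Exact finite-population voting fraction for one party within a domain.

    ``domain`` is one of ``all``, ``internet``, ``no_internet``. This is the
    truth p^k that simulated estimators are measured against.
    """
    if party not in PARTIES:
        raise InvalidArgumentError(f"unknown party {party!r}; expected one of {PARTIES}")
    if len(pop) == 0:
        raise EmptyDomainError("population table is empty")
    if domain == "all":
        sub = pop
    elif domain == "internet":
        sub = pop.loc[pop["internet"]]
    elif domain == "no_internet":
        sub = pop.loc[~pop["internet"]]
    else:
        raise InvalidArgumentError(f"unknown domain {domain!r}")
    if len(sub) == 0:
        raise EmptyDomainError(f"domain {domain!r} selects no rows")
    return float(sub[f"vote_{party}"].mean())


def save_population(pop: pd.DataFrame, path) -> None:
    """Write a population table as CSV, booleans encoded 0/1."""
    out = pop.copy()
    for col in ("internet", "vote_p1", "vote_p2", "vote_p3"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def load_population(path) -> pd.DataFrame:
    """Read a population CSV written by :func:`save_population`."""
    raw = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        from .exceptions import SchemaError

        raise SchemaError(f"population file missing columns: {missing}")
    return pd.DataFrame(
        {
            "age": raw["age"].astype(float),
            "gender": pd.Categorical(raw["gender"], categories=["female", "male"]),
            "nationality": pd.Categorical(
                raw["nationality"], categories=["native", "non-native"]
            ),
            "education": pd.Categorical(
                raw["education"], categories=["higher", "primary", "secondary"]
            ),
            "internet": raw["internet"].astype(bool),
            "vote_p1": raw["vote_p1"].astype(bool),
            "vote_p2": raw["vote_p2"].astype(bool),
            "vote_p3": raw["vote_p3"].astype(bool),
        }
    )
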
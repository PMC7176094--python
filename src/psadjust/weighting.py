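"""From propensities to adjusted volunteer weights and weighted estimates.

Two weighting schemes are supported:

* ``ht_class`` — Horvitz–Thompson-type stratified weights: the combined
  sample is sorted by π̂ and cut into C propensity classes (five by
  default); inside class c the adjustment factor

      f_c = (Σ_{k∈s_rc} d_k / Σ_{k∈s_r} d_k) / (Σ_{j∈s_vc} d_j / Σ_{j∈s_v} d_j)

  multiplies each volunteer's base weight, so total volunteer weight mass
  is conserved;
* ``hajek`` — inverse-odds weights w_j = (1 − π̂_j)/π̂_j on volunteer units,
  adjusting the volunteer sample towards the reference-sample population.

Estimates are normalised (Hajek-ratio) weighted means Σwy/Σw, so a
proportion always stays inside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateWeightsError,
    InvalidArgumentError,
    UnclippedPropensityError,
)
from .propensity import PropensityVector
from .sampling import CombinedSample

__all__ = [
    "PSAWeights",
    "stratify_by_propensity",
    "ht_class_weights",
    "hajek_weights",
    "weighted_proportion",
]


@dataclass
class PSAWeights:
    """Adjusted weights for the volunteer units.

    ``class_assignments`` (per combined-sample unit) and ``factors`` (per
    class) are populated only for the ``ht_class`` method.
    """

    w: np.ndarray
    method: str
    n_classes: int | None = None
    class_assignments: np.ndarray | None = None
    factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w <= 0):
            raise InvalidArgumentError("PSA weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.w)


def stratify_by_propensity(
    sample: CombinedSample, p: PropensityVector, n_classes: int = 5
) -> np.ndarray:
    """Assign every combined-sample unit to a propensity class.

    Class boundaries are the ``n_classes``-quantiles of the combined π̂
    distribution; intervals are right-closed with boundary ties kept in the
    lower class, so the assignment is monotone in π̂. If ties collapse some
    quantiles the effective number of classes shrinks and a warning is
    emitted.
    """
    if n_classes < 2:
        raise InvalidArgumentError(f"n_classes must be >= 2, got {n_classes}")
    if sample.n < n_classes:
        raise InvalidArgumentError("fewer units than requested classes")
    if len(p) != sample.n:
        raise InvalidArgumentError("propensity vector length mismatch")
    values = p.values
    inner = np.quantile(values, np.arange(1, n_classes) / n_classes)
    assignments = np.searchsorted(inner, values, side="left").astype(int)
    if len(np.unique(assignments)) < n_classes:
        warnings.warn(
            f"only {len(np.unique(assignments))} distinct propensity classes "
            f"out of {n_classes} requested (tied propensities)",
            stacklevel=2,
        )
    return assignments


def ht_class_weights(
    sample: CombinedSample,
    classes: np.ndarray,
    d: np.ndarray | None = None,
    n_classes: int | None = None,
) -> PSAWeights:
    """Horvitz–Thompson-type class-adjusted weights for volunteer units.

    A class holding volunteers but no reference weight (or vice versa) is
    merged with its neighbour toward the centre class, with a warning; the
    total volunteer weight mass Σ w equals Σ d over volunteers exactly.
    """
    classes = np.asarray(classes, dtype=int).copy()
    d = sample.d if d is None else np.asarray(d, dtype=float)
    if len(classes) != sample.n or len(d) != sample.n:
        raise InvalidArgumentError("classes/d length mismatch with sample")
    z = sample.z

    labels = np.unique(classes)
    centre = labels[len(labels) // 2]
    # merge one-sided classes toward the centre until every class is two-sided
    while True:
        labels = np.unique(classes)
        if len(labels) == 1:
            break
        bad = None
        for c in labels:
            mask = classes == c
            has_vol = np.any(mask & (z == 1))
            has_ref_wt = d[mask & (z == 0)].sum() > 0
            if not (has_vol and has_ref_wt):
                bad = c
                break
        if bad is None:
            break
        pos = int(np.flatnonzero(labels == bad)[0])
        if bad < centre:
            target = labels[pos + 1]
        elif bad > centre:
            target = labels[pos - 1]
        else:
            target = labels[pos - 1] if pos > 0 else labels[pos + 1]
        warnings.warn(
            f"propensity class {bad} lacks volunteer or reference mass; "
            f"merged into class {target}",
            stacklevel=2,
        )
        classes[classes == bad] = target

    ref_total = d[z == 0].sum()
    vol_total = d[z == 1].sum()
    if ref_total <= 0 or vol_total <= 0:
        raise DegenerateWeightsError("zero total design weight on one side")

    w = np.empty(int((z == 1).sum()))
    factors = {}
    vol_idx = np.flatnonzero(z == 1)
    for c in np.unique(classes):
        mask = classes == c
        ref_share = d[mask & (z == 0)].sum() / ref_total
        vol_share = d[mask & (z == 1)].sum() / vol_total
        f_c = ref_share / vol_share
        factors[c] = f_c
        sel = np.isin(vol_idx, np.flatnonzero(mask & (z == 1)))
        w[sel] = f_c * d[vol_idx[sel]]
    return PSAWeights(
        w,
        "ht_class",
        n_classes=len(factors),
        class_assignments=classes,
        factors=np.array([factors[c] for c in sorted(factors)]),
    )


def hajek_weights(p_volunteer: PropensityVector | np.ndarray) -> PSAWeights:
    """Inverse-odds weights w = (1 − π̂)/π̂ for volunteer units.

    Propensities must lie strictly inside (0, 1); apply
    :func:`psadjust.propensity.clip_propensities` first if any raw propensity
    is exactly 0 or 1.
    """
    values = (
        p_volunteer.values
        if isinstance(p_volunteer, PropensityVector)
        else np.asarray(p_volunteer, dtype=float)
    )
    if np.any(values <= 0) or np.any(values >= 1):
        raise UnclippedPropensityError(
            "propensities must be strictly in (0, 1); clip them first"
        )
    return PSAWeights((1.0 - values) / values, "hajek")


def weighted_proportion(y, weights: PSAWeights | np.ndarray) -> float:
    """Normalised weighted mean Σ w·y / Σ w of a binary outcome."""
    y = np.asarray(y, dtype=float)
    w = weights.w if isinstance(weights, PSAWeights) else np.asarray(weights, dtype=float)
    if len(y) != len(w):
        raise InvalidArgumentError("y and weights must be aligned")
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("total weight is zero")
    return float(np.dot(w, y) / total)
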
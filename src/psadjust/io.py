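"""Tabular I/O, configuration files, manifests and small test fixtures.

The single tabular dialect is headered CSV (comma separator, UTF-8,
booleans encoded 0/1). Study configuration files may be YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidArgumentError, SchemaError
from .population import generate_population
from .propensity import PropensityVector
from .sampling import CombinedSample, DrawnSample, combine
from .weighting import PSAWeights

logger = logging.getLogger("psadjust")

__all__ = [
    "load_tabular",
    "load_config",
    "make_fixture",
    "export_propensities",
    "export_weights",
    "write_manifest",
]


def _package_version() -> str:
    try:
        return version("psadjust")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        return "unknown"


def load_tabular(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a headered CSV and type its columns against a schema.

    ``schema`` maps column names to ``"numeric"``, ``"category"`` or
    ``"binary"``; columns not named are left as parsed. Raises
    :class:`SchemaError` naming any missing column, and a row-level
    :class:`SchemaError` with the offending line number on unparseable cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise InvalidArgumentError(f"empty input file: {path}")
    table = pd.read_csv(path)
    if table.empty:
        raise InvalidArgumentError(f"no data rows in {path}")
    for col, kind in (schema or {}).items():
        if col not in table.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
        if kind == "numeric":
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise SchemaError(
                    f"unparseable numeric value in column {col!r} at line {line} of {path}"
                )
            table[col] = coerced
        elif kind == "binary":
            vals = pd.to_numeric(table[col], errors="coerce")
            if not vals.isin([0, 1]).all():
                bad = ~vals.isin([0, 1])
                line = int(bad.idxmax()) + 2
                raise SchemaError(
                    f"non-binary value in column {col!r} at line {line} of {path}"
                )
            table[col] = vals.astype(bool)
        elif kind == "category":
            table[col] = table[col].astype("category")
        else:
            raise InvalidArgumentError(f"unknown schema kind {kind!r} for {col!r}")
    logger.info("loaded %d rows from %s", len(table), path)
    return table


def load_config(path) -> dict:
    """Read a YAML or JSON study configuration into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def make_fixture(kind: str, seed: int = 0):
    """Deterministic small datasets used by tests and examples.

    * ``toy_combined`` — a 12-unit combined sample (6 volunteer, 6
      reference) with one binary covariate, suited to exhaustive k-NN /
      Naive-Bayes hand computations;
    * ``toy_separable`` — two pure cells: volunteers all at x=1, reference
      all at x=0;
    * ``mini_population`` — ``generate_population(2000, seed)``.
    """
    if kind == "mini_population":
        return generate_population(2000, seed)
    if kind == "toy_combined":
        rng = np.random.default_rng(seed)
        x_ref = (rng.random(6) < 0.3).astype(int)
        x_vol = (rng.random(6) < 0.7).astype(int)
        ref = DrawnSample(pd.DataFrame({"x": x_ref.astype(str)}), np.ones(6), "reference")
        vol = DrawnSample(pd.DataFrame({"x": x_vol.astype(str)}), np.ones(6), "volunteer")
        return combine(ref, vol, ["x"])
    if kind == "toy_separable":
        ref = DrawnSample(pd.DataFrame({"x": ["0"] * 6}), np.ones(6), "reference")
        vol = DrawnSample(pd.DataFrame({"x": ["1"] * 6}), np.ones(6), "volunteer")
        return combine(ref, vol, ["x"])
    raise InvalidArgumentError(f"unknown fixture kind {kind!r}")


def export_propensities(
    sample: CombinedSample, raw: PropensityVector, clipped: PropensityVector, path
) -> None:
    """Write per-unit propensities as CSV (row id, z, raw, clipped)."""
    pd.DataFrame(
        {
            "unit": np.arange(sample.n),
            "z": sample.z,
            "propensity_raw": raw.values,
            "propensity_clipped": clipped.values,
        }
    ).to_csv(path, index=False)


def export_weights(
    sample: CombinedSample, weights: PSAWeights, path, p: PropensityVector | None = None
) -> None:
    """Write volunteer weights as CSV (unit id, π̂, class, factor, w)."""
    vol_idx = np.flatnonzero(sample.z == 1)
    out = {"unit": vol_idx, "w": weights.w}
    if p is not None:
        out["propensity"] = p.values[vol_idx]
    if weights.class_assignments is not None:
        cls = weights.class_assignments[vol_idx]
        out["class"] = cls
        labels = sorted(set(weights.class_assignments.tolist()))
        fmap = dict(zip(labels, weights.factors))
        out["factor"] = [fmap[c] for c in cls]
    pd.DataFrame(out).to_csv(path, index=False)


def write_manifest(out_dir, config: dict, seed) -> Path:
    """Record the run configuration (hash), seed and package version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "package_version": _package_version(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
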
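"""CSV/JSON plumbing: samples, stratum tables, run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .strata import StratifiedSample, StratumTable, assign_strata, build_stratum_table

__all__ = [
    "read_sample",
    "write_sample",
    "write_stratum_table",
    "read_stratum_table_values",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"  # round-trip fidelity for doubles


def read_sample(path, outcome: str, stratum_feature: str,
                features: Sequence[str] | None = None) -> StratifiedSample:
    """Read a learning table from CSV and derive strata.

    The header must name the outcome and stratum columns; all remaining
    columns (or an explicit ``features`` list) are numeric main features.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path} is empty") from None
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    for col in (outcome, stratum_feature):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if features is None:
        features = [c for c in df.columns
                    if c not in (outcome, stratum_feature, "provenance")]
    for col in features:
        if col not in df.columns:
            raise ValueError(f"feature column {col!r} not found in {path}")
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any() and not df[col].isna().any():
            raise ValueError(f"feature column {col!r} contains non-numeric values")
        df[col] = parsed
    return assign_strata(df.drop(columns=["provenance"], errors="ignore"),
                         outcome, stratum_feature, features)


def write_sample(sample: StratifiedSample, path) -> None:
    """Write a (corrected) sample to CSV including its provenance."""
    df = sample.data.copy()
    df["provenance"] = sample.provenance
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_stratum_table(table: StratumTable, path) -> None:
    Path(path).write_text(json.dumps(table.to_json_dict(), indent=2) + "\n")


def read_stratum_table_values(path) -> dict:
    """Read per-stratum values (N_h or p_select) keyed by (level, outcome).

    Accepts either the table format written by :func:`write_stratum_table`
    or a flat mapping {"level,outcome": value}.
    """
    raw = json.loads(Path(path).read_text())
    out_N, out_p = {}, {}
    for key, val in raw.items():
        if isinstance(val, Mapping) and "stratum" in val:
            cell = tuple(val["stratum"])
            if val.get("N_h") is not None:
                out_N[cell] = val["N_h"]
            if val.get("p_select") is not None:
                out_p[cell] = val["p_select"]
        else:
            parts = key.split(",")
            cell = tuple(_coerce(p) for p in parts)
            out_N[cell] = val
    return {"population_counts": out_N or None, "p_select": out_p or None}


def _coerce(text: str):
    text = text.strip()
    try:
        f = float(text)
        return int(f) if f == int(f) else f
    except ValueError:
        return text


def write_manifest(path, config: Mapping, seed) -> str:
    """Write a JSON run manifest (config, seed, versions) and return its hash."""
    import sklearn

    import twophase

    manifest = {
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "versions": {
            "twophase": twophase.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    text = json.dumps(manifest, indent=2, sort_keys=True, default=str)
    manifest["hash"] = hashlib.sha256(text.encode()).hexdigest()
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")
    return manifest["hash"]
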
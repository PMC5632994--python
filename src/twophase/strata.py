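"""Strata, selection probabilities and inverse-probability weights.

In a two-phase case-control study the sample is drawn by enriching both a
rare binary outcome ``y`` and a rare categorical exposure ``x_e``.  All
observations sharing the same ``(x_e, y)`` cell were selected with the same
probability; such a cell is a *stratum*.  Given per-stratum sample sizes
``n_h`` and population sizes ``N_h`` (or the selection probabilities
``P(S=1|h) = n_h/N_h`` directly), the integer inverse-probability weight

    w_h = [ max_h' P(S=1|h') / P(S=1|h) ]

(rounded to the closest integer, never below 1) is the replication factor
that restores the population stratum proportions while keeping the number
of newly generated observations minimal.  The reweighted sample size is
``n' = sum_h n_h * w_h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StratifiedSample",
    "StratumTable",
    "assign_strata",
    "selection_probabilities",
    "ip_weights",
    "reweighted_size",
    "build_stratum_table",
]


@dataclass
class StratifiedSample:
    """A learning table with derived stratum labels.

    Rows carry a binary outcome, one categorical stratum feature (the
    exposure) and ``p`` numeric main features.  ``stratum_id`` maps every
    row to an integer ``1..H`` determined by its ``(stratum level, outcome)``
    cell, in lexicographic cell order.
    """

    data: pd.DataFrame
    outcome: str
    stratum_feature: str
    features: list[str]
    stratum_id: np.ndarray
    strata: list[tuple[Any, Any]]  # ordered (stratum level, outcome) cells
    provenance: str = "original"

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def y(self) -> np.ndarray:
        """Outcome recoded to {0, 1} by sorted level order."""
        levels = sorted(pd.unique(self.data[self.outcome]))
        if len(levels) == 1:
            return np.zeros(self.n, dtype=int)
        return (self.data[self.outcome].to_numpy() == levels[1]).astype(int)

    def stratum_counts(self) -> pd.Series:
        """Sample size n_h per stratum id, zero-filled for empty strata."""
        counts = pd.Series(self.stratum_id).value_counts().sort_index()
        return counts.reindex(range(1, len(self.strata) + 1), fill_value=0)

    def feature_matrix(self) -> np.ndarray:
        """Main features as an (n, p) float array."""
        return self.data[self.features].to_numpy(dtype=float)

    def design_frame(self) -> pd.DataFrame:
        """Predictors for classifiers: encoded stratum feature + main features.

        The stratum feature is encoded to integer codes in sorted level
        order (a 0/1 exposure stays 0/1).
        """
        xe = self.data[self.stratum_feature]
        levels = sorted(pd.unique(xe))
        codes = xe.map({lev: i for i, lev in enumerate(levels)})
        out = pd.DataFrame({self.stratum_feature: codes.to_numpy(dtype=float)},
                           index=self.data.index)
        for c in self.features:
            out[c] = self.data[c].to_numpy(dtype=float)
        return out

    def take(self, indices: np.ndarray, provenance: str | None = None) -> "StratifiedSample":
        """Row-subset/replicate the sample, keeping stratum bookkeeping."""
        idx = np.asarray(indices)
        return replace(
            self,
            data=self.data.iloc[idx].reset_index(drop=True),
            stratum_id=self.stratum_id[idx],
            provenance=self.provenance if provenance is None else provenance,
        )

    def with_features(self, values: np.ndarray, provenance: str) -> "StratifiedSample":
        """Return a copy with the main-feature block replaced."""
        data = self.data.copy()
        data[self.features] = values
        return replace(self, data=data, provenance=provenance)


@dataclass
class StratumTable:
    """Per-stratum bookkeeping: n_h, N_h, P(S=1|h), integer weight w_h.

    ``raw_ratio`` keeps the unrounded ratio max p / p for diagnostics when
    rounding error matters.
    """

    table: pd.DataFrame  # index stratum_id; columns n_h, N_h, p_select, w_h, raw_ratio
    strata: list[tuple[Any, Any]] = field(default_factory=list)

    @property
    def n_h(self) -> np.ndarray:
        return self.table["n_h"].to_numpy()

    @property
    def w_h(self) -> np.ndarray:
        return self.table["w_h"].to_numpy()

    @property
    def p_select(self) -> np.ndarray:
        return self.table["p_select"].to_numpy()

    @property
    def n_prime(self) -> int:
        return reweighted_size(self.n_h, self.w_h)

    def weight_of(self, stratum_id: np.ndarray) -> np.ndarray:
        """Per-row weight lookup for an array of stratum ids."""
        w = self.table["w_h"]
        missing = set(np.unique(stratum_id)) - set(w.index)
        if missing:
            raise ValueError(f"strata {sorted(missing)} missing from the stratum table")
        return w.reindex(stratum_id).to_numpy()

    def to_json_dict(self) -> dict:
        recs = {}
        for sid, row in self.table.iterrows():
            level, outcome = self.strata[sid - 1] if self.strata else (None, None)
            recs[str(sid)] = {
                "stratum": [level, outcome],
                "n_h": int(row["n_h"]),
                "N_h": None if pd.isna(row["N_h"]) else float(row["N_h"]),
                "p_select": float(row["p_select"]),
                "w_h": int(row["w_h"]),
            }
        return recs


def assign_strata(
    data: pd.DataFrame,
    outcome: str,
    stratum_feature: str,
    features: Sequence[str] | None = None,
) -> StratifiedSample:
    """Derive stratum labels from the (stratum feature, outcome) cells.

    Stratum ids are 1-based and follow the lexicographic order of the
    observed ``(stratum level, outcome)`` cells, so the labelling is a
    deterministic function of the two columns.
    """
    for col in (outcome, stratum_feature):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not present in the data")
        if data[col].isna().any():
            raise ValueError(f"column {col!r} contains missing values")
    y = data[outcome]
    n_levels = y.nunique()
    if n_levels > 2:
        raise ValueError(
            f"outcome {outcome!r} must be binary; found {n_levels} distinct values"
        )
    if pd.api.types.is_float_dtype(data[stratum_feature]) and \
            data[stratum_feature].nunique() > max(32, len(data) // 10):
        raise ValueError(
            "stratum feature looks continuous; strata require a categorical "
            "feature with shared selection probabilities"
        )
    if features is None:
        features = [c for c in data.columns if c not in (outcome, stratum_feature)]
    features = list(features)
    observed = set(zip(data[stratum_feature], y))
    try:
        cells = sorted(observed)
    except TypeError:  # mixed-type levels: fall back to string order
        cells = sorted(observed, key=lambda t: (str(t[0]), str(t[1])))
    cell_to_id = {cell: i + 1 for i, cell in enumerate(cells)}
    ids = np.array([cell_to_id[c] for c in zip(data[stratum_feature], y)], dtype=int)
    return StratifiedSample(
        data=data.reset_index(drop=True).copy(),
        outcome=outcome,
        stratum_feature=stratum_feature,
        features=features,
        stratum_id=ids,
        strata=cells,
    )


def selection_probabilities(n_h: Sequence[float], N_h: Sequence[float]) -> np.ndarray:
    """Per-stratum selection probability P(S=1|h) = n_h / N_h."""
    n = np.asarray(n_h, dtype=float)
    N = np.asarray(N_h, dtype=float)
    if n.shape != N.shape:
        raise ValueError("n_h and N_h must have the same length")
    if np.any(N <= 0):
        raise ValueError("population counts N_h must be positive")
    if np.any(n <= 0):
        raise ValueError("sample counts n_h must be positive")
    if np.any(n > N):
        raise ValueError("n_h cannot exceed N_h")
    return n / N


def ip_weights(p_select: Sequence[float]) -> np.ndarray:
    """Integer IP weights w_h = round(max_h' p(h') / p(h)), floored at 1.

    Rounding is half-away-from-zero (a ratio of exactly x.5 rounds up), and
    the most-selected stratum always receives weight 1.
    """
    p = np.asarray(p_select, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("selection probabilities must lie in (0, 1]")
    ratio = p.max() / p
    w = np.floor(ratio + 0.5).astype(int)  # half-away-from-zero for positive ratios
    return np.maximum(w, 1)


def reweighted_size(n_h: Sequence[int], w_h: Sequence[int]) -> int:
    """Total reweighted sample size n' = sum_h n_h * w_h."""
    n = np.asarray(n_h)
    w = np.asarray(w_h)
    if n.shape != w.shape:
        raise ValueError("n_h and w_h must have the same length")
    return int(np.sum(n * w))


def build_stratum_table(
    sample: StratifiedSample,
    population_counts: Mapping[tuple, float] | Sequence[float] | None = None,
    p_select: Mapping[tuple, float] | Sequence[float] | None = None,
) -> StratumTable:
    """Assemble the per-stratum table of counts, probabilities and weights.

    Either population counts ``N_h`` or selection probabilities may be
    supplied, keyed by ``(stratum level, outcome)`` or given as a sequence
    aligned with the sample's stratum order.  If both are given they must
    agree to a relative tolerance of 1e-9.
    """
    if population_counts is None and p_select is None:
        raise ValueError("either population_counts or p_select is required")
    n_h = sample.stratum_counts().to_numpy()
    if np.any(n_h == 0):
        raise ValueError("every stratum must contain at least one sampled row")

    N = _aligned(population_counts, sample.strata) if population_counts is not None else None
    p = _aligned(p_select, sample.strata) if p_select is not None else None
    if N is not None:
        p_from_counts = selection_probabilities(n_h, N)
        if p is not None:
            if not np.allclose(p, p_from_counts, rtol=1e-9, atol=0):
                raise ValueError(
                    "supplied selection probabilities are inconsistent with n_h/N_h"
                )
        p = p_from_counts
    assert p is not None
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("selection probabilities must lie in (0, 1]")
    w = ip_weights(p)
    table = pd.DataFrame(
        {
            "n_h": n_h,
            "N_h": N if N is not None else np.nan,
            "p_select": p,
            "w_h": w,
            "raw_ratio": p.max() / p,
        },
        index=pd.RangeIndex(1, len(n_h) + 1, name="stratum_id"),
    )
    return StratumTable(table=table, strata=list(sample.strata))


def _aligned(values, strata: list[tuple]) -> np.ndarray:
    if isinstance(values, Mapping):
        missing = [c for c in strata if c not in values]
        if missing:
            raise ValueError(f"values missing for strata {missing}")
        return np.array([float(values[c]) for c in strata])
    arr = np.asarray(values, dtype=float)
    if arr.shape != (len(strata),):
        raise ValueError(
            f"expected {len(strata)} per-stratum values, got shape {arr.shape}"
        )
    return arr
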
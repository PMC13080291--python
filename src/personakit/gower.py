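"""Weighted Gower dissimilarity for mixed-type survey records.

The distance between two respondents is

    d(x, y) = sum_v w_v * delta_v(x, y) / sum_v w_v

with per-variable contributions delta_v = 1{x_v != y_v} for categorical
variables and |x_v - y_v| / range_v for numeric variables (range frozen at
spec construction; a constant variable contributes 0).  Weights enter both
sums, so distances stay in [0, 1] and are invariant to rescaling all
weights.  Under the default pairwise-deletion policy a variable missing in
either record is dropped from both sums; under "penalize" it contributes a
full mismatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedDistanceError
from .survey_io import SurveyDataset, SurveySchema, is_missing

MISSING_POLICIES = ("pairwise-deletion", "penalize")


@dataclass(frozen=True)
class DistanceSpec:
    """Distance configuration: which variables, weights, ranges, missing policy."""

    schema: SurveySchema
    missing_policy: str = "pairwise-deletion"
    numeric_ranges: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.missing_policy not in MISSING_POLICIES:
            raise SchemaError(f"unknown missing policy {self.missing_policy!r}")
        if not any(v.weight > 0 for v in self.schema.variables):
            raise SchemaError("at least one variable must have positive weight")
        object.__setattr__(self, "numeric_ranges", dict(self.numeric_ranges))

    @classmethod
    def from_dataset(
        cls,
        dataset: SurveyDataset,
        variables: Sequence[str] | None = None,
        missing_policy: str = "pairwise-deletion",
    ) -> "DistanceSpec":
        """Build a spec, freezing numeric ranges (max - min) from the data."""
        schema = dataset.schema if variables is None else dataset.schema.subset(variables)
        ranges = {}
        for v in schema.variables:
            if v.kind == "numeric":
                if v.numeric_range is not None:
                    ranges[v.name] = float(v.numeric_range[1] - v.numeric_range[0])
                else:
                    col = dataset.data[v.name].astype(float)
                    ranges[v.name] = float(np.nanmax(col) - np.nanmin(col)) if col.notna().any() else 0.0
        return cls(schema=schema, missing_policy=missing_policy, numeric_ranges=ranges)

    @property
    def names(self) -> tuple[str, ...]:
        return self.schema.names

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.schema.variables], dtype=float)

    @property
    def is_categorical(self) -> np.ndarray:
        return np.array([v.kind == "categorical" for v in self.schema.variables])

    @property
    def ranges(self) -> np.ndarray:
        return np.array(
            [self.numeric_ranges.get(v.name, 0.0) if v.kind == "numeric" else 0.0
             for v in self.schema.variables], dtype=float)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal, entries in [0,1]."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        object.__setattr__(self, "values", vals)

    def loc(self, i, j) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.ids),
                     columns=list(self.ids)).to_csv(path)


# ---------------------------------------------------------------------------
# Encoding and vectorized distance kernels
# ---------------------------------------------------------------------------

def encode_records(df: pd.DataFrame, spec: DistanceSpec) -> np.ndarray:
    """Encode records as an (n, p) float matrix; NaN marks missing.

    Categorical values become their category index (schema order); numeric
    values stay as floats.  Raises on out-of-vocabulary categories.
    """
    cols = []
    for v in spec.schema.variables:
        col = df[v.name]
        if v.kind == "categorical":
            codes = pd.Categorical(col, categories=v.categories).codes.astype(float)
            bad = (codes < 0) & col.notna().to_numpy()
            if bad.any():
                raise SchemaError(
                    f"{v.name}: value {col[bad].iloc[0]!r} not in categories")
            codes[codes < 0] = np.nan
            cols.append(codes)
        else:
            cols.append(pd.to_numeric(col).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def encode_record(record: Mapping, spec: DistanceSpec) -> np.ndarray:
    """Encode a single record (mapping variable -> value) to a length-p row."""
    row = np.empty(len(spec.names))
    for j, v in enumerate(spec.schema.variables):
        val = record.get(v.name, None)
        if is_missing(val):
            row[j] = np.nan
        elif v.kind == "categorical":
            try:
                row[j] = v.categories.index(val)
            except ValueError:
                raise SchemaError(f"{v.name}: value {val!r} not in categories") from None
        else:
            row[j] = float(val)
    return row


def cross_gower(Xa: np.ndarray, Xb: np.ndarray, spec: DistanceSpec) -> np.ndarray:
    """All weighted Gower distances between rows of ``Xa`` and rows of ``Xb``.

    Returns an (na, nb) matrix; entries with no jointly observed variable
    (pairwise-deletion) are NaN.
    """
    w = spec.weights
    is_cat = spec.is_categorical
    ranges = spec.ranges
    penalize = spec.missing_policy == "penalize"
    na, nb = Xa.shape[0], Xb.shape[0]
    num = np.zeros((na, nb))
    den = np.zeros((na, nb))
    for j in range(Xa.shape[1]):
        a = Xa[:, j][:, None]
        b = Xb[:, j][None, :]
        obs = ~np.isnan(a) & ~np.isnan(b)
        if is_cat[j]:
            delta = (a != b).astype(float)
        else:
            rng = ranges[j]
            delta = np.abs(a - b) / rng if rng > 0 else np.zeros((na, nb))
        if penalize:
            delta = np.where(obs, delta, 1.0)
            num += w[j] * delta
            den += w[j]
        else:
            num += w[j] * np.where(obs, delta, 0.0)
            den += w[j] * obs
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    return d


def gower(x: Mapping, y: Mapping, spec: DistanceSpec) -> float:
    """Weighted Gower distance between two respondent records, in [0, 1]."""
    d = cross_gower(encode_record(x, spec)[None, :],
                    encode_record(y, spec)[None, :], spec)[0, 0]
    if np.isnan(d):
        raise UndefinedDistanceError(
            "no jointly observed variable between records under pairwise deletion")
    return float(d)


def pairwise_distances(dataset: SurveyDataset, spec: DistanceSpec) -> DistanceMatrix:
    """Full pairwise :class:`DistanceMatrix` over a dataset (>= 2 records)."""
    if len(dataset) < 2:
        raise ValueError("need at least two records")
    X = encode_records(dataset.data, spec)
    D = cross_gower(X, X, spec)
    if np.isnan(D).any():
        warnings.warn("some record pairs share no observed variable; "
                      "their distances are undefined (NaN)")
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry despite float summation order
    return DistanceMatrix(ids=tuple(dataset.ids), values=D)
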
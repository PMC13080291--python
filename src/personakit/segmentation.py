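"""Demographic overrepresentation segmentation of clusters.

For each cluster, a three-way contingency table (default axes: age group x
sex x race/ethnicity) compares the cluster's demographic composition with
the full sample.  A cell's expected count under demographic-independent
cluster assignment is cluster_size * survey_count / N, and the
observed/expected (O/E) percentage is 100 * observed / expected, rounded
half away from zero.  Cells significantly overrepresented (one-sided exact
binomial tail below alpha, with a minimum observed count and a per-cluster
cap) become persona segments; a cluster with no flagged cell yields one
whole-cluster segment at its modal demographic cell.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InconsistencyError
from .survey_io import SurveyDataset

DEFAULT_AXES = ("age_group", "sex", "race_ethnicity")


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention behind printed O/E values)."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def observed_expected(cluster_count: int, survey_count: int,
                      cluster_size: int, N: int) -> int:
    """Integer O/E percentage: round(100 * observed / expected), half away from 0.

    A zero survey count with zero observed yields 0; zero survey count with
    a positive observed count is inconsistent.
    """
    if N <= 0 or cluster_size <= 0:
        raise ValueError("N and cluster_size must be positive")
    if survey_count == 0:
        if cluster_count == 0:
            return 0
        raise InconsistencyError("cluster_count > 0 in a cell with survey_count = 0")
    if cluster_count == 0:
        return 0
    expected = cluster_size * survey_count / N
    return int(round_half_away(100.0 * cluster_count / expected))


@dataclass(frozen=True)
class SegmentTable:
    """Per-cluster contingency table with O/E percentages and flags.

    ``cells`` has one row per demographic cell: the axis values, the
    full-sample count, the in-cluster count, the expected count, the O/E
    percentage, a one-sided binomial p-value (NaN until flagged), and a
    boolean flag.
    """

    cluster_id: int | str
    axes: tuple[str, ...]
    cells: pd.DataFrame
    cluster_size: int
    total_n: int
    n_missing_cluster: int = 0
    n_missing_survey: int = 0

    def __post_init__(self):
        required = list(self.axes) + ["survey_count", "cluster_count",
                                      "expected", "oe_pct", "p_value", "flag"]
        missing = [c for c in required if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cells missing columns {missing}")
        object.__setattr__(self, "cells", self.cells.reset_index(drop=True))

    @classmethod
    def from_counts(
        cls,
        cluster_id,
        axes: Sequence[str],
        counts: pd.DataFrame,
        cluster_size: int,
        total_n: int,
    ) -> "SegmentTable":
        """Build a table from precomputed (survey_count, cluster_count) cells.

        Used for printed-table fixtures where the respondent-level data are
        not available.
        """
        cells = counts.copy().reset_index(drop=True)
        cells["expected"] = cluster_size * cells["survey_count"] / total_n
        cells["oe_pct"] = [
            observed_expected(int(c), int(s), cluster_size, total_n)
            for c, s in zip(cells["cluster_count"], cells["survey_count"])
        ]
        cells["p_value"] = np.nan
        cells["flag"] = False
        return cls(cluster_id=cluster_id, axes=tuple(axes), cells=cells,
                   cluster_size=cluster_size, total_n=total_n)

    def flagged(self) -> pd.DataFrame:
        return self.cells[self.cells["flag"]]


def joint_table(
    dataset: SurveyDataset,
    assignments: Mapping,
    cluster_id,
    axes: Sequence[str] = DEFAULT_AXES,
) -> SegmentTable:
    """Joint demographic table of a cluster against the full sample.

    Cells cover the full category product of the axes; respondents missing
    any axis value are excluded from the counts (tracked separately).
    """
    for a in axes:
        if a not in dataset.schema:
            raise ConfigurationError(f"unknown axis variable {a!r}")
        if dataset.schema[a].kind != "categorical":
            raise ConfigurationError(f"axis variable {a!r} is not categorical")
    axes = tuple(axes)
    df = dataset.data
    observed_mask = df[list(axes)].notna().all(axis=1)
    member_ids = [i for i, c in assignments.items() if c == cluster_id]
    member_mask = df.index.isin(member_ids)
    survey = df.loc[observed_mask, list(axes)]
    cluster = df.loc[observed_mask & member_mask, list(axes)]
    total_n = len(survey)
    cluster_size = len(cluster)
    levels = [dataset.schema[a].categories for a in axes]
    rows = []
    s_counts = survey.groupby(list(axes), observed=True).size()
    c_counts = cluster.groupby(list(axes), observed=True).size()
    for combo in itertools.product(*levels):
        key = combo if len(combo) > 1 else combo[0]
        rows.append({**dict(zip(axes, combo)),
                     "survey_count": int(s_counts.get(key, 0)),
                     "cluster_count": int(c_counts.get(key, 0))})
    counts = pd.DataFrame(rows)
    table = SegmentTable.from_counts(cluster_id, axes, counts, cluster_size, total_n)
    return replace(
        table,
        n_missing_cluster=int(sum(1 for i in member_ids) - cluster_size),
        n_missing_survey=int(len(df) - total_n),
    )


@dataclass(frozen=True)
class FlagPolicy:
    """Overrepresentation flagging rule.

    A cell is flagged when its one-sided exact binomial tail probability
    P(X >= cluster_count), X ~ Binomial(cluster_size, survey_count / N),
    falls below ``alpha`` and its observed count reaches ``min_count``; at
    most ``max_per_cluster`` lowest-p cells are kept per cluster.
    """

    alpha: float = 0.05
    min_count: int = 5
    max_per_cluster: int = 4


def binomial_tail(cluster_count: int, cluster_size: int, cell_prob: float) -> float:
    """One-sided exact tail P(X >= cluster_count), X ~ Bin(cluster_size, p)."""
    if cluster_count <= 0:
        return 1.0
    return float(stats.binom.sf(cluster_count - 1, cluster_size, cell_prob))


def flag_cells(table: SegmentTable, policy: FlagPolicy = FlagPolicy()) -> SegmentTable:
    """Return a copy of the table with p-values and overrepresentation flags."""
    cells = table.cells.copy()
    p_values = []
    for _, row in cells.iterrows():
        prob = row["survey_count"] / table.total_n if table.total_n else 0.0
        p_values.append(binomial_tail(int(row["cluster_count"]),
                                      table.cluster_size, prob))
    cells["p_value"] = p_values
    eligible = (cells["p_value"] < policy.alpha) & \
               (cells["cluster_count"] >= policy.min_count)

    # deterministic ranking: p ascending, larger observed count first, then the
    # cell's position in axis category order (so the result is invariant to
    # the physical row order of the table)
    def cell_key(i):
        return tuple(str(cells.at[i, a]) for a in table.axes)

    order = cells.index[eligible].tolist()
    order.sort(key=lambda i: (cells.at[i, "p_value"],
                              -cells.at[i, "cluster_count"], cell_key(i)))
    keep = set(order[: policy.max_per_cluster])
    cells["flag"] = [i in keep for i in cells.index]
    return replace(table, cells=cells)


@dataclass(frozen=True)
class SegmentSpec:
    """A persona segment: a demographic cell within a cluster."""

    cluster_id: int | str
    demographic_cell: Mapping[str, str]
    member_ids: tuple
    rank: int
    whole_cluster: bool = False


def make_segments(
    table: SegmentTable,
    assignments: Mapping,
    dataset: SurveyDataset,
) -> list[SegmentSpec]:
    """One segment per flagged cell (in flag rank order); if no cell is
    flagged, a single whole-cluster segment at the cluster's modal cell."""
    member_ids = [i for i, c in assignments.items() if c == table.cluster_id]
    df = dataset.data.loc[[i for i in member_ids if i in dataset.data.index]]
    flagged = table.flagged()
    flagged = flagged.sort_values(["p_value", "cluster_count"],
                                  ascending=[True, False], kind="stable")
    segments: list[SegmentSpec] = []
    if len(flagged):
        for rank, (_, row) in enumerate(flagged.iterrows(), start=1):
            cell = {a: row[a] for a in table.axes}
            mask = pd.Series(True, index=df.index)
            for a, v in cell.items():
                mask &= df[a] == v
            segments.append(SegmentSpec(
                cluster_id=table.cluster_id, demographic_cell=cell,
                member_ids=tuple(df.index[mask]), rank=rank))
        return segments
    # fallback: whole cluster at its modal joint cell
    observed = df.dropna(subset=list(table.axes))
    if len(observed):
        top = observed.groupby(list(table.axes), observed=True).size().idxmax()
        top = (top,) if not isinstance(top, tuple) else top
        cell = dict(zip(table.axes, top))
    else:
        cell = {a: None for a in table.axes}
    return [SegmentSpec(cluster_id=table.cluster_id, demographic_cell=cell,
                        member_ids=tuple(df.index), rank=1, whole_cluster=True)]


def export_tables(tables: Sequence[SegmentTable], path: str | Path) -> None:
    """Tidy CSV export: one row per cell across all clusters."""
    frames = []
    for t in tables:
        cells = t.cells.copy()
        cells.insert(0, "cluster", t.cluster_id)
        frames.append(cells)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
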
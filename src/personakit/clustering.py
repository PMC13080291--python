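"""K-prototypes clustering under weighted Gower distance.

The algorithm alternates (i) assignment of each record to its nearest
prototype under the weighted Gower distance (ties broken toward the lowest
cluster index) and (ii) prototype update — per-variable mode for
categorical variables (ties broken by schema category order) and mean for
numeric variables — until assignments stabilise.  Several random restarts
are run and the best-objective model kept; everything is deterministic
given (seed, n_restarts).

The number of clusters is chosen by maximising a cross-validated silhouette
score: each fold's records are held out, clusters are fitted on the
complement, held-out records are assigned to their nearest prototype, and
their silhouette widths are computed against the training members'
clusters.  Pooling the held-out widths across folds scores K on data not
used to build the clusters.

A small gender-minority subgroup that is excluded from the main clustering
can be represented through a predicate-defined supplemental cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleError, UndefinedSilhouetteError
from .gower import (DistanceMatrix, DistanceSpec, cross_gower, encode_record,
                    encode_records)
from .survey_io import SurveyDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterModel:
    """Fitted K-prototypes model (cluster indices are 1-based, size-ordered)."""

    K: int
    prototypes: pd.DataFrame              # one row per cluster, decoded values
    assignments: pd.Series                # respondent id -> cluster index 1..K
    objective: float
    seed: int
    n_restarts: int
    converged: bool
    excluded_ids: tuple = ()
    objective_trajectory: tuple = ()      # per-iteration objective, best restart

    def members(self, k: int) -> tuple:
        return tuple(self.assignments.index[self.assignments == k])

    def sizes(self) -> dict[int, int]:
        return {k: int((self.assignments == k).sum()) for k in range(1, self.K + 1)}


@dataclass(frozen=True)
class SilhouetteResult:
    """Per-point silhouette widths and their mean; folds=0 means in-sample."""

    per_point: Mapping
    mean: float
    K: int
    folds: int = 0


@dataclass(frozen=True)
class SupplementalCluster:
    """Predicate-defined standalone cluster with per-variable summaries."""

    predicate: Mapping[str, tuple]
    members: tuple
    summary: Mapping[str, Mapping]

    def modal(self, variable: str):
        return self.summary[variable]["modal"]


# ---------------------------------------------------------------------------
# Core fitting on encoded arrays
# ---------------------------------------------------------------------------

def _distinct_rows(X: np.ndarray) -> np.ndarray:
    """Indices of first occurrences of distinct rows (NaN-safe)."""
    seen, keep = set(), []
    for i, row in enumerate(X):
        key = row.tobytes()
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return np.array(keep, dtype=int)


def _update_prototypes(X: np.ndarray, labels: np.ndarray, K: int,
                       spec: DistanceSpec) -> np.ndarray:
    """Mode (ties -> lowest category index) / mean per cluster per variable."""
    p = X.shape[1]
    is_cat = spec.is_categorical
    P = np.empty((K, p))
    for k in range(K):
        Xk = X[labels == k]
        for j in range(p):
            col = Xk[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                col = X[:, j][~np.isnan(X[:, j])]  # degenerate: global fallback
            if is_cat[j]:
                counts = np.bincount(col.astype(int))
                P[k, j] = float(np.argmax(counts))  # argmax -> lowest index on ties
            else:
                P[k, j] = float(col.mean())
    return P


def _objective(X: np.ndarray, P: np.ndarray, labels: np.ndarray,
               spec: DistanceSpec) -> float:
    D = cross_gower(X, P, spec)
    return float(np.nansum(D[np.arange(len(labels)), labels]))


def _fit_once(X: np.ndarray, K: int, spec: DistanceSpec, rng: np.random.Generator,
              max_iter: int):
    n = X.shape[0]
    distinct = _distinct_rows(X)
    if K > len(distinct):
        raise InfeasibleError(f"K={K} exceeds {len(distinct)} distinct records")
    init = rng.choice(distinct, size=K, replace=False)
    P = X[init].copy()
    labels = np.full(n, -1)
    trajectory = []
    converged = False
    for _ in range(max_iter):
        D = cross_gower(X, P, spec)
        D = np.where(np.isnan(D), 1.0, D)  # undefined pair -> maximal distance
        new_labels = np.argmin(D, axis=1)  # argmin -> lowest cluster on ties
        # empty-cluster repair: reseed with the record farthest from its prototype
        for k in range(K):
            if not np.any(new_labels == k):
                far = int(np.argmax(D[np.arange(n), new_labels]))
                new_labels[far] = k
                P[k] = X[far]
                D[far, k] = 0.0
        trajectory.append(float(D[np.arange(n), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        P = _update_prototypes(X, labels, K, spec)
    labels = new_labels
    obj = _objective(X, P, labels, spec)
    return labels, P, obj, converged, tuple(trajectory)


def _fit_encoded(X: np.ndarray, K: int, spec: DistanceSpec, seed: int,
                 n_restarts: int, max_iter: int):
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        result = _fit_once(X, K, spec, rng, max_iter)
        if best is None or result[2] < best[2]:
            best = result
    return best


def _relabel_by_size(labels: np.ndarray, K: int):
    """Map raw labels to 0..K-1 ordered by descending size (stable on ties)."""
    counts = np.bincount(labels, minlength=K)
    order = np.argsort(-counts, kind="stable")
    mapping = np.empty(K, dtype=int)
    mapping[order] = np.arange(K)
    return mapping[labels], mapping


def _decode_prototypes(P: np.ndarray, spec: DistanceSpec) -> pd.DataFrame:
    rows = []
    for k in range(P.shape[0]):
        row = {}
        for j, v in enumerate(spec.schema.variables):
            row[v.name] = (v.categories[int(P[k, j])] if v.kind == "categorical"
                           else float(P[k, j]))
        rows.append(row)
    return pd.DataFrame(rows, index=range(1, P.shape[0] + 1))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def fit_kprototypes(
    dataset: SurveyDataset,
    spec: DistanceSpec,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> ClusterModel:
    """Fit K prototypes to the dataset's clustering variables.

    Respondents missing any clustering variable are excluded (counted in
    ``excluded_ids``).  Returns the best model over ``n_restarts`` seeded
    restarts, with clusters relabelled 1..K by descending size.
    """
    if K < 1:
        raise InfeasibleError("K must be >= 1")
    complete = dataset.complete_on(spec.names)
    excluded = tuple(i for i in dataset.ids if i not in set(complete.ids))
    X = encode_records(complete.data, spec)
    labels, P, obj, converged, trajectory = _fit_encoded(
        X, K, spec, seed, n_restarts, max_iter)
    labels, mapping = _relabel_by_size(labels, K)
    P = P[np.argsort(mapping)]
    if not converged:
        warnings.warn(f"K-prototypes did not converge within {max_iter} iterations")
    return ClusterModel(
        K=K,
        prototypes=_decode_prototypes(P, spec),
        assignments=pd.Series(labels + 1, index=list(complete.ids), name="cluster"),
        objective=obj,
        seed=seed,
        n_restarts=n_restarts,
        converged=converged,
        excluded_ids=excluded,
        objective_trajectory=trajectory,
    )


def assign(model: ClusterModel, record: Mapping, spec: DistanceSpec) -> int:
    """Cluster index (1-based) of the nearest prototype; ties -> lowest index."""
    x = encode_record(record, spec)[None, :]
    P = encode_records(model.prototypes, spec)
    d = cross_gower(x, P, spec)[0]
    d = np.where(np.isnan(d), 1.0, d)
    return int(np.argmin(d)) + 1


def silhouette(assignments: Mapping, distances: DistanceMatrix) -> SilhouetteResult:
    """In-sample silhouette widths from a precomputed distance matrix.

    s(i) = (b - a) / max(a, b) with a the mean distance to co-members
    (excluding self) and b the smallest mean distance to another cluster's
    members.  Points in singleton clusters get s = 0 by convention.
    """
    ids = list(distances.ids)
    labels = np.array([assignments[i] for i in ids])
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise UndefinedSilhouetteError("silhouette needs at least two clusters")
    D = distances.values
    onehot = (labels[:, None] == uniq[None, :]).astype(float)
    sums = D @ onehot                      # (n, C) total distance to each cluster
    counts = onehot.sum(axis=0)
    own = np.array([np.where(uniq == l)[0][0] for l in labels])
    n = len(ids)
    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if counts[c] <= 1:
            continue  # singleton convention: s = 0
        a = sums[i, c] / (counts[c] - 1)
        other = [sums[i, cc] / counts[cc] for cc in range(len(uniq)) if cc != c]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return SilhouetteResult(per_point=dict(zip(ids, s.tolist())),
                            mean=float(s.mean()), K=len(uniq), folds=0)


def cv_silhouette(
    dataset: SurveyDataset,
    spec: DistanceSpec,
    K: int,
    folds: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 100,
    reference: str = "members",
) -> SilhouetteResult:
    """Cross-validated silhouette: fit on each fold's complement, score held-out.

    Held-out records are assigned to the nearest training prototype; their
    widths use mean distances to training members per cluster (default) or
    distances to prototypes (``reference="prototypes"``).  Per-point widths
    are pooled across all folds.  Deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if reference not in ("members", "prototypes"):
        raise ValueError("reference must be 'members' or 'prototypes'")
    complete = dataset.complete_on(spec.names)
    ids = np.array(list(complete.ids), dtype=object)
    X = encode_records(complete.data, spec)
    n = len(ids)
    if folds > n:
        raise ValueError("more folds than records")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xF01D,)))
    perm = rng.permutation(n)
    per_point: dict = {}
    for f, test_idx in enumerate(np.array_split(perm, folds)):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, Xte = X[train_mask], X[test_idx]
        if len(_distinct_rows(Xtr)) < K:
            raise InfeasibleError(
                f"fold {f}: training complement has fewer than K={K} distinct records")
        labels_tr, P, _, _, _ = _fit_encoded(
            Xtr, K, spec, seed=int(seed * 1000 + f) % (2**31 - 1),
            n_restarts=n_restarts, max_iter=max_iter)
        Dte_p = cross_gower(Xte, P, spec)
        Dte_p = np.where(np.isnan(Dte_p), 1.0, Dte_p)
        assigned = np.argmin(Dte_p, axis=1)
        if reference == "prototypes":
            for i, idx in enumerate(test_idx):
                a = Dte_p[i, assigned[i]]
                b = np.min(np.delete(Dte_p[i], assigned[i]))
                denom = max(a, b)
                per_point[ids[idx]] = 0.0 if denom == 0 else float((b - a) / denom)
            continue
        Dte = cross_gower(Xte, Xtr, spec)
        Dte = np.where(np.isnan(Dte), 1.0, Dte)
        onehot = (labels_tr[:, None] == np.arange(K)[None, :]).astype(float)
        sums = Dte @ onehot
        counts = onehot.sum(axis=0)
        for i, idx in enumerate(test_idx):
            c = assigned[i]
            a = sums[i, c] / counts[c]
            other = [sums[i, cc] / counts[cc] for cc in range(K) if cc != c and counts[cc] > 0]
            b = min(other)
            denom = max(a, b)
            per_point[ids[idx]] = 0.0 if denom == 0 else float((b - a) / denom)
    widths = np.array([per_point[i] for i in ids])
    return SilhouetteResult(per_point=per_point, mean=float(widths.mean()),
                            K=K, folds=folds)


def select_k(
    dataset: SurveyDataset,
    spec: DistanceSpec,
    k_range: Sequence[int],
    folds: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> tuple[int, dict[int, float]]:
    """Pick K maximising mean CV silhouette over ``k_range`` (ties -> smallest K)."""
    scores: dict[int, float] = {}
    for K in sorted(set(int(k) for k in k_range)):
        scores[K] = cv_silhouette(dataset, spec, K, folds=folds, seed=seed,
                                  n_restarts=n_restarts, max_iter=max_iter).mean
        logger.info("K=%d: mean CV silhouette %.4f", K, scores[K])
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def build_supplemental_cluster(
    dataset: SurveyDataset,
    predicate: Mapping[str, Sequence],
) -> SupplementalCluster:
    """Standalone cluster of all respondents matching a declarative predicate.

    ``predicate`` maps variable names to allowed values, e.g.
    ``{"sex": ("Nonbinary", "Transgender")}``.  The summary holds, per
    variable, value counts over members, the count of missing answers, and
    the modal value (ties broken by schema category order).
    """
    for name in predicate:
        if name not in dataset.schema:
            raise KeyError(f"predicate references unknown variable {name!r}")
    mask = pd.Series(True, index=dataset.data.index)
    for name, allowed in predicate.items():
        mask &= dataset.data[name].isin(list(allowed))
    members = tuple(dataset.data.index[mask])
    if not members:
        warnings.warn("supplemental-cluster predicate matched no respondents")
    sub = dataset.data.loc[list(members)]
    summary = {}
    for v in dataset.schema.variables:
        col = sub[v.name]
        counts = col.value_counts().to_dict()
        if v.kind == "categorical":
            ordered = {c: int(counts.get(c, 0)) for c in v.categories if counts.get(c, 0)}
            modal = None
            if ordered:
                top = max(ordered.values())
                modal = next(c for c in v.categories if ordered.get(c, 0) == top)
        else:
            ordered = {float(k): int(c) for k, c in counts.items()}
            modal = float(col.mean()) if col.notna().any() else None
        summary[v.name] = {"counts": ordered, "missing": int(col.isna().sum()),
                           "modal": modal}
    return SupplementalCluster(predicate={k: tuple(v) for k, v in predicate.items()},
                               members=members, summary=summary)
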
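"""Survey schema, dataset I/O, and derived-variable recodes.

A survey is a respondent-by-variable table of (mostly categorical) answers.
The schema declares, for every variable, its kind, category vocabulary,
analysis role (demographic / technological / outcome), and clustering
weight.  Technology-related variables default to a 5:1 weight relative to
demographic variables so that clustering differentiates respondents chiefly
on technology adoption.

Missing answers are carried as ``None`` (NaN inside the backing DataFrame)
and written as empty CSV fields.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, SchemaError

logger = logging.getLogger(__name__)

#: sentinel used in record dictionaries for a missing answer
MISSING = None

ROLES = ("demographic", "technological", "outcome")
KINDS = ("categorical", "numeric")


def default_weight(role: str) -> float:
    """Default clustering weight: 1 for demographics, 5 otherwise (5:1)."""
    return 1.0 if role == "demographic" else 5.0


def is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one survey variable."""

    name: str
    kind: str = "categorical"
    categories: tuple[str, ...] = ()
    numeric_range: tuple[float, float] | None = None
    role: str = "demographic"
    weight: float | None = None

    def __post_init__(self):
        if not self.name or not str(self.name).isidentifier():
            raise SchemaError(f"variable name {self.name!r} is not an identifier")
        if self.kind not in KINDS:
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        if self.role not in ROLES:
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        if self.kind == "categorical":
            cats = tuple(self.categories)
            if len(cats) < 2:
                raise SchemaError(f"{self.name}: needs >=2 categories")
            if len(set(cats)) != len(cats):
                raise SchemaError(f"{self.name}: duplicate categories")
            object.__setattr__(self, "categories", cats)
        else:
            if self.numeric_range is not None:
                lo, hi = self.numeric_range
                if not lo <= hi:
                    raise SchemaError(f"{self.name}: invalid numeric_range")
                object.__setattr__(self, "numeric_range", (float(lo), float(hi)))
        w = default_weight(self.role) if self.weight is None else float(self.weight)
        if not w > 0:
            raise SchemaError(f"{self.name}: weight must be strictly positive")
        object.__setattr__(self, "weight", w)


@dataclass(frozen=True)
class SurveySchema:
    """Ordered collection of variable declarations."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self):
        variables = tuple(self.variables)
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        object.__setattr__(self, "variables", variables)

    # -- lookup ---------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def by_role(self, *roles: str) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.role in roles)

    def clustering_names(self, exclude: Sequence[str] = ()) -> tuple[str, ...]:
        """Variables entering the cluster analysis (all roles by default)."""
        return tuple(v.name for v in self.variables if v.name not in exclude)

    # -- derivation -----------------------------------------------------
    def subset(self, names: Sequence[str]) -> "SurveySchema":
        missing = [n for n in names if n not in self]
        if missing:
            raise SchemaError(f"unknown variables: {missing}")
        return SurveySchema(tuple(self[n] for n in names))

    def with_variable(self, spec: VariableSpec) -> "SurveySchema":
        if spec.name in self:
            raise SchemaError(f"variable {spec.name!r} already in schema")
        return SurveySchema(self.variables + (spec,))

    def reweighted(self, tech_weight: float) -> "SurveySchema":
        """Return a schema with non-demographic weights set to ``tech_weight``.

        Used for exploratory weight sweeps (e.g. 3 or 10 instead of 5).
        """
        return SurveySchema(
            tuple(
                v if v.role == "demographic" else replace(v, weight=float(tech_weight))
                for v in self.variables
            )
        )

    # -- YAML -----------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveySchema":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "variables" not in raw:
            raise FormatError(f"{path}: expected a mapping with a 'variables' list")
        specs = []
        for item in raw["variables"]:
            specs.append(
                VariableSpec(
                    name=item["name"],
                    kind=item.get("kind", "categorical"),
                    categories=tuple(item.get("categories", ())),
                    numeric_range=tuple(item["numeric_range"]) if item.get("numeric_range") else None,
                    role=item.get("role", "demographic"),
                    weight=item.get("weight"),
                )
            )
        return cls(tuple(specs))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    **({"categories": list(v.categories)} if v.kind == "categorical" else {}),
                    **({"numeric_range": list(v.numeric_range)} if v.numeric_range else {}),
                    "role": v.role,
                    "weight": v.weight,
                }
                for v in self.variables
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass(frozen=True)
class SurveyDataset:
    """Respondent records conforming to a :class:`SurveySchema`.

    ``data`` is indexed by respondent id with one column per schema variable;
    missing answers are NaN.
    """

    schema: SurveySchema
    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise SchemaError(f"duplicate respondent ids: {dupes[:5]}")
        missing_cols = [n for n in self.schema.names if n not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing required column(s): {missing_cols}")
        df = df.loc[:, list(self.schema.names)].copy()
        df.index.name = ID_COLUMN
        df = df.where(df.notna(), np.nan)  # one missing sentinel (None -> NaN)
        for v in self.schema.variables:
            col = df[v.name]
            if v.kind == "categorical":
                bad = col.dropna()[~col.dropna().isin(v.categories)]
                if len(bad):
                    row, val = bad.index[0], bad.iloc[0]
                    raise SchemaError(
                        f"row {row!r}, column {v.name!r}: value {val!r} not in categories"
                    )
            else:
                vals = pd.to_numeric(col, errors="raise")
                if v.numeric_range is not None:
                    lo, hi = v.numeric_range
                    out = vals.dropna()[(vals.dropna() < lo) | (vals.dropna() > hi)]
                    if len(out):
                        raise SchemaError(
                            f"row {out.index[0]!r}, column {v.name!r}: value outside range"
                        )
                df[v.name] = vals
        object.__setattr__(self, "data", df)

    # -- basics ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> tuple:
        return tuple(self.data.index)

    def record(self, respondent_id) -> dict:
        row = self.data.loc[respondent_id]
        return {k: (None if pd.isna(v) else v) for k, v in row.items()}

    def filter(self, mask: pd.Series, provenance: str | None = None) -> "SurveyDataset":
        return SurveyDataset(self.schema, self.data.loc[mask],
                             provenance if provenance is not None else self.provenance)

    def complete_on(self, names: Sequence[str]) -> "SurveyDataset":
        """Subset of respondents with no missing value on ``names``."""
        mask = self.data[list(names)].notna().all(axis=1)
        n_drop = int((~mask).sum())
        if n_drop:
            logger.info("excluding %d respondent(s) with missing values on %s",
                        n_drop, list(names))
        return self.filter(mask)


ID_COLUMN = "respondent_id"


def read_survey(
    path: str | Path,
    schema: SurveySchema,
    delimiter: str = ",",
    strict: bool = True,
    provenance: str | None = None,
) -> SurveyDataset:
    """Read a CSV/TSV survey table into a validated :class:`SurveyDataset`.

    The header must name a superset of the schema variables plus a
    ``respondent_id`` column.  Under ``strict=True`` an out-of-vocabulary
    categorical value raises :class:`SchemaError` naming the row and column;
    under ``strict=False`` such values are coerced to missing (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                         encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if ID_COLUMN not in df.columns:
        raise SchemaError(f"missing required column(s): ['{ID_COLUMN}']")
    missing_cols = [n for n in schema.names if n not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")
    df = df.set_index(ID_COLUMN)
    df = df.replace({"": np.nan})
    if not strict:
        for v in schema.by_role(*ROLES):
            if v.kind != "categorical" or v.name not in df.columns:
                continue
            col = df[v.name]
            bad = col.notna() & ~col.isin(v.categories)
            if bad.any():
                logger.warning("coercing %d out-of-vocabulary value(s) in %s to missing",
                               int(bad.sum()), v.name)
                df.loc[bad, v.name] = np.nan
    return SurveyDataset(schema, df, provenance or str(path))


def write_survey(dataset: SurveyDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write a dataset as UTF-8 CSV/TSV, empty fields for missing answers."""
    out = dataset.data.copy()
    out.index.name = ID_COLUMN
    out.to_csv(path, sep=delimiter, na_rep="", encoding="utf-8")


def response_rate(n_responses: int, n_contacted: int, decimals: int = 0) -> float:
    """Survey response rate as a percentage, rounded half away from zero."""
    if n_contacted <= 0:
        raise ValueError("n_contacted must be positive")
    pct = 100.0 * n_responses / n_contacted
    scale = 10 ** decimals
    return math.floor(pct * scale + 0.5) / scale if pct >= 0 else -math.floor(
        -pct * scale + 0.5) / scale


# ---------------------------------------------------------------------------
# Race / ethnicity recode
# ---------------------------------------------------------------------------

RACE_ETHNICITY_LEVELS = ("White", "Black", "Hispanic", "Asian", "Other")


def recode_race_ethnicity(hispanic_flag, selected_races: Iterable[str] | None):
    """Collapse a Hispanic-ethnicity flag and multi-select race into 5 levels.

    Anyone indicating Hispanic ethnicity is "Hispanic"; otherwise a single
    selection of White, Black, or Asian keeps that label; every other pattern
    (multiple races, or any other race label) is "Other".  Both inputs
    missing yields the missing marker, not an exception.
    """
    races = frozenset(selected_races) if selected_races else frozenset()
    flag_missing = is_missing(hispanic_flag)
    if not flag_missing and str(hispanic_flag).lower() not in ("yes", "no"):
        raise SchemaError(f"hispanic_flag must be yes/no/missing, got {hispanic_flag!r}")
    if not flag_missing and str(hispanic_flag).lower() == "yes":
        return "Hispanic"
    if flag_missing and not races:
        return MISSING
    if not races:
        return MISSING
    if len(races) == 1:
        (only,) = races
        if only in ("White", "Black", "Asian"):
            return only
    return "Other"


# ---------------------------------------------------------------------------
# Derived (calculated) variables
# ---------------------------------------------------------------------------

_MISSING_KEY = "<missing>"


def _key(value) -> str:
    return _MISSING_KEY if is_missing(value) else str(value)


@dataclass(frozen=True)
class RecodeRule:
    """Total mapping from a tuple of source answers to a derived category.

    ``mapping`` maps tuples of input values (the missing marker spelled
    ``"<missing>"``) to an output category; combinations absent from the
    mapping fall back to ``fallback`` (which may be ``None`` = missing).
    """

    name: str
    inputs: tuple[str, ...]
    output: str
    output_categories: tuple[str, ...]
    mapping: Mapping[tuple, str] = field(default_factory=dict)
    fallback: str | None = None
    role: str = "technological"
    weight: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "output_categories", tuple(self.output_categories))
        norm = {}
        for combo, out in dict(self.mapping).items():
            combo = tuple(_key(v) for v in combo)
            if len(combo) != len(self.inputs):
                raise ConfigurationError(f"rule {self.name}: arity mismatch in {combo}")
            if out is not None and out not in self.output_categories:
                raise ConfigurationError(
                    f"rule {self.name}: output {out!r} not in declared categories")
            norm[combo] = out
        if self.fallback is not None and self.fallback not in self.output_categories:
            raise ConfigurationError(f"rule {self.name}: fallback not in categories")
        object.__setattr__(self, "mapping", norm)

    def apply(self, values: Sequence) -> str | None:
        combo = tuple(_key(v) for v in values)
        return self.mapping.get(combo, self.fallback)

    def output_spec(self) -> VariableSpec:
        return VariableSpec(name=self.output, kind="categorical",
                            categories=self.output_categories,
                            role=self.role, weight=self.weight)


def derive_calculated_variables(dataset: SurveyDataset,
                                rules: Sequence[RecodeRule]) -> SurveyDataset:
    """Append derived variables to a dataset; deterministic and idempotent.

    Pre-existing columns are never changed; the record count is preserved.
    """
    if not rules:
        return dataset
    schema = dataset.schema
    df = dataset.data.copy()
    for rule in rules:
        unknown = [n for n in rule.inputs if n not in schema]
        if unknown:
            raise ConfigurationError(f"rule {rule.name}: unknown input variable(s) {unknown}")
        if rule.output in schema:
            raise ConfigurationError(f"rule {rule.name}: output {rule.output!r} already exists")
        cols = [df[n] for n in rule.inputs]
        out = [
            rule.apply(vals)
            for vals in zip(*(c.where(c.notna(), None) for c in cols))
        ]
        df[rule.output] = pd.Series(out, index=df.index, dtype=object)
        schema = schema.with_variable(rule.output_spec())
    return SurveyDataset(schema, df, dataset.provenance)


def technological_readiness_rule(
    confidence_var: str,
    confidence_scale: Sequence[str],
    needs_help_var: str,
    needs_help_scale: Sequence[str],
    name: str = "tech_readiness_rule",
    output: str = "tech_readiness",
) -> RecodeRule:
    """Binary readiness from device confidence and needs-help agreement.

    "Higher" iff confidence is in the top half of its scale AND the
    needs-help statement is in the bottom half of its scale (scales ordered
    low-to-high); anything else non-missing is "Lower".  Both sources
    missing stays missing.
    """
    conf = list(confidence_scale)
    help_ = list(needs_help_scale)
    conf_hi = set(conf[len(conf) // 2:])
    help_lo = set(help_[: len(help_) // 2])
    mapping = {}
    for c in conf + [_MISSING_KEY]:
        for h in help_ + [_MISSING_KEY]:
            if c == _MISSING_KEY and h == _MISSING_KEY:
                mapping[(c, h)] = None
            elif c in conf_hi and h in help_lo:
                mapping[(c, h)] = "Higher"
            else:
                mapping[(c, h)] = "Lower"
    return RecodeRule(name=name, inputs=(confidence_var, needs_help_var),
                      output=output, output_categories=("Higher", "Lower"),
                      mapping=mapping, fallback="Lower")


def waverify_usage_rule(
    usage_var: str,
    willingness_var: str,
    willingness_scale: Sequence[str],
    name: str = "waverify_usage_rule",
    output: str = "waverify_usage",
) -> RecodeRule:
    """Three-level digital vaccine-record usage: Yes / Willing / Not willing.

    "Yes" if the usage question is affirmative regardless of willingness;
    otherwise willingness at or above the scale midpoint maps to "Willing",
    below to "Not willing".
    """
    will = list(willingness_scale)
    willing_hi = set(will[len(will) // 2:])
    mapping = {}
    for u in ("yes", "no", _MISSING_KEY):
        for w in will + [_MISSING_KEY]:
            if u == "yes":
                mapping[(u, w)] = "Yes"
            elif w == _MISSING_KEY:
                mapping[(u, w)] = None
            elif w in willing_hi:
                mapping[(u, w)] = "Willing"
            else:
                mapping[(u, w)] = "Not willing"
    return RecodeRule(name=name, inputs=(usage_var, willingness_var),
                      output=output, output_categories=("Yes", "Willing", "Not willing"),
                      mapping=mapping, fallback=None)
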
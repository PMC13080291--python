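"""Seeded synthetic survey generator with planted cluster structure.

The generator emulates the statistical shape the pipeline assumes: ~1,100
respondents, 15 categorical variables (7 demographic, 8 technology /
opinion), K planted clusters of configurable sizes, and a small
gender-minority subgroup kept outside the main clusters.  Each cluster has
a per-variable prototype; a respondent copies the prototype value with
probability ``adherence`` and otherwise draws uniformly from the variable's
categories (an independent-noise mixture).  Cluster prototypes are redrawn
until every pair disagrees on at least half of the variables, so "planted
cluster" means a genuinely separated prototype, not an arbitrary random
draw.  Demographic cells can be planted as overrepresented within a target
cluster by a multiplicative boost of the cell's probability.

Defaults mirror the survey the pipeline is designed for: cluster sizes
(272, 223, 302, 57, 249) plus an 8-person nonbinary/transgender subgroup,
N = 1103 in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .survey_io import SurveyDataset, SurveySchema, VariableSpec

#: sexes participating in the main cluster analysis
BINARY_SEXES = ("Female", "Male")

DEFAULT_CLUSTER_SIZES = (272, 223, 302, 57, 249)
DEFAULT_MINORITY = {"Nonbinary": 5, "Transgender": 3}


def default_schema() -> SurveySchema:
    """Schema of the cluster-analysis variables (all categorical).

    Seven demographics (weight 1) and eight technology/opinion variables
    (weight 5, the 5:1 weighting).
    """
    d = dict(role="demographic")
    t = dict(role="technological")
    return SurveySchema((
        VariableSpec("age_group", categories=("18-39", "40-59", "60+"), **d),
        VariableSpec("sex", categories=("Female", "Male", "Transgender",
                                        "Nonbinary", "Prefer not to respond"), **d),
        VariableSpec("race_ethnicity", categories=("White", "Black", "Hispanic",
                                                   "Asian", "Other"), **d),
        VariableSpec("region", categories=("Eastern", "Western"), **d),
        VariableSpec("english_only", categories=("Only English", "Other language"), **d),
        VariableSpec("parental_status", categories=("Parent", "Not a parent"), **d),
        VariableSpec("education", categories=("Less than high school",
                                              "High school graduate",
                                              "2-year or some college",
                                              "4-year degree or more"), **d),
        VariableSpec("tech_readiness", categories=("Higher", "Lower"), **t),
        VariableSpec("ehealth_use", categories=("Used", "Not used"), **t),
        VariableSpec("waverify_referral", categories=("Referral", "News", "Health care",
                                                      "Other", "Never heard"), **t),
        VariableSpec("waverify_usage", categories=("Yes", "Willing", "Not willing"), **t),
        VariableSpec("covid_policy_opinion", categories=("Support", "Oppose"), **t),
        VariableSpec("health_portal", categories=("Yes", "No"), **t),
        VariableSpec("wa_notify", categories=("Yes", "No"), **t),
        VariableSpec("tracking", categories=("Yes", "No"), **t),
    ))


@dataclass(frozen=True)
class PlantedCell:
    """A demographic cell to overrepresent inside one cluster."""

    cluster: int                      # 1-based planted cluster index
    cell: Mapping[str, str]           # axis variable -> category
    boost: float                      # multiplicative factor on the cell probability


@dataclass(frozen=True)
class GeneratorConfig:
    schema: SurveySchema = field(default_factory=default_schema)
    cluster_sizes: tuple[int, ...] = DEFAULT_CLUSTER_SIZES
    adherence: float = 0.9
    planted_overrepresentation: tuple[PlantedCell, ...] = ()
    minority_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MINORITY))
    minority_variable: str = "sex"
    missing_rate: float = 0.0
    min_prototype_separation: float = 0.5   # fraction of variables that must differ
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.adherence <= 1:
            raise ConfigurationError("adherence must be in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ConfigurationError("cluster sizes must be positive")
        object.__setattr__(self, "cluster_sizes", tuple(int(s) for s in self.cluster_sizes))
        object.__setattr__(self, "planted_overrepresentation",
                           tuple(self.planted_overrepresentation))
        object.__setattr__(self, "minority_counts", dict(self.minority_counts))

    @property
    def minority_size(self) -> int:
        return sum(self.minority_counts.values())

    @property
    def total_n(self) -> int:
        return sum(self.cluster_sizes) + self.minority_size


@dataclass(frozen=True)
class GroundTruth:
    labels: Mapping            # respondent id -> planted cluster (1-based)
    overrepresented_cells: tuple[PlantedCell, ...]
    minority_ids: tuple


def _categories_for(config: GeneratorConfig, name: str) -> tuple[str, ...]:
    cats = config.schema[name].categories
    if name == config.minority_variable:
        return tuple(c for c in cats if c in BINARY_SEXES) or cats
    return cats


def _draw_prototypes(config: GeneratorConfig, rng: np.random.Generator) -> list[dict]:
    names = config.schema.names
    C = len(config.cluster_sizes)
    protos: list[dict] = []
    for c in range(C):
        for _ in range(500):
            cand = {n: _categories_for(config, n)[rng.integers(len(_categories_for(config, n)))]
                    for n in names}
            ok = all(
                sum(cand[n] != p[n] for n in names) >= config.min_prototype_separation * len(names)
                for p in protos)
            if ok:
                protos.append(cand)
                break
        else:
            raise ConfigurationError(
                "could not draw sufficiently separated cluster prototypes")
    return protos


def _cell_probability(config: GeneratorConfig, proto: dict,
                      cell: Mapping[str, str]) -> float:
    p = 1.0
    for name, value in cell.items():
        cats = _categories_for(config, name)
        if value not in cats:
            raise ConfigurationError(f"planted cell value {value!r} not drawable for {name}")
        base = (1 - config.adherence) / len(cats)
        p *= base + (config.adherence if proto[name] == value else 0.0)
    return p


def generate(config: GeneratorConfig,
             seed: int | None = None) -> tuple[SurveyDataset, GroundTruth]:
    """Draw a synthetic survey and its ground truth; deterministic given seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    protos = _draw_prototypes(config, rng)
    names = config.schema.names
    rows, labels = [], {}
    rid = 0
    for c, size in enumerate(config.cluster_sizes, start=1):
        planted = [p for p in config.planted_overrepresentation if p.cluster == c]
        block = {}
        for name in names:
            cats = _categories_for(config, name)
            use_proto = rng.random(size) < config.adherence
            noise = rng.integers(len(cats), size=size)
            col = np.where(use_proto,
                           np.full(size, cats.index(protos[c - 1][name])), noise)
            block[name] = [cats[i] for i in col]
        for plant in planted:
            p0 = _cell_probability(config, protos[c - 1], plant.cell)
            target = plant.boost * p0
            if target >= 1:
                raise ConfigurationError(
                    f"boost {plant.boost} makes cell probability {target:.3f} >= 1")
            alpha = (target - p0) / (1 - p0)
            if alpha < 0:
                raise ConfigurationError("boost must be >= 1")
            overwrite = rng.random(size) < alpha
            for name, value in plant.cell.items():
                col = block[name]
                block[name] = [value if o else v for v, o in zip(col, overwrite)]
        for i in range(size):
            rid += 1
            rec_id = f"R{rid:04d}"
            rows.append({"respondent_id": rec_id,
                         **{n: block[n][i] for n in names}})
            labels[rec_id] = c
    # gender-minority subgroup: predicate variable fixed, rest drawn from a
    # random planted cluster's mixture per respondent
    minority_ids = []
    for value, count in config.minority_counts.items():
        for _ in range(int(count)):
            rid += 1
            rec_id = f"R{rid:04d}"
            donor = protos[rng.integers(len(protos))]
            rec = {"respondent_id": rec_id}
            for name in names:
                cats = _categories_for(config, name)
                if rng.random() < config.adherence:
                    rec[name] = donor[name]
                else:
                    rec[name] = cats[rng.integers(len(cats))]
            rec[config.minority_variable] = value
            rows.append(rec)
            minority_ids.append(rec_id)
    df = pd.DataFrame(rows).set_index("respondent_id")
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    dataset = SurveyDataset(config.schema, df, provenance="synthetic")
    truth = GroundTruth(labels=labels,
                        overrepresented_cells=config.planted_overrepresentation,
                        minority_ids=tuple(minority_ids))
    return dataset, truth
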
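"""Persona assembly, manual overrides, validation, and card rendering.

A persona is one demographic cell of a cluster segment plus the modal
values of the profile characteristics and outcome variables among that
segment's members (modal ties broken by schema category order).  The
gender-minority supplemental cluster becomes a standalone persona built
from its aggregate summary.  Manual judgment — diversity-motivated value
substitutions and persona removals — enters only through an explicit
overrides configuration, and every override records the automatic value,
the final value, and a reason.

Validation compares each persona's assigned outcome values with the
distribution of those outcomes among respondents matching the persona's
seven profile characteristics exactly (or, when that group is small, on at
least six of the seven).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .clustering import SupplementalCluster
from .errors import ConfigurationError
from .segmentation import SegmentSpec
from .survey_io import SurveyDataset

logger = logging.getLogger(__name__)

#: the seven profile characteristics used for persona matching
DEFAULT_CHARACTERISTICS = (
    "age_group", "sex", "race_ethnicity", "region",
    "english_only", "parental_status", "education",
)

#: persona outcome variables (technology behaviours and opinions)
DEFAULT_OUTCOMES = (
    "tech_readiness", "waverify_referral", "waverify_usage",
    "covid_policy_opinion", "health_portal", "wa_notify", "tracking",
)

#: the four outcomes tabulated during validation
DEFAULT_VALIDATION_OUTCOMES = (
    "tech_readiness", "covid_policy_opinion", "health_portal", "tracking",
)


@dataclass(frozen=True)
class Override:
    field: str
    auto_value: object
    final_value: object
    reason: str


@dataclass(frozen=True)
class Persona:
    persona_id: str
    cluster_id: int | str
    demographics: Mapping[str, object]
    outcomes: Mapping[str, object]
    member_ids: tuple = ()
    overrides: tuple[Override, ...] = ()
    narrative: Mapping[str, object] = field(default_factory=dict)
    status: str = "active"
    removal_reason: str | None = None

    @property
    def active(self) -> bool:
        return self.status == "active"

    def value(self, name: str):
        if name in self.demographics:
            return self.demographics[name]
        return self.outcomes[name]


def _modal_value(values: pd.Series, categories: Sequence[str]):
    """Most frequent non-missing value; ties broken by category order."""
    counts = values.value_counts()
    if counts.empty:
        return None
    top = counts.max()
    for c in categories:
        if counts.get(c, 0) == top:
            return c
    return counts.idxmax()


def assemble_personas(
    segments: Sequence[SegmentSpec],
    supplemental: SupplementalCluster | None,
    dataset: SurveyDataset,
    outcome_vars: Sequence[str] = DEFAULT_OUTCOMES,
    characteristics: Sequence[str] = DEFAULT_CHARACTERISTICS,
) -> list[Persona]:
    """One persona per segment (plus one for the supplemental cluster).

    Axis characteristics come from the segment's demographic cell;
    remaining characteristics and all outcomes are the modal values among
    the segment's members.
    """
    for name in list(outcome_vars) + list(characteristics):
        if name not in dataset.schema:
            raise ConfigurationError(f"unknown variable {name!r}")
    personas: list[Persona] = []
    n = 0
    for seg in segments:
        if not seg.member_ids:
            warnings.warn(f"segment {seg.cluster_id}/{seg.rank} is empty; skipped")
            continue
        n += 1
        members = dataset.data.loc[list(seg.member_ids)]
        demographics = {}
        for name in characteristics:
            if name in seg.demographic_cell:
                demographics[name] = seg.demographic_cell[name]
            else:
                demographics[name] = _modal_value(
                    members[name], dataset.schema[name].categories)
        outcomes = {
            name: _modal_value(members[name], dataset.schema[name].categories)
            for name in outcome_vars
        }
        personas.append(Persona(
            persona_id=f"P{n}", cluster_id=seg.cluster_id,
            demographics=demographics, outcomes=outcomes,
            member_ids=tuple(seg.member_ids)))
    if supplemental is not None and supplemental.members:
        n += 1
        demographics = {name: supplemental.modal(name) for name in characteristics}
        outcomes = {name: supplemental.modal(name) for name in outcome_vars}
        personas.append(Persona(
            persona_id=f"P{n}", cluster_id="supplemental",
            demographics=demographics, outcomes=outcomes,
            member_ids=tuple(supplemental.members)))
    return personas


def apply_overrides(personas: Sequence[Persona],
                    overrides_config: Sequence[Mapping]) -> list[Persona]:
    """Apply value overrides and removals, recording provenance.

    Each config item is either ``{persona, field, final_value, reason}`` or
    ``{persona, action: remove, reason}``.
    """
    by_id = {p.persona_id: p for p in personas}
    for item in overrides_config:
        pid = item.get("persona")
        if pid not in by_id:
            raise ConfigurationError(f"override names unknown persona {pid!r}")
        p = by_id[pid]
        if item.get("action") == "remove":
            by_id[pid] = replace(p, status="removed",
                                 removal_reason=item.get("reason", ""))
            continue
        name = item.get("field")
        reason = item.get("reason", "")
        if not reason:
            raise ConfigurationError(f"override on {pid} needs a nonempty reason")
        if name in p.demographics:
            auto = p.demographics[name]
            demographics = {**p.demographics, name: item["final_value"]}
            by_id[pid] = replace(
                p, demographics=demographics,
                overrides=p.overrides + (Override(name, auto, item["final_value"], reason),))
        elif name in p.outcomes:
            auto = p.outcomes[name]
            outcomes = {**p.outcomes, name: item["final_value"]}
            by_id[pid] = replace(
                p, outcomes=outcomes,
                overrides=p.overrides + (Override(name, auto, item["final_value"], reason),))
        else:
            raise ConfigurationError(f"override names unknown field {name!r} on {pid}")
    result = [by_id[p.persona_id] for p in personas]
    logger.info("%d active persona(s) after overrides", sum(p.active for p in result))
    return result


def load_overrides(path: str | Path) -> list[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or []
    if not isinstance(raw, list):
        raise ConfigurationError("overrides file must be a YAML list")
    return raw


@dataclass(frozen=True)
class ValidationReport:
    persona_id: str
    exact_match_n: int
    relaxed_match_n: int | None
    group_used: str                         # "exact" | "relaxed" | "none"
    outcomes: Mapping[str, Mapping]         # var -> {persona_value, distribution,
                                            #         modal_value, discrepancy}
    resolution: str = "n/a"

    @property
    def discrepancies(self) -> list[str]:
        return [v for v, d in self.outcomes.items() if d["discrepancy"]]


def _match_counts(df: pd.DataFrame, demographics: Mapping) -> pd.Series:
    """Number of the profile characteristics each respondent matches."""
    agree = pd.DataFrame(
        {name: df[name] == value for name, value in demographics.items()})
    return agree.sum(axis=1)


def validate_persona(
    persona: Persona,
    dataset: SurveyDataset,
    characteristics: Sequence[str] = DEFAULT_CHARACTERISTICS,
    outcome_vars: Sequence[str] = DEFAULT_VALIDATION_OUTCOMES,
    small_group_threshold: int = 10,
) -> ValidationReport:
    """Compare persona outcomes with matched respondents' distributions.

    The exact-match group agrees with the persona on all characteristics;
    if it is smaller than ``small_group_threshold``, the relaxed group
    (agreement on all but at most one characteristic) is tabulated instead.
    """
    if not persona.active:
        raise ConfigurationError(f"persona {persona.persona_id} is not active")
    demo = {k: persona.demographics[k] for k in characteristics}
    df = dataset.data
    n_match = _match_counts(df, demo)
    exact = df[n_match == len(demo)]
    report_outcomes = {}
    relaxed_n = None
    if len(exact) >= small_group_threshold:
        group, used = exact, "exact"
    else:
        relaxed = df[n_match >= len(demo) - 1]
        relaxed_n = len(relaxed)
        group, used = relaxed, "relaxed"
        if len(relaxed) == 0:
            used = "none"
    for name in outcome_vars:
        if len(group) == 0:
            report_outcomes[name] = {"persona_value": persona.value(name),
                                     "distribution": {}, "modal_value": None,
                                     "discrepancy": False, "n": 0}
            continue
        col = group[name]
        dist = {k: int(v) for k, v in col.value_counts().items()}
        modal = _modal_value(col, dataset.schema[name].categories)
        report_outcomes[name] = {
            "persona_value": persona.value(name),
            "distribution": dist,
            "modal_value": modal,
            "discrepancy": bool(modal is not None and persona.value(name) != modal),
            "n": int(col.notna().sum()),
        }
    return ValidationReport(
        persona_id=persona.persona_id,
        exact_match_n=len(exact),
        relaxed_match_n=relaxed_n,
        group_used=used,
        outcomes=report_outcomes,
    )


# ---------------------------------------------------------------------------
# Card rendering
# ---------------------------------------------------------------------------

_PLACEHOLDER = "(not provided)"
_NARRATIVE_FIELDS = ("name", "age", "marital_status", "occupation", "quotes", "drivers")


def render_persona_card(persona: Persona) -> tuple[dict, str]:
    """Render one persona as (JSON-able dict, Markdown text).

    Computed fields come from the pipeline; quotes/drivers and other
    narrative fields are user-supplied metadata and render as explicit
    placeholders when absent.  Output field order is stable, so rendering
    is deterministic and idempotent.
    """
    if not persona.active:
        raise ConfigurationError(f"persona {persona.persona_id} is not active")
    card = {
        "persona_id": persona.persona_id,
        "cluster_id": persona.cluster_id,
        "demographics": dict(persona.demographics),
        "outcomes": dict(persona.outcomes),
        "overrides": [
            {"field": o.field, "auto_value": o.auto_value,
             "final_value": o.final_value, "reason": o.reason}
            for o in persona.overrides
        ],
        "narrative": {f: persona.narrative.get(f) for f in _NARRATIVE_FIELDS},
    }

    def fmt(value):
        return _PLACEHOLDER if value in (None, [], "") else value

    lines = [f"# Persona {persona.persona_id}",
             "",
             f"*Cluster:* {persona.cluster_id}",
             "",
             "## Demographics"]
    for k, v in persona.demographics.items():
        lines.append(f"- **{k}**: {fmt(v)}")
    lines += ["", "## Public health opinions and technology use"]
    for k, v in persona.outcomes.items():
        suffix = ""
        for o in persona.overrides:
            if o.field == k:
                suffix = f" *(override of {fmt(o.auto_value)}: {o.reason})*"
        lines.append(f"- **{k}**: {fmt(v)}{suffix}")
    lines += ["", "## Quotes"]
    quotes = persona.narrative.get("quotes") or []
    lines += [f"> {q}" for q in quotes] if quotes else [_PLACEHOLDER]
    lines += ["", "## Drivers"]
    drivers = persona.narrative.get("drivers") or []
    lines += [f"- {d}" for d in drivers] if drivers else [_PLACEHOLDER]
    lines += ["", "## Profile"]
    for f in ("name", "age", "marital_status", "occupation"):
        lines.append(f"- **{f}**: {fmt(persona.narrative.get(f))}")
    return card, "\n".join(lines) + "\n"


def render_cards(personas: Sequence[Persona], outdir: str | Path) -> list[Path]:
    """Write one ``.json`` + ``.md`` card per active persona; returns md paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in personas:
        if not p.active:
            continue
        card, md = render_persona_card(p)
        (outdir / f"{p.persona_id}.json").write_text(
            json.dumps(card, indent=2, default=str), encoding="utf-8")
        md_path = outdir / f"{p.persona_id}.md"
        md_path.write_text(md, encoding="utf-8")
        paths.append(md_path)
    return paths


def personas_to_json(personas: Sequence[Persona], path: str | Path) -> None:
    payload = []
    for p in personas:
        payload.append({
            "persona_id": p.persona_id,
            "cluster_id": p.cluster_id,
            "status": p.status,
            "removal_reason": p.removal_reason,
            "demographics": dict(p.demographics),
            "outcomes": dict(p.outcomes),
            "overrides": [
                {"field": o.field, "auto_value": o.auto_value,
                 "final_value": o.final_value, "reason": o.reason}
                for o in p.overrides],
            "member_ids": list(p.member_ids),
        })
    Path(path).write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")
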
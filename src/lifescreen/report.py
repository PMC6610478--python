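"""Recommendation reports and second-level referral routing.

Turns a scored assessment into (a) the catalog of traffic-light
recommendation messages, keyed by component, sub-block and risk, and (b) the
referral plan that routes respondents with at least one moderate or relevant
component to the second-level (long-version) instruments.  The message
catalog is an external UTF-8 resource (``data/messages.json``) so that the
English text can be swapped for another locale without code changes.
"""
from __future__ import annotations

import functools
import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Any, Mapping

from .levels import RiskLevel
from .rules import (
    ComponentResult,
    RuleVariant,
    ruleset_version,
    score_assessment,
    _resolve_variant,
    _ruleset,
)
from .schema import ResponseSet, load_schema, validate_response

__all__ = [
    "Message",
    "Referral",
    "ReferralPlan",
    "AssessmentReport",
    "CatalogError",
    "load_catalog",
    "check_catalog",
    "select_messages",
    "build_referral_plan",
    "assess",
    "INSTRUMENTS",
]

# Sub-blocks reported separately within a component; every other component
# reports a single "main" dimension keyed by its aggregate risk.
SUB_BLOCKS: Mapping[int, tuple[str, ...]] = {
    1: ("bmi_wc", "bp", "glycemia", "cholesterol"),
    6: ("smoking", "drinking", "illicit"),
}

# Canonical second-level instrument names, in report order.
EQ5D = "EQ-5D-5L"
BIOIMPEDANCE = "Bio-impedance body composition"
NUTRITION_Q = "Detailed nutrition questionnaire"
HANDGRIP = "Handgrip strength test"
BALANCE = "Body balance test"
SIT_REACH = "Sit and reach test"
REACTION = "Reaction time test"
HRV = "Heart rate variability (HRV) test"
RSES = "Rosenberg Self-Esteem Scale (RSES)"
NEO_FFI = "NEO Five-Factor Inventory (NEO-FFI)"
SPS = "Social Provision Scale (SPS)"
SF12 = "12-item health survey (SF-12)"
HADS = "Hospital Anxiety and Depression Scale (HADS)"
GDS30 = "30-item Geriatric Depression Scale (GDS-30)"
PSS = "Perceived Stress Scale (PSS)"
MMSE = "Mini Mental State Examination (MMSE)"
MIDAS = "Migraine Disability Assessment (MIDAS)"
SUBSTANCES_Q = "Detailed substances questionnaire"
ESS = "Epworth Sleepiness Scale (ESS)"
PSQI = "Pittsburgh Sleep Quality Index (PSQI)"
SPIROMETRY = "Spirometry"
OXIMETRY = "Oximetry"

INSTRUMENTS: tuple[str, ...] = (
    EQ5D, BIOIMPEDANCE, NUTRITION_Q, HANDGRIP, BALANCE, SIT_REACH, REACTION,
    HRV, RSES, NEO_FFI, SPS, SF12, HADS, GDS30, PSS, MMSE, MIDAS,
    SUBSTANCES_Q, ESS, PSQI, SPIROMETRY, OXIMETRY,
)
_INSTRUMENT_ORDER = {name: i for i, name in enumerate(INSTRUMENTS)}


class CatalogError(RuntimeError):
    """The message catalog is missing a reachable (component, sub-block, risk) cell."""


@dataclass(frozen=True)
class Message:
    """One recommendation message (or a not-assessed placeholder)."""

    component_id: int
    sub_block: str
    risk: RiskLevel
    text: str


@dataclass(frozen=True)
class Referral:
    """One second-level instrument with the components that triggered it."""

    instrument: str
    triggers: frozenset[int]
    optional: bool = False


@dataclass(frozen=True)
class ReferralPlan:
    instruments: tuple[Referral, ...]
    triggering_components: frozenset[int]

    def names(self) -> set[str]:
        return {r.instrument for r in self.instruments}

    def __bool__(self) -> bool:
        return bool(self.instruments)


@functools.lru_cache(maxsize=1)
def _catalog_data() -> dict:
    text = (resources.files("lifescreen") / "data" / "messages.json").read_text("utf-8")
    return json.loads(text)


def load_catalog() -> Mapping[str, Any]:
    return _catalog_data()["catalog"]


def placeholder_text() -> str:
    return _catalog_data()["placeholder"]


def _possible_item_risks(item_id: str, variant: RuleVariant) -> set[RiskLevel]:
    cells = dict(_ruleset()["categorical"][item_id])
    cells.update({a: r.value for a, r in variant.overrides.get(item_id, {}).items()})
    return {RiskLevel(v) for v in cells.values() if v != "not_scored"}


def _reachable_risks(component_id: int, sub_block: str,
                     variant: RuleVariant) -> set[RiskLevel]:
    """Risks a dimension can actually take, derived from the rule table."""
    three = {RiskLevel.LOW, RiskLevel.MODERATE, RiskLevel.RELEVANT}
    if component_id == 1:
        return set(three)  # every numeric rule spans all three bands
    if component_id == 6:
        members = {"smoking": ("6.1", "6.2", "6.3"),
                   "drinking": ("6.4", "6.5"),
                   "illicit": ("6.6", "6.7")}[sub_block]
        reachable: set[RiskLevel] = set()
        for item in members:
            reachable |= _possible_item_risks(item, variant)
        if sub_block == "smoking" and variant.ex_smoker_supersession:
            reachable.add(RiskLevel.LOW)
        # a dimension whose items are all unanswered except one low-capable
        # item can be low; every sub-block here has a low-capable item
        return reachable
    schema = load_schema()
    reachable = set()
    for item in schema.component(component_id).items:
        if item.id in _ruleset()["categorical"]:
            reachable |= _possible_item_risks(item.id, variant)
    if component_id == 4:
        reachable |= three  # food-frequency grid spans all three bands
    return reachable


def check_catalog(variant: RuleVariant | str | None = None) -> None:
    """Assert a catalog cell exists for every reachable dimension risk.

    Raises :class:`CatalogError` naming each missing
    ``component.sub_block.risk`` key.
    """
    variant = _resolve_variant(variant)
    catalog = load_catalog()
    missing: list[str] = []
    for cid in range(1, 9):
        for sub in SUB_BLOCKS.get(cid, ("main",)):
            for risk in sorted(_reachable_risks(cid, sub, variant),
                               key=lambda r: r.value):
                if catalog.get(str(cid), {}).get(sub, {}).get(risk.value) is None:
                    missing.append(f"{cid}.{sub}.{risk.value}")
    if missing:
        raise CatalogError(
            f"message catalog is missing reachable cells: {missing} "
            f"(variant {variant.name!r})")


def _dimension_risks(result: ComponentResult) -> Mapping[str, RiskLevel]:
    if result.component_id in SUB_BLOCKS:
        return {sub: result.sub_block_risks[sub]
                for sub in SUB_BLOCKS[result.component_id]}
    return {"main": result.aggregate}


def select_messages(results: list[ComponentResult]) -> list[Message]:
    """Pick one catalog message per scored dimension, placeholders elsewhere.

    A fully unanswered component yields a single per-component placeholder;
    a scored component with an unanswered sub-block (e.g. unknown lab value)
    yields a placeholder for that sub-block only.
    """
    catalog = load_catalog()
    messages: list[Message] = []
    for result in results:
        cid = result.component_id
        if not result.aggregate.scored:
            messages.append(Message(cid, "main", RiskLevel.NOT_SCORED,
                                    placeholder_text()))
            continue
        for sub, risk in _dimension_risks(result).items():
            if not risk.scored:
                messages.append(Message(cid, sub, RiskLevel.NOT_SCORED,
                                        placeholder_text()))
                continue
            text = catalog.get(str(cid), {}).get(sub, {}).get(risk.value)
            if text is None:
                raise CatalogError(
                    f"no catalog message for key {cid}.{sub}.{risk.value}")
            messages.append(Message(cid, sub, risk, text))
    return messages


def _item_risk(result: ComponentResult, item_id: str) -> RiskLevel:
    for s in result.item_scores:
        if s.item_id == item_id:
            return s.risk
    return RiskLevel.NOT_SCORED


_TRIGGERING = (RiskLevel.MODERATE, RiskLevel.RELEVANT)


def build_referral_plan(results: list[ComponentResult],
                        response: ResponseSet) -> ReferralPlan:
    """Route moderate/relevant scorers to second-level instruments.

    Component-level triggers: body composition and a detailed nutrition
    questionnaire for components 1 and 4; the physical test battery for
    component 2; a detailed substances questionnaire for component 6; ESS and
    PSQI for component 7; SF-12 for component 8 (plus spirometry and oximetry
    when a respiratory disease is reported).  Components 3 and 5 route at the
    item/condition level, since each sub-question has its own instrument.
    Any trigger adds the EQ-5D-5L generic health questionnaire.  Respondents
    with all components low (or not scored) get an empty plan.
    """
    by_id = {r.component_id: r for r in results}
    flagged = frozenset(cid for cid, r in by_id.items()
                        if r.aggregate in _TRIGGERING)
    acc: dict[str, tuple[set[int], bool]] = {}

    def add(name: str, cid: int, optional: bool = False) -> None:
        triggers, opt = acc.get(name, (set(), True))
        triggers.add(cid)
        acc[name] = (triggers, opt and optional)

    if 1 in flagged:
        add(BIOIMPEDANCE, 1)
        add(NUTRITION_Q, 1)
    if 2 in flagged:
        for name in (HANDGRIP, BALANCE, SIT_REACH, REACTION, HRV):
            add(name, 2)
    if 3 in flagged:
        r3 = by_id[3]
        if _item_risk(r3, "3.1") in _TRIGGERING:
            add(RSES, 3)
            add(NEO_FFI, 3, optional=True)
        if _item_risk(r3, "3.2") in _TRIGGERING:
            add(SPS, 3)
        if any(_item_risk(r3, i) in _TRIGGERING
               for i in ("3.3.1", "3.3.2", "3.3.3", "3.3.4")):
            add(SF12, 3)
    if 4 in flagged:
        add(BIOIMPEDANCE, 4)
        add(NUTRITION_Q, 4)
    if 5 in flagged:
        mental = response.get("mental_conditions") or frozenset()
        neuro = response.get("neuro_conditions") or frozenset()
        age = response.get("age")
        if "depression" in mental:
            add(HADS, 5)
            if age is not None and age > 65:
                add(GDS30, 5)
        if "anxiety_stress" in mental:
            add(PSS, 5)
        if mental & {"easy_irritation", "ocd", "bipolar", "anorexia", "other"}:
            add(RSES, 5, optional=True)
        if "lack_of_memory" in neuro:
            add(MMSE, 5)
        if "nausea_dizziness_migraine" in neuro:
            add(MIDAS, 5)
        # stroke, parkinson, epilepsy and "other" neurological conditions have
        # no dedicated instrument: they trigger only the component message
        # and the generic EQ-5D-5L below.
    if 6 in flagged:
        add(SUBSTANCES_Q, 6)
    if 7 in flagged:
        add(ESS, 7)
        add(PSQI, 7)
    if 8 in flagged:
        add(SF12, 8)
        chronic = response.get("chronic_conditions") or frozenset()
        if "respiratory_disease" in chronic:
            add(SPIROMETRY, 8)
            add(OXIMETRY, 8)
    if flagged:
        for cid in flagged:
            add(EQ5D, cid)

    instruments = tuple(
        Referral(name, frozenset(triggers), optional)
        for name, (triggers, optional) in sorted(
            acc.items(), key=lambda kv: _INSTRUMENT_ORDER[kv[0]])
    )
    return ReferralPlan(instruments=instruments, triggering_components=flagged)


# ---------------------------------------------------------------------------
# The assembled report


def _jsonable(value: Any) -> Any:
    if isinstance(value, RiskLevel):
        return value.value
    if isinstance(value, (frozenset, set)):
        return sorted(value)
    if isinstance(value, tuple):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    return value


@dataclass(frozen=True)
class AssessmentReport:
    """A complete first-level screening report for one respondent."""

    results: tuple[ComponentResult, ...]
    messages: tuple[Message, ...]
    referral: ReferralPlan
    variant_name: str
    ruleset_version: str
    schema_version: str
    respondent_id: str | None = None
    generated_at: str | None = None

    def with_timestamp(self, timestamp: str) -> "AssessmentReport":
        return replace(self, generated_at=timestamp)

    def to_dict(self) -> dict:
        schema = load_schema()
        meta = {
            "engine": "lifescreen",
            "ruleset_version": self.ruleset_version,
            "schema_version": self.schema_version,
            "rule_variant": self.variant_name,
            "respondent_id": self.respondent_id,
        }
        if self.generated_at is not None:
            meta["generated_at"] = self.generated_at
        return {
            "meta": meta,
            "components": [
                {
                    "id": r.component_id,
                    "title": schema.component(r.component_id).title,
                    "aggregate": r.aggregate.value,
                    "color": r.aggregate.color,
                    "sub_blocks": {k: v.value for k, v in r.sub_block_risks.items()},
                    "items": [
                        {"item": s.item_id, "answer": _jsonable(s.answer),
                         "risk": s.risk.value, "rule": s.rule_id}
                        for s in r.item_scores
                    ],
                }
                for r in self.results
            ],
            "messages": [
                {"component": m.component_id, "sub_block": m.sub_block,
                 "risk": m.risk.value, "text": m.text}
                for m in self.messages
            ],
            "referral": {
                "instruments": [
                    {"name": r.instrument, "optional": r.optional,
                     "triggered_by": sorted(r.triggers)}
                    for r in self.referral.instruments
                ],
                "triggering_components": sorted(self.referral.triggering_components),
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, ensure_ascii=False)

    def to_markdown(self) -> str:
        schema = load_schema()
        lines = ["# Lifestyle screening report", "",
                 f"Rule variant: `{self.variant_name}` "
                 f"(rules v{self.ruleset_version}, "
                 f"questionnaire v{self.schema_version})", ""]
        msgs_by_comp: dict[int, list[Message]] = {}
        for m in self.messages:
            msgs_by_comp.setdefault(m.component_id, []).append(m)
        for r in self.results:
            title = schema.component(r.component_id).title
            lines.append(f"## {r.component_id}. {title} — "
                         f"{r.aggregate.value.upper()} ({r.aggregate.color})")
            lines.append("")
            for m in msgs_by_comp.get(r.component_id, []):
                label = "" if m.sub_block == "main" else f"**{m.sub_block}** "
                tag = m.risk.color if m.risk.scored else "not assessed"
                lines.append(f"- {label}[{tag}] {m.text}")
            lines.append("")
        lines.append("## Second-level assessment referral")
        lines.append("")
        if self.referral.instruments:
            for ref in self.referral.instruments:
                opt = " (optional, academic purposes only)" if ref.optional else ""
                comps = ", ".join(str(c) for c in sorted(ref.triggers))
                lines.append(f"- {ref.instrument}{opt} — triggered by "
                             f"component(s) {comps}")
        else:
            lines.append("No referral: all assessed components are low risk.")
        lines.append("")
        return "\n".join(lines)


def assess(response: ResponseSet | Mapping[str, Any],
           variant: RuleVariant | str | None = None,
           respondent_id: str | None = None) -> AssessmentReport:
    """Validate (if needed), score, and report a single respondent.

    Accepts either a validated :class:`ResponseSet` or a raw record mapping;
    raw records failing validation raise
    :class:`~lifescreen.schema.ResponseValidationError`.
    """
    if not isinstance(response, ResponseSet):
        response = validate_response(response)
    variant = _resolve_variant(variant)
    results = score_assessment(response, variant)
    messages = tuple(select_messages(results))
    referral = build_referral_plan(results, response)
    return AssessmentReport(
        results=tuple(results),
        messages=messages,
        referral=referral,
        variant_name=variant.name,
        ruleset_version=ruleset_version(),
        schema_version=load_schema().version,
        respondent_id=respondent_id,
    )
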
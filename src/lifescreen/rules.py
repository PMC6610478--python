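"""Table-driven risk engine: per-item traffic-light rules and component aggregation.

Every scored questionnaire answer maps to a :class:`RiskLevel` through a
versioned declarative rule table (``data/rules.json``).  Numeric measures
(BMI, waist circumference, blood pressure, glycemia, total cholesterol) use
interval rules with WHO-style cut-offs; categorical items use direct lookup.
A component's aggregate risk is the maximum over its scored items: low only
if every scored answer is green, relevant as soon as one answer is orange,
moderate in between.

Two auditable rule-set editions ("variants") are shipped.  ``as_printed``
applies the rule table verbatim.  ``narrative_corrected`` — the default —
patches two internally inconsistent rows so the table matches the stated
scoring intent: a never-user of illicit substances is low risk (not
moderate), and an ex-smoker's cessation-time answer supersedes the blanket
moderate for having ever smoked, so that quitting more than ten years ago
yields a low smoking risk.
"""
from __future__ import annotations

import functools
import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Any, Mapping, Sequence

from .levels import RiskLevel, max_scored
from .schema import ResponseSet, compute_bmi

__all__ = [
    "ItemScore",
    "ComponentResult",
    "RuleVariant",
    "get_variant",
    "ruleset_version",
    "score_bmi",
    "score_waist",
    "score_blood_pressure",
    "score_lab",
    "score_categorical_item",
    "score_nutrition_frequencies",
    "score_smoking_block",
    "aggregate_component",
    "score_assessment",
    "FOOD_FIELDS",
    "HEALTHY_FOOD_FIELDS",
    "INDULGENT_FOOD_FIELDS",
    "ANIMAL_FOOD_FIELDS",
]

log = logging.getLogger(__name__)

DEFAULT_VARIANT_NAME = "narrative_corrected"

FOOD_FIELDS = (
    "food_vegetables_fruit",
    "food_milk_products",
    "food_fish_meat_eggs",
    "food_bread_pasta_cereal",
    "food_legumes_grains",
    "food_fried_salty",
    "food_sweets",
)
HEALTHY_FOOD_FIELDS = FOOD_FIELDS[:5]
INDULGENT_FOOD_FIELDS = FOOD_FIELDS[5:]
ANIMAL_FOOD_FIELDS = ("food_milk_products", "food_fish_meat_eggs")

_AT_LEAST_4_PER_WEEK = {"once_or_more_per_day", "times_4_6_per_week"}
_LT_ONCE_PER_WEEK = {"lt_once_per_week", "never"}


@functools.lru_cache(maxsize=1)
def _ruleset() -> dict:
    text = (resources.files("lifescreen") / "data" / "rules.json").read_text("utf-8")
    return json.loads(text)


def ruleset_version() -> str:
    return _ruleset()["version"]


@dataclass(frozen=True)
class RuleVariant:
    """A named, auditable edition of the rule set.

    ``overrides`` patches individual (item, answer) cells of the categorical
    table; ``ex_smoker_supersession`` controls whether the cessation-time
    answer replaces the ever-smoked moderate within the smoking sub-block.
    """

    name: str
    overrides: Mapping[str, Mapping[str, RiskLevel]]
    ex_smoker_supersession: bool


@functools.lru_cache(maxsize=None)
def get_variant(name: str | None = None) -> RuleVariant:
    """Return a rule variant by name (default ``narrative_corrected``)."""
    name = name or DEFAULT_VARIANT_NAME
    try:
        raw = _ruleset()["variants"][name]
    except KeyError:
        known = sorted(_ruleset()["variants"])
        raise KeyError(f"unknown rule variant {name!r}; known: {known}") from None
    overrides = {
        item: {ans: RiskLevel(risk) for ans, risk in cells.items()}
        for item, cells in raw["overrides"].items()
    }
    return RuleVariant(name=name, overrides=overrides,
                       ex_smoker_supersession=bool(raw["ex_smoker_supersession"]))


@dataclass(frozen=True)
class ItemScore:
    """Risk assigned to one questionnaire item, with the rule that produced it."""

    item_id: str
    answer: Any
    risk: RiskLevel
    rule_id: str


@dataclass(frozen=True)
class ComponentResult:
    """Per-item risks plus the aggregate for one of the 8 components."""

    component_id: int
    item_scores: tuple[ItemScore, ...]
    aggregate: RiskLevel
    sub_block_risks: Mapping[str, RiskLevel]


# ---------------------------------------------------------------------------
# Numeric rules


def score_bmi(bmi: float) -> RiskLevel:
    """Classify body mass index (kg/m^2).

    Low on [18.5, 25); moderate below 18.5 (underweight) or on [25, 30)
    (overweight); relevant at 30 and above (obesity).  Thresholds are applied
    to the unrounded value with no epsilon tolerance.
    """
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    t = _ruleset()["numeric"]["bmi"]
    if bmi >= t["relevant_min"]:
        return RiskLevel.RELEVANT
    if bmi >= t["moderate_min"] or bmi < t["low_min"]:
        return RiskLevel.MODERATE
    return RiskLevel.LOW


def score_waist(waist: float, sex: str) -> RiskLevel:
    """Classify waist circumference (cm) with sex-specific cut-offs.

    Men: low <94, moderate 94-102 (inclusive), relevant >102.
    Women: low <80, moderate 80-88 (inclusive), relevant >88.
    """
    if waist <= 0:
        raise ValueError("waist circumference must be positive")
    try:
        t = _ruleset()["numeric"]["waist"][sex]
    except KeyError:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}") from None
    if waist > t["relevant_gt"]:
        return RiskLevel.RELEVANT
    if waist >= t["moderate_min"]:
        return RiskLevel.MODERATE
    return RiskLevel.LOW


def score_blood_pressure(sbp: float, dbp: float) -> RiskLevel:
    """Classify blood pressure (mmHg); the relevant rule is disjunctive.

    Relevant if SBP >= 140 or DBP >= 90; moderate if SBP in [130, 140) or
    DBP in [85, 90); low if SBP < 130 and DBP < 85.
    """
    t = _ruleset()["numeric"]["blood_pressure"]
    if sbp >= t["sbp_relevant_min"] or dbp >= t["dbp_relevant_min"]:
        return RiskLevel.RELEVANT
    if sbp >= t["sbp_moderate_min"] or dbp >= t["dbp_moderate_min"]:
        return RiskLevel.MODERATE
    return RiskLevel.LOW


def score_lab(value_or_category: float | str, lab: str) -> RiskLevel:
    """Classify a self-reported lab value (mg/dl) or its category.

    Glycemia: low <110, moderate [110, 126), relevant >=126.
    Cholesterol: low <190, moderate [190, 240), relevant >=240.
    Categorical fallback when no number is known: normal -> low,
    high -> moderate, unknown -> not scored.
    """
    if lab not in ("glycemia", "cholesterol"):
        raise ValueError(f"lab must be 'glycemia' or 'cholesterol', got {lab!r}")
    if isinstance(value_or_category, str):
        fallback = _ruleset()["lab_category_fallback"]
        try:
            return RiskLevel(fallback[value_or_category])
        except KeyError:
            raise ValueError(
                f"unknown lab category {value_or_category!r}") from None
    value = float(value_or_category)
    if value <= 0:
        raise ValueError("lab value must be positive")
    t = _ruleset()["numeric"][lab]
    if value >= t["relevant_min"]:
        return RiskLevel.RELEVANT
    if value >= t["moderate_min"]:
        return RiskLevel.MODERATE
    return RiskLevel.LOW


# ---------------------------------------------------------------------------
# Categorical rules


def score_categorical_item(item_id: str, answer: str,
                           variant: RuleVariant | str | None = None) -> RiskLevel:
    """Look up the traffic-light risk for a categorical answer.

    The mapping is the declarative rule table, patched by the chosen
    variant's overrides.  Unknown (item, answer) pairs raise ``KeyError``.
    """
    variant = _resolve_variant(variant)
    table = _ruleset()["categorical"]
    if item_id not in table:
        raise KeyError(f"no categorical rule for item {item_id!r}")
    override = variant.overrides.get(item_id, {})
    if answer in override:
        return override[answer]
    cells = table[item_id]
    if answer not in cells:
        raise KeyError(f"answer {answer!r} is not in the domain of item {item_id}")
    return RiskLevel(cells[answer])


def _resolve_variant(variant: RuleVariant | str | None) -> RuleVariant:
    if isinstance(variant, RuleVariant):
        return variant
    return get_variant(variant)


def score_nutrition_frequencies(freqs: Mapping[str, str],
                                exemption: bool = False) -> RiskLevel:
    """Score the weekly food-frequency grid (7 food groups).

    Low requires every healthy group (vegetables/fruit, milk products,
    fish/meat/eggs, bread/pasta/cereal, legumes/grains) at four or more times
    per week AND both indulgent groups (fried/salty, sweets) under once per
    week.  Relevant when any healthy group is never consumed, or when either
    indulgent group reaches four or more times per week.  Everything else is
    moderate.  An incomplete grid is not scored.

    With the dietary-exemption flag (religious or vegetarian/vegan habits),
    "never" on the animal-product groups does not trigger the relevant rule.
    """
    values = {f: freqs.get(f) for f in FOOD_FIELDS}
    if any(v is None for v in values.values()):
        return RiskLevel.NOT_SCORED
    exempt = set(ANIMAL_FOOD_FIELDS) if exemption else set()
    never_healthy = any(values[f] == "never" and f not in exempt
                        for f in HEALTHY_FOOD_FIELDS)
    frequent_indulgent = any(values[f] in _AT_LEAST_4_PER_WEEK
                             for f in INDULGENT_FOOD_FIELDS)
    if never_healthy or frequent_indulgent:
        return RiskLevel.RELEVANT
    all_healthy_frequent = all(values[f] in _AT_LEAST_4_PER_WEEK
                               for f in HEALTHY_FOOD_FIELDS)
    all_indulgent_rare = all(values[f] in _LT_ONCE_PER_WEEK
                             for f in INDULGENT_FOOD_FIELDS)
    if all_healthy_frequent and all_indulgent_rare:
        return RiskLevel.LOW
    return RiskLevel.MODERATE


def score_smoking_block(a61: str | None, a62: str | None, a63: str | None,
                        variant: RuleVariant | str | None = None
                        ) -> tuple[list[ItemScore], RiskLevel]:
    """Score the three smoking items (current, past, time since quitting).

    A current smoker is relevant.  For an ex-smoker, the cessation-time
    answer refines the risk: under the default ``narrative_corrected``
    variant it supersedes the blanket moderate for having ever smoked (the
    ever-smoked item is recorded as not scored), so quitting more than ten
    years ago leaves the whole block at low risk.  Under ``as_printed`` both
    items contribute and a long-quit ex-smoker stays moderate.
    """
    variant = _resolve_variant(variant)
    if a63 is not None and not (a61 == "no" and a62 == "yes"):
        raise ValueError(
            "cessation time (item 6.3) is only asked of ex-smokers "
            "(item 6.1 'no' and item 6.2 'yes')")

    def _lookup(item_id: str, answer: str | None) -> ItemScore:
        if answer is None:
            return ItemScore(item_id, None, RiskLevel.NOT_SCORED, f"{item_id}:missing")
        return ItemScore(item_id, answer,
                         score_categorical_item(item_id, answer, variant), item_id)

    s61 = _lookup("6.1", a61)
    s62 = _lookup("6.2", a62)
    s63 = _lookup("6.3", a63)
    if variant.ex_smoker_supersession and a63 is not None:
        s62 = ItemScore("6.2", a62, RiskLevel.NOT_SCORED, "6.2:superseded-by-6.3")
    scores = [s61, s62, s63]
    return scores, max_scored(s.risk for s in scores)


# ---------------------------------------------------------------------------
# Aggregation and whole-questionnaire scoring


def aggregate_component(item_scores: Sequence[ItemScore | RiskLevel]) -> RiskLevel:
    """Aggregate item risks for one component.

    Relevant if at least one scored answer is orange; moderate if at least
    one is yellow without any orange; low if all scored answers are green;
    not scored when no item carries risk information.
    """
    levels = [s.risk if isinstance(s, ItemScore) else s for s in item_scores]
    return max_scored(levels)


def _cat_item(resp: ResponseSet, item_id: str, field: str,
              variant: RuleVariant) -> ItemScore:
    answer = resp.get(field)
    if answer is None:
        return ItemScore(item_id, None, RiskLevel.NOT_SCORED, f"{item_id}:missing")
    return ItemScore(item_id, answer,
                     score_categorical_item(item_id, answer, variant), item_id)


def _checklist_item(resp: ResponseSet, item_id: str, field: str,
                    variant: RuleVariant) -> ItemScore:
    answer = resp.get(field)
    if answer is None:
        return ItemScore(item_id, None, RiskLevel.NOT_SCORED, f"{item_id}:missing")
    token = "yes" if answer else "no"
    return ItemScore(item_id, sorted(answer) if answer else "no",
                     score_categorical_item(item_id, token, variant), item_id)


def _score_component_1(resp: ResponseSet) -> ComponentResult:
    weight, height = resp.get("weight"), resp.get("height")
    if weight is not None and height is not None:
        bmi = compute_bmi(weight, height)
        s11 = ItemScore("1.1", bmi, score_bmi(bmi), "bmi")
    else:
        s11 = ItemScore("1.1", None, RiskLevel.NOT_SCORED, "bmi:missing")

    waist, sex = resp.get("waist"), resp.get("sex")
    if waist is not None and sex is not None:
        s12 = ItemScore("1.2", waist, score_waist(waist, sex), "waist")
    else:
        s12 = ItemScore("1.2", None, RiskLevel.NOT_SCORED, "waist:missing")

    sbp, dbp = resp.get("sbp"), resp.get("dbp")
    if sbp is not None and dbp is not None:
        s13 = ItemScore("1.3", (sbp, dbp), score_blood_pressure(sbp, dbp),
                        "blood_pressure")
    else:
        s13 = ItemScore("1.3", None, RiskLevel.NOT_SCORED, "blood_pressure:missing")

    def _lab(item_id: str, lab: str) -> ItemScore:
        value = resp.get(lab)
        category = resp.get(f"{lab}_category")
        if value is not None:  # a number takes precedence over the category
            return ItemScore(item_id, value, score_lab(value, lab), lab)
        if category is not None:
            return ItemScore(item_id, category, score_lab(category, lab),
                             f"{lab}:categorical")
        return ItemScore(item_id, None, RiskLevel.NOT_SCORED, f"{lab}:missing")

    s14 = _lab("1.4", "glycemia")
    s15 = _lab("1.5", "cholesterol")

    scores = (s11, s12, s13, s14, s15)
    sub_blocks = {
        "bmi_wc": max_scored((s11.risk, s12.risk)),
        "bp": s13.risk,
        "glycemia": s14.risk,
        "cholesterol": s15.risk,
    }
    return ComponentResult(1, scores, aggregate_component(scores), sub_blocks)


def _score_component_6(resp: ResponseSet, variant: RuleVariant) -> ComponentResult:
    smoking_scores, smoking_risk = score_smoking_block(
        resp.get("smokes"), resp.get("smoked_before"), resp.get("quit_smoking"),
        variant)
    s64 = _cat_item(resp, "6.4", "alcohol", variant)
    s65 = _cat_item(resp, "6.5", "alcohol_before", variant)
    s66 = _cat_item(resp, "6.6", "drugs", variant)
    s67 = _cat_item(resp, "6.7", "drugs_before", variant)
    scores = tuple(smoking_scores) + (s64, s65, s66, s67)
    sub_blocks = {
        "smoking": smoking_risk,
        "drinking": max_scored((s64.risk, s65.risk)),
        "illicit": max_scored((s66.risk, s67.risk)),
    }
    return ComponentResult(6, scores, aggregate_component(scores), sub_blocks)


def score_assessment(resp: ResponseSet,
                     variant: RuleVariant | str | None = None
                     ) -> list[ComponentResult]:
    """Score a validated response: one :class:`ComponentResult` per component.

    Deterministic: identical input yields identical output.  Missing answers
    score ``NOT_SCORED`` and are excluded from aggregation; an entirely
    unanswered component aggregates to ``NOT_SCORED``.
    """
    variant = _resolve_variant(variant)
    results: list[ComponentResult] = []

    results.append(_score_component_1(resp))

    c2 = tuple(_cat_item(resp, i, f, variant) for i, f in
               (("2.1", "sedentary"), ("2.2", "walking"),
                ("2.3", "exercise"), ("2.4", "exercise_days")))
    results.append(ComponentResult(2, c2, aggregate_component(c2), {}))

    c3 = tuple(_cat_item(resp, i, f, variant) for i, f in
               (("3.1", "life_satisfaction"), ("3.2", "support_network"),
                ("3.3.1", "adl_hygiene"), ("3.3.2", "adl_mobility"),
                ("3.3.3", "adl_money"), ("3.3.4", "adl_digital")))
    results.append(ComponentResult(3, c3, aggregate_component(c3), {}))

    s41 = _cat_item(resp, "4.1", "healthy_diet", variant)
    freqs = {f: resp.get(f) for f in FOOD_FIELDS}
    if all(v is None for v in freqs.values()):
        s42 = ItemScore("4.2", None, RiskLevel.NOT_SCORED, "4.2:missing")
    else:
        exemption = bool(resp.get("dietary_exemption", False))
        risk42 = score_nutrition_frequencies(freqs, exemption)
        rule42 = "4.2:exempt" if exemption else "4.2"
        s42 = ItemScore("4.2", {k: v for k, v in freqs.items() if v is not None},
                        risk42, rule42)
    c4 = (s41, s42)
    results.append(ComponentResult(4, c4, aggregate_component(c4), {}))

    c5 = (_checklist_item(resp, "5.1", "mental_conditions", variant),
          _checklist_item(resp, "5.2", "neuro_conditions", variant))
    results.append(ComponentResult(5, c5, aggregate_component(c5), {}))

    results.append(_score_component_6(resp, variant))

    c7 = tuple(_cat_item(resp, i, f, variant) for i, f in
               (("7.1", "sleeps_well"), ("7.2", "sleep_hours"),
                ("7.3", "night_wakings"), ("7.4", "wakes_tired"),
                ("7.5", "sleeping_pills")))
    results.append(ComponentResult(7, c7, aggregate_component(c7), {}))

    vas = resp.get("health_vas")
    c8 = (_checklist_item(resp, "8.1", "chronic_conditions", variant),
          _cat_item(resp, "8.2", "daily_medications", variant),
          _cat_item(resp, "8.3", "natural_products", variant),
          _cat_item(resp, "8.4", "health_perception", variant),
          ItemScore("8.5", vas, RiskLevel.NOT_SCORED, "8.5:unscored"))
    results.append(ComponentResult(8, c8, aggregate_component(c8), {}))

    if log.isEnabledFor(logging.DEBUG):
        for result in results:
            for s in result.item_scores:
                log.debug("item %s -> rule %s -> %s", s.item_id, s.rule_id,
                          s.risk.value)
    return results
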
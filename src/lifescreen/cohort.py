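"""Seeded synthetic respondent cohorts and batch assessment summaries.

The generator draws skip-logic-consistent questionnaire records from
configurable marginal distributions: truncated-normal continuous vitals
(truncation inside the validator ranges, so generated records always
validate), categorical answers from probability vectors, and checklists from
a none-probability plus per-condition weights.  Factors are sampled
independently — the cohort exercises the rule plumbing, it makes no
epidemiological claim.  Missingness is applied after skip logic so that
structurally absent items are not double-counted, and a dropped parent
answer always drops its gated children.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.special import ndtr, ndtri

from .levels import RiskLevel
from .report import AssessmentReport, assess
from .schema import ResponseSet, load_schema, validate_response

__all__ = [
    "TruncNormal",
    "ChecklistSpec",
    "CohortSpec",
    "CohortSummary",
    "generate_records",
    "generate_cohort",
    "assess_cohort",
    "summarize_cohort",
]


class TruncNormal(BaseModel):
    """Location-scale normal truncated to [lo, hi]."""

    model_config = ConfigDict(extra="forbid")
    loc: float
    scale: float = Field(gt=0)
    lo: float
    hi: float

    @model_validator(mode="after")
    def _ordered(self) -> "TruncNormal":
        if not self.lo < self.hi:
            raise ValueError("truncation requires lo < hi")
        return self

    def sample(self, rng: np.random.Generator) -> float:
        a = ndtr((self.lo - self.loc) / self.scale)
        b = ndtr((self.hi - self.loc) / self.scale)
        u = rng.random()
        x = self.loc + self.scale * ndtri(a + u * (b - a))
        return float(min(max(x, self.lo), self.hi))


class ChecklistSpec(BaseModel):
    """Marginals for a multi-select item: P(none) plus per-option weights."""

    model_config = ConfigDict(extra="forbid")
    p_none: float = Field(ge=0, le=1)
    weights: dict[str, float]

    @field_validator("weights")
    @classmethod
    def _unit_weights(cls, w: dict[str, float]) -> dict[str, float]:
        for k, v in w.items():
            if not 0 <= v <= 1:
                raise ValueError(f"weight for {k!r} must be in [0, 1]")
        return w

    def sample(self, rng: np.random.Generator, domain: Sequence[str],
               none_token: str) -> str:
        if rng.random() < self.p_none:
            return none_token
        options = [t for t in domain if t != none_token]
        picked = [t for t in options if rng.random() < self.weights.get(t, 0.0)]
        if not picked:
            weights = np.array([self.weights.get(t, 0.0) for t in options])
            if weights.sum() <= 0:
                return none_token
            picked = [options[int(rng.choice(len(options), p=weights / weights.sum()))]]
        return ";".join(picked)


_PROB_TOL = 1e-9

_DEFAULT_CONTINUOUS: dict[str, dict] = {
    "weight": {"loc": 74.0, "scale": 14.0, "lo": 40.0, "hi": 160.0},
    "height": {"loc": 1.67, "scale": 0.10, "lo": 1.45, "hi": 2.05},
    "waist": {"loc": 92.0, "scale": 13.0, "lo": 55.0, "hi": 150.0},
    "sbp": {"loc": 128.0, "scale": 18.0, "lo": 90.0, "hi": 210.0},
    "dbp": {"loc": 78.0, "scale": 11.0, "lo": 50.0, "hi": 120.0},
    "glycemia": {"loc": 100.0, "scale": 25.0, "lo": 60.0, "hi": 400.0},
    "cholesterol": {"loc": 205.0, "scale": 38.0, "lo": 90.0, "hi": 400.0},
}

_FREQ = ("once_or_more_per_day", "times_4_6_per_week", "times_1_3_per_week",
         "lt_once_per_week", "never")


def _freq(p: Sequence[float]) -> dict[str, float]:
    return dict(zip(_FREQ, p))


_DEFAULT_CATEGORICAL: dict[str, dict[str, float]] = {
    "education": {"none": 0.02, "basic_1st_cycle": 0.12, "basic_2nd_cycle": 0.10,
                  "basic_3rd_cycle": 0.18, "secondary": 0.28, "higher": 0.28,
                  "prefer_not_to_answer": 0.02},
    "employment": {"unemployed": 0.07, "employed": 0.50, "student": 0.08,
                   "unable_to_work": 0.03, "retired": 0.30,
                   "prefer_not_to_answer": 0.02},
    "glycemia_category": {"normal": 0.70, "high": 0.15, "unknown": 0.15},
    "cholesterol_category": {"normal": 0.60, "high": 0.25, "unknown": 0.15},
    "sedentary": {"yes": 0.35, "no": 0.65},
    "walking": {"lt30": 0.30, "30to60": 0.40, "gt60": 0.30},
    "exercise": {"yes": 0.45, "no": 0.55},
    "exercise_days": {"one_or_two": 0.45, "three_or_more": 0.55},
    "life_satisfaction": {"strongly_disagree": 0.03, "disagree": 0.07,
                          "neutral": 0.15, "agree": 0.45, "strongly_agree": 0.25,
                          "prefer_not_to_answer": 0.05},
    "support_network": {"none": 0.05, "one_or_two": 0.20, "three_to_five": 0.40,
                        "six_or_more": 0.35},
    "adl_hygiene": {"yes": 0.92, "no": 0.08},
    "adl_mobility": {"yes": 0.85, "no": 0.15},
    "adl_money": {"yes": 0.85, "no": 0.10, "not_applicable": 0.05},
    "adl_digital": {"yes": 0.60, "no": 0.30, "not_applicable": 0.10},
    "healthy_diet": {"yes": 0.65, "no": 0.35},
    "food_vegetables_fruit": _freq([0.45, 0.25, 0.20, 0.07, 0.03]),
    "food_milk_products": _freq([0.50, 0.20, 0.15, 0.10, 0.05]),
    "food_fish_meat_eggs": _freq([0.35, 0.35, 0.20, 0.07, 0.03]),
    "food_bread_pasta_cereal": _freq([0.55, 0.25, 0.12, 0.05, 0.03]),
    "food_legumes_grains": _freq([0.15, 0.25, 0.35, 0.18, 0.07]),
    "food_fried_salty": _freq([0.05, 0.12, 0.30, 0.38, 0.15]),
    "food_sweets": _freq([0.12, 0.18, 0.30, 0.28, 0.12]),
    "smokes": {"yes": 0.18, "no": 0.82},
    "smoked_before": {"yes": 0.30, "no": 0.70},
    "quit_smoking": {"lt_1y": 0.10, "1_to_5y": 0.25, "5_to_10y": 0.25,
                     "gt_10y": 0.40},
    "alcohol": {"yes": 0.30, "no": 0.70},
    "alcohol_before": {"yes": 0.25, "no": 0.75},
    "drugs": {"yes": 0.03, "no": 0.97},
    "drugs_before": {"yes": 0.07, "no": 0.93},
    "sleeps_well": {"yes": 0.70, "no": 0.30},
    "sleep_hours": {"lt5h": 0.12, "5to7h": 0.38, "ge7h": 0.50},
    "night_wakings": {"never_or_once": 0.45, "2_3_times": 0.40, "4_or_more": 0.15},
    "wakes_tired": {"yes": 0.35, "no": 0.65},
    "sleeping_pills": {"yes": 0.15, "no": 0.85},
    "daily_medications": {"none_or_one": 0.55, "two_to_five": 0.35,
                          "more_than_five": 0.10},
    "natural_products": {"yes": 0.25, "no": 0.75},
    "health_perception": {"very_good": 0.10, "good": 0.40, "reasonable": 0.38,
                          "bad": 0.10, "very_bad": 0.02},
}

_DEFAULT_CHECKLIST: dict[str, dict] = {
    "exercise_types": {"p_none": 0.0,
                       "weights": {"ball_games": 0.15, "running_outdoor": 0.25,
                                   "group_lessons": 0.25, "fitness_equipment": 0.30,
                                   "swimming": 0.20, "other": 0.15}},
    "mental_conditions": {"p_none": 0.78,
                          "weights": {"depression": 0.45, "anxiety_stress": 0.55,
                                      "easy_irritation": 0.15, "ocd": 0.05,
                                      "bipolar": 0.04, "anorexia": 0.02,
                                      "other": 0.10}},
    "neuro_conditions": {"p_none": 0.88,
                         "weights": {"stroke": 0.15, "parkinson": 0.05,
                                     "epilepsy": 0.07, "lack_of_memory": 0.45,
                                     "nausea_dizziness_migraine": 0.35,
                                     "other": 0.10}},
    "chronic_conditions": {"p_none": 0.70,
                           "weights": {"heart_disease": 0.25, "neuropathy": 0.08,
                                       "respiratory_disease": 0.25,
                                       "retinopathy": 0.08,
                                       "peripheral_arterial_disease": 0.07,
                                       "nephropathy": 0.05, "other": 0.20}},
}


class CohortSpec(BaseModel):
    """Seeded parameterization of the synthetic respondent generator."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=200, ge=0)
    seed: int = 0
    p_female: float = Field(default=0.52, ge=0, le=1)
    age: TruncNormal = Field(
        default_factory=lambda: TruncNormal(loc=48, scale=18, lo=18, hi=95))
    continuous: dict[str, TruncNormal] = Field(
        default_factory=lambda: {k: TruncNormal(**v)
                                 for k, v in _DEFAULT_CONTINUOUS.items()})
    p_numeric_lab: dict[str, float] = Field(
        default_factory=lambda: {"glycemia": 0.30, "cholesterol": 0.30})
    categorical: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in _DEFAULT_CATEGORICAL.items()})
    checklist: dict[str, ChecklistSpec] = Field(
        default_factory=lambda: {k: ChecklistSpec(**v)
                                 for k, v in _DEFAULT_CHECKLIST.items()})
    p_dietary_exemption: float = Field(default=0.03, ge=0, le=1)
    missing_rate: float = Field(default=0.02, ge=0, le=1)
    missingness: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_marginals(self) -> "CohortSpec":
        schema = load_schema()
        for name, probs in self.categorical.items():
            spec = schema.fields.get(name)
            if spec is None or spec.type != "categorical":
                raise ValueError(f"{name!r} is not a categorical questionnaire field")
            unknown = set(probs) - set(spec.domain)
            if unknown:
                raise ValueError(f"{name}: unknown answer tokens {sorted(unknown)}")
            total = sum(probs.values())
            if abs(total - 1.0) > _PROB_TOL:
                raise ValueError(f"{name}: probabilities sum to {total}, not 1")
        for name, tn in {**self.continuous, "age": self.age}.items():
            fname = name if name != "age" else "age"
            spec = schema.fields.get(fname)
            if spec is None:
                raise ValueError(f"{name!r} is not a questionnaire field")
            if spec.min is not None and tn.lo < spec.min or \
               spec.max is not None and tn.hi > spec.max:
                raise ValueError(
                    f"{name}: truncation [{tn.lo}, {tn.hi}] outside the "
                    f"validator range [{spec.min}, {spec.max}]")
        for name, rate in self.missingness.items():
            if name not in schema.fields:
                raise ValueError(f"missingness: unknown field {name!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness[{name!r}] must be in [0, 1]")
        return self

    @classmethod
    def lowest_risk(cls, n: int = 100, seed: int = 0) -> "CohortSpec":
        """A degenerate spec whose every answer scores low by construction."""

        def point(token: str, domain_field: str) -> dict[str, float]:
            domain = load_schema().fields[domain_field].domain
            return {t: (1.0 if t == token else 0.0) for t in domain}

        categorical = {k: dict(v) for k, v in _DEFAULT_CATEGORICAL.items()}
        for field_name, token in [
            ("sedentary", "no"), ("walking", "gt60"), ("exercise", "yes"),
            ("exercise_days", "three_or_more"),
            ("life_satisfaction", "strongly_agree"),
            ("support_network", "six_or_more"),
            ("adl_hygiene", "yes"), ("adl_mobility", "yes"),
            ("adl_money", "yes"), ("adl_digital", "yes"),
            ("healthy_diet", "yes"),
            ("food_vegetables_fruit", "once_or_more_per_day"),
            ("food_milk_products", "once_or_more_per_day"),
            ("food_fish_meat_eggs", "times_4_6_per_week"),
            ("food_bread_pasta_cereal", "once_or_more_per_day"),
            ("food_legumes_grains", "times_4_6_per_week"),
            ("food_fried_salty", "lt_once_per_week"),
            ("food_sweets", "never"),
            ("smokes", "no"), ("smoked_before", "no"),
            ("alcohol", "no"), ("alcohol_before", "no"),
            ("drugs", "no"), ("drugs_before", "no"),
            ("sleeps_well", "yes"), ("sleep_hours", "ge7h"),
            ("night_wakings", "never_or_once"), ("wakes_tired", "no"),
            ("sleeping_pills", "no"),
            ("daily_medications", "none_or_one"), ("natural_products", "no"),
            ("health_perception", "very_good"),
        ]:
            categorical[field_name] = point(token, field_name)
        checklist = {
            "exercise_types": ChecklistSpec(p_none=0.0,
                                            weights={"fitness_equipment": 1.0}),
            "mental_conditions": ChecklistSpec(p_none=1.0, weights={}),
            "neuro_conditions": ChecklistSpec(p_none=1.0, weights={}),
            "chronic_conditions": ChecklistSpec(p_none=1.0, weights={}),
        }
        continuous = {
            "weight": TruncNormal(loc=65, scale=1.0, lo=62, hi=68),
            "height": TruncNormal(loc=1.72, scale=0.02, lo=1.68, hi=1.76),
            "waist": TruncNormal(loc=74, scale=2.0, lo=68, hi=79),
            "sbp": TruncNormal(loc=112, scale=5.0, lo=100, hi=125),
            "dbp": TruncNormal(loc=70, scale=4.0, lo=60, hi=80),
            "glycemia": TruncNormal(loc=90, scale=6.0, lo=70, hi=105),
            "cholesterol": TruncNormal(loc=165, scale=10.0, lo=120, hi=185),
        }
        return cls(n=n, seed=seed, continuous=continuous,
                   categorical=categorical, checklist=checklist,
                   p_numeric_lab={"glycemia": 1.0, "cholesterol": 1.0},
                   p_dietary_exemption=0.0, missing_rate=0.0)


# ---------------------------------------------------------------------------
# Generation


def _choice(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    tokens = list(probs)
    p = np.array([probs[t] for t in tokens], dtype=float)
    return tokens[int(rng.choice(len(tokens), p=p / p.sum()))]


# fields never dropped by missingness: demographics anchor skip logic and the
# on-site measurements are taken by staff, not self-reported
_ALWAYS_PRESENT = {"age", "sex"}


def _one_record(spec: CohortSpec, rng: np.random.Generator,
                schema) -> dict[str, Any]:
    rec: dict[str, Any] = {}
    rec["age"] = int(round(spec.age.sample(rng)))
    rec["sex"] = "female" if rng.random() < spec.p_female else "male"
    rec["education"] = _choice(rng, spec.categorical["education"])
    rec["employment"] = _choice(rng, spec.categorical["employment"])

    rec["weight"] = round(spec.continuous["weight"].sample(rng), 1)
    rec["height"] = round(spec.continuous["height"].sample(rng), 2)
    rec["waist"] = round(spec.continuous["waist"].sample(rng), 1)
    sbp = round(spec.continuous["sbp"].sample(rng))
    dbp = round(spec.continuous["dbp"].sample(rng))
    if dbp >= sbp:  # keep the physiological ordering the validator enforces
        dbp = sbp - 5
    rec["sbp"], rec["dbp"] = float(sbp), float(dbp)

    for lab in ("glycemia", "cholesterol"):
        if rng.random() < spec.p_numeric_lab[lab]:
            rec[lab] = round(spec.continuous[lab].sample(rng))
        else:
            rec[f"{lab}_category"] = _choice(rng, spec.categorical[f"{lab}_category"])

    rec["sedentary"] = _choice(rng, spec.categorical["sedentary"])
    rec["walking"] = _choice(rng, spec.categorical["walking"])
    rec["exercise"] = _choice(rng, spec.categorical["exercise"])
    if rec["exercise"] == "yes":
        ck = spec.checklist["exercise_types"]
        fs = schema.fields["exercise_types"]
        picked = ck.sample(rng, fs.domain, none_token="")
        if picked:
            rec["exercise_types"] = picked
        rec["exercise_days"] = _choice(rng, spec.categorical["exercise_days"])

    rec["life_satisfaction"] = _choice(rng, spec.categorical["life_satisfaction"])
    rec["support_network"] = _choice(rng, spec.categorical["support_network"])
    if rec["age"] > 65:
        for f in ("adl_hygiene", "adl_mobility", "adl_money", "adl_digital"):
            rec[f] = _choice(rng, spec.categorical[f])

    rec["healthy_diet"] = _choice(rng, spec.categorical["healthy_diet"])
    for f in ("food_vegetables_fruit", "food_milk_products", "food_fish_meat_eggs",
              "food_bread_pasta_cereal", "food_legumes_grains",
              "food_fried_salty", "food_sweets"):
        rec[f] = _choice(rng, spec.categorical[f])
    rec["dietary_exemption"] = ("true" if rng.random() < spec.p_dietary_exemption
                                else "false")

    for f in ("mental_conditions", "neuro_conditions"):
        fs = schema.fields[f]
        rec[f] = spec.checklist[f].sample(rng, fs.domain, fs.none_token)

    rec["smokes"] = _choice(rng, spec.categorical["smokes"])
    if rec["smokes"] == "yes":
        rec["smoked_before"] = "yes" if rng.random() < 0.5 else "no"
    else:
        rec["smoked_before"] = _choice(rng, spec.categorical["smoked_before"])
        if rec["smoked_before"] == "yes":
            rec["quit_smoking"] = _choice(rng, spec.categorical["quit_smoking"])
    for f in ("alcohol", "alcohol_before", "drugs", "drugs_before",
              "sleeps_well", "sleep_hours", "night_wakings", "wakes_tired",
              "sleeping_pills"):
        rec[f] = _choice(rng, spec.categorical[f])

    fs = schema.fields["chronic_conditions"]
    rec["chronic_conditions"] = spec.checklist["chronic_conditions"].sample(
        rng, fs.domain, fs.none_token)
    rec["daily_medications"] = _choice(rng, spec.categorical["daily_medications"])
    rec["natural_products"] = _choice(rng, spec.categorical["natural_products"])
    rec["health_perception"] = _choice(rng, spec.categorical["health_perception"])
    rec["health_vas"] = int(rng.integers(0, 101))

    # missingness last, after skip logic; dropping a parent drops its children
    for f in list(rec):
        if f in _ALWAYS_PRESENT:
            continue
        rate = spec.missingness.get(f, spec.missing_rate)
        if rate and rng.random() < rate:
            del rec[f]
    if "smokes" not in rec or "smoked_before" not in rec:
        rec.pop("quit_smoking", None)
    if "exercise" not in rec or rec.get("exercise") == "no":
        rec.pop("exercise_days", None)
        rec.pop("exercise_types", None)
    return rec


def generate_records(spec: CohortSpec) -> list[dict[str, Any]]:
    """Draw ``spec.n`` raw records; fixed seed gives an identical cohort."""
    rng = np.random.default_rng(spec.seed)
    schema = load_schema()
    return [_one_record(spec, rng, schema) for _ in range(spec.n)]


def generate_cohort(spec: CohortSpec) -> list[ResponseSet]:
    """Generate and validate a cohort; every record passes validation."""
    return [validate_response(rec) for rec in generate_records(spec)]


def assess_cohort(responses: Iterable[ResponseSet],
                  variant: str | None = None) -> list[AssessmentReport]:
    return [assess(r, variant=variant) for r in responses]


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class CohortSummary:
    """Batch outcome tallies: risk distribution and referral burden."""

    n: int
    component_counts: Mapping[int, Mapping[str, int]]
    referral_rate: float
    instrument_counts: Mapping[str, int]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "component_counts": {str(cid): dict(c)
                                 for cid, c in sorted(self.component_counts.items())},
            "referral_rate": self.referral_rate,
            "instrument_counts": dict(sorted(self.instrument_counts.items())),
        }

    def to_frame(self) -> pd.DataFrame:
        """Per-component risk counts as a table (components x risk levels)."""
        levels = [lv.value for lv in RiskLevel]
        rows = {cid: [self.component_counts[cid].get(lv, 0) for lv in levels]
                for cid in sorted(self.component_counts)}
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=levels)
        frame.index.name = "component"
        return frame


def _report_aggregates(report: AssessmentReport | Mapping) -> dict[int, str]:
    if isinstance(report, AssessmentReport):
        return {r.component_id: r.aggregate.value for r in report.results}
    return {int(c["id"]): c["aggregate"] for c in report["components"]}


def _report_instruments(report: AssessmentReport | Mapping) -> list[str]:
    if isinstance(report, AssessmentReport):
        return [r.instrument for r in report.referral.instruments]
    return [i["name"] for i in report["referral"]["instruments"]]


def summarize_cohort(reports: Sequence[AssessmentReport | Mapping]
                     ) -> CohortSummary:
    """Tally component risks and referral burden over assessed reports.

    Accepts in-memory :class:`AssessmentReport` objects or their JSON dict
    form (as read back from stored report files).
    """
    n = len(reports)
    counts: dict[int, Counter] = {cid: Counter() for cid in range(1, 9)}
    instruments: Counter = Counter()
    referred = 0
    for report in reports:
        for cid, agg in _report_aggregates(report).items():
            counts[cid][agg] += 1
        names = _report_instruments(report)
        instruments.update(names)
        if names:
            referred += 1
    rate = referred / n if n else 0.0
    return CohortSummary(
        n=n,
        component_counts={cid: dict(c) for cid, c in counts.items()},
        referral_rate=rate,
        instrument_counts=dict(instruments),
    )
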
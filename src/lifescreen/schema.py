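"""Questionnaire data model: bundled schema, response validation, derived measures.

The questionnaire is shipped as versioned declarative data
(``data/questionnaire.json``): eight scored components plus a short
demographic block, each item with its printed numbering, answer domain and
skip-logic gate.  This module loads that schema, validates raw respondent
records against it (answer domains, numeric ranges, skip logic) and computes
the derived body mass index.
"""
from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

__all__ = [
    "FieldSpec",
    "ItemSpec",
    "ComponentSpec",
    "QuestionnaireSchema",
    "SchemaError",
    "ValidationIssue",
    "ResponseValidationError",
    "ResponseSet",
    "load_schema",
    "validation_errors",
    "validate_response",
    "compute_bmi",
    "walking_minutes_to_answer",
    "sleep_hours_to_answer",
    "night_wakings_to_answer",
    "years_since_quit_to_answer",
]


class SchemaError(RuntimeError):
    """The bundled questionnaire data is corrupt or inconsistent."""


@dataclass(frozen=True)
class FieldSpec:
    """One machine-readable answer slot (a questionnaire item may have several)."""

    name: str
    type: str  # number | integer | categorical | checklist | boolean
    item_id: str | None
    component: int | None
    prompt: str = ""
    domain: tuple[str, ...] = ()
    min: float | None = None
    max: float | None = None
    unit: str = ""
    gate: str | None = None
    none_token: str | None = None
    range_hint: str = ""


@dataclass(frozen=True)
class ItemSpec:
    id: str
    component: int
    prompt: str
    scored: str  # "scored" | "neutral" (scored but risk-neutral) | "unscored"
    fields: tuple[str, ...]
    gate: str | None = None


@dataclass(frozen=True)
class ComponentSpec:
    id: int
    title: str
    items: tuple[ItemSpec, ...]


@dataclass(frozen=True)
class QuestionnaireSchema:
    """The full questionnaire: 8 components, demographics, field index."""

    version: str
    title: str
    components: tuple[ComponentSpec, ...]
    demographics: tuple[FieldSpec, ...]
    fields: Mapping[str, FieldSpec] = field(repr=False, default_factory=dict)

    def item_ids(self) -> set[str]:
        return {it.id for comp in self.components for it in comp.items}

    def field_names(self) -> tuple[str, ...]:
        return tuple(self.fields)

    def component(self, cid: int) -> ComponentSpec:
        for comp in self.components:
            if comp.id == cid:
                return comp
        raise KeyError(cid)

    def item(self, item_id: str) -> ItemSpec:
        for comp in self.components:
            for it in comp.items:
                if it.id == item_id:
                    return it
        raise KeyError(item_id)

    def to_json(self, indent: int = 2) -> str:
        """Dump the schema for external UI builders (stable key order)."""
        return json.dumps(_raw_schema(), indent=indent, ensure_ascii=False)


@functools.lru_cache(maxsize=1)
def _raw_schema() -> dict:
    text = (resources.files("lifescreen") / "data" / "questionnaire.json").read_text("utf-8")
    return json.loads(text)


def _field_from_dict(d: Mapping[str, Any], item_id: str | None, component: int | None,
                     prompt: str = "") -> FieldSpec:
    return FieldSpec(
        name=d["field"],
        type=d["type"],
        item_id=item_id,
        component=component,
        prompt=d.get("prompt", prompt),
        domain=tuple(d.get("domain", ())),
        min=d.get("min"),
        max=d.get("max"),
        unit=d.get("unit", ""),
        gate=d.get("gate"),
        none_token=d.get("none_token"),
        range_hint=d.get("range_hint", ""),
    )


@functools.lru_cache(maxsize=1)
def load_schema() -> QuestionnaireSchema:
    """Load the bundled questionnaire schema (cached; stable across calls)."""
    try:
        raw = _raw_schema()
        demographics = tuple(_field_from_dict(d, None, None) for d in raw["demographics"])
        components: list[ComponentSpec] = []
        fields: dict[str, FieldSpec] = {f.name: f for f in demographics}
        for comp in raw["components"]:
            cid = int(comp["id"])
            items: list[ItemSpec] = []
            for it in comp["items"]:
                fspecs = [_field_from_dict(f, it["id"], cid, it.get("prompt", ""))
                          for f in it["fields"]]
                for f in fspecs:
                    if f.name in fields:
                        raise SchemaError(f"duplicate field {f.name!r}")
                    fields[f.name] = f
                items.append(ItemSpec(id=it["id"], component=cid,
                                      prompt=it.get("prompt", ""),
                                      scored=it.get("scored", "scored"),
                                      fields=tuple(f.name for f in fspecs),
                                      gate=it.get("gate")))
            for extra in comp.get("extra_fields", ()):
                f = _field_from_dict(extra, None, cid)
                fields[f.name] = f
            components.append(ComponentSpec(id=cid, title=comp["title"], items=tuple(items)))
        schema = QuestionnaireSchema(version=raw["version"], title=raw["title"],
                                     components=tuple(components),
                                     demographics=demographics, fields=fields)
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise SchemaError(f"bundled questionnaire schema is corrupt: {exc}") from exc
    if [c.id for c in schema.components] != list(range(1, 9)):
        raise SchemaError("questionnaire must contain components 1..8 in order")
    return schema


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    item_id: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"item {self.item_id}" if self.item_id else self.field
        return f"{where} ({self.field}): {self.message}"


class ResponseValidationError(ValueError):
    """Raised when a raw record fails validation; carries the full issue list."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = list(issues)
        super().__init__("; ".join(str(i) for i in self.issues))


class _ParseError(ValueError):
    pass


_TRUE = {"yes", "true", "1"}
_FALSE = {"no", "false", "0"}


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and not value.strip():
        return True
    return False


def _parse_value(spec: FieldSpec, value: Any) -> Any:
    if spec.type in ("number", "integer"):
        if isinstance(value, bool):
            raise _ParseError("expected a number")
        if isinstance(value, str):
            try:
                value = float(value.strip())
            except ValueError:
                raise _ParseError(f"not a number: {value!r}") from None
        if not isinstance(value, (int, float)):
            raise _ParseError("expected a number")
        value = float(value)
        if spec.type == "integer":
            if value != int(value):
                raise _ParseError("expected a whole number")
            value = int(value)
        if spec.min is not None and value < spec.min or \
           spec.max is not None and value > spec.max:
            msg = f"out of range [{spec.min}, {spec.max}]" + \
                  (f" {spec.unit}" if spec.unit else "")
            if spec.range_hint and spec.max is not None and value > spec.max:
                msg += f"; {spec.range_hint}"
            raise _ParseError(msg)
        return value
    if spec.type == "categorical":
        if not isinstance(value, str):
            raise _ParseError("expected an answer token")
        token = value.strip().lower()
        if token not in spec.domain:
            raise _ParseError(f"{value!r} is not one of {list(spec.domain)}")
        return token
    if spec.type == "checklist":
        if isinstance(value, str):
            tokens = [t.strip().lower() for t in value.split(";") if t.strip()]
        elif isinstance(value, (list, tuple, set, frozenset)):
            tokens = [str(t).strip().lower() for t in value]
        else:
            raise _ParseError("expected a checklist (';'-separated tokens or a list)")
        bad = [t for t in tokens if t not in spec.domain]
        if bad:
            raise _ParseError(f"{bad} not among {list(spec.domain)}")
        if spec.none_token and spec.none_token in tokens and len(tokens) > 1:
            raise _ParseError(f"{spec.none_token!r} is exclusive of other options")
        if spec.none_token and tokens == [spec.none_token]:
            return frozenset()
        return frozenset(tokens)
    if spec.type == "boolean":
        if isinstance(value, bool):
            return value
        if isinstance(value, str):
            token = value.strip().lower()
            if token in _TRUE:
                return True
            if token in _FALSE:
                return False
        raise _ParseError(f"not a yes/no value: {value!r}")
    raise SchemaError(f"unknown field type {spec.type!r}")  # pragma: no cover


def _gate_satisfied(gate: str, parsed: Mapping[str, Any]) -> bool:
    if gate == "age_over_65":
        age = parsed.get("age")
        return age is not None and age > 65
    if gate == "exercises":
        return parsed.get("exercise") == "yes"
    if gate == "ex_smoker":
        return parsed.get("smokes") == "no" and parsed.get("smoked_before") == "yes"
    raise SchemaError(f"unknown gate {gate!r}")  # pragma: no cover


def validation_errors(raw: Mapping[str, Any]) -> list[ValidationIssue]:
    """Check a raw record against the schema; return all issues found.

    Absent answers are allowed (they stay missing and score ``NOT_SCORED``
    downstream); present answers must belong to their item's printed domain,
    lie within physiological ranges, and respect skip logic.
    """
    schema = load_schema()
    issues: list[ValidationIssue] = []
    parsed: dict[str, Any] = {}

    for key, value in raw.items():
        if key not in schema.fields:
            issues.append(ValidationIssue(key, None, "unknown field"))
            continue
        if _is_missing(value):
            continue
        spec = schema.fields[key]
        try:
            parsed[key] = _parse_value(spec, value)
        except _ParseError as exc:
            issues.append(ValidationIssue(key, spec.item_id, str(exc)))

    # physiological ordering of blood pressure
    sbp, dbp = parsed.get("sbp"), parsed.get("dbp")
    if sbp is not None and dbp is not None and dbp >= sbp:
        issues.append(ValidationIssue(
            "dbp", "1.3", f"diastolic ({dbp:g}) must be below systolic ({sbp:g})"))

    # skip logic: gated answers may be present only when their gate holds
    gates = _raw_schema()["gates"]
    for name, value in list(parsed.items()):
        spec = schema.fields[name]
        if spec.gate and not _gate_satisfied(spec.gate, parsed):
            issues.append(ValidationIssue(
                name, spec.item_id, f"skip-logic violation: {gates[spec.gate]}"))

    return issues


def validate_response(raw: Mapping[str, Any]) -> "ResponseSet":
    """Validate a raw record; return a :class:`ResponseSet` or raise.

    Raises :class:`ResponseValidationError` carrying one issue per violated
    constraint, each naming the offending field and questionnaire item.
    """
    issues = validation_errors(raw)
    if issues:
        raise ResponseValidationError(issues)
    schema = load_schema()
    parsed = {}
    for key, value in raw.items():
        if _is_missing(value):
            continue
        parsed[key] = _parse_value(schema.fields[key], value)
    return ResponseSet(answers=parsed)


@dataclass(frozen=True)
class ResponseSet:
    """One respondent's validated answers, keyed by machine field name.

    Missing answers are simply absent keys — distinct from explicit
    "prefer not to answer" tokens, although both are excluded from scoring.
    """

    answers: dict[str, Any]

    def get(self, name: str, default: Any = None) -> Any:
        return self.answers.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self.answers

    def to_record(self) -> dict[str, Any]:
        """Flatten back to a raw record (CSV/JSON friendly primitives)."""
        schema = load_schema()
        out: dict[str, Any] = {}
        for name, value in self.answers.items():
            spec = schema.fields[name]
            if spec.type == "checklist":
                if not value:
                    out[name] = spec.none_token or ""
                else:
                    order = {t: i for i, t in enumerate(spec.domain)}
                    out[name] = ";".join(sorted(value, key=order.__getitem__))
            elif spec.type == "boolean":
                out[name] = "true" if value else "false"
            else:
                out[name] = value
        return out


# ---------------------------------------------------------------------------
# Derived measures and answer-domain encoders


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) / height (m) squared.  No rounding."""
    if height <= 0:
        raise ValueError("height must be positive (metres)")
    if weight <= 0:
        raise ValueError("weight must be positive (kg)")
    return weight / (height * height)


def walking_minutes_to_answer(minutes: float) -> str:
    """Encode daily walking minutes as the walking-time answer token."""
    if minutes < 0:
        raise ValueError("minutes must be non-negative")
    if minutes < 30:
        return "lt30"
    if minutes <= 60:
        return "30to60"
    return "gt60"


def sleep_hours_to_answer(hours: float) -> str:
    """Encode nightly sleep hours as the sleep-duration answer token."""
    if hours < 0:
        raise ValueError("hours must be non-negative")
    if hours < 5:
        return "lt5h"
    if hours < 7:
        return "5to7h"
    return "ge7h"


def night_wakings_to_answer(count: int) -> str:
    """Encode the number of nightly awakenings as its answer token."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if count <= 1:
        return "never_or_once"
    if count <= 3:
        return "2_3_times"
    return "4_or_more"


def years_since_quit_to_answer(years: float) -> str:
    """Encode years since smoking cessation as the quit-time answer token.

    Category edges follow the printed options: under one year, one up to five,
    five up to ten (ten included), and strictly more than ten years ago.
    """
    if years < 0:
        raise ValueError("years must be non-negative")
    if years < 1:
        return "lt_1y"
    if years < 5:
        return "1_to_5y"
    if years <= 10:
        return "5_to_10y"
    return "gt_10y"
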
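"""Readers and writers for batch cohorts, reports and configuration.

Batch cohorts travel as UTF-8 comma-separated CSV (header of machine field
names, empty cell = missing answer, checklists as ';'-joined tokens) or as
JSON-lines.  The formats are anonymous by construction: no name or
identifier columns exist beyond the implicit row order.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Iterable, Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .cohort import CohortSpec
from .schema import load_schema

__all__ = [
    "BatchFormatError",
    "RunConfig",
    "read_batch",
    "write_batch_csv",
    "read_jsonl",
    "write_jsonl",
    "load_cohort_spec",
    "validate_report_dict",
]


class BatchFormatError(ValueError):
    """A batch file's structure does not match the questionnaire schema."""


class RunConfig(BaseModel):
    """End-to-end run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    rule_variant: Literal["as_printed", "narrative_corrected"] = "narrative_corrected"
    locale: str = "en"
    input_path: str | None = None
    output_path: str | None = None
    input_format: Literal["csv", "jsonl"] = "csv"
    cohort_spec_path: str | None = None
    verbosity: Literal["quiet", "normal", "debug"] = "normal"


def _check_header(columns: Iterable[str]) -> None:
    known = set(load_schema().field_names())
    columns = list(columns)
    unknown = [c for c in columns if c not in known]
    if unknown:
        missing = sorted(known - set(columns))
        raise BatchFormatError(
            f"unknown column(s) {unknown}; schema columns absent from the "
            f"header: {missing}")


def read_batch(path: str | Path,
               format: Literal["csv", "jsonl"] = "csv") -> list[dict[str, Any]]:
    """Read one raw record per respondent row; empty cells become missing."""
    path = Path(path)
    if format == "jsonl":
        records = read_jsonl(path)
        for i, rec in enumerate(records):
            if not isinstance(rec, dict):
                raise BatchFormatError(f"line {i + 1}: expected a JSON object")
        return records
    if format != "csv":
        raise ValueError(f"unknown batch format {format!r}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise BatchFormatError("empty file: a header row is required")
        _check_header(reader.fieldnames)
        records: list[dict[str, Any]] = []
        for i, row in enumerate(reader):
            if None in row:
                raise BatchFormatError(
                    f"row {i + 2}: more cells than header columns")
            records.append({k: v for k, v in row.items()
                            if v is not None and v.strip() != ""})
    return records


def write_batch_csv(records: Iterable[Mapping[str, Any]],
                    path: str | Path) -> None:
    """Write records as a cohort CSV with the full schema header."""
    columns = list(load_schema().field_names())
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="raise")
        writer.writeheader()
        for rec in records:
            writer.writerow({k: _cell(v) for k, v in rec.items()})


def _cell(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (frozenset, set)):
        return ";".join(sorted(value))
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def read_jsonl(path: str | Path) -> list[Any]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def write_jsonl(objects: Iterable[Any], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for obj in objects:
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Load a cohort spec from a YAML or JSON config file."""
    with Path(path).open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return CohortSpec.model_validate(data)


_REPORT_REQUIRED = {
    "meta": dict,
    "components": list,
    "messages": list,
    "referral": dict,
}


def validate_report_dict(report: Mapping[str, Any]) -> None:
    """Structural check of a report payload against the shipped report schema.

    Raises ``ValueError`` on the first violation.  The JSON Schema document
    this mirrors is shipped as ``data/report_schema.json``.
    """
    for key, typ in _REPORT_REQUIRED.items():
        if key not in report:
            raise ValueError(f"report is missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report[{key!r}] must be a {typ.__name__}")
    components = report["components"]
    if [c.get("id") for c in components] != list(range(1, 9)):
        raise ValueError("report must contain components 1..8 in order")
    for c in components:
        for key in ("aggregate", "color", "items"):
            if key not in c:
                raise ValueError(f"component {c.get('id')} is missing {key!r}")
        if c["aggregate"] not in ("low", "moderate", "relevant", "not_scored"):
            raise ValueError(f"component {c['id']}: bad aggregate {c['aggregate']!r}")
    for m in report["messages"]:
        for key in ("component", "sub_block", "risk", "text"):
            if key not in m:
                raise ValueError(f"message is missing {key!r}")
    referral = report["referral"]
    for key in ("instruments", "triggering_components"):
        if key not in referral:
            raise ValueError(f"referral is missing {key!r}")
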
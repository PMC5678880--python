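"""Rendering of rules and selection reports as text, CSV and JSON.

Metrics are rendered from their exact rational values at two decimals
with trailing zeros stripped ("1", "2.5", "4.8"), the convention of the
published panel; CSV/JSON exports carry floats rounded to two decimals.
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import MARKERS
from .mining import AssociationRule
from .selection import SelectionReport

METRIC_NAMES = ("coverage", "confidence", "lift", "leverage", "conviction")


def format_metric(value: Fraction | float, decimals: int = 2, strip: bool = True) -> str:
    """Half-up rounding at ``decimals`` places, trailing zeros stripped."""
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantized = dec.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
    text = format(quantized, "f")
    if strip and "." in text:
        text = text.rstrip("0").rstrip(".")
    return text


def round_metric(value: Fraction | float, decimals: int = 2) -> float:
    """Numeric form of :func:`format_metric` (half-up, not banker's)."""
    if isinstance(value, float) and math.isinf(value):
        return math.inf
    return float(format_metric(value, decimals=decimals, strip=False))


def _rule_row(rule: AssociationRule, label: str = "", trace: str = "") -> dict:
    row: dict = {"rule_id": label}
    for marker in MARKERS:
        state = ""
        for item_label in rule.antecedent:
            name, _, value = item_label.partition("=")
            if name == marker:
                state = value
        row[marker] = state
    row["consequent"] = rule.consequent
    row["nA"] = rule.counts.nA
    row["nAB"] = rule.counts.nAB
    for metric in METRIC_NAMES:
        row[metric] = round_metric(getattr(rule, metric))
    if trace:
        row["selected_by"] = trace
    return row


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame([_rule_row(r) for r in rules]).drop(columns=["rule_id"])


def report_to_frame(report: SelectionReport) -> pd.DataFrame:
    return pd.DataFrame(
        [_rule_row(s.rule, label=s.label, trace=s.trace) for s in report.rules]
    )


def report_to_records(report: SelectionReport) -> list[dict]:
    """JSON-ready records: antecedent as explicit item list."""
    records = []
    for s in report.rules:
        records.append(
            {
                "rule_id": s.label,
                "antecedent": sorted(s.rule.antecedent),
                "consequent": s.rule.consequent,
                "nA": s.rule.counts.nA,
                "nAB": s.rule.counts.nAB,
                **{m: round_metric(getattr(s.rule, m)) for m in METRIC_NAMES},
                "selected_by": s.trace,
            }
        )
    return records


def report_to_json(report: SelectionReport, indent: int = 2) -> str:
    return json.dumps({"rules": report_to_records(report)}, indent=indent)


def render_text(report: SelectionReport) -> str:
    """IF/THEN table mimicking the published panel layout."""
    header = (
        ["Rule"]
        + [f"if {m} is" for m in MARKERS]
        + ["then", "n(A)", "n(A^B)"]
        + [m.capitalize() for m in METRIC_NAMES]
    )
    rows = [header]
    for s in report.rules:
        row = _rule_row(s.rule, label=s.label, trace=s.trace)
        name, _, state = row["consequent"].partition("=")
        rows.append(
            [s.label]
            + [row[m] for m in MARKERS]
            + [f"==> {name} = {state}", str(row["nA"]), str(row["nAB"])]
            + [format_metric(getattr(s.rule, m)) for m in METRIC_NAMES]
        )
    widths = [max(len(str(r[i])) for r in rows) for i in range(len(header))]
    lines = [
        "  ".join(str(cell).ljust(width) for cell, width in zip(row, widths)).rstrip()
        for row in rows
    ]
    lines.insert(1, "-" * len(lines[0]))
    return "\n".join(lines)


def write_report(report: SelectionReport, path: str | Path, fmt: str = "csv") -> Path:
    path = Path(path)
    if fmt == "csv":
        report_to_frame(report).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(report_to_json(report) + "\n", encoding="utf-8")
    elif fmt == "text":
        path.write_text(render_text(report) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


__all__ = [
    "METRIC_NAMES",
    "format_metric",
    "round_metric",
    "rules_to_frame",
    "report_to_frame",
    "report_to_records",
    "report_to_json",
    "render_text",
    "write_report",
]
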
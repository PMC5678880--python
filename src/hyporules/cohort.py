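"""Cohort table I/O for the three-marker neuroblastoma hypoxia panel.

A cohort is an ordered list of :class:`TumorRecord`, one per tumor, each
carrying a microarray-derived hypoxia cluster label (hypoxic/normoxic),
clinical covariates, and a semiquantitative immunohistochemistry score
for each of HIF-1α, PDK1 and PHD3.  Scores use the pathology convention
of percentage-positivity bins (``<1%``, ``1–20%``, ``21–50%``, ``51–70%``,
``71–100%``), optionally with a staining-intensity grade.

The packaged 25-tumor fixture is exposed through :func:`load_fixture`.
Its six medium-positivity (``21–50%``) cells carry an explicit
``medium_resolution`` (high/low) because the per-tumor intensity grades
behind them were never recorded individually; the resolutions were
derived once by the exhaustive consistency audit
(:func:`hyporules.dichotomize.resolve_by_consistency`) against the
published rule occurrence counts, which admit exactly one assignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import CohortValueError, IntegrityError, SchemaError

MARKERS: tuple[str, ...] = ("HIF1A", "PDK1", "PHD3")

PERCENT_BINS: tuple[str, ...] = ("<1%", "1–20%", "21–50%", "51–70%", "71–100%")
MEDIUM_BIN = "21–50%"

#: ASCII-hyphen spellings accepted on input, normalized to the en-dash
#: canonical form (CSV files authored in plain editors use "1-20%").
_BIN_ALIASES: dict[str, str] = {b.replace("–", "-"): b for b in PERCENT_BINS}

INTENSITIES = ("weak", "moderate", "strong", "unknown")
RESOLUTIONS = ("high", "low", "not_applicable")
CLUSTERS = ("hypoxic", "normoxic")
SEXES = ("male", "female", "unknown")
STAGES = ("1", "2A", "2B", "3", "4", "4S", "unknown")
HISTOLOGIES = ("FH", "UH", "unknown")
MYCN_STATES = ("yes", "no", "unknown")

_FIXTURE_NAME = "nb25_cohort.csv"


def normalize_bin(value: str) -> str:
    """Return the canonical en-dash spelling of a percentage bin.

    Raises :class:`CohortValueError` for anything outside the five-bin
    vocabulary (including near-misses like ``70-100%``).
    """
    value = value.strip()
    if value in PERCENT_BINS:
        return value
    if value in _BIN_ALIASES:
        return _BIN_ALIASES[value]
    raise CohortValueError(
        f"unrecognized percentage bin {value!r}; expected one of {PERCENT_BINS}"
    )


@dataclass(frozen=True)
class MarkerScore:
    """One marker's staged immunohistochemistry score.

    ``medium_resolution`` pre-resolves a medium (``21–50%``) bin to a
    binary level and may only be set for that bin; for all other bins
    the binary level is forced by the bin itself.
    """

    percent_bin: str
    intensity: str = "unknown"
    medium_resolution: str = "not_applicable"

    def __post_init__(self) -> None:
        object.__setattr__(self, "percent_bin", normalize_bin(self.percent_bin))
        if self.intensity not in INTENSITIES:
            raise CohortValueError(f"unrecognized intensity {self.intensity!r}")
        if self.medium_resolution not in RESOLUTIONS:
            raise CohortValueError(
                f"unrecognized medium_resolution {self.medium_resolution!r}"
            )
        if self.medium_resolution != "not_applicable" and self.percent_bin != MEDIUM_BIN:
            raise CohortValueError(
                "medium_resolution may only be set for the 21–50% bin, "
                f"got bin {self.percent_bin!r}"
            )


@dataclass
class TumorRecord:
    """One tumor: identity, hypoxia cluster label, covariates, marker scores."""

    tumor_id: int
    cluster: str
    marker_scores: Mapping[str, MarkerScore]
    sex: str = "unknown"
    age_months: float = 0.0
    inss_stage: str = "unknown"
    outcome: str = ""
    histology: str = "unknown"
    mycn_amplified: str = "unknown"

    def __post_init__(self) -> None:
        if not isinstance(self.tumor_id, int) or self.tumor_id < 1:
            raise CohortValueError(f"tumor_id must be a positive integer, got {self.tumor_id!r}")
        if self.cluster not in CLUSTERS:
            raise CohortValueError(
                f"tumor {self.tumor_id}: cluster must be one of {CLUSTERS}, got {self.cluster!r}"
            )
        missing = [m for m in MARKERS if m not in self.marker_scores]
        if missing:
            raise IntegrityError(f"tumor {self.tumor_id}: missing marker scores for {missing}")
        for name, enum in (
            ("sex", SEXES),
            ("inss_stage", STAGES),
            ("histology", HISTOLOGIES),
            ("mycn_amplified", MYCN_STATES),
        ):
            if getattr(self, name) not in enum:
                raise CohortValueError(
                    f"tumor {self.tumor_id}: {name} must be one of {enum}, "
                    f"got {getattr(self, name)!r}"
                )
        if self.age_months < 0:
            raise CohortValueError(f"tumor {self.tumor_id}: negative age_months")
        self.marker_scores = dict(self.marker_scores)


Cohort = list  # ordered collection of TumorRecord


def _required_columns() -> list[str]:
    return ["tumor_id", "cluster"] + [f"{m}_percent_bin" for m in MARKERS]


_COLUMNS = (
    ["tumor_id", "cluster", "sex", "age_months", "inss_stage", "outcome",
     "histology", "mycn_amplified"]
    + [f"{m}_{suffix}" for m in MARKERS
       for suffix in ("percent_bin", "intensity", "medium_resolution")]
)


def read_cohort(path: str | Path, dialect: str = "excel") -> list[TumorRecord]:
    """Read a cohort CSV into validated :class:`TumorRecord` objects.

    The header must name at least ``tumor_id``, ``cluster`` and one
    ``<MARKER>_percent_bin`` column per marker; intensity and
    medium-resolution columns are optional.  Unknown enum strings are
    rejected with the offending row cited, never coerced.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, dialect=dialect)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        header = [h.strip() for h in reader.fieldnames]
        for col in _required_columns():
            if col not in header:
                raise SchemaError(f"{path}: missing required column {col!r}")
        records: list[TumorRecord] = []
        seen: set[int] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                record = _record_from_row(row)
            except (CohortValueError, IntegrityError) as exc:
                raise type(exc)(f"{path} row {lineno}: {exc}") from exc
            if record.tumor_id in seen:
                raise IntegrityError(
                    f"{path} row {lineno}: duplicate tumor_id {record.tumor_id}"
                )
            seen.add(record.tumor_id)
            records.append(record)
    return records


def _record_from_row(row: Mapping[str, str]) -> TumorRecord:
    def get(col: str, default: str = "") -> str:
        value = row.get(col)
        return value.strip() if value else default

    scores = {}
    for marker in MARKERS:
        scores[marker] = MarkerScore(
            percent_bin=get(f"{marker}_percent_bin"),
            intensity=get(f"{marker}_intensity", "unknown") or "unknown",
            medium_resolution=get(f"{marker}_medium_resolution", "not_applicable")
            or "not_applicable",
        )
    try:
        tumor_id = int(get("tumor_id"))
    except ValueError as exc:
        raise CohortValueError(f"tumor_id {get('tumor_id')!r} is not an integer") from exc
    age_raw = get("age_months", "0")
    try:
        age = float(age_raw) if age_raw else 0.0
    except ValueError as exc:
        raise CohortValueError(f"age_months {age_raw!r} is not numeric") from exc
    return TumorRecord(
        tumor_id=tumor_id,
        cluster=get("cluster"),
        sex=get("sex", "unknown") or "unknown",
        age_months=age,
        inss_stage=get("inss_stage", "unknown") or "unknown",
        outcome=get("outcome"),
        histology=get("histology", "unknown") or "unknown",
        mycn_amplified=get("mycn_amplified", "unknown") or "unknown",
        marker_scores=scores,
    )


def write_cohort(cohort: Iterable[TumorRecord], path: str | Path) -> Path:
    """Write a cohort to CSV; an empty cohort yields a header-only file.

    Round-trips with :func:`read_cohort` field-for-field (bins are
    written in canonical en-dash form).
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(handle, fieldnames=_COLUMNS)
        writer.writeheader()
        for record in cohort:
            row = {
                "tumor_id": record.tumor_id,
                "cluster": record.cluster,
                "sex": record.sex,
                "age_months": _trim_number(record.age_months),
                "inss_stage": record.inss_stage,
                "outcome": record.outcome,
                "histology": record.histology,
                "mycn_amplified": record.mycn_amplified,
            }
            for marker in MARKERS:
                score = record.marker_scores[marker]
                row[f"{marker}_percent_bin"] = score.percent_bin
                row[f"{marker}_intensity"] = score.intensity
                row[f"{marker}_medium_resolution"] = score.medium_resolution
            writer.writerow(row)
    return path


def _trim_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def load_fixture() -> list[TumorRecord]:
    """Return the packaged 25-tumor cohort (8 hypoxic, 17 normoxic)."""
    with resources.as_file(
        resources.files("hyporules.data").joinpath(_FIXTURE_NAME)
    ) as fixture_path:
        return read_cohort(fixture_path)


__all__ = [
    "MARKERS",
    "PERCENT_BINS",
    "MEDIUM_BIN",
    "INTENSITIES",
    "RESOLUTIONS",
    "CLUSTERS",
    "MarkerScore",
    "TumorRecord",
    "normalize_bin",
    "read_cohort",
    "write_cohort",
    "load_fixture",
]
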
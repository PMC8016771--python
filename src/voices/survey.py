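"""Survey response ingestion, validation, exclusion rules and demographics.

Responses arrive as a delimited table (one respondent per row) with
demographic columns and nine 3-point priority ratings. This module parses
and validates them into :class:`ResponseRecord` objects, maps countries onto
the UN Statistics Division regional scheme (four European regions plus
Non-Europe), applies keyword-guarded cohort exclusion rules, and produces
the count/percentage demographic table used to describe a cohort.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

from voices.errors import DegenerateDataError, SchemaError, UnknownCountryError
from voices.synthetic import AGE_BANDS, MTGS, TOPICS

REGIONS = ("Eastern Europe", "Northern Europe", "Southern Europe",
           "Western Europe", "Non-Europe")
EUROPEAN_REGIONS = REGIONS[:4]
GENDERS = ("female", "male", "undisclosed")


@dataclass
class ResponseRecord:
    """One respondent's demographics, priority ratings, and open answers."""

    respondent_id: str
    gender: str
    age_band: str
    country: str
    mtg: str
    is_member: bool
    role: str
    ratings: dict = field(default_factory=dict)   # topic -> int in {1,2,3}
    open_answers: dict = field(default_factory=dict)  # question_id -> text


@dataclass
class ExclusionRule:
    """Drop matching records unless a rescue keyword appears in open text.

    Models cohort-cleaning rules of the form "exclude respondents from
    country X in disease group Y unless their free text mentions one of
    these terms" (e.g. excluding common-thyroid-disorder respondents who
    reached a rare-disease survey through an advocacy-group mailing).
    """

    label: str
    country: str | None = None
    mtg: str | None = None
    keywords: tuple = ()

    def __post_init__(self):
        if self.country is None and self.mtg is None:
            raise SchemaError(f"rule {self.label!r}: no matching criterion set")

    def matches(self, record: ResponseRecord) -> bool:
        if self.country is not None and record.country.lower() != self.country.lower():
            return False
        if self.mtg is not None and record.mtg.lower() != self.mtg.lower():
            return False
        return True

    def rescued(self, record: ResponseRecord) -> bool:
        text = " ".join(record.open_answers.values()).lower()
        return any(kw.lower() in text for kw in self.keywords)


@dataclass
class ValidationIssue:
    row: int
    column: str
    value: str
    message: str


@dataclass
class ValidationReport:
    issues: list = field(default_factory=list)

    def add(self, row: int, column: str, value, message: str) -> None:
        self.issues.append(ValidationIssue(row, column, str(value), message))

    def __len__(self) -> int:
        return len(self.issues)


# ---------------------------------------------------------------------------
# Region mapping

def _load_region_table() -> dict[str, str]:
    text = resources.files("voices.data").joinpath("un_regions.csv").read_text("utf-8")
    table: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines()):
        region = row["region"]
        table[row["alpha2"].lower()] = region
        table[row["name"].lower()] = region
        for alias in row["aliases"].split("|"):
            if alias.strip():
                table[alias.strip().lower()] = region
    return table


_REGION_TABLE = _load_region_table()


def map_region(country: str) -> str:
    """Map a country (ISO-3166 name, alpha-2 code, or common alias) to its
    UN Statistics Division region; non-European countries map to Non-Europe.

    Raises :class:`UnknownCountryError` for countries absent from the
    shipped table — never silently Non-Europe.
    """
    key = country.strip().lower()
    if key not in _REGION_TABLE:
        raise UnknownCountryError(f"country not in region table: {country!r}")
    return _REGION_TABLE[key]


def known_countries() -> list[str]:
    return sorted(_REGION_TABLE)


# ---------------------------------------------------------------------------
# Loading

_MANDATORY = ("respondent_id", "gender", "age_band", "country", "mtg",
              "is_member", "role")


def load_responses(path, schema_config: dict | None = None,
                   ) -> tuple[list[ResponseRecord], ValidationReport]:
    """Read a delimited response table into validated records.

    ``schema_config`` may carry ``columns`` (file-column -> canonical-name
    remapping), ``delimiter`` (default ','), and ``open_question_columns``
    (column -> question id for free-text answers). Every row is parsed or
    reported: out-of-scale or unparseable ratings are recorded as absent
    with a validation entry; unknown MTG / age-band / country values are
    collected in the report but the record is retained.
    """
    cfg = schema_config or {}
    frame = pd.read_csv(path, sep=cfg.get("delimiter", ","), dtype=str,
                        keep_default_na=False)
    if cfg.get("columns"):
        frame = frame.rename(columns=cfg["columns"])

    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    open_cols = cfg.get("open_question_columns", {})
    report = ValidationReport()
    records: list[ResponseRecord] = []
    for i, row in enumerate(frame.to_dict("records")):
        ratings: dict[str, int] = {}
        for topic in TOPICS:
            col = f"rating_{topic}"
            raw = str(row.get(col, "")).strip()
            if raw in ("", "nan", "NA"):
                continue
            try:
                value = int(float(raw))
            except ValueError:
                report.add(i, col, raw, "unparseable rating, recorded absent")
                continue
            if value not in (1, 2, 3):
                report.add(i, col, raw, "rating outside 1-3, recorded absent")
                continue
            ratings[topic] = value

        mtg = row["mtg"].strip()
        if mtg not in MTGS:
            report.add(i, "mtg", mtg, "unknown MTG label")
        age = row["age_band"].strip()
        if age not in AGE_BANDS:
            report.add(i, "age_band", age, "unknown age band")
        country = row["country"].strip()
        try:
            map_region(country)
        except UnknownCountryError:
            report.add(i, "country", country, "unknown country")
        gender = row["gender"].strip().lower()
        if gender not in GENDERS:
            report.add(i, "gender", gender, "unknown gender label")

        records.append(ResponseRecord(
            respondent_id=row["respondent_id"].strip(),
            gender=gender,
            age_band=age,
            country=country,
            mtg=mtg,
            is_member=str(row["is_member"]).strip().lower() in ("true", "1", "yes"),
            role=row["role"].strip().lower(),
            ratings=ratings,
            open_answers={qid: str(row.get(col, ""))
                          for col, qid in open_cols.items()},
        ))
    return records, report


def records_from_table(cohort: pd.DataFrame,
                       document_set=None) -> list[ResponseRecord]:
    """Build records directly from an in-memory synthetic cohort table."""
    answers: dict[str, dict[str, str]] = {}
    if document_set is not None:
        for doc in document_set.documents:
            answers.setdefault(doc.respondent_id, {})[doc.question_id] = doc.raw_text
    records = []
    for row in cohort.to_dict("records"):
        ratings = {}
        for topic in TOPICS:
            value = row.get(f"rating_{topic}")
            if value is not None and value == value:  # not NaN
                ratings[topic] = int(value)
        records.append(ResponseRecord(
            respondent_id=row["respondent_id"], gender=row["gender"],
            age_band=row["age_band"], country=row["country"], mtg=row["mtg"],
            is_member=bool(row["is_member"]), role=row["role"],
            ratings=ratings,
            open_answers=answers.get(row["respondent_id"], {}),
        ))
    return records


# ---------------------------------------------------------------------------
# Exclusions

def apply_exclusions(records: list[ResponseRecord],
                     rules: list[ExclusionRule],
                     ) -> tuple[list[ResponseRecord], list[dict]]:
    """Apply exclude-unless-keyword-present rules; returns (kept, audit log).

    A record matching a rule's (country, MTG) criteria is dropped unless any
    of the rule's keywords appears (case-insensitive substring) in its open
    answers. The audit log lists every dropped respondent id with the rule
    label. Records matching no rule are never dropped.
    """
    kept: list[ResponseRecord] = []
    audit: list[dict] = []
    for record in records:
        dropped_by = None
        for rule in rules:
            if rule.matches(record) and not rule.rescued(record):
                dropped_by = rule.label
                break
        if dropped_by is None:
            kept.append(record)
        else:
            audit.append({"respondent_id": record.respondent_id,
                          "rule": dropped_by})
    return kept, audit


# ---------------------------------------------------------------------------
# Demographics

def _percent(count: int, total: int) -> float:
    """100·count/total, rounded half-up to 1 decimal (presentation rule)."""
    frac = Decimal(100 * count) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _tally(labels, order, total) -> list[tuple[str, int, float]]:
    counts: dict[str, int] = {}
    for label in labels:
        counts[label] = counts.get(label, 0) + 1
    known = [(lab, counts[lab], _percent(counts[lab], total))
             for lab in order if lab in counts]
    extra = [(lab, n, _percent(n, total))
             for lab, n in sorted(counts.items()) if lab not in order]
    return known + extra


def demographic_summary(records: list[ResponseRecord]) -> dict:
    """Count and percentage per label for each demographic category.

    Returns ``{category: [(label, count, percent)]}`` for gender, age band,
    MTG, UN region, respondent role, and advocacy-group membership; percent
    is 100·count/total rounded half-up to one decimal. Countries outside
    the region table are tallied under ``"unknown"``.
    """
    if not records:
        raise DegenerateDataError("cannot summarise an empty cohort")
    total = len(records)

    def region_of(record):
        try:
            return map_region(record.country)
        except UnknownCountryError:
            return "unknown"

    return {
        "gender": _tally((r.gender for r in records), GENDERS, total),
        "age_band": _tally((r.age_band for r in records), AGE_BANDS, total),
        "mtg": _tally((r.mtg for r in records), MTGS, total),
        "region": _tally((region_of(r) for r in records), REGIONS, total),
        "role": _tally((r.role for r in records), ("patient", "caregiver"), total),
        "membership": _tally(("member" if r.is_member else "non-member"
                              for r in records), ("member", "non-member"), total),
    }


def demographics_frame(summary: dict) -> pd.DataFrame:
    rows = [
        {"category": cat, "label": label, "count": count, "percent": pct}
        for cat, entries in summary.items()
        for label, count, pct in entries
    ]
    return pd.DataFrame(rows, columns=["category", "label", "count", "percent"])
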
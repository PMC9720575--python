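"""Crash-record data model, KABCO recoding, residency partition, descriptives.

Police-reported crash severity uses the KABCO scale (K fatal,
A incapacitating, B evident, C possible, O no injury).  For three-class
severity modelling the five codes are collapsed to severe injury
(SI = K + A), minor injury (MIN = B + C) and no injury (NI = O), and
crashes are split by the truck's licensing state into in-state and
out-of-state groups.  This module holds the record type, the recode and
partition operations, the CSV/data-dictionary readers, and the
count/percent descriptive tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

KABCO_CODES = ("K", "A", "B", "C", "O")

SI = "SI"
MIN = "MIN"
NI = "NI"
SEVERITY_OUTCOMES = (SI, MIN, NI)
#: Baseline (reference) outcome for modelling.
DEFAULT_REFERENCE = NI

_KABCO_TO_OUTCOME = {"K": SI, "A": SI, "B": MIN, "C": MIN, "O": NI}


def recode_kabco(code: str) -> str:
    """Collapse a KABCO code to the three-class outcome.

    K and A map to severe injury (SI), B and C to minor injury (MIN),
    and O to no injury (NI).
    """
    try:
        return _KABCO_TO_OUTCOME[code]
    except KeyError:
        raise ValueError(
            f"unknown KABCO severity code {code!r}; expected one of "
            f"{', '.join(KABCO_CODES)}"
        ) from None


@dataclass(frozen=True)
class CrashRecord:
    """One crash: KABCO severity, truck licensing state, year, attributes.

    ``attributes`` maps attribute names (e.g. ``primary_contributing_factor``)
    to categorical levels (e.g. ``Fatigue``).
    """

    severity_kabco: str
    license_state: str
    year: int | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.severity_kabco not in KABCO_CODES:
            raise ValueError(
                f"unknown KABCO severity code {self.severity_kabco!r}; "
                f"expected one of {', '.join(KABCO_CODES)}"
            )

    @property
    def outcome(self) -> str:
        return recode_kabco(self.severity_kabco)


@dataclass(frozen=True)
class DataDictionary:
    """Attribute vocabularies plus the CSV column mapping.

    ``attributes`` maps each attribute name to its allowed levels.
    ``severity_column`` / ``state_column`` / ``year_column`` name the CSV
    columns carrying the KABCO code, licensing state and calendar year.
    """

    attributes: Mapping[str, tuple[str, ...]]
    severity_column: str = "severity_kabco"
    state_column: str = "license_state"
    year_column: str | None = "year"

    def levels(self, variable: str) -> tuple[str, ...]:
        if variable not in self.attributes:
            raise KeyError(
                f"attribute {variable!r} is not declared in the data "
                f"dictionary (known: {', '.join(sorted(self.attributes))})"
            )
        return tuple(self.attributes[variable])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DataDictionary":
        raw = yaml.safe_load(Path(path).read_text())
        cols = raw.get("columns", {})
        return cls(
            attributes={k: tuple(v) for k, v in raw.get("attributes", {}).items()},
            severity_column=cols.get("severity", "severity_kabco"),
            state_column=cols.get("state", "license_state"),
            year_column=cols.get("year", "year"),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "attributes": {k: list(v) for k, v in self.attributes.items()},
            "columns": {
                "severity": self.severity_column,
                "state": self.state_column,
                "year": self.year_column,
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class LoadReport:
    """Counts of accepted and quarantined rows from a load or partition."""

    n_accepted: int = 0
    n_rejected: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def add_rejection(self, reason: str) -> None:
        self.n_rejected += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


def load_records(
    path: str | Path, dictionary: DataDictionary
) -> tuple[list[CrashRecord], LoadReport]:
    """Read crash records from CSV, quarantining malformed rows.

    Rows with an unknown KABCO code, a missing licensing state, or an
    attribute level outside the declared vocabulary are routed to the
    report rather than silently dropped.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return records_from_frame(frame, dictionary)


def records_from_frame(
    frame: pd.DataFrame, dictionary: DataDictionary
) -> tuple[list[CrashRecord], LoadReport]:
    report = LoadReport()
    records: list[CrashRecord] = []
    attr_cols = [c for c in dictionary.attributes if c in frame.columns]
    for _, row in frame.iterrows():
        code = str(row.get(dictionary.severity_column, "")).strip()
        state = str(row.get(dictionary.state_column, "")).strip()
        if code not in KABCO_CODES:
            report.add_rejection(f"unknown severity code {code!r}")
            continue
        if not state:
            report.add_rejection("missing license state")
            continue
        attrs: dict[str, str] = {}
        bad_level = None
        for col in attr_cols:
            level = str(row[col]).strip()
            if not level:
                continue
            if level not in dictionary.attributes[col]:
                bad_level = f"level {level!r} not in vocabulary of {col!r}"
                break
            attrs[col] = level
        if bad_level:
            report.add_rejection(bad_level)
            continue
        year = None
        if dictionary.year_column and dictionary.year_column in frame.columns:
            raw_year = str(row[dictionary.year_column]).strip()
            year = int(raw_year) if raw_year else None
        records.append(
            CrashRecord(severity_kabco=code, license_state=state,
                        year=year, attributes=attrs)
        )
        report.n_accepted += 1
    return records, report


@dataclass
class Partition:
    """Residency split of a record collection, with quarantined leftovers."""

    in_state: list[CrashRecord]
    out_state: list[CrashRecord]
    rejected: list[CrashRecord]
    report: LoadReport


def partition_residency(
    records: Iterable[CrashRecord], home_state: str
) -> Partition:
    """Split records into in-state vs out-of-state by truck licensing state.

    A record is in-state iff its ``license_state`` equals ``home_state``;
    records with an empty state code are quarantined and counted.
    """
    part = Partition([], [], [], LoadReport())
    for rec in records:
        state = (rec.license_state or "").strip()
        if not state:
            part.rejected.append(rec)
            part.report.add_rejection("missing license state")
        elif state == home_state:
            part.in_state.append(rec)
            part.report.n_accepted += 1
        else:
            part.out_state.append(rec)
            part.report.n_accepted += 1
    return part


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DescriptiveTable:
    """Count / row-percent cross-tab of one attribute against severity.

    One row per attribute level: counts per outcome, row percents (half-up
    rounded to one decimal, raw fractions retained), and the row total.
    """

    variable: str
    frame: pd.DataFrame  # columns: level, n_SI, pct_SI, ..., total, raw_*

    @property
    def total(self) -> int:
        return int(self.frame["total"].sum())

    def to_csv(self, path: str | Path) -> None:
        cols = ["level"] + [c for out in SEVERITY_OUTCOMES
                            for c in (f"n_{out}", f"pct_{out}")] + ["total"]
        self.frame[cols].to_csv(path, index=False)

    def to_text(self) -> str:
        header = f"{self.variable}"
        cols = ["level"] + [c for out in SEVERITY_OUTCOMES
                            for c in (f"n_{out}", f"pct_{out}")] + ["total"]
        body = self.frame[cols].to_string(index=False)
        return f"{header}\n{body}"


def descriptive_table(
    records: Iterable[CrashRecord],
    variable: str,
    dictionary: DataDictionary | None = None,
) -> DescriptiveTable:
    """Cross-tabulate an attribute's levels against the 3-class severity.

    Row percent = 100 * count / row-total, reported both raw and rounded
    half-up to one decimal so rows sum to 100 up to 0.1-point rounding.
    """
    if dictionary is not None and variable not in dictionary.attributes:
        raise KeyError(
            f"attribute {variable!r} is not declared in the data dictionary"
        )
    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        level = rec.attributes.get(variable)
        if level is None:
            continue
        row = counts.setdefault(level, {out: 0 for out in SEVERITY_OUTCOMES})
        row[rec.outcome] += 1
    levels: Iterable[str]
    if dictionary is not None:
        declared = dictionary.levels(variable)
        levels = list(declared) + [l for l in counts if l not in declared]
    else:
        levels = sorted(counts)
    rows = []
    for level in levels:
        row = counts.get(level, {out: 0 for out in SEVERITY_OUTCOMES})
        total = sum(row.values())
        entry: dict[str, object] = {"level": level, "total": total}
        for out in SEVERITY_OUTCOMES:
            n = row[out]
            raw = 100.0 * n / total if total else 0.0
            entry[f"n_{out}"] = n
            entry[f"raw_pct_{out}"] = raw
            entry[f"pct_{out}"] = _round_half_up(raw, 1)
        rows.append(entry)
    frame = pd.DataFrame(rows)
    return DescriptiveTable(variable=variable, frame=frame)


def severity_distribution(records: Iterable[CrashRecord]) -> dict[str, int]:
    """Marginal count of records per three-class outcome."""
    dist = {out: 0 for out in SEVERITY_OUTCOMES}
    for rec in records:
        dist[rec.outcome] += 1
    return dist


def indicator_frame(
    records: Iterable[CrashRecord],
    indicators: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Expand categorical attributes into 0/1 model covariates.

    ``indicators`` maps covariate name -> (attribute, level); the covariate
    is 1 where the record's attribute equals the level.  The returned frame
    also carries the recoded ``severity`` outcome column.
    """
    rows = []
    for rec in records:
        row = {
            name: int(rec.attributes.get(attr) == level)
            for name, (attr, level) in indicators.items()
        }
        row["severity"] = rec.outcome
        rows.append(row)
    return pd.DataFrame(rows)
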
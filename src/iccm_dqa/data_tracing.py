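"""Tracing indicator counts level-by-level through the reporting system.

A data trace follows one indicator (e.g. children treated for malaria
with ACT) from a recount of the CHW registers, through the CHW monthly
summary forms, the facility supervisor's summary, any intermediate
aggregation level, up to a terminal level (national HIS or implementing
partner database). The outputs are

* a counts-and-differences table, one row per sampled facility, with the
  count observed at each level and the stepwise differences between
  adjacent levels (higher level minus lower level) plus the end-to-end
  difference (terminal minus register recount);
* consistency ratios between adjacent levels — verified or lower-level
  summed count divided by the count reported at the next level, so 1
  means agreement, above 1 under-reporting and below 1 over-reporting
  (note the two conventions point opposite ways: differences subtract
  upward, ratios divide downward);
* reporting performance — percentage of expected reports that are
  available, and complete (all required fields filled);
* timeliness, which is reported as not assessable whenever submission
  dates are missing, as is common in the field.

Missing counts are never coerced to zero: a blank cell propagates as
missing, the row stays in the table flagged, and it is excluded from
ratio aggregates.
"""

from __future__ import annotations

import csv
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError, TracingError
from .register_verification import RegisterEntry, ValidationRule
from .reporting_model import (
    IndicatorDefinition,
    Level,
    Period,
    ReportingSystem,
    ancestry_path,
    expected_reports,
    month_index,
    month_str,
)

# ---------------------------------------------------------------------------
# Summary reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryReport:
    """One periodic report filed by one site for one month.

    ``about_site_id`` identifies whose data the row refers to: a CHW's
    monthly report is about the CHW, while a district ledger and the
    national HIS hold one row per facility. Defaults to the filing site.
    ``counts`` maps report field name to a count, ``None`` for a blank
    cell; a field absent from the mapping was not on the form at all.
    """

    site_id: str
    level_id: str
    period_month: str
    counts: Mapping[str, int | None]
    submission_date: _dt.date | None = None
    about_site_id: str | None = None

    @property
    def about(self) -> str:
        return self.about_site_id or self.site_id

    @property
    def fields_present(self) -> dict[str, bool]:
        return {f: v is not None for f, v in self.counts.items()}


_REPORT_FIXED_COLUMNS = ["site_id", "level_id", "period_month", "about_site_id", "submission_date"]


def load_reports(path: str | Path) -> list[SummaryReport]:
    """Read a reports CSV: one row per site-month, indicator counts as
    columns, blank = missing."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"reports file not found: {path}")
    reports: list[SummaryReport] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ("site_id", "level_id", "period_month") if c not in header]
        if missing:
            raise DataError(f"reports file {path} missing columns {missing}")
        count_fields = [c for c in header if c not in _REPORT_FIXED_COLUMNS]
        for row in reader:
            counts: dict[str, int | None] = {}
            for f in count_fields:
                raw = (row.get(f) or "").strip()
                counts[f] = int(raw) if raw else None
            sub_raw = (row.get("submission_date") or "").strip()
            reports.append(
                SummaryReport(
                    site_id=row["site_id"].strip(),
                    level_id=row["level_id"].strip(),
                    period_month=row["period_month"].strip(),
                    counts=counts,
                    submission_date=_dt.date.fromisoformat(sub_raw) if sub_raw else None,
                    about_site_id=(row.get("about_site_id") or "").strip() or None,
                )
            )
    return reports


def write_reports(reports: Sequence[SummaryReport], path: str | Path) -> None:
    fields = sorted({f for r in reports for f in r.counts})
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REPORT_FIXED_COLUMNS + fields)
        for r in reports:
            writer.writerow(
                [
                    r.site_id,
                    r.level_id,
                    r.period_month,
                    r.about_site_id or "",
                    r.submission_date.isoformat() if r.submission_date else "",
                ]
                + ["" if r.counts.get(f) is None else r.counts[f] for f in fields]
            )


# ---------------------------------------------------------------------------
# Counts-and-differences core
# ---------------------------------------------------------------------------

def differences(counts: Sequence[int | None]) -> tuple[list[int | None], int | None]:
    """Stepwise (next level minus previous) and end-to-end differences.

    A ``None`` count makes any difference touching it ``None``. By the
    telescoping identity, whenever every count is present the end-to-end
    difference equals the sum of the stepwise differences.
    """
    step = [
        None if (counts[i] is None or counts[i + 1] is None) else counts[i + 1] - counts[i]
        for i in range(len(counts) - 1)
    ]
    end = None if (counts[0] is None or counts[-1] is None) else counts[-1] - counts[0]
    return step, end


@dataclass(frozen=True)
class TraceRow:
    group_id: str  # grouping site above the facility (e.g. district), for display
    facility_id: str
    counts: tuple[int | None, ...]  # register recount, then one per level in order
    stepwise: tuple[int | None, ...]
    end_to_end: int | None
    has_missing: bool


@dataclass
class TraceResult:
    """Counts-and-differences table for one indicator up to one terminal."""

    indicator_id: str
    terminal_level_id: str
    column_names: list[str]  # "register" + level ids from community upward
    rows: list[TraceRow]

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            # identifier columns carry an _id suffix so a level named
            # "facility" cannot collide with them
            rec: dict[str, object] = {"group_id": row.group_id, "facility_id": row.facility_id}
            rec[self.column_names[0]] = row.counts[0]
            for k in range(1, len(self.column_names)):
                rec[self.column_names[k]] = row.counts[k]
                rec[f"diff_{self.column_names[k]}_minus_{self.column_names[k-1]}"] = row.stepwise[k - 1]
            rec["diff_end_to_end"] = row.end_to_end
            rec["has_missing"] = row.has_missing
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_json_obj(self) -> dict:
        return {
            "indicator": self.indicator_id,
            "terminal_level": self.terminal_level_id,
            "columns": self.column_names,
            "rows": [
                {
                    "group": r.group_id,
                    "facility": r.facility_id,
                    "counts": list(r.counts),
                    "stepwise_differences": list(r.stepwise),
                    "end_to_end_difference": r.end_to_end,
                    "has_missing": r.has_missing,
                }
                for r in self.rows
            ],
        }


def trace_from_counts(
    count_table: pd.DataFrame,
    count_columns: Sequence[str],
    indicator_id: str = "indicator",
    terminal_level_id: str = "terminal",
    group_column: str | None = None,
    facility_column: str | None = None,
) -> TraceResult:
    """Build a :class:`TraceResult` from an already-extracted count table.

    This is the computation a DQA team's analysis sheet performs once the
    per-level counts have been transcribed: given one row per facility and
    one column per level (first column = register recount), compute every
    stepwise and end-to-end difference.
    """
    rows = []
    for idx, rec in count_table.iterrows():
        counts = tuple(
            None if pd.isna(rec[c]) else int(rec[c]) for c in count_columns
        )
        step, end = differences(counts)
        rows.append(
            TraceRow(
                group_id=str(rec[group_column]) if group_column else "",
                facility_id=str(rec[facility_column]) if facility_column else str(idx),
                counts=counts,
                stepwise=tuple(step),
                end_to_end=end,
                has_missing=any(c is None for c in counts),
            )
        )
    return TraceResult(
        indicator_id=indicator_id,
        terminal_level_id=terminal_level_id,
        column_names=list(count_columns),
        rows=rows,
    )


# ---------------------------------------------------------------------------
# Full trace against a reporting system
# ---------------------------------------------------------------------------

def _register_recount(
    entries: Sequence[RegisterEntry],
    rule: ValidationRule,
    chw_ids: set[str],
    period: Period,
) -> int:
    return sum(
        1
        for e in entries
        if e.chw_site_id in chw_ids
        and period.contains_date(e.encounter_date)
        and (e.treatments & rule.treatment_codes)
    )


def _cell(
    reports_by_key: Mapping[tuple[str, str, str], list[SummaryReport]],
    level_id: str,
    site_about_pairs: Iterable[tuple[str, str]],
    months: Sequence[str],
    field_name: str,
) -> int | None:
    """Sum the indicator field over the matching reports.

    The cell is missing when no matching report exists at all, or when any
    matching report leaves the field blank — a recount of forms that are
    not there, or not filled, is not a zero.
    """
    total = 0
    found = False
    for site_id, about_id in site_about_pairs:
        for month in months:
            for report in reports_by_key.get((level_id, site_id, month), ()):
                if report.about != about_id:
                    continue
                found = True
                if field_name not in report.counts:
                    raise TracingError(
                        f"indicator field {field_name!r} absent from reports at "
                        f"level {level_id!r}"
                    )
                value = report.counts[field_name]
                if value is None:
                    return None
                total += value
    return total if found else None


def trace_indicator(
    system: ReportingSystem,
    entries: Sequence[RegisterEntry],
    reports: Sequence[SummaryReport],
    indicator: IndicatorDefinition | str,
    period: Period,
    terminal: Level | str,
    rule: ValidationRule | None = None,
    rules: Sequence[ValidationRule] | None = None,
    facilities: Sequence[str] | None = None,
) -> TraceResult:
    """Trace one indicator from register recounts to the terminal level.

    One row per facility: the register recount over the facility's CHWs,
    then the period-summed count attributable to that facility at each
    level on its path to the terminal.
    """
    if isinstance(indicator, str):
        indicator = system.indicator(indicator)
    terminal_id = terminal.id if isinstance(terminal, Level) else terminal
    if rule is None:
        if rules is None:
            raise ConfigError("trace_indicator needs the indicator's register rule")
        matches = [r for r in rules if r.id == indicator.register_rule_id]
        if not matches:
            raise ConfigError(
                f"no rule {indicator.register_rule_id!r} supplied for "
                f"indicator {indicator.id!r}"
            )
        rule = matches[0]

    community_id = system.community_level.id
    facility_level = next((lv for lv in system.levels if lv.role == "facility"), None)
    if facility_level is None:
        raise ConfigError("system has no facility-role level to group the trace by")

    if facilities is None:
        facilities = sorted(s.id for s in system.sites_at(facility_level.id))

    months = period.months()
    reports_by_key: dict[tuple[str, str, str], list[SummaryReport]] = {}
    for r in reports:
        reports_by_key.setdefault((r.level_id, r.site_id, r.period_month), []).append(r)

    rows: list[TraceRow] = []
    column_names: list[str] | None = None
    for fac_id in facilities:
        facility = system.site(fac_id)
        path = ancestry_path(system, facility, terminal_id)
        level_ids = [community_id] + [s.level_id for s in path]
        if column_names is None:
            column_names = ["register"] + level_ids
        chw_ids = {
            s.id for s in system.children(fac_id) if s.level_id == community_id
        }
        counts: list[int | None] = [
            _register_recount(entries, rule, chw_ids, period)
        ]
        # community level: the CHWs' own monthly summary forms
        counts.append(
            _cell(
                reports_by_key,
                community_id,
                [(cid, cid) for cid in sorted(chw_ids)],
                months,
                indicator.report_field,
            )
        )
        # facility level and above: each path site's reports about this facility
        for path_site in path:
            counts.append(
                _cell(
                    reports_by_key,
                    path_site.level_id,
                    [(path_site.id, fac_id)],
                    months,
                    indicator.report_field,
                )
            )
        step, end = differences(counts)
        group = sorted(facility.parent_ids)[0] if facility.parent_ids else ""
        rows.append(
            TraceRow(
                group_id=group,
                facility_id=fac_id,
                counts=tuple(counts),
                stepwise=tuple(step),
                end_to_end=end,
                has_missing=any(c is None for c in counts),
            )
        )

    return TraceResult(
        indicator_id=indicator.id,
        terminal_level_id=terminal_id,
        column_names=column_names or ["register"],
        rows=rows,
    )


# ---------------------------------------------------------------------------
# Consistency ratios
# ---------------------------------------------------------------------------

AGREEMENT = "agreement"
UNDER_REPORTING = "under-reporting"
OVER_REPORTING = "over-reporting"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ConsistencyResult:
    """Verified (or lower-level summed) count against the next level's count."""

    indicator_id: str
    lower: str
    higher: str
    scope_id: str
    verified_or_summed: int | None
    reported: int | None
    ratio: float | None
    label: str


def consistency_ratio(
    verified: int | None, reported: int | None
) -> tuple[float | None, str]:
    """Ratio = verified ÷ reported, with the field convention for direction:
    1 agreement, > 1 under-reporting, < 1 over-reporting. Missing or 0/0
    inputs yield an undefined sentinel, never an exception."""
    if verified is None or reported is None:
        return None, UNDEFINED
    if verified < 0 or reported < 0:
        raise ValueError("counts must be nonnegative")
    if reported == 0:
        if verified == 0:
            return None, UNDEFINED
        return math.inf, UNDER_REPORTING
    ratio = verified / reported
    if ratio == 1.0:
        return ratio, AGREEMENT
    return ratio, UNDER_REPORTING if ratio > 1 else OVER_REPORTING


def consistency_results(
    trace: TraceResult, include_aggregate: bool = True
) -> list[ConsistencyResult]:
    """Per-facility and (optionally) aggregate consistency for each adjacent
    level pair in a trace.

    The aggregate for a level pair is the ratio of summed counts over the
    facilities where both counts are present (not the mean of per-facility
    ratios); rows with a missing count in the pair are excluded from the
    aggregate but still emitted individually with an undefined label.
    """
    out: list[ConsistencyResult] = []
    names = trace.column_names
    for k in range(len(names) - 1):
        lower_name, higher_name = names[k], names[k + 1]
        sums = [0, 0]
        any_pair = False
        for row in trace.rows:
            lower, higher = row.counts[k], row.counts[k + 1]
            ratio, label = consistency_ratio(lower, higher)
            out.append(
                ConsistencyResult(
                    indicator_id=trace.indicator_id,
                    lower=lower_name,
                    higher=higher_name,
                    scope_id=row.facility_id,
                    verified_or_summed=lower,
                    reported=higher,
                    ratio=ratio,
                    label=label,
                )
            )
            if lower is not None and higher is not None:
                sums[0] += lower
                sums[1] += higher
                any_pair = True
        if include_aggregate:
            ratio, label = (
                consistency_ratio(sums[0], sums[1]) if any_pair else (None, UNDEFINED)
            )
            out.append(
                ConsistencyResult(
                    indicator_id=trace.indicator_id,
                    lower=lower_name,
                    higher=higher_name,
                    scope_id="__all__",
                    verified_or_summed=sums[0] if any_pair else None,
                    reported=sums[1] if any_pair else None,
                    ratio=ratio,
                    label=label,
                )
            )
    return out


def consistency_to_dataframe(results: Sequence[ConsistencyResult]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "indicator": r.indicator_id,
                "lower": r.lower,
                "higher": r.higher,
                "scope": r.scope_id,
                "verified_or_summed": r.verified_or_summed,
                "reported": r.reported,
                "ratio": r.ratio,
                "label": r.label,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Reporting performance (availability / completeness)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AvailabilityResult:
    level_id: str
    site_id: str
    expected: int
    available: int
    complete: int
    pct_available: float | None
    pct_complete: float | None


def _pct(numerator: int, denominator: int) -> float | None:
    return 100.0 * numerator / denominator if denominator > 0 else None


def reporting_performance(
    system: ReportingSystem,
    reports: Sequence[SummaryReport],
    period: Period,
    required_fields: Mapping[str, Sequence[str]] | None = None,
    completeness_denominator: str = "expected",
) -> list[AvailabilityResult]:
    """Availability and completeness of reports per site and level.

    Expected comes from the activity calendar and the level's
    reports-per-month; available counts the active site-months with at
    least one report found; complete counts those whose reports have every
    required field filled. With the default denominator (expected),
    pct_complete <= pct_available holds; a flag switches the completeness
    denominator to available reports instead.
    """
    if completeness_denominator not in {"expected", "available"}:
        raise ConfigError(
            f"unknown completeness_denominator {completeness_denominator!r}"
        )
    if required_fields is None:
        all_fields = [ind.report_field for ind in system.indicators.values()]
        required_fields = {lv.id: all_fields for lv in system.levels}

    by_site_month: dict[tuple[str, str], list[SummaryReport]] = {}
    for r in reports:
        if period.contains_month(r.period_month):
            by_site_month.setdefault((r.site_id, r.period_month), []).append(r)

    results: list[AvailabilityResult] = []
    for level in system.levels:
        req = list(required_fields.get(level.id, ()))
        expected_map = expected_reports(system, level, period)
        for site_id in sorted(expected_map):
            expected_n = expected_map[site_id]
            months = system.active_months(site_id, period)
            available = 0
            complete = 0
            for m in months:
                found = by_site_month.get((site_id, m), [])
                if not found:
                    continue
                available += 1
                if all(
                    all(rep.counts.get(f) is not None for f in req) for rep in found
                ):
                    complete += 1
            denom = expected_n if completeness_denominator == "expected" else available
            results.append(
                AvailabilityResult(
                    level_id=level.id,
                    site_id=site_id,
                    expected=expected_n,
                    available=available,
                    complete=complete,
                    pct_available=_pct(available, expected_n),
                    pct_complete=_pct(complete, denom),
                )
            )
    return results


def availability_by_level(
    results: Sequence[AvailabilityResult], completeness_denominator: str = "expected"
) -> dict[str, AvailabilityResult]:
    """Roll site-level availability up to one summary row per level."""
    out: dict[str, AvailabilityResult] = {}
    for level_id in sorted({r.level_id for r in results}):
        rows = [r for r in results if r.level_id == level_id]
        expected = sum(r.expected for r in rows)
        available = sum(r.available for r in rows)
        complete = sum(r.complete for r in rows)
        denom = expected if completeness_denominator == "expected" else available
        out[level_id] = AvailabilityResult(
            level_id=level_id,
            site_id="__all__",
            expected=expected,
            available=available,
            complete=complete,
            pct_available=_pct(available, expected),
            pct_complete=_pct(complete, denom),
        )
    return out


def availability_to_dataframe(results: Sequence[AvailabilityResult]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "level": r.level_id,
                "site": r.site_id,
                "expected": r.expected,
                "available": r.available,
                "complete": r.complete,
                "pct_available": r.pct_available,
                "pct_complete": r.pct_complete,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Timeliness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimelinessResult:
    level_id: str
    assessable: bool
    n_reports: int
    n_on_time: int | None
    pct_on_time: float | None


def timeliness(
    reports: Sequence[SummaryReport],
    deadline_day: int,
    period: Period | None = None,
) -> dict[str, TimelinessResult]:
    """Percent of reports submitted by day ``deadline_day`` of the month
    following the report month (closed bound: a report dated exactly on
    the deadline is on time).

    If any report in a level's scope lacks a submission date, timeliness
    is flagged not assessable for that level — undated forms are the norm
    in the field and a partial percentage would mislead.
    """
    scoped = [
        r for r in reports if period is None or period.contains_month(r.period_month)
    ]
    out: dict[str, TimelinessResult] = {}
    for level_id in sorted({r.level_id for r in scoped}):
        rows = [r for r in scoped if r.level_id == level_id]
        if any(r.submission_date is None for r in rows):
            out[level_id] = TimelinessResult(level_id, False, len(rows), None, None)
            continue
        on_time = 0
        for r in rows:
            next_idx = month_index(r.period_month) + 1
            deadline = _dt.date(next_idx // 12, next_idx % 12 + 1, deadline_day)
            if r.submission_date <= deadline:
                on_time += 1
        out[level_id] = TimelinessResult(
            level_id, True, len(rows), on_time, _pct(on_time, len(rows))
        )
    return out
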
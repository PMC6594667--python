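"""Synthetic reporting systems, CHW registers and level-by-level reports.

No public register-level dataset exists for community case management
programs, so the toolkit ships a generator that emulates the data
landscape every metric operates on: a community level of CHWs under
facilities under districts, reporting monthly up to a national HIS (and
optionally, in parallel, an implementing partner's database), with
sick-child encounters arriving as a Poisson process per CHW-month and
illness.

Errors are injected by four independent, parameterized processes that
mirror the failure modes a DQA measures separately:

* **evidence omission** — a register entry records a treatment but the
  symptomatic/diagnostic evidence is dropped; degrades verification
  ratios without touching counts;
* **transcription noise** — a transcribed count is perturbed by
  ``round(Normal(0, sigma))``, truncated so counts stay nonnegative;
  produces both over- and under-reporting;
* **report loss** — a whole monthly report is missing; degrades
  availability, and propagates as under-reporting when an aggregating
  clerk sums only the forms that exist;
* **field blanking** — a present report leaves the indicator cell blank;
  degrades completeness.

Every realized error event is recorded in a :class:`GroundTruth`, and
replaying those events on the true counts reproduces the emitted
observed reports exactly — so tests can separate what the generator put
in from what the metrics read out. All randomness flows from a single
seed through named ``numpy`` SeedSequence child streams (cases,
evidence, transcription, missing, blank, misc), so each process can be
varied without disturbing the others.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_tracing import SummaryReport
from .errors import ConfigError
from .register_verification import RegisterEntry
from .reporting_model import (
    IndicatorDefinition,
    Level,
    Period,
    ReportingSystem,
    Site,
    add_months,
    month_index,
)

ILLNESS_FIELDS = {
    "malaria": "malaria_treated",
    "diarrhea": "diarrhea_treated",
    "pneumonia": "pneumonia_treated",
}

_ILLNESS_TREATMENT = {"malaria": "act", "diarrhea": "ors", "pneumonia": "amoxicillin"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Structure, case process and error process of a synthetic program.

    Defaults mirror a typical assessment round: 8 facilities in 4
    districts, a handful of CHWs per facility, a 3-month reporting
    quarter, malaria the most common presentation. Error probabilities
    are illustrative (no published register dataset quantifies them);
    their ordering across illnesses follows the common field pattern of
    diarrhea being the worst-documented treatment and malaria, anchored
    by an RDT result, the best.
    """

    n_districts: int = 4
    facilities_per_district: int = 2
    chws_per_facility: int = 7
    n_months: int = 3
    start_month: str = "2016-01"
    case_rates: Mapping[str, float] = field(
        default_factory=lambda: {"malaria": 6.0, "diarrhea": 4.0, "pneumonia": 3.0}
    )
    p_evidence_omission: Mapping[str, float] = field(
        default_factory=lambda: {"malaria": 0.05, "diarrhea": 0.3, "pneumonia": 0.15}
    )
    p_transcription: float = 0.1
    transcription_sigma: float = 5.0
    p_report_missing: Mapping[str, float] = field(
        default_factory=lambda: {
            "community": 0.1,
            "facility": 0.05,
            "district": 0.02,
            "national": 0.0,
            "partner": 0.0,
        }
    )
    p_field_blank: float = 0.02
    partner_terminal: bool = False
    record_submission_dates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in [
            ("p_transcription", self.p_transcription),
            ("p_field_blank", self.p_field_blank),
            *((f"p_evidence_omission[{k}]", v) for k, v in self.p_evidence_omission.items()),
            *((f"p_report_missing[{k}]", v) for k, v in self.p_report_missing.items()),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if any(r < 0 for r in self.case_rates.values()):
            raise ConfigError("case rates must be nonnegative")
        if self.n_months < 1:
            raise ConfigError("n_months must be >= 1")

    @classmethod
    def zero_error(cls, **kwargs) -> "SyntheticConfig":
        """A config with every error probability set to 0."""
        base = dict(
            p_evidence_omission={"malaria": 0.0, "diarrhea": 0.0, "pneumonia": 0.0},
            p_transcription=0.0,
            p_report_missing={
                "community": 0.0,
                "facility": 0.0,
                "district": 0.0,
                "national": 0.0,
                "partner": 0.0,
            },
            p_field_blank=0.0,
        )
        base.update(kwargs)
        return cls(**base)

    def months(self) -> list[str]:
        return [add_months(self.start_month, i) for i in range(self.n_months)]

    def period(self) -> Period:
        return Period(self.start_month, add_months(self.start_month, self.n_months - 1))


# ---------------------------------------------------------------------------
# Ground truth and realized error events
# ---------------------------------------------------------------------------

ReportKey = tuple[str, str, str, str]  # (level_id, site_id, about_id, month)


@dataclass
class RealizedEvents:
    """The error events the generator actually drew."""

    missing_reports: set[ReportKey] = field(default_factory=set)
    blank_fields: dict[ReportKey, frozenset[str]] = field(default_factory=dict)
    transcription: dict[tuple[ReportKey, str], int] = field(default_factory=dict)
    evidence_omitted: list[tuple[int, str]] = field(default_factory=list)  # (entry idx, illness)


@dataclass
class GroundTruth:
    """True counts, true aggregates and realized events for one bundle.

    :meth:`replay_reports` re-applies the realized events to the true
    counts and must reproduce the emitted observed reports exactly.
    """

    true_community: dict[tuple[str, str, str], int]  # (chw_id, month, field) -> count
    events: RealizedEvents
    months: list[str]
    fields: list[str]

    def true_facility(self, system: ReportingSystem) -> dict[tuple[str, str, str], int]:
        """True (error-free) aggregate per facility-month-field."""
        community_id = system.community_level.id
        out: dict[tuple[str, str, str], int] = {}
        for fac in system.sites.values():
            if system.level(fac.level_id).role != "facility":
                continue
            chws = [s.id for s in system.children(fac.id) if s.level_id == community_id]
            for m in self.months:
                for f in self.fields:
                    out[(fac.id, m, f)] = sum(
                        self.true_community.get((c, m, f), 0) for c in chws
                    )
        return out

    def replay_reports(self, system: ReportingSystem) -> list[SummaryReport]:
        return _build_reports(
            system, self.true_community, self.months, self.fields,
            _EventReplayer(self.events), submission_dates={},
        )

    def to_json_obj(self) -> dict:
        return {
            "months": self.months,
            "fields": self.fields,
            "true_community": [
                {"chw": k[0], "month": k[1], "field": k[2], "count": v}
                for k, v in sorted(self.true_community.items())
            ],
            "events": {
                "missing_reports": [list(k) for k in sorted(self.events.missing_reports)],
                "blank_fields": [
                    {"report": list(k), "fields": sorted(v)}
                    for k, v in sorted(self.events.blank_fields.items())
                ],
                "transcription": [
                    {"report": list(k), "field": f, "delta": d}
                    for (k, f), d in sorted(self.events.transcription.items())
                ],
                "evidence_omitted": [
                    {"entry_index": i, "illness": ill}
                    for i, ill in self.events.evidence_omitted
                ],
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_obj(), indent=1))


class _EventDrawer:
    """Draws error events from the config's probabilities and records them."""

    def __init__(self, config: SyntheticConfig, seeds: Mapping[str, np.random.Generator]):
        self.config = config
        self.rng_missing = seeds["missing"]
        self.rng_blank = seeds["blank"]
        self.rng_trans = seeds["transcription"]
        self.events = RealizedEvents()

    def report_missing(self, key: ReportKey) -> bool:
        p = self.config.p_report_missing.get(key[0], 0.0)
        if p > 0 and self.rng_missing.random() < p:
            self.events.missing_reports.add(key)
            return True
        return False

    def transcription_delta(self, key: ReportKey, field_name: str, value: int) -> int:
        p = self.config.p_transcription
        if p > 0 and self.rng_trans.random() < p:
            delta = int(round(self.rng_trans.normal(0.0, self.config.transcription_sigma)))
            delta = max(delta, -value)  # counts stay >= 0
            self.events.transcription[(key, field_name)] = delta
            return delta
        return 0

    def blank_field(self, key: ReportKey, field_name: str) -> bool:
        p = self.config.p_field_blank
        if p > 0 and self.rng_blank.random() < p:
            prev = self.events.blank_fields.get(key, frozenset())
            self.events.blank_fields[key] = prev | {field_name}
            return True
        return False


class _EventReplayer:
    """Applies a previously realized event record instead of drawing."""

    def __init__(self, events: RealizedEvents):
        self.events = events

    def report_missing(self, key: ReportKey) -> bool:
        return key in self.events.missing_reports

    def transcription_delta(self, key: ReportKey, field_name: str, value: int) -> int:
        return self.events.transcription.get((key, field_name), 0)

    def blank_field(self, key: ReportKey, field_name: str) -> bool:
        return field_name in self.events.blank_fields.get(key, frozenset())


# ---------------------------------------------------------------------------
# System construction
# ---------------------------------------------------------------------------

def build_system(config: SyntheticConfig) -> ReportingSystem:
    """Reporting system for the configured structure: community CHWs →
    facilities → districts → national HIS (+ optional parallel partner)."""
    levels = [
        Level("community", "Community (CHW)", 0, "community"),
        Level("facility", "Health facility", 1, "facility"),
        Level("district", "District", 2, "intermediate"),
        Level("national", "National HIS", 3, "terminal"),
    ]
    flows = [("community", "facility"), ("facility", "district"), ("district", "national")]
    if config.partner_terminal:
        levels.append(Level("partner", "Implementing partner", 4, "terminal"))
        flows.append(("district", "partner"))

    sites: dict[str, Site] = {"national": Site("national", "national", "National HIS")}
    if config.partner_terminal:
        sites["partner"] = Site("partner", "partner", "Implementing partner")
    district_parents = ("national", "partner") if config.partner_terminal else ("national",)
    for d in range(1, config.n_districts + 1):
        did = f"d{d:02d}"
        sites[did] = Site(did, "district", f"District {d}", district_parents)
        for f in range(1, config.facilities_per_district + 1):
            fid = f"{did}f{f:02d}"
            sites[fid] = Site(
                fid, "facility", f"Facility {d}.{f}", (did,), n_chws=config.chws_per_facility
            )
            for c in range(1, config.chws_per_facility + 1):
                cid = f"{fid}c{c:02d}"
                sites[cid] = Site(cid, "community", f"CHW {d}.{f}.{c}", (fid,))

    indicators = {
        ILLNESS_FIELDS[ill]: IndicatorDefinition(
            id=ILLNESS_FIELDS[ill],
            illness=ill,
            description=f"Children treated for {ill}",
            register_rule_id=f"{ill}_default",
            report_field=ILLNESS_FIELDS[ill],
        )
        for ill in ILLNESS_FIELDS
    }
    return ReportingSystem(
        levels=levels, sites=sites, indicators=indicators, flow_edges=flows
    )


# ---------------------------------------------------------------------------
# Register entry construction
# ---------------------------------------------------------------------------

def _make_entry(
    chw_id: str, month: str, illness: str, rng: np.random.Generator
) -> RegisterEntry:
    idx = month_index(month)
    year, mon = idx // 12, idx % 12 + 1
    day = int(rng.integers(1, calendar.monthrange(year, mon)[1] + 1))
    age = int(rng.integers(2, 60))
    if illness == "malaria":
        symptoms, diagnostics = {"fever"}, {"rdt": "positive"}
    elif illness == "diarrhea":
        symptoms, diagnostics = {"diarrhea"}, {}
    else:  # pneumonia
        symptoms = {"cough", "fast_breathing"}
        diagnostics = {"respiratory_rate": 52 if age < 12 else 44}
    return RegisterEntry(
        chw_site_id=chw_id,
        encounter_date=_dt.date(year, mon, day),
        child_age_months=age,
        symptoms=frozenset(symptoms),
        diagnostics=diagnostics,
        treatments=frozenset({_ILLNESS_TREATMENT[illness]}),
    )


def _omit_evidence(entry: RegisterEntry, illness: str) -> RegisterEntry:
    # drop the evidence, keep the treatment: the count survives, the
    # verification fails
    if illness == "malaria":
        return replace(entry, diagnostics={k: v for k, v in entry.diagnostics.items() if k != "rdt"})
    if illness == "diarrhea":
        return replace(entry, symptoms=entry.symptoms - {"diarrhea"})
    return replace(
        entry,
        symptoms=entry.symptoms - {"fast_breathing"},
        diagnostics={k: v for k, v in entry.diagnostics.items() if k != "respiratory_rate"},
    )


# ---------------------------------------------------------------------------
# Report pipeline (shared by generation and replay)
# ---------------------------------------------------------------------------

def _build_reports(
    system: ReportingSystem,
    true_community: Mapping[tuple[str, str, str], int],
    months: Sequence[str],
    fields: Sequence[str],
    drawer,
    submission_dates: Mapping[ReportKey, _dt.date],
) -> list[SummaryReport]:
    """Build observed reports bottom-up, applying error events per cell.

    Aggregating clerks (facility) sum the forms that exist, skipping
    blanks; copying clerks (district, terminals) carry blanks forward and
    produce no row when the source row is absent. Iteration order is fixed
    (sorted site ids, months in order) so drawing and replaying events
    walk the cells identically.
    """
    community_id = system.community_level.id
    reports: list[SummaryReport] = []
    observed: dict[ReportKey, dict[str, int | None]] = {}

    def emit(key: ReportKey, counts: dict[str, int | None]) -> None:
        out: dict[str, int | None] = {}
        for f in fields:
            value = counts[f]
            if value is not None:
                value = value + drawer.transcription_delta(key, f, value)
            if drawer.blank_field(key, f):
                value = None
            out[f] = value
        if drawer.report_missing(key):
            return
        observed[key] = out
        level_id, site_id, about_id, month = key
        reports.append(
            SummaryReport(
                site_id=site_id,
                level_id=level_id,
                period_month=month,
                counts=out,
                submission_date=submission_dates.get(key),
                about_site_id=about_id if about_id != site_id else None,
            )
        )

    facilities = sorted(
        s.id for s in system.sites.values() if system.level(s.level_id).role == "facility"
    )
    chws_by_facility = {
        fid: sorted(s.id for s in system.children(fid) if s.level_id == community_id)
        for fid in facilities
    }

    # community: each CHW's monthly summary of their register
    for fid in facilities:
        for cid in chws_by_facility[fid]:
            for m in months:
                counts = {f: true_community.get((cid, m, f), 0) for f in fields}
                emit((community_id, cid, cid, m), counts)

    # facility: supervisor sums the CHW forms that were submitted
    for fid in facilities:
        for m in months:
            counts: dict[str, int | None] = {}
            for f in fields:
                total = 0
                for cid in chws_by_facility[fid]:
                    cell = observed.get((community_id, cid, cid, m))
                    if cell is not None and cell.get(f) is not None:
                        total += cell[f]
                counts[f] = total
            emit(("facility", fid, fid, m), counts)

    # district and terminals: per-facility rows copied from the level below
    copy_chain: list[tuple[str, str]] = [("district", "facility"), ("national", "district")]
    if any(lv.id == "partner" for lv in system.levels):
        copy_chain.append(("partner", "district"))

    district_of = {
        fid: sorted(system.site(fid).parent_ids)[0] for fid in facilities
    }
    site_at_level = {
        "facility": lambda fid: fid,
        "district": lambda fid: district_of[fid],
        "national": lambda fid: "national",
        "partner": lambda fid: "partner",
    }
    for level_id, source_level in copy_chain:
        for fid in facilities:
            src_site = site_at_level[source_level](fid)
            own_site = site_at_level[level_id](fid)
            for m in months:
                src = observed.get((source_level, src_site, fid, m))
                if src is None:
                    continue  # nothing reached this clerk for that month
                emit((level_id, own_site, fid, m), dict(src))

    return reports


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    system: ReportingSystem
    entries: list[RegisterEntry]
    reports: list[SummaryReport]
    ground_truth: GroundTruth
    config: SyntheticConfig

    def period(self) -> Period:
        return self.config.period()


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a seed-deterministic bundle of system, registers, reports
    and ground truth.

    With every error probability at 0 the observed data equal the truth at
    every level: all verification and consistency ratios are 1, all trace
    differences 0, availability and completeness 100%.
    """
    root = np.random.SeedSequence(config.seed)
    names = ["cases", "evidence", "transcription", "missing", "blank", "misc"]
    streams = dict(zip(names, (np.random.default_rng(s) for s in root.spawn(len(names)))))

    system = build_system(config)
    months = config.months()
    fields = [ILLNESS_FIELDS[ill] for ill in ("malaria", "diarrhea", "pneumonia")]
    community_id = system.community_level.id
    chw_ids = sorted(
        s.id for s in system.sites.values() if s.level_id == community_id
    )

    rng_cases = streams["cases"]
    rng_evidence = streams["evidence"]
    rng_misc = streams["misc"]

    true_community: dict[tuple[str, str, str], int] = {}
    entries: list[RegisterEntry] = []
    evidence_omitted: list[tuple[int, str]] = []
    for cid in chw_ids:
        for m in months:
            for ill in ("malaria", "diarrhea", "pneumonia"):
                rate = float(config.case_rates.get(ill, 0.0))
                n = int(rng_cases.poisson(rate)) if rate > 0 else 0
                true_community[(cid, m, ILLNESS_FIELDS[ill])] = n
                p_omit = float(config.p_evidence_omission.get(ill, 0.0))
                for _ in range(n):
                    entry = _make_entry(cid, m, ill, rng_misc)
                    if p_omit > 0 and rng_evidence.random() < p_omit:
                        entry = _omit_evidence(entry, ill)
                        evidence_omitted.append((len(entries), ill))
                    entries.append(entry)

    submission_dates: dict[ReportKey, _dt.date] = {}
    drawer = _EventDrawer(config, streams)
    reports = _build_reports(
        system, true_community, months, fields, drawer, submission_dates
    )
    if config.record_submission_dates:
        dated = []
        for r in reports:
            nxt = month_index(r.period_month) + 1
            day = int(rng_misc.integers(1, 16))
            date = _dt.date(nxt // 12, nxt % 12 + 1, day)
            dated.append(
                SummaryReport(
                    site_id=r.site_id,
                    level_id=r.level_id,
                    period_month=r.period_month,
                    counts=r.counts,
                    submission_date=date,
                    about_site_id=r.about_site_id,
                )
            )
        reports = dated

    drawer.events.evidence_omitted = evidence_omitted
    ground_truth = GroundTruth(
        true_community=true_community,
        events=drawer.events,
        months=months,
        fields=fields,
    )
    return SyntheticBundle(
        system=system,
        entries=entries,
        reports=reports,
        ground_truth=ground_truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Published counts-and-differences fixture
# ---------------------------------------------------------------------------

_TABLE4_ROWS = [
    # district, facility, register recount, CHW summary forms,
    # facility supervisor summary, national HIS
    (1, 1, 69, 64, 64, 64),
    (1, 2, 275, 299, 327, 327),
    (2, 3, 1035, 1066, 991, 1092),
    (2, 4, 190, 182, 183, 245),
    (3, 5, 105, 107, 106, 106),
    (3, 6, 121, 125, 120, 120),
    (4, 7, 620, 836, 829, 829),
    (4, 8, 982, 1153, 1150, 1170),
]

_TABLE4_PRINTED_DIFFS = [
    # summary-register, supervisor-summary, HIS-supervisor, HIS-register
    (1, -5, 0, 0, -5),
    (2, 24, 28, 0, 52),
    (3, 31, -75, 101, 57),
    (4, -8, 1, 62, 55),
    (5, 2, -1, 0, 1),
    (6, 4, -5, 0, -1),
    (7, 216, -7, 0, 209),
    (8, 171, -3, 20, 188),
]

TABLE4_COUNT_COLUMNS = ["register", "chw_summary", "supervisor_summary", "national_his"]


def table4_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The published eight-facility malaria counts-and-differences example.

    Returns ``(counts, printed_differences)``: counts holds the four
    per-level count columns for 8 facilities across 4 districts; the
    second frame holds the difference columns as printed, for comparison
    against recomputed differences (they are not inputs to the trace).
    """
    counts = pd.DataFrame(
        _TABLE4_ROWS, columns=["district", "facility"] + TABLE4_COUNT_COLUMNS
    )
    printed = pd.DataFrame(
        _TABLE4_PRINTED_DIFFS,
        columns=[
            "facility",
            "diff_chw_summary_minus_register",
            "diff_supervisor_summary_minus_chw_summary",
            "diff_national_his_minus_supervisor_summary",
            "diff_national_his_minus_register",
        ],
    )
    return counts, printed
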
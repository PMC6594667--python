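"""Model of a multi-level community-health reporting system.

A reporting system is an ordered set of levels (community at rank 0,
then facility, intermediate aggregation levels, and one or more terminal
levels such as the national HIS or an implementing partner's database),
a site hierarchy hanging off those levels, the indicators that flow
through it, and the level-to-level flow edges. Every other part of the
toolkit — register verification, data tracing, systems assessment,
sampling — traverses this structure.

Levels carry an explicit ``rank`` rather than inferring order from flow
edges: country data flows differ (some have parallel terminal branches,
some have no national edge at all) and edge-order inference is ambiguous.

Months are written ISO ``YYYY-MM`` throughout; all ids are
case-sensitive strings.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigError, RoutingError, StructuralError

LEVEL_ROLES = ("community", "facility", "intermediate", "terminal")

ILLNESSES = ("diarrhea", "malaria", "pneumonia", "stockout", "supervision", "other")

TREATMENT_ILLNESSES = ("diarrhea", "malaria", "pneumonia")


# ---------------------------------------------------------------------------
# Months and periods
# ---------------------------------------------------------------------------

def month_index(month: str) -> int:
    """Index of an ISO ``YYYY-MM`` month on a linear scale (months since 0000-01)."""
    try:
        year_s, mon_s = month.split("-")
        year, mon = int(year_s), int(mon_s)
    except (ValueError, AttributeError):
        raise ConfigError(f"month {month!r} is not in YYYY-MM form") from None
    if not 1 <= mon <= 12:
        raise ConfigError(f"month {month!r} is not in YYYY-MM form")
    return year * 12 + (mon - 1)


def month_str(index: int) -> str:
    return f"{index // 12:04d}-{index % 12 + 1:02d}"


def month_of(date: _dt.date) -> str:
    return f"{date.year:04d}-{date.month:02d}"


def add_months(month: str, n: int) -> str:
    return month_str(month_index(month) + n)


@dataclass(frozen=True)
class Period:
    """A closed range of calendar months, e.g. a reporting quarter."""

    start: str
    end: str

    def __post_init__(self) -> None:
        if month_index(self.end) < month_index(self.start):
            raise ConfigError(f"period end {self.end} precedes start {self.start}")

    @property
    def n_months(self) -> int:
        return month_index(self.end) - month_index(self.start) + 1

    def months(self) -> list[str]:
        start = month_index(self.start)
        return [month_str(start + i) for i in range(self.n_months)]

    def contains_month(self, month: str) -> bool:
        return month_index(self.start) <= month_index(month) <= month_index(self.end)

    def contains_date(self, date: _dt.date) -> bool:
        return self.contains_month(month_of(date))

    @classmethod
    def from_config(cls, obj) -> "Period":
        if isinstance(obj, Period):
            return obj
        if isinstance(obj, Mapping):
            return cls(str(obj["start"]), str(obj["end"]))
        raise ConfigError(f"cannot interpret {obj!r} as a period")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Level:
    id: str
    name: str
    rank: int
    role: str
    reports_per_month: int = 1
    features: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.role not in LEVEL_ROLES:
            raise ConfigError(
                f"level {self.id!r}: role {self.role!r} not one of {LEVEL_ROLES}"
            )
        if self.reports_per_month < 1:
            raise ConfigError(f"level {self.id!r}: reports_per_month must be >= 1")


@dataclass(frozen=True)
class Site:
    id: str
    level_id: str
    name: str
    parent_ids: tuple[str, ...] = ()
    active: bool = True
    n_chws: int = 0

    def __post_init__(self) -> None:
        if self.n_chws < 0:
            raise ConfigError(f"site {self.id!r}: n_chws must be nonnegative")


@dataclass(frozen=True)
class IndicatorDefinition:
    id: str
    illness: str
    report_field: str
    description: str = ""
    register_rule_id: str | None = None

    def __post_init__(self) -> None:
        if self.illness not in ILLNESSES:
            raise ConfigError(
                f"indicator {self.id!r}: illness {self.illness!r} not one of {ILLNESSES}"
            )
        if not self.report_field:
            raise ConfigError(f"indicator {self.id!r}: report_field must be nonempty")
        if self.illness in TREATMENT_ILLNESSES and not self.register_rule_id:
            raise ConfigError(
                f"indicator {self.id!r}: treatment indicators must reference "
                f"a register validation rule"
            )


@dataclass
class ReportingSystem:
    """A validated reporting-system map.

    ``activity`` optionally scopes a site's activity to specific months
    (CHWs not active for the entire reporting period are a standard DQA
    exclusion); a site absent from the calendar is active throughout.
    """

    levels: list[Level]
    sites: dict[str, Site]
    indicators: dict[str, IndicatorDefinition]
    flow_edges: list[tuple[str, str]]
    activity: dict[str, frozenset[str]] = field(default_factory=dict)
    allow_multi_parent_community: bool = False

    def __post_init__(self) -> None:
        self.levels = sorted(self.levels, key=lambda lv: lv.rank)
        self._levels_by_id = {lv.id: lv for lv in self.levels}
        self.validate()

    # -- lookups ---------------------------------------------------------

    def level(self, level_id: str) -> Level:
        try:
            return self._levels_by_id[level_id]
        except KeyError:
            raise ConfigError(f"unknown level {level_id!r}") from None

    def site(self, site_id: str) -> Site:
        try:
            return self.sites[site_id]
        except KeyError:
            raise ConfigError(f"unknown site {site_id!r}") from None

    def sites_at(self, level_id: str) -> list[Site]:
        return [s for s in self.sites.values() if s.level_id == level_id]

    def children(self, site_id: str) -> list[Site]:
        return [s for s in self.sites.values() if site_id in s.parent_ids]

    @property
    def community_level(self) -> Level:
        return next(lv for lv in self.levels if lv.role == "community")

    @property
    def terminal_levels(self) -> list[Level]:
        return [lv for lv in self.levels if lv.role == "terminal"]

    def indicator(self, indicator_id: str) -> IndicatorDefinition:
        try:
            return self.indicators[indicator_id]
        except KeyError:
            raise ConfigError(f"unknown indicator {indicator_id!r}") from None

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        by_id = self._levels_by_id
        if len(by_id) != len(self.levels):
            dupes = sorted(
                {lv.id for lv in self.levels if sum(l.id == lv.id for l in self.levels) > 1}
            )
            raise StructuralError(f"duplicate level ids: {dupes}")
        ranks = [lv.rank for lv in self.levels]
        if len(set(ranks)) != len(ranks):
            raise StructuralError("level ranks must be unique within a system")
        n_comm = sum(lv.role == "community" for lv in self.levels)
        if n_comm != 1:
            raise StructuralError(f"exactly one community level required, found {n_comm}")
        if not self.terminal_levels:
            raise StructuralError("at least one terminal level required")

        terminal_ids = {lv.id for lv in self.terminal_levels}
        for site in self.sites.values():
            level = by_id.get(site.level_id)
            if level is None:
                raise StructuralError(f"site {site.id!r}: unknown level {site.level_id!r}")
            if site.level_id not in terminal_ids and not site.parent_ids:
                raise StructuralError(f"orphan site {site.id!r}: non-terminal sites need a parent")
            if (
                level.role == "community"
                and len(site.parent_ids) > 1
                and not self.allow_multi_parent_community
            ):
                raise StructuralError(
                    f"community site {site.id!r} reports to multiple parents "
                    f"{sorted(site.parent_ids)}; enable allow_multi_parent_community "
                    f"to permit this"
                )
            for pid in site.parent_ids:
                parent = self.sites.get(pid)
                if parent is None:
                    raise StructuralError(f"site {site.id!r}: unknown parent {pid!r}")
                if by_id[parent.level_id].rank <= level.rank:
                    raise StructuralError(
                        f"site {site.id!r} (level {site.level_id!r}) has parent "
                        f"{pid!r} at rank <= its own; parents must sit strictly higher"
                    )

        self._check_no_cycles()

        for frm, to in self.flow_edges:
            if frm not in by_id or to not in by_id:
                raise StructuralError(f"flow edge ({frm!r}, {to!r}) references unknown level")
            if by_id[to].rank <= by_id[frm].rank:
                raise StructuralError(
                    f"flow edge ({frm!r}, {to!r}) must point from lower to higher rank"
                )

        # every site must be able to reach at least one terminal level
        for site in self.sites.values():
            if not any(self._reaches(site, lv.id) for lv in self.terminal_levels):
                raise StructuralError(f"site {site.id!r} cannot reach any terminal level")

    def _check_no_cycles(self) -> None:
        # rank ordering already precludes cycles when parents sit strictly
        # higher; this walk is a belt-and-braces check that names offenders
        state: dict[str, int] = {}

        def visit(sid: str, stack: list[str]) -> None:
            if state.get(sid) == 1:
                cycle = stack[stack.index(sid):] + [sid]
                raise StructuralError(f"cycle in site hierarchy: {' -> '.join(cycle)}")
            if state.get(sid) == 2:
                return
            state[sid] = 1
            for pid in self.sites[sid].parent_ids:
                if pid in self.sites:
                    visit(pid, stack + [sid])
            state[sid] = 2

        for sid in self.sites:
            visit(sid, [])

    def _reaches(self, site: Site, terminal_level_id: str) -> bool:
        if site.level_id == terminal_level_id:
            return True
        return any(
            self._reaches(self.sites[pid], terminal_level_id)
            for pid in site.parent_ids
            if pid in self.sites
        )

    # -- activity --------------------------------------------------------

    def active_months(self, site_id: str, period: Period) -> list[str]:
        site = self.site(site_id)
        if not site.active:
            return []
        months = period.months()
        calendar = self.activity.get(site_id)
        if calendar is None:
            return months
        return [m for m in months if m in calendar]

    # -- serialization ---------------------------------------------------

    def to_config(self) -> dict:
        cfg: dict = {
            "levels": [
                {
                    "id": lv.id,
                    "name": lv.name,
                    "rank": lv.rank,
                    "role": lv.role,
                    "reports_per_month": lv.reports_per_month,
                    "features": sorted(lv.features),
                }
                for lv in self.levels
            ],
            "sites": [
                {
                    "id": s.id,
                    "level": s.level_id,
                    "name": s.name,
                    "parents": list(s.parent_ids),
                    "active": s.active,
                    "n_chws": s.n_chws,
                }
                for s in self.sites.values()
            ],
            "indicators": [
                {
                    "id": ind.id,
                    "illness": ind.illness,
                    "description": ind.description,
                    "register_rule": ind.register_rule_id,
                    "report_field": ind.report_field,
                }
                for ind in self.indicators.values()
            ],
            "flows": [list(edge) for edge in self.flow_edges],
        }
        if self.activity:
            cfg["activity"] = {sid: sorted(m) for sid, m in self.activity.items()}
        if self.allow_multi_parent_community:
            cfg["options"] = {"allow_multi_parent_community": True}
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=False))


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_system_map(source: str | Path | Mapping) -> ReportingSystem:
    """Load and validate a reporting-system map from YAML/JSON or a dict.

    The document declares ``levels``, ``sites``, ``indicators`` and
    ``flows`` (plus optional ``activity`` and ``options``); every
    structural invariant is checked and violations raise
    :class:`StructuralError` naming the offending sites or levels.
    """
    if isinstance(source, Mapping):
        cfg = source
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"system map not found: {path}")
        cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, Mapping):
        raise ConfigError("system map must be a mapping")
    for key in ("levels", "sites"):
        if key not in cfg:
            raise ConfigError(f"system map missing required key {key!r}")

    levels = [
        Level(
            id=str(e["id"]),
            name=str(e.get("name", e["id"])),
            rank=int(e["rank"]),
            role=str(e["role"]),
            reports_per_month=int(e.get("reports_per_month", 1)),
            features=frozenset(e.get("features", ())),
        )
        for e in cfg["levels"]
    ]

    sites: dict[str, Site] = {}
    for e in cfg["sites"]:
        site = Site(
            id=str(e["id"]),
            level_id=str(e["level"]),
            name=str(e.get("name", e["id"])),
            parent_ids=tuple(str(p) for p in e.get("parents", ())),
            active=bool(e.get("active", True)),
            n_chws=int(e.get("n_chws", 0)),
        )
        if site.id in sites:
            raise StructuralError(f"duplicate site id {site.id!r}")
        sites[site.id] = site

    indicators: dict[str, IndicatorDefinition] = {}
    for e in cfg.get("indicators", ()):
        ind = IndicatorDefinition(
            id=str(e["id"]),
            illness=str(e["illness"]),
            description=str(e.get("description", "")),
            register_rule_id=e.get("register_rule"),
            report_field=str(e["report_field"]),
        )
        if ind.id in indicators:
            raise StructuralError(f"duplicate indicator id {ind.id!r}")
        indicators[ind.id] = ind

    flows = [(str(a), str(b)) for a, b in cfg.get("flows", ())]
    activity = {
        str(sid): frozenset(str(m) for m in months)
        for sid, months in (cfg.get("activity") or {}).items()
    }
    options = cfg.get("options") or {}

    return ReportingSystem(
        levels=levels,
        sites=sites,
        indicators=indicators,
        flow_edges=flows,
        activity=activity,
        allow_multi_parent_community=bool(options.get("allow_multi_parent_community", False)),
    )


# ---------------------------------------------------------------------------
# Traversal
# ---------------------------------------------------------------------------

def ancestry_path(system: ReportingSystem, site: Site | str, terminal: Level | str) -> list[Site]:
    """The routing path from ``site`` up to a site at the terminal level.

    With parallel terminal branches a site can have several upward routes;
    at each step the lowest-id parent whose closure reaches the terminal is
    taken, so the path is deterministic given the system.
    """
    if isinstance(site, str):
        site = system.site(site)
    terminal_id = terminal.id if isinstance(terminal, Level) else terminal
    terminal_level = system.level(terminal_id)
    if terminal_level.role != "terminal":
        raise RoutingError(f"level {terminal_id!r} is not a terminal level")

    path = [site]
    current = site
    while current.level_id != terminal_id:
        candidates = sorted(
            (
                system.sites[pid]
                for pid in current.parent_ids
                if system._reaches(system.sites[pid], terminal_id)
            ),
            key=lambda s: s.id,
        )
        if not candidates:
            raise RoutingError(
                f"site {site.id!r}: terminal level {terminal_id!r} unreachable "
                f"(stuck at {current.id!r})"
            )
        current = candidates[0]
        path.append(current)
    return path


def expected_reports(
    system: ReportingSystem, level: Level | str, period: Period
) -> dict[str, int]:
    """Expected report count per site at a level over a period.

    Expected = active months x reports-per-month for the level (monthly
    reporting by default). A site inactive for part of the period, per the
    activity calendar, expects proportionally fewer reports.
    """
    level_id = level.id if isinstance(level, Level) else level
    lv = system.level(level_id)
    return {
        site.id: len(system.active_months(site.id, period)) * lv.reports_per_month
        for site in system.sites_at(level_id)
    }
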
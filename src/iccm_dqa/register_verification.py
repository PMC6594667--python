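"""Verification of CHW register entries against illness-specific evidence rules.

A CHW register holds one row per sick-child encounter. When a treatment
is recorded, a DQA checks whether the entry also carries the
corresponding symptomatic and diagnostic evidence — e.g. a recorded ACT
treatment should be backed by a recorded fever and a positive malaria
RDT. The *verification ratio* compares the count of recorded treatments
to the count of appropriately recorded treatments per illness.

Ratio orientation: by default recorded ÷ appropriate, so a value above 1
means some recorded treatments lack evidence ("worse" points the same
way as consistency-ratio under-reporting). The opposite orientation is
available via a flag.

Evidence rules are configuration, not code: a small boolean-expression
grammar (``all``/``any``/``present``/``eq``/``ge``/``age_lt``/``age_ge``)
over declared symptom and diagnostic codes, validated at load time so an
undeclared code can never surface mid-evaluation. The bundled default
rules follow standard iCCM case definitions (fast breathing thresholds
of 50/min under 12 months and 40/min for 12–59 months).
"""

from __future__ import annotations

import csv
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError, DataError, RuleError
from .reporting_model import Period, ReportingSystem

# ---------------------------------------------------------------------------
# Code registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodeRegistry:
    """Declared symptom, diagnostic and treatment codes.

    Loaders reject rows with unknown codes; rules referencing unknown
    codes fail at load time.
    """

    symptoms: frozenset[str]
    diagnostics: frozenset[str]
    treatments: frozenset[str]

    def known(self, code: str) -> bool:
        return code in self.symptoms or code in self.diagnostics or code in self.treatments


DEFAULT_CODES = CodeRegistry(
    symptoms=frozenset(
        {"fever", "cough", "diarrhea", "fast_breathing", "vomiting",
         "convulsions", "chest_indrawing", "blood_in_stool"}
    ),
    diagnostics=frozenset({"rdt", "respiratory_rate", "muac"}),
    treatments=frozenset(
        {"act", "ors", "zinc", "amoxicillin", "paracetamol", "albendazole"}
    ),
)


# ---------------------------------------------------------------------------
# Register entries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegisterEntry:
    """One sick-child encounter as recorded in a CHW register."""

    chw_site_id: str
    encounter_date: _dt.date
    child_age_months: int | None
    symptoms: frozenset[str]
    diagnostics: Mapping[str, object]  # code -> result (str or number); absent = missing
    treatments: frozenset[str]
    referral: bool = False


REGISTER_COLUMNS = [
    "chw_site_id",
    "encounter_date",
    "child_age_months",
    "symptoms",
    "diagnostics",
    "treatments",
    "referral",
]


def _parse_multivalue(text: str) -> list[str]:
    return [tok.strip() for tok in text.split("|") if tok.strip()]


def load_registers(
    path: str | Path, registry: CodeRegistry = DEFAULT_CODES
) -> tuple[list[RegisterEntry], list[dict]]:
    """Read a register CSV; malformed rows go to a rejects list, never dropped.

    Multi-valued fields (symptoms, treatments) are ``|``-separated code
    lists; diagnostics are ``code=value`` pairs, also ``|``-separated.
    Returns ``(entries, rejects)`` where each reject records the row
    number, raw row and reason.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"register file not found: {path}")
    entries: list[RegisterEntry] = []
    rejects: list[dict] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in REGISTER_COLUMNS if c not in header]
        if missing_cols:
            raise DataError(f"register file {path} missing columns {missing_cols}")
        for lineno, row in enumerate(reader, start=2):
            try:
                entries.append(_parse_register_row(row, registry))
            except ValueError as exc:
                rejects.append({"line": lineno, "row": dict(row), "reason": str(exc)})
    return entries, rejects


def _parse_register_row(row: Mapping[str, str], registry: CodeRegistry) -> RegisterEntry:
    try:
        date = _dt.date.fromisoformat(row["encounter_date"].strip())
    except ValueError:
        raise ValueError(f"unparseable encounter_date {row['encounter_date']!r}")
    age_raw = (row.get("child_age_months") or "").strip()
    age = int(age_raw) if age_raw else None

    symptoms = _parse_multivalue(row.get("symptoms") or "")
    for code in symptoms:
        if code not in registry.symptoms:
            raise ValueError(f"unknown symptom code {code!r}")
    treatments = _parse_multivalue(row.get("treatments") or "")
    for code in treatments:
        if code not in registry.treatments:
            raise ValueError(f"unknown treatment code {code!r}")

    diagnostics: dict[str, object] = {}
    for pair in _parse_multivalue(row.get("diagnostics") or ""):
        if "=" not in pair:
            raise ValueError(f"diagnostic {pair!r} is not a code=value pair")
        code, value = pair.split("=", 1)
        code, value = code.strip(), value.strip()
        if code not in registry.diagnostics:
            raise ValueError(f"unknown diagnostic code {code!r}")
        try:
            diagnostics[code] = int(value)
        except ValueError:
            try:
                diagnostics[code] = float(value)
            except ValueError:
                diagnostics[code] = value

    referral = (row.get("referral") or "").strip().lower() in {"1", "true", "yes", "y"}
    return RegisterEntry(
        chw_site_id=row["chw_site_id"].strip(),
        encounter_date=date,
        child_age_months=age,
        symptoms=frozenset(symptoms),
        diagnostics=diagnostics,
        treatments=frozenset(treatments),
        referral=referral,
    )


def write_registers(entries: Iterable[RegisterEntry], path: str | Path) -> None:
    """Write entries in the same CSV dialect :func:`load_registers` reads."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTER_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.chw_site_id,
                    e.encounter_date.isoformat(),
                    "" if e.child_age_months is None else e.child_age_months,
                    "|".join(sorted(e.symptoms)),
                    "|".join(f"{k}={e.diagnostics[k]}" for k in sorted(e.diagnostics)),
                    "|".join(sorted(e.treatments)),
                    "1" if e.referral else "0",
                ]
            )


# ---------------------------------------------------------------------------
# Evidence-rule expressions
# ---------------------------------------------------------------------------

class _Expr:
    def evaluate(self, entry: RegisterEntry) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def codes(self) -> set[str]:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class _All(_Expr):
    terms: tuple[_Expr, ...]

    def evaluate(self, entry):
        return all(t.evaluate(entry) for t in self.terms)

    def codes(self):
        return set().union(*(t.codes() for t in self.terms)) if self.terms else set()


@dataclass(frozen=True)
class _Any(_Expr):
    terms: tuple[_Expr, ...]

    def evaluate(self, entry):
        return any(t.evaluate(entry) for t in self.terms)

    def codes(self):
        return set().union(*(t.codes() for t in self.terms)) if self.terms else set()


@dataclass(frozen=True)
class _Present(_Expr):
    code: str

    def evaluate(self, entry):
        return self.code in entry.symptoms or entry.diagnostics.get(self.code) is not None

    def codes(self):
        return {self.code}


@dataclass(frozen=True)
class _Eq(_Expr):
    code: str
    value: object

    def evaluate(self, entry):
        return entry.diagnostics.get(self.code) == self.value

    def codes(self):
        return {self.code}


@dataclass(frozen=True)
class _Ge(_Expr):
    code: str
    threshold: float

    def evaluate(self, entry):
        value = entry.diagnostics.get(self.code)
        return isinstance(value, (int, float)) and value >= self.threshold

    def codes(self):
        return {self.code}


@dataclass(frozen=True)
class _AgeLt(_Expr):
    months: int

    def evaluate(self, entry):
        return entry.child_age_months is not None and entry.child_age_months < self.months

    def codes(self):
        return set()


@dataclass(frozen=True)
class _AgeGe(_Expr):
    months: int

    def evaluate(self, entry):
        return entry.child_age_months is not None and entry.child_age_months >= self.months

    def codes(self):
        return set()


def _compile_expr(obj) -> _Expr:
    if not isinstance(obj, Mapping) or len(obj) != 1:
        raise RuleError(f"rule expression {obj!r} must be a single-key mapping")
    (key, value), = obj.items()
    if key == "all":
        return _All(tuple(_compile_expr(v) for v in value))
    if key == "any":
        return _Any(tuple(_compile_expr(v) for v in value))
    if key == "present":
        return _Present(str(value))
    if key == "eq":
        code, val = value
        return _Eq(str(code), val)
    if key == "ge":
        code, threshold = value
        return _Ge(str(code), float(threshold))
    if key == "age_lt":
        return _AgeLt(int(value))
    if key == "age_ge":
        return _AgeGe(int(value))
    raise RuleError(f"unknown rule operator {key!r}")


@dataclass(frozen=True)
class ValidationRule:
    """Which treatments an illness rule covers and what evidence they need."""

    id: str
    illness: str
    treatment_codes: frozenset[str]
    required_evidence: _Expr

    @classmethod
    def from_config(cls, cfg: Mapping, registry: CodeRegistry = DEFAULT_CODES) -> "ValidationRule":
        rule = cls(
            id=str(cfg["id"]),
            illness=str(cfg["illness"]),
            treatment_codes=frozenset(str(t) for t in cfg["treatments"]),
            required_evidence=_compile_expr(cfg["evidence"]),
        )
        unknown = {t for t in rule.treatment_codes if t not in registry.treatments}
        unknown |= {c for c in rule.required_evidence.codes() if not registry.known(c)}
        if unknown:
            raise RuleError(f"rule {rule.id!r} references undeclared codes {sorted(unknown)}")
        return rule


DEFAULT_RULE_CONFIG = [
    {
        "id": "malaria_default",
        "illness": "malaria",
        "treatments": ["act"],
        "evidence": {"all": [{"present": "fever"}, {"eq": ["rdt", "positive"]}]},
    },
    {
        "id": "diarrhea_default",
        "illness": "diarrhea",
        "treatments": ["ors", "zinc"],
        "evidence": {"present": "diarrhea"},
    },
    {
        "id": "pneumonia_default",
        "illness": "pneumonia",
        "treatments": ["amoxicillin"],
        "evidence": {
            "all": [
                {"present": "cough"},
                {
                    "any": [
                        {"present": "fast_breathing"},
                        {"all": [{"age_lt": 12}, {"ge": ["respiratory_rate", 50]}]},
                        {
                            "all": [
                                {"age_ge": 12},
                                {"age_lt": 60},
                                {"ge": ["respiratory_rate", 40]},
                            ]
                        },
                    ]
                },
            ]
        },
    },
]


def default_rules(registry: CodeRegistry = DEFAULT_CODES) -> list[ValidationRule]:
    return [ValidationRule.from_config(cfg, registry) for cfg in DEFAULT_RULE_CONFIG]


def load_rules(path: str | Path, registry: CodeRegistry = DEFAULT_CODES) -> list[ValidationRule]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"rule file not found: {path}")
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, list):
        raise RuleError("rule file must be a list of rule mappings")
    return [ValidationRule.from_config(item, registry) for item in cfg]


# ---------------------------------------------------------------------------
# Evaluation and aggregation
# ---------------------------------------------------------------------------

def evaluate_rule(entry: RegisterEntry, rule: ValidationRule) -> tuple[bool, bool]:
    """Evaluate one entry: ``(recorded, appropriate)``.

    ``recorded`` — a treatment covered by the rule is recorded.
    ``appropriate`` — recorded *and* the required evidence is on the entry.
    """
    recorded = bool(entry.treatments & rule.treatment_codes)
    appropriate = recorded and rule.required_evidence.evaluate(entry)
    return recorded, appropriate


RATIO_NOT_APPLICABLE = "not_applicable"
RATIO_INFINITE = "infinite"
RATIO_OK = "ok"


@dataclass(frozen=True)
class VerificationResult:
    """Verification counts and ratio for one illness within one scope."""

    scope: str  # "chw" | "facility" | "overall"
    scope_id: str
    illness: str
    recorded: int
    appropriate: int
    ratio: float | None
    flag: str

    def __post_init__(self) -> None:
        if not 0 <= self.appropriate <= self.recorded:
            raise ValueError("appropriate must satisfy 0 <= appropriate <= recorded")


def _ratio(numerator: int, denominator: int) -> tuple[float | None, str]:
    if denominator > 0:
        return numerator / denominator, RATIO_OK
    if numerator > 0:
        return math.inf, RATIO_INFINITE
    return None, RATIO_NOT_APPLICABLE


def verification_ratio(
    recorded: int, appropriate: int, orientation: str = "recorded_over_appropriate"
) -> tuple[float | None, str]:
    """Ratio with 0/0 -> not-applicable sentinel and x/0 -> flagged infinity."""
    if orientation == "recorded_over_appropriate":
        return _ratio(recorded, appropriate)
    if orientation == "appropriate_over_recorded":
        return _ratio(appropriate, recorded)
    raise ConfigError(f"unknown ratio orientation {orientation!r}")


def verify_register(
    entries: Sequence[RegisterEntry],
    rules: Sequence[ValidationRule],
    period: Period,
    group_by: str = "chw",
    system: ReportingSystem | None = None,
    orientation: str = "recorded_over_appropriate",
) -> list[VerificationResult]:
    """Count recorded vs appropriately recorded treatments per illness and scope.

    Entries are filtered to the period by encounter date (closed interval
    on month boundaries). ``group_by`` is ``"chw"``, ``"facility"`` (needs
    ``system`` to roll CHWs up to their facility) or ``"overall"``.
    """
    if group_by not in {"chw", "facility", "overall"}:
        raise ConfigError(f"unknown group_by {group_by!r}")
    if group_by == "facility" and system is None:
        raise ConfigError("group_by='facility' requires a reporting system")

    def group_key(entry: RegisterEntry) -> str:
        if group_by == "overall":
            return "overall"
        if group_by == "chw":
            return entry.chw_site_id
        site = system.site(entry.chw_site_id)
        if not site.parent_ids:
            raise ConfigError(f"community site {site.id!r} has no facility parent")
        return sorted(site.parent_ids)[0]

    counts: dict[tuple[str, str], list[int]] = {}
    for entry in entries:
        if not period.contains_date(entry.encounter_date):
            continue
        key_scope = group_key(entry)
        for rule in rules:
            recorded, appropriate = evaluate_rule(entry, rule)
            if recorded:
                cell = counts.setdefault((key_scope, rule.illness), [0, 0])
                cell[0] += 1
                cell[1] += int(appropriate)

    # emit zero rows for every group x illness seen, plus overall zeros on empty input
    if group_by == "overall" and not counts:
        counts = {("overall", rule.illness): [0, 0] for rule in rules}

    results = []
    for (scope_id, illness), (recorded, appropriate) in sorted(counts.items()):
        ratio, flag = verification_ratio(recorded, appropriate, orientation)
        results.append(
            VerificationResult(
                scope=group_by,
                scope_id=scope_id,
                illness=illness,
                recorded=recorded,
                appropriate=appropriate,
                ratio=ratio,
                flag=flag,
            )
        )
    return results
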
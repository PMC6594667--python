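"""Multi-stage site selection for DQA fieldwork.

A DQA visits a small, logistically feasible set of sites — a snapshot,
explicitly not a statistically representative sample. Selection runs in
stages (e.g. provinces → districts → facilities): at each stage the
eligible pool is restricted to units whose parent was selected at the
previous stage, exclusions are applied with machine-readable reason
codes (insecurity, no CHW active for the entire reporting period, old
report forms, distance), and ``n`` units are drawn by simple random
sampling without replacement. Back-up facilities are drawn in the same
random pass, after the primaries, so one seed fully determines both;
they substitute, in draw order, for primaries that turn out to be
inaccessible. A purposeful stage takes an explicit list instead of a
draw (used where insecurity rules out travel to randomly chosen sites).
Every step is written to an audit log.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DataError, SamplingError


@dataclass(frozen=True)
class FrameUnit:
    id: str
    stage: str
    parent_id: str | None = None
    eligible: bool = True
    exclusion_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.eligible and not self.exclusion_reasons:
            raise ConfigError(
                f"frame unit {self.id!r}: every exclusion needs a reason code"
            )


@dataclass
class SamplingFrame:
    units: list[FrameUnit]

    def at_stage(self, stage: str) -> list[FrameUnit]:
        return [u for u in self.units if u.stage == stage]


@dataclass(frozen=True)
class PlanStage:
    stage: str
    n: int
    method: str = "random"  # "random" | "purposeful"
    units: tuple[str, ...] = ()  # explicit list, required for purposeful stages

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"stage {self.stage!r}: n must be >= 1")
        if self.method not in {"random", "purposeful"}:
            raise ConfigError(f"stage {self.stage!r}: unknown method {self.method!r}")
        if self.method == "purposeful" and not self.units:
            raise ConfigError(
                f"stage {self.stage!r}: purposeful stages need an explicit unit list"
            )


@dataclass(frozen=True)
class SamplingPlan:
    stages: tuple[PlanStage, ...]
    n_backups: int = 0
    seed: int = 0


@dataclass
class Selection:
    """Result of executing a plan: primaries per stage, ordered backups for
    the final stage, and an append-only audit log."""

    primaries: dict[str, list[str]]
    backups: list[str]
    used_backups: list[str] = field(default_factory=list)
    audit_log: list[dict] = field(default_factory=list)

    @property
    def final_stage(self) -> str:
        return list(self.primaries)[-1]

    def final_sites(self) -> list[str]:
        return self.primaries[self.final_stage]


def load_frame(path: str | Path) -> SamplingFrame:
    """Frame CSV: id, stage, parent_id, eligible, exclusion_reasons
    (``|``-separated reason codes)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"frame file not found: {path}")
    units = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            eligible = (row.get("eligible") or "1").strip().lower() not in {"0", "false", "no"}
            reasons = tuple(
                t.strip() for t in (row.get("exclusion_reasons") or "").split("|") if t.strip()
            )
            units.append(
                FrameUnit(
                    id=row["id"].strip(),
                    stage=row["stage"].strip(),
                    parent_id=(row.get("parent_id") or "").strip() or None,
                    eligible=eligible,
                    exclusion_reasons=reasons,
                )
            )
    return SamplingFrame(units)


def load_plan(source: str | Path | Mapping) -> SamplingPlan:
    if isinstance(source, Mapping):
        cfg = source
    else:
        path = Path(source)
        if not path.exists():
            raise DataError(f"plan file not found: {path}")
        cfg = yaml.safe_load(path.read_text())
    stages = tuple(
        PlanStage(
            stage=str(s["stage"]),
            n=int(s["n"]),
            method=str(s.get("method", "random")),
            units=tuple(str(u) for u in s.get("units", ())),
        )
        for s in cfg["stages"]
    )
    return SamplingPlan(
        stages=stages,
        n_backups=int(cfg.get("n_backups", 0)),
        seed=int(cfg.get("seed", 0)),
    )


def select_sites(
    frame: SamplingFrame, plan: SamplingPlan, seed: int | None = None
) -> Selection:
    """Execute the plan. Deterministic given (frame, plan, seed)."""
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    primaries: dict[str, list[str]] = {}
    backups: list[str] = []
    audit: list[dict] = []
    selected_parents: list[str] | None = None

    for stage_idx, stage in enumerate(plan.stages):
        stage_units = frame.at_stage(stage.stage)
        if not stage_units:
            raise ConfigError(f"frame has no units at stage {stage.stage!r}")
        in_scope = [
            u
            for u in stage_units
            if selected_parents is None or u.parent_id in selected_parents
        ]
        excluded = [(u.id, list(u.exclusion_reasons)) for u in in_scope if not u.eligible]
        pool = sorted(u.id for u in in_scope if u.eligible)

        is_final = stage_idx == len(plan.stages) - 1
        event: dict = {
            "stage": stage.stage,
            "method": stage.method,
            "pool_size": len(pool),
            "excluded": excluded,
            "n_requested": stage.n,
        }
        if stage.method == "purposeful":
            missing = [u for u in stage.units if u not in pool]
            if missing:
                raise SamplingError(
                    f"stage {stage.stage!r}: purposeful units not in eligible pool: {missing}"
                )
            chosen = list(stage.units)
            stage_backups: list[str] = []
        else:
            if len(pool) < stage.n:
                raise SamplingError(
                    f"stage {stage.stage!r}: pool has {len(pool)} eligible units, "
                    f"{stage.n} requested (shortfall {stage.n - len(pool)})"
                )
            n_extra = plan.n_backups if is_final else 0
            order = list(rng.permutation(len(pool)))
            drawn = [pool[i] for i in order[: stage.n + n_extra]]
            chosen = drawn[: stage.n]
            stage_backups = drawn[stage.n:]
            if is_final and len(stage_backups) < plan.n_backups:
                event["backup_shortfall"] = plan.n_backups - len(stage_backups)
        event["selected"] = chosen
        if is_final:
            event["backups"] = stage_backups
            backups = stage_backups
        audit.append(event)
        primaries[stage.stage] = chosen
        selected_parents = chosen

    return Selection(primaries=primaries, backups=backups, audit_log=audit)


def replace_with_backup(selection: Selection, inaccessible_site: str) -> Selection:
    """Substitute the first unused backup for an inaccessible primary site."""
    final = selection.primaries[selection.final_stage]
    if inaccessible_site not in final:
        raise SamplingError(
            f"{inaccessible_site!r} is not a selected site at stage "
            f"{selection.final_stage!r}"
        )
    unused = [b for b in selection.backups if b not in selection.used_backups]
    if not unused:
        raise SamplingError(
            f"no backup remaining to replace {inaccessible_site!r}"
        )
    backup = unused[0]
    idx = final.index(inaccessible_site)
    final[idx] = backup
    selection.used_backups.append(backup)
    selection.audit_log.append(
        {"event": "backup_replacement", "replaced": inaccessible_site, "with": backup}
    )
    return selection


def write_audit_log(selection: Selection, path: str | Path) -> None:
    """Audit log as JSONL, one event per line."""
    with Path(path).open("w") as fh:
        for event in selection.audit_log:
            fh.write(json.dumps(event) + "\n")
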
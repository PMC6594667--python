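"""Systems-assessment questionnaire scoring and scorecard aggregation.

The systems assessment scores standardized questions about the
functional dimensions of a reporting system on a 1–3 scale
(1 = no, not at all; 2 = yes, partly; 3 = yes, completely). A score of
1 or 2 must be accompanied by a note explaining the reason. Scores are
averaged per dimension at three grains — per site, per reporting level,
and across all levels — and displayed as a spider (radar) diagram. The
closer a dimension's mean sits to 3, the more functional the system is
on that dimension.

The default dimension set has five entries (M&E structures, indicator
definitions, forms, data management, national-system links); a sixth —
use of data for decision making — can be enabled in configuration, and
the whole set is configurable.

Level and overall means pool item scores (mean over all contributing
item responses in the grain) rather than averaging site means; a flag
switches to mean-of-site-means. Not-applicable (NA) responses are
excluded from both numerator and denominator everywhere; a cell with no
applicable items is empty, never imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError, DataError, ValidationError
from .reporting_model import ReportingSystem

DEFAULT_DIMENSIONS = [
    "me_structures",
    "indicator_definitions",
    "data_collection_forms",
    "data_management",
    "national_links",
]

SIXTH_DIMENSION = "data_use"

DIMENSION_LABELS = {
    "me_structures": "M&E structures, functions and capabilities",
    "indicator_definitions": "Indicator definitions and reporting guidelines",
    "data_collection_forms": "Data collection and reporting forms",
    "data_management": "Data management processes",
    "national_links": "Links with national reporting system",
    "data_use": "Use of data for decision making",
}

NA = "NA"


@dataclass(frozen=True)
class AssessmentQuestion:
    id: str
    dimension: str
    applicable_levels: frozenset[str]
    text: str
    requires_feature: str | None = None


@dataclass(frozen=True)
class AssessmentResponse:
    question_id: str
    site_id: str
    score: int | None  # None encodes NA
    note: str = ""


# A representative default question bank. The field tools carry a much
# larger bank; this one is illustrative and covers every dimension at
# every common level so that a default run produces a full scorecard.
DEFAULT_QUESTIONNAIRE = [
    {"id": "mes1", "dimension": "me_structures",
     "text": "Staff responsible for iCCM data review are designated at this level.",
     "levels": "all"},
    {"id": "mes2", "dimension": "me_structures",
     "text": "Staff have been trained on the current reporting tools.",
     "levels": "all"},
    {"id": "ind1", "dimension": "indicator_definitions",
     "text": "Written indicator definitions are available and match the national set.",
     "levels": "all"},
    {"id": "ind2", "dimension": "indicator_definitions",
     "text": "Reporting deadlines are documented and known to reporting staff.",
     "levels": "all"},
    {"id": "form1", "dimension": "data_collection_forms",
     "text": "The current register/report form version is in use at this level.",
     "levels": "all"},
    {"id": "form2", "dimension": "data_collection_forms",
     "text": "Forms capture every data element needed for the traced indicators.",
     "levels": "all"},
    {"id": "dm1", "dimension": "data_management",
     "text": "Written procedures exist for handling late, incomplete or missing reports.",
     "levels": "all"},
    {"id": "dm2", "dimension": "data_management",
     "text": "Reported totals are checked against source documents before forwarding.",
     "levels": "all"},
    {"id": "dm3", "dimension": "data_management",
     "text": "Archived copies of source documents are retrievable for the assessed period.",
     "levels": "all"},
    {"id": "dm4", "dimension": "data_management",
     "text": "Electronic data entry includes validation checks for out-of-range values.",
     "levels": "all", "requires_feature": "electronic_entry"},
    {"id": "link1", "dimension": "national_links",
     "text": "Community data reported here are incorporated into the national HIS.",
     "levels": "all"},
    {"id": "use1", "dimension": "data_use",
     "text": "Results are reviewed at this level and documented decisions follow from them.",
     "levels": "all"},
]


def load_questionnaire(
    source: str | Path | Sequence[Mapping] | None = None,
    system: ReportingSystem | None = None,
    dimensions: Sequence[str] | None = None,
) -> list[AssessmentQuestion]:
    """Load and validate assessment questions, applying applicability filters.

    A question carrying ``requires_feature`` is kept only for levels that
    declare that feature in the system map (e.g. electronic-data-entry
    questions drop out at levels without an electronic system). Questions
    whose dimension is not in the configured set raise a config error.
    """
    if source is None:
        raw: Sequence[Mapping] = DEFAULT_QUESTIONNAIRE
    elif isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise DataError(f"questionnaire file not found: {path}")
        raw = yaml.safe_load(path.read_text())
    else:
        raw = source
    if dimensions is None:
        dimensions = DEFAULT_DIMENSIONS + [SIXTH_DIMENSION]

    all_levels = (
        frozenset(lv.id for lv in system.levels) if system is not None else None
    )
    questions: list[AssessmentQuestion] = []
    for item in raw:
        dim = str(item["dimension"])
        if dim not in dimensions:
            raise ConfigError(
                f"question {item.get('id')!r}: unknown dimension {dim!r} "
                f"(configured: {list(dimensions)})"
            )
        levels_spec = item.get("levels", "all")
        if levels_spec == "all":
            if all_levels is None:
                levels = frozenset({"all"})
            else:
                levels = all_levels
        else:
            levels = frozenset(str(lv) for lv in levels_spec)
            if all_levels is not None:
                unknown = levels - all_levels
                if unknown:
                    raise ConfigError(
                        f"question {item.get('id')!r}: unknown levels {sorted(unknown)}"
                    )
        feature = item.get("requires_feature")
        if feature and system is not None:
            levels = frozenset(
                lv for lv in levels if feature in system.level(lv).features
            )
            if not levels:
                continue  # not applicable anywhere in this system
        if not levels:
            raise ConfigError(f"question {item.get('id')!r}: no applicable level")
        questions.append(
            AssessmentQuestion(
                id=str(item["id"]),
                dimension=dim,
                applicable_levels=levels,
                text=str(item.get("text", "")),
                requires_feature=feature,
            )
        )
    return questions


def load_responses(path: str | Path) -> list[AssessmentResponse]:
    """Read responses CSV (question_id, site_id, score, note); score ``NA``
    marks a question excluded as not applicable."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"responses file not found: {path}")
    responses: list[AssessmentResponse] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            raw = (row.get("score") or "").strip()
            if raw.upper() == NA or raw == "":
                score: int | None = None
            else:
                score = int(raw)
                if score not in (1, 2, 3):
                    raise ValidationError(
                        f"response ({row.get('question_id')}, {row.get('site_id')}): "
                        f"score must be 1, 2, 3 or NA, got {raw!r}"
                    )
            responses.append(
                AssessmentResponse(
                    question_id=(row.get("question_id") or "").strip(),
                    site_id=(row.get("site_id") or "").strip(),
                    score=score,
                    note=(row.get("note") or "").strip(),
                )
            )
    return responses


def validate_responses(
    responses: Sequence[AssessmentResponse],
    questions: Sequence[AssessmentQuestion],
) -> None:
    """Enforce the note rule: scores of 1 or 2 require a reason note.

    Mirrors the assessment tool's behavior of auto-generating a mandatory
    reasons field for low scores. Raises listing every offending response.
    """
    known = {q.id for q in questions}
    offenders = []
    unknown = []
    for r in responses:
        if r.question_id not in known:
            unknown.append((r.question_id, r.site_id))
        if r.score in (1, 2) and not r.note:
            offenders.append((r.question_id, r.site_id))
    if unknown:
        raise ValidationError(f"responses reference unknown questions: {unknown}")
    if offenders:
        raise ValidationError(
            f"scores of 1 or 2 require an explanatory note; missing for: {offenders}"
        )


@dataclass
class Scorecard:
    """Mean 1–3 score per dimension at site, level and overall grains.

    Each cell is ``(mean, n_items)``; a dimension with no contributing
    items in a grain is absent (rendered as not-applicable downstream).
    """

    dimensions: list[str]
    by_site: dict[tuple[str, str], tuple[float, int]]  # (dimension, site_id)
    by_level: dict[tuple[str, str], tuple[float, int]]  # (dimension, level_id)
    overall: dict[str, tuple[float, int]]  # dimension

    def to_records(self) -> list[dict]:
        records = []
        for (dim, site), (mean, n) in sorted(self.by_site.items()):
            records.append(
                {"grain": "site", "dimension": dim, "scope": site, "mean": mean, "n_items": n}
            )
        for (dim, level), (mean, n) in sorted(self.by_level.items()):
            records.append(
                {"grain": "level", "dimension": dim, "scope": level, "mean": mean, "n_items": n}
            )
        for dim, (mean, n) in sorted(self.overall.items()):
            records.append(
                {"grain": "overall", "dimension": dim, "scope": "__all__", "mean": mean, "n_items": n}
            )
        return records


def score(
    responses: Sequence[AssessmentResponse],
    questions: Sequence[AssessmentQuestion],
    system: ReportingSystem,
    aggregation: str = "pooled",
) -> Scorecard:
    """Aggregate responses into the dimension × site/level/overall scorecard.

    ``aggregation="pooled"`` (default) computes level and overall means
    over all contributing item scores; ``"site_means"`` averages the site
    means instead (unweighted). NA responses are excluded everywhere.
    """
    if aggregation not in {"pooled", "site_means"}:
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    validate_responses(responses, questions)
    q_by_id = {q.id: q for q in questions}

    site_scores: dict[tuple[str, str], list[int]] = {}
    dims_seen: list[str] = []
    for q in questions:
        if q.dimension not in dims_seen:
            dims_seen.append(q.dimension)
    for r in responses:
        if r.score is None:
            continue  # NA: excluded from numerator and denominator
        q = q_by_id[r.question_id]
        site = system.site(r.site_id)
        if q.applicable_levels != frozenset({"all"}) and site.level_id not in q.applicable_levels:
            raise ValidationError(
                f"response ({r.question_id}, {r.site_id}): question not applicable "
                f"at level {site.level_id!r}"
            )
        site_scores.setdefault((q.dimension, r.site_id), []).append(r.score)

    by_site = {
        key: (sum(v) / len(v), len(v)) for key, v in site_scores.items()
    }

    by_level: dict[tuple[str, str], tuple[float, int]] = {}
    overall: dict[str, tuple[float, int]] = {}
    if aggregation == "pooled":
        level_pool: dict[tuple[str, str], list[int]] = {}
        overall_pool: dict[str, list[int]] = {}
        for (dim, site_id), scores in site_scores.items():
            level_id = system.site(site_id).level_id
            level_pool.setdefault((dim, level_id), []).extend(scores)
            overall_pool.setdefault(dim, []).extend(scores)
        by_level = {k: (sum(v) / len(v), len(v)) for k, v in level_pool.items()}
        overall = {k: (sum(v) / len(v), len(v)) for k, v in overall_pool.items()}
    else:
        level_means: dict[tuple[str, str], list[float]] = {}
        overall_means: dict[str, list[float]] = {}
        for (dim, site_id), (mean, n) in by_site.items():
            level_id = system.site(site_id).level_id
            level_means.setdefault((dim, level_id), []).append(mean)
            overall_means.setdefault(dim, []).append(mean)
        by_level = {k: (sum(v) / len(v), len(v)) for k, v in level_means.items()}
        overall = {k: (sum(v) / len(v), len(v)) for k, v in overall_means.items()}

    return Scorecard(
        dimensions=dims_seen, by_site=by_site, by_level=by_level, overall=overall
    )


def spider_chart_data(
    scorecard: Scorecard,
    grain: str = "overall",
    scope: str | None = None,
    dimensions: Sequence[str] | None = None,
) -> list[tuple[str, float | None]]:
    """Ordered (dimension, mean) series for a radar plot.

    Dimensions with no applicable items yield ``None`` — a gap on the
    chart, never a zero (which would read as an off-scale score).
    """
    dims = list(dimensions) if dimensions is not None else scorecard.dimensions
    series: list[tuple[str, float | None]] = []
    for dim in dims:
        if grain == "overall":
            cell = scorecard.overall.get(dim)
        elif grain == "level":
            cell = scorecard.by_level.get((dim, scope))
        elif grain == "site":
            cell = scorecard.by_site.get((dim, scope))
        else:
            raise ConfigError(f"unknown grain {grain!r}")
        series.append((dim, cell[0] if cell else None))
    return series


def render_radar(
    series: Sequence[tuple[str, float | None]],
    path: str | Path,
    title: str = "Systems assessment",
) -> None:
    """Render a spider diagram of dimension means (scale fixed to 1–3)."""
    import math as _math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [DIMENSION_LABELS.get(d, d) for d, _ in series]
    values = [v for _, v in series]
    n = len(series)
    angles = [2 * _math.pi * i / n for i in range(n)]
    # close the polygon through present values only; gaps stay gaps
    fig, ax = plt.subplots(subplot_kw={"polar": True}, figsize=(6, 6))
    plot_angles = angles + angles[:1]
    plot_values = values + values[:1]
    ax.plot(
        [a for a, v in zip(plot_angles, plot_values) if v is not None],
        [v for v in plot_values if v is not None],
        marker="o",
    )
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylim(0, 3)
    ax.set_yticks([1, 2, 3])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
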
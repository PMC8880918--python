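"""Taxonomy and task-analysis management, file I/O, and reporting.

The toolkit's inputs are flat, diff-able text files:

* taxonomy: YAML with three PSF categories (personal, job, organization),
  each holding labelled subPSFs with definitions and weights summing to ~1;
* task analysis: CSV ``task_id,task_title,subtask_id,description``;
* ratings: long CSV ``subtask_id,level,name,rating`` with level ``category``
  or ``subpsf``;
* expert panel: CSV ``id,experience,education,relevancy``;
* opinions: CSV ``item,expert,term``;
* pairwise judgments: CSV ``category,criterion_a,criterion_b,term,direction``
  with an optional ``expert`` column;
* linguistic scales: YAML mapping term -> fuzzy-number breakpoints.

The bundled defaults (``load_* ("default")``) are the published
emergency-department case study: 17 subPSFs, 5 tasks with 31 subtasks, and
the 31 category-level rating rows.  Loaders validate eagerly and report the
first offending record with its line number; nothing is partially loaded.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import yaml

from .ahp import DEFAULT_AHP_SCALE
from .consensus import ExpertProfile, OpinionSet
from .fuzzy import FuzzyNumber, make_fuzzy
from .slim import CATEGORIES, HEPResult, RatingSheet, SubtaskRating

__all__ = [
    "SubPSF",
    "PSFCategory",
    "PSFTaxonomy",
    "Subtask",
    "Task",
    "TaskAnalysis",
    "load_taxonomy",
    "save_taxonomy",
    "load_task_analysis",
    "load_ratings",
    "load_panel",
    "load_opinions",
    "load_judgments",
    "load_scale",
    "render_report",
]

_WEIGHT_TOL = 1e-3 + 1e-12


@dataclass(frozen=True)
class SubPSF:
    label: str
    definition: str
    weight: float


@dataclass(frozen=True)
class PSFCategory:
    name: str
    subpsfs: tuple[SubPSF, ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.subpsfs]
        if len(set(labels)) != len(labels):
            raise ValueError(f"category {self.name!r}: duplicate subPSF labels")
        total = sum(s.weight for s in self.subpsfs)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"category {self.name!r}: subPSF weights sum to {total:.4f}, "
                "expected 1 within 0.001"
            )

    @property
    def weights(self) -> dict[str, float]:
        return {s.label: s.weight for s in self.subpsfs}


@dataclass(frozen=True)
class PSFTaxonomy:
    """Three PSF categories with their weighted subPSFs."""

    categories: tuple[PSFCategory, ...]

    def __post_init__(self) -> None:
        names = tuple(c.name for c in self.categories)
        if names != CATEGORIES:
            raise ValueError(
                f"taxonomy categories must be {CATEGORIES} in order, got {names}"
            )

    def category(self, name: str) -> PSFCategory:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    def weights(self, category: str) -> dict[str, float]:
        return self.category(category).weights

    @property
    def n_subpsfs(self) -> int:
        return sum(len(c.subpsfs) for c in self.categories)


@dataclass(frozen=True)
class Subtask:
    id: str
    description: str


@dataclass(frozen=True)
class Task:
    id: str
    title: str
    subtasks: tuple[Subtask, ...]


@dataclass(frozen=True)
class TaskAnalysis:
    """Ordered tasks, each with ordered dotted-id subtasks (e.g. "2.4")."""

    tasks: tuple[Task, ...]

    def __post_init__(self) -> None:
        ids = [s.id for t in self.tasks for s in t.subtasks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subtask ids in task analysis")
        for t in self.tasks:
            for s in t.subtasks:
                if not s.id.startswith(f"{t.id}."):
                    raise ValueError(
                        f"subtask {s.id!r} is not numbered under task {t.id!r}"
                    )

    @property
    def subtask_ids(self) -> list[str]:
        return [s.id for t in self.tasks for s in t.subtasks]

    @property
    def n_subtasks(self) -> int:
        return len(self.subtask_ids)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _bundled(name: str):
    return resources.files("fuzzyslim.data").joinpath(name)

def _open_text(source, default_name: str):
    """Open ``source`` ("default", a path, or a file object) for reading."""
    if source == "default":
        return _bundled(default_name).open("r", encoding="utf-8")
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source  # file-like


def _csv_records(
    fh, required: Sequence[str], optional: Sequence[str] = ()
) -> Iterator[tuple[int, dict[str, str]]]:
    """Yield (line_number, record) from a CSV with a header row."""
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise ValueError("empty file: missing header row")
    missing = [c for c in required if c not in reader.fieldnames]
    if missing:
        raise ValueError(f"missing required columns {missing} in header")
    known = set(required) | set(optional)
    unknown = [c for c in reader.fieldnames if c not in known]
    if unknown:
        raise ValueError(f"unknown columns {unknown} in header")
    for rec in reader:
        if any(v is None for v in rec.values()):
            raise ValueError(f"line {reader.line_num}: wrong number of fields")
        yield reader.line_num, {k: v.strip() for k, v in rec.items()}


def _parse_float(value: str, line: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"line {line}: {what} {value!r} is not a number") from None


# --------------------------------------------------------------------------
# taxonomy
# --------------------------------------------------------------------------

def load_taxonomy(source="default") -> PSFTaxonomy:
    """Load a PSF taxonomy from YAML (the bundled 17-factor one by default)."""
    with _open_text(source, "taxonomy.yaml") as fh:
        doc = yaml.safe_load(fh)
    try:
        cats = []
        for c in doc["categories"]:
            subs = tuple(
                SubPSF(str(s["label"]), str(s.get("definition", "")), float(s["weight"]))
                for s in c["subpsfs"]
            )
            cats.append(PSFCategory(str(c["name"]), subs))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed taxonomy file: {exc}") from None
    return PSFTaxonomy(tuple(cats))


def save_taxonomy(taxonomy: PSFTaxonomy, path) -> None:
    """Write a taxonomy back to YAML; round-trips through load_taxonomy."""
    doc = {
        "categories": [
            {
                "name": c.name,
                "subpsfs": [
                    {"label": s.label, "definition": s.definition, "weight": s.weight}
                    for s in c.subpsfs
                ],
            }
            for c in taxonomy.categories
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


# --------------------------------------------------------------------------
# task analysis and ratings
# --------------------------------------------------------------------------

def load_task_analysis(source="default") -> TaskAnalysis:
    """Load a task analysis CSV (bundled: 5 tasks, 31 subtasks)."""
    with _open_text(source, "task_analysis.csv") as fh:
        tasks: dict[str, Task] = {}
        order: list[str] = []
        subtasks: dict[str, list[Subtask]] = {}
        titles: dict[str, str] = {}
        for line, rec in _csv_records(
            fh, ("task_id", "task_title", "subtask_id", "description")
        ):
            tid, sid = rec["task_id"], rec["subtask_id"]
            if tid not in titles:
                titles[tid] = rec["task_title"]
                order.append(tid)
                subtasks[tid] = []
            elif titles[tid] != rec["task_title"]:
                raise ValueError(
                    f"line {line}: task {tid} retitled to {rec['task_title']!r}"
                )
            if any(s.id == sid for ss in subtasks.values() for s in ss):
                raise ValueError(f"line {line}: duplicate subtask id {sid!r}")
            if not sid.startswith(f"{tid}."):
                raise ValueError(
                    f"line {line}: subtask id {sid!r} inconsistent with task {tid!r}"
                )
            subtasks[tid].append(Subtask(sid, rec["description"]))
    if not order:
        raise ValueError("task analysis contains no rows")
    return TaskAnalysis(
        tuple(Task(tid, titles[tid], tuple(subtasks[tid])) for tid in order)
    )


def load_ratings(source="default", tasks: TaskAnalysis | None = None) -> RatingSheet:
    """Load a long-format rating sheet; checks ids against ``tasks`` if given.

    The bundled default holds the case study's 31 category-level rows.
    """
    known = set(tasks.subtask_ids) if tasks is not None else None
    grouped: dict[str, dict[str, float]] = {}
    levels: dict[str, str] = {}
    with _open_text(source, "case_study_ratings.csv") as fh:
        for line, rec in _csv_records(fh, ("subtask_id", "level", "name", "rating")):
            sid, level, name = rec["subtask_id"], rec["level"], rec["name"]
            if known is not None and sid not in known:
                raise ValueError(
                    f"line {line}: subtask id {sid!r} not in the task analysis"
                )
            if level not in ("category", "subpsf"):
                raise ValueError(f"line {line}: unknown level {level!r}")
            if levels.setdefault(sid, level) != level:
                raise ValueError(
                    f"line {line}: subtask {sid} mixes category- and "
                    "subPSF-level ratings"
                )
            r = _parse_float(rec["rating"], line, "rating")
            if not 1.0 <= r <= 9.0:
                raise ValueError(f"line {line}: rating {r} outside [1, 9]")
            if name in grouped.setdefault(sid, {}):
                raise ValueError(f"line {line}: duplicate rating for {sid}/{name}")
            grouped[sid][name] = r
    if not grouped:
        raise ValueError("rating sheet contains no rows")
    entries = {
        sid: SubtaskRating(sid, levels[sid], ratings)
        for sid, ratings in grouped.items()
    }
    return RatingSheet(entries)


# --------------------------------------------------------------------------
# panels, opinions, judgments, scales
# --------------------------------------------------------------------------

def load_panel(source) -> list[ExpertProfile]:
    """Load expert profiles (weights unassigned; see consensus.expert_weights)."""
    profiles: list[ExpertProfile] = []
    seen: set[str] = set()
    with _open_text(source, "panel.csv") as fh:
        for line, rec in _csv_records(fh, ("id", "experience", "education", "relevancy")):
            if rec["id"] in seen:
                raise ValueError(f"line {line}: duplicate expert id {rec['id']!r}")
            seen.add(rec["id"])
            profiles.append(
                ExpertProfile(
                    rec["id"],
                    _parse_float(rec["experience"], line, "experience"),
                    rec["education"],
                    rec["relevancy"],
                )
            )
    if not profiles:
        raise ValueError("panel file contains no experts")
    return profiles


def load_opinions(
    source, scale: Mapping[str, FuzzyNumber]
) -> list[OpinionSet]:
    """Load linguistic opinions and resolve terms against ``scale``."""
    grouped: dict[str, dict[str, FuzzyNumber]] = {}
    with _open_text(source, "opinions.csv") as fh:
        for line, rec in _csv_records(fh, ("item", "expert", "term")):
            term = rec["term"].lower()
            if term not in scale:
                raise ValueError(
                    f"line {line}: unknown term {rec['term']!r} "
                    f"(scale has: {sorted(scale)})"
                )
            item = grouped.setdefault(rec["item"], {})
            if rec["expert"] in item:
                raise ValueError(
                    f"line {line}: duplicate opinion for {rec['item']}/{rec['expert']}"
                )
            item[rec["expert"]] = scale[term]
    if not grouped:
        raise ValueError("opinions file contains no rows")
    experts = {frozenset(ops) for ops in grouped.values()}
    if len(experts) != 1:
        raise ValueError("every expert must rate every item exactly once")
    return [OpinionSet(item, ops) for item, ops in grouped.items()]


def load_judgments(
    source,
) -> dict[str, dict[str, list[tuple[str, str, str, str]]]]:
    """Load pairwise judgments grouped by category, then by expert.

    Rows without an ``expert`` column (or with it empty) fall under the
    pseudo-expert ``"panel"``.  Terms are validated against the AHP scale.
    """
    grouped: dict[str, dict[str, list[tuple[str, str, str, str]]]] = {}
    with _open_text(source, "judgments.csv") as fh:
        for line, rec in _csv_records(
            fh,
            ("category", "criterion_a", "criterion_b", "term", "direction"),
            optional=("expert",),
        ):
            if rec["term"] not in DEFAULT_AHP_SCALE:
                raise ValueError(f"line {line}: unknown term {rec['term']!r}")
            if rec["direction"] not in ("a_over_b", "b_over_a"):
                raise ValueError(f"line {line}: unknown direction {rec['direction']!r}")
            expert = rec.get("expert") or "panel"
            grouped.setdefault(rec["category"], {}).setdefault(expert, []).append(
                (rec["criterion_a"], rec["criterion_b"], rec["term"], rec["direction"])
            )
    if not grouped:
        raise ValueError("judgments file contains no rows")
    return grouped


def load_scale(source="default") -> dict[str, FuzzyNumber]:
    """Load a linguistic scale (term -> breakpoints) from YAML."""
    with _open_text(source, "opinion_scale.yaml") as fh:
        doc = yaml.safe_load(fh)
    try:
        terms = doc["terms"]
        return {str(t).lower(): make_fuzzy(tuple(pts)) for t, pts in terms.items()}
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed scale file: {exc}") from None


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def _ranked(results: Sequence[HEPResult]) -> list[HEPResult]:
    # deterministic: HEP descending, ties broken by subtask id
    return sorted(results, key=lambda r: (-r.hep, r.subtask_id))


def render_report(results: Sequence[HEPResult], format: str = "table") -> str:
    """Render assessment results, ranked by HEP (worst first).

    ``"table"`` gives a fixed-width text report with a ranking summary;
    ``"csv"`` gives machine-readable full-precision rows that re-parse to
    identical values.
    """
    if format == "csv":
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["rank", "subtask_id", "r_personal", "r_job", "r_organization",
                    "sli", "hep"])
        for rank, r in enumerate(_ranked(results), start=1):
            w.writerow([rank, r.subtask_id, repr(r.r_personal), repr(r.r_job),
                        repr(r.r_organization), repr(r.sli), repr(r.hep)])
        return buf.getvalue()
    if format != "table":
        raise ValueError(f"unknown report format {format!r}")
    if not results:
        raise ValueError("no results to report")
    lines = [
        f"{'rank':>4}  {'subtask':<8} {'R_per':>7} {'R_job':>7} {'R_org':>7} "
        f"{'SLI':>7} {'HEP':>10}",
    ]
    for rank, r in enumerate(_ranked(results), start=1):
        lines.append(
            f"{rank:>4}  {r.subtask_id:<8} {r.r_personal:>7.3f} {r.r_job:>7.3f} "
            f"{r.r_organization:>7.3f} {r.sli:>7.3f} {r.hep:>10.2E}"
        )
    from .slim import extremes

    worst_ids, best_ids = extremes(results)
    hi = max(r.hep for r in results)
    lo = min(r.hep for r in results)
    lines.append("")
    lines.append(f"highest HEP: subtask {', '.join(worst_ids)} ({hi:.2E})")
    lines.append(f"lowest HEP:  subtask {', '.join(best_ids)} ({lo:.2E})")
    return "\n".join(lines) + "\n"
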
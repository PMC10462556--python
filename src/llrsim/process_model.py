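"""Surgical process model for parenchyma-sparing laparoscopic liver resection.

A procedure is decomposed into phases and modules following the generic
minimally-invasive-liver-treatment process model.  Modules are coded
``PxxMyy`` (phase number, module number); phase ``08a`` (destructive
isolation) keeps its alphanumeric label.  Each tumor-location category
(segments 5 & 6; segments 7 & 8; segment 5 with gallbladder removal) has its
own workflow graph: an ordered list of module nodes with occurrence
probabilities, question (decision) nodes, free-order groups, and mandatory
precedence chains.  The three built-in graphs are stored as editable JSON
data files bundled with the package.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "TIMED_PHASES",
    "IDLE",
    "ModuleCode",
    "SurgeryCategory",
    "GraphEntry",
    "Question",
    "ProcessGraph",
    "ValidationReport",
    "parse_module_code",
    "build_category_graph",
    "graph_module_set",
    "validate_graph",
    "graph_to_json",
    "graph_from_json",
]

#: Phases that carry timed modules in the resection workflow.
TIMED_PHASES = frozenset({"05", "06", "07", "08a", "10", "11", "13"})

#: Pseudo module code for idle intervals (lens cleaning, no visible activity).
IDLE = "IDLE"

_CODE_RE = re.compile(r"^P(?P<phase>05|06|07|08a|10|11|13)M(?P<module>\d{2})$")

#: Supply-duct handling modules never observed in segments 7 & 8.
_S78_FORBIDDEN = ("P08aM03", "P08aM05", "P08aM06")


@dataclass(frozen=True)
class ModuleCode:
    """A ``PxxMyy`` module code, or the reserved pseudo-code ``IDLE``.

    ``phase`` is ``"05"``..."13"`` or ``"08a"``; ``module`` is the two-digit
    module number within the phase.  Parsing then formatting a code is the
    identity.
    """

    phase: str
    module: str

    def __str__(self) -> str:
        if self.phase == IDLE:
            return IDLE
        return f"P{self.phase}M{self.module}"

    @property
    def is_idle(self) -> bool:
        return self.phase == IDLE


def parse_module_code(code: str) -> ModuleCode:
    """Parse a module code string; raises ``ValueError`` on unknown codes."""
    if code == IDLE:
        return ModuleCode(IDLE, "")
    m = _CODE_RE.match(code)
    if m is None:
        raise ValueError(f"not a valid module code: {code!r}")
    return ModuleCode(m.group("phase"), m.group("module"))


def module_phase(code: str) -> str:
    """Phase label of a module code string (``"IDLE"`` for idle records)."""
    return parse_module_code(code).phase


class SurgeryCategory(str, Enum):
    """Tumor-location category of a parenchyma-sparing resection."""

    S56 = "S56"  #: segments 5 & 6, no gallbladder removal
    S78 = "S78"  #: posterosuperior segments 7 & 8
    S5GB = "S5GB"  #: segment 5 with gallbladder removal (cholecystectomy)

    @classmethod
    def coerce(cls, value: "SurgeryCategory | str") -> "SurgeryCategory":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValueError(
                f"unknown surgery category {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


@dataclass(frozen=True)
class GraphEntry:
    """One module node of a workflow graph.

    ``probability`` is the probability that the module occurs once or more in
    a surgery (``None`` for continuation rows that revisit a module already
    listed, e.g. resection resumed after a mid-resection duct division).
    """

    label: str
    module: str
    probability: float | None
    phase: str = ""
    section: str = ""
    free_order: bool = False
    insertable: bool = False


@dataclass(frozen=True)
class Question:
    """A zero-duration decision point.

    Static questions carry fixed outcome probabilities.  Dynamic questions
    (repeat loops) reference a module whose occurrence-count distribution
    defines count-dependent outcome probabilities via its survival function;
    the numeric schedule is evaluated by the simulation engine.
    """

    id: str
    kind: str  # "static" | "dynamic"
    outcomes: dict[str, float] = field(default_factory=dict)
    after: str | None = None
    module: str | None = None


@dataclass
class ProcessGraph:
    """Category-specific workflow: nodes, questions, groups, precedence."""

    category: SurgeryCategory
    entries: list[GraphEntry]
    questions: list[Question]
    precedence: list[tuple[str, str]]
    untimed_modules: frozenset[str]
    most_probable_path: list[str]  # node labels, in order
    schema: str = "llrsim-workflow/1"

    # -- views -----------------------------------------------------------

    def nodes(self) -> list[GraphEntry]:
        return list(self.entries)

    def entry(self, label: str) -> GraphEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def occurrence_probability(self, module: str) -> float:
        """P(module occurs >= once) = max over the module's node entries."""
        probs = [e.probability for e in self.entries
                 if e.module == module and e.probability is not None]
        if not probs:
            raise KeyError(f"module {module} not in graph")
        return max(probs)

    def free_order_groups(self) -> list[list[str]]:
        groups: dict[str, list[str]] = {}
        for e in self.entries:
            if e.free_order and not e.insertable:
                groups.setdefault(e.section, []).append(e.label)
        return [g for g in groups.values() if len(g) > 1]

    def path_modules(self) -> list[str]:
        by_label = {e.label: e.module for e in self.entries}
        return [by_label[lbl] for lbl in self.most_probable_path]

    def __eq__(self, other: object) -> bool:  # structural equality
        if not isinstance(other, ProcessGraph):
            return NotImplemented
        return (
            self.category == other.category
            and self.entries == other.entries
            and self.questions == other.questions
            and self.precedence == other.precedence
            and self.untimed_modules == other.untimed_modules
            and self.most_probable_path == other.most_probable_path
        )


# ---------------------------------------------------------------------------
# construction from bundled data

_WORKFLOW_FILES = {
    SurgeryCategory.S56: "workflow_s56.json",
    SurgeryCategory.S78: "workflow_s78.json",
    SurgeryCategory.S5GB: "workflow_s5gb.json",
}


def _load_bundled(name: str) -> dict:
    with resources.files("llrsim.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def graph_from_dict(doc: dict) -> ProcessGraph:
    category = SurgeryCategory.coerce(doc["category"])
    entries: list[GraphEntry] = []
    for section in doc["sections"]:
        for raw in section["entries"]:
            entries.append(
                GraphEntry(
                    label=raw["label"],
                    module=raw["module"],
                    probability=raw["probability"],
                    phase=section["phase"],
                    section=section["name"],
                    free_order=bool(section.get("free_order", False)),
                )
            )
    for raw in doc.get("insert_anytime", []):
        entries.append(
            GraphEntry(
                label=raw["label"],
                module=raw["module"],
                probability=raw["probability"],
                phase=parse_module_code(raw["module"]).phase,
                section="insert-anytime",
                insertable=True,
            )
        )
    questions = [
        Question(
            id=q["id"],
            kind=q["kind"],
            outcomes=dict(q.get("outcomes", {})),
            after=q.get("after"),
            module=q.get("module"),
        )
        for q in doc.get("questions", [])
    ]
    return ProcessGraph(
        category=category,
        entries=entries,
        questions=questions,
        precedence=[tuple(p) for p in doc.get("precedence", [])],
        untimed_modules=frozenset(doc.get("untimed_modules", [])),
        most_probable_path=list(doc.get("most_probable_path", [])),
        schema=doc.get("schema", "llrsim-workflow/1"),
    )


def build_category_graph(category: SurgeryCategory | str) -> ProcessGraph:
    """The built-in workflow graph for a surgery category.

    Graphs are data, not code: they live in bundled JSON files so that users
    can edit occurrence probabilities or structure without touching code.
    """
    category = SurgeryCategory.coerce(category)
    return graph_from_dict(_load_bundled(_WORKFLOW_FILES[category]))


def graph_module_set(graph: ProcessGraph) -> set[str]:
    """The set of all module codes that appear as nodes in the graph."""
    return {e.module for e in graph.entries}


# ---------------------------------------------------------------------------
# serialization

def graph_to_dict(graph: ProcessGraph) -> dict:
    sections: list[dict] = []
    for e in graph.entries:
        if e.insertable:
            continue
        if not sections or sections[-1]["name"] != e.section:
            sections.append(
                {"phase": e.phase, "name": e.section,
                 "free_order": e.free_order, "entries": []}
            )
        sections[-1]["entries"].append(
            {"label": e.label, "module": e.module, "probability": e.probability}
        )
    return {
        "schema": graph.schema,
        "category": graph.category.value,
        "sections": sections,
        "insert_anytime": [
            {"label": e.label, "module": e.module, "probability": e.probability}
            for e in graph.entries if e.insertable
        ],
        "untimed_modules": sorted(graph.untimed_modules),
        "questions": [
            {k: v for k, v in
             {"id": q.id, "kind": q.kind, "after": q.after,
              "module": q.module, "outcomes": q.outcomes or None}.items()
             if v is not None}
            for q in graph.questions
        ],
        "precedence": [list(p) for p in graph.precedence],
        "most_probable_path": list(graph.most_probable_path),
    }


def graph_to_json(graph: ProcessGraph, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(graph_to_dict(graph), indent=2) + "\n", encoding="utf-8"
    )


def graph_from_json(path: str | Path) -> ProcessGraph:
    return graph_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    """Outcome of a structural check; ``violations`` is empty iff valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def validate_graph(graph: ProcessGraph) -> ValidationReport:
    """Check the ProcessGraph invariants; reports, never raises."""
    report = ValidationReport()
    for e in graph.entries:
        try:
            parse_module_code(e.module)
        except ValueError:
            report.violations.append(f"node {e.label!r}: bad module code {e.module!r}")
        if e.probability is not None and not 0.0 <= e.probability <= 1.0:
            report.violations.append(
                f"node {e.label!r}: occurrence probability {e.probability} outside [0, 1]"
            )
    for q in graph.questions:
        if q.kind == "static":
            total = sum(q.outcomes.values())
            if abs(total - 1.0) > 1e-9:
                report.violations.append(
                    f"question {q.id!r}: outcome probabilities sum to {total}, not 1"
                )
        elif q.kind == "dynamic":
            if q.module is None:
                report.violations.append(
                    f"question {q.id!r}: dynamic question lacks a module reference"
                )
        else:
            report.violations.append(f"question {q.id!r}: unknown kind {q.kind!r}")
    # mandatory modules must lie on the most probable path
    path_modules = set()
    labels = {e.label for e in graph.entries}
    for lbl in graph.most_probable_path:
        if lbl not in labels:
            report.violations.append(f"path label {lbl!r} is not a graph node")
        else:
            path_modules.add(graph.entry(lbl).module)
    for e in graph.entries:
        if e.probability == 1.0 and e.module not in path_modules:
            report.violations.append(
                f"mandatory module {e.module} ({e.label!r}) missing from most probable path"
            )
    if graph.category is SurgeryCategory.S78:
        present = graph_module_set(graph) & set(_S78_FORBIDDEN)
        for mod in sorted(present):
            report.violations.append(
                f"supply-duct module {mod} must not appear in the S78 graph"
            )
    return report
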
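"""Reading, writing, verification and normalization of surgical step logs.

A step log is the registration of one procedure from its endoscopic video:
one record per executed module with start/end video time in seconds.  The
registration rules of the study apply:

* consecutive records in the same module count as a single occurrence
  (:func:`collapse_repeats`);
* intra-operative ultrasound imaging (P05M02) may run in parallel with
  planning (P06M01) or with region marking (P10M01); all other overlaps are
  registration errors;
* planning time overlapped by imaging is attributed to imaging — the P06
  statistic is "planning duration without imaging" — whereas parallel
  marking-imaging time counts toward both (:func:`attribute_parallel_time`);
* planning records may have zero duration (planning that happened off-camera
  or in a blink), as may insufflation (P07M02), whose duration is not
  recognizable on video;
* idle intervals (lens cleaning, no visible activity) are explicit ``IDLE``
  records;
* exsufflation and incision closing (P13M08/P13M09) happen after the camera
  leaves the abdomen and are absent from logs by convention, as is the
  intra-operative preparation hour, which is a configuration constant.

On disk a cohort is a CSV table ``surgery_id,category,module,start_s,end_s``
with times serialized at one decimal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .process_model import (
    IDLE,
    ProcessGraph,
    SurgeryCategory,
    graph_module_set,
    parse_module_code,
)

__all__ = [
    "StepRecord",
    "SurgeryLog",
    "SteplogError",
    "VerificationReport",
    "ALLOWED_PARALLEL",
    "ZERO_DURATION_OK",
    "PREP_TIME_S",
    "read_steplogs",
    "write_steplogs",
    "verify_log",
    "collapse_repeats",
    "attribute_parallel_time",
]

#: Unordered module pairs that may legitimately overlap in time.
ALLOWED_PARALLEL = frozenset(
    {frozenset({"P05M02", "P06M01"}), frozenset({"P05M02", "P10M01"})}
)

#: Modules for which zero-duration records are legitimate.
ZERO_DURATION_OK = frozenset({"P06M01", "P07M02"})

#: Fixed intra-operative preparation time (s); not part of endoscopic totals.
PREP_TIME_S = 3600.0

_COLUMNS = ["surgery_id", "category", "module", "start_s", "end_s"]


class SteplogError(ValueError):
    """Malformed step-log input (bad module code, negative duration, ...)."""


@dataclass(frozen=True)
class StepRecord:
    """One executed module occurrence: code plus video start/end seconds."""

    module: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.module != IDLE:
            parse_module_code(self.module)  # raises on bad codes
        if self.start_s < 0:
            raise SteplogError(f"{self.module}: negative start time {self.start_s}")
        if self.end_s < self.start_s:
            raise SteplogError(
                f"{self.module}: end {self.end_s} precedes start {self.start_s}"
            )
        if self.end_s == self.start_s and self.module not in ZERO_DURATION_OK:
            raise SteplogError(
                f"{self.module}: zero duration only permitted for {sorted(ZERO_DURATION_OK)}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SurgeryLog:
    """Time-ordered step records of one procedure."""

    surgery_id: str
    category: SurgeryCategory
    steps: list[StepRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.category = SurgeryCategory.coerce(self.category)
        self.steps = sorted(self.steps, key=lambda r: (r.start_s, r.end_s, r.module))

    def modules(self) -> list[str]:
        return [r.module for r in self.steps]


# ---------------------------------------------------------------------------
# I/O

def read_steplogs(source: str | Path | io.TextIOBase) -> list[SurgeryLog]:
    """Read a step-log CSV into one :class:`SurgeryLog` per surgery id.

    Rows are validated; the first malformed row raises :class:`SteplogError`
    naming the offending line (header is line 1).
    """
    df = pd.read_csv(source, dtype={"surgery_id": str, "category": str, "module": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SteplogError(f"step-log file lacks columns: {missing}")
    logs: dict[str, SurgeryLog] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            record = StepRecord(
                module=row.module, start_s=float(row.start_s), end_s=float(row.end_s)
            )
            category = SurgeryCategory.coerce(row.category)
        except (ValueError, SteplogError) as exc:
            raise SteplogError(f"line {i}: {exc}") from None
        log = logs.get(row.surgery_id)
        if log is None:
            logs[row.surgery_id] = log = SurgeryLog(row.surgery_id, category, [])
        elif log.category is not category:
            raise SteplogError(
                f"line {i}: surgery {row.surgery_id} changes category "
                f"{log.category.value} -> {category.value}"
            )
        log.steps.append(record)
    out = list(logs.values())
    for log in out:
        log.steps.sort(key=lambda r: (r.start_s, r.end_s, r.module))
    return out


def write_steplogs(cohort: Iterable[SurgeryLog], destination: str | Path | io.TextIOBase) -> None:
    """Write a cohort as the step-log CSV (times at one decimal).

    ``read_steplogs(write_steplogs(c)) == c`` for cohorts whose times are
    representable at one decimal.
    """
    rows = [
        {
            "surgery_id": log.surgery_id,
            "category": log.category.value,
            "module": rec.module,
            "start_s": f"{rec.start_s:.1f}",
            "end_s": f"{rec.end_s:.1f}",
        }
        for log in cohort
        for rec in log.steps
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(destination, index=False)


# ---------------------------------------------------------------------------
# verification

@dataclass
class VerificationReport:
    """Conformance of one log against the registration rules and a graph."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def _overlap(a: StepRecord, b: StepRecord) -> float:
    return min(a.end_s, b.end_s) - max(a.start_s, b.start_s)


def verify_log(log: SurgeryLog, graph: ProcessGraph) -> VerificationReport:
    """Check a log against a workflow graph; reports, never raises.

    Flags (a) modules that are not graph nodes, (b) overlaps outside the
    allowed parallel pairs, and (c) violations of the graph's mandatory
    precedence chains (compared on first occurrences, when both modules are
    present).
    """
    report = VerificationReport()
    known = graph_module_set(graph) | {IDLE}
    for rec in log.steps:
        if rec.module not in known:
            report.violations.append(f"module {rec.module} not in {graph.category.value} graph")
    steps = log.steps
    for i, a in enumerate(steps):
        for b in steps[i + 1:]:
            if b.start_s >= a.end_s:
                break
            if _overlap(a, b) > 0 and frozenset({a.module, b.module}) not in ALLOWED_PARALLEL:
                report.violations.append(
                    f"disallowed overlap: {a.module} [{a.start_s}, {a.end_s}] with "
                    f"{b.module} [{b.start_s}, {b.end_s}]"
                )
    first: dict[str, float] = {}
    for rec in steps:
        first.setdefault(rec.module, rec.start_s)
    for before, after in graph.precedence:
        if before in first and after in first and first[after] < first[before]:
            report.violations.append(
                f"precedence violation: first {after} at {first[after]} precedes "
                f"first {before} at {first[before]}"
            )
    return report


# ---------------------------------------------------------------------------
# normalization

def collapse_repeats(log: SurgeryLog) -> SurgeryLog:
    """Merge maximal runs of consecutive same-module records.

    Successive actions in the same module count as a single occurrence; the
    merged record spans the first start to the last end, so no module's total
    footprint changes.  Non-adjacent repeats remain distinct occurrences.
    Idempotent.
    """
    merged: list[StepRecord] = []
    for rec in log.steps:
        if merged and merged[-1].module == rec.module:
            merged[-1] = replace(merged[-1], end_s=max(merged[-1].end_s, rec.end_s))
        else:
            merged.append(rec)
    return SurgeryLog(log.surgery_id, log.category, merged)


def attribute_parallel_time(log: SurgeryLog) -> dict[str, list[float]]:
    """Per-module per-occurrence attributed durations.

    Imaging keeps its full duration.  Planning time overlapped by imaging is
    attributed to imaging: each P06M01 duration is reduced by its overlap
    with P05M02 records ("planning duration without imaging").  Parallel
    region marking keeps its full duration ("considered for both").  All
    occurrences stay counted, including planning occurrences reduced to zero.
    """
    imaging = [r for r in log.steps if r.module == "P05M02"]
    out: dict[str, list[float]] = {}
    for rec in log.steps:
        duration = rec.duration_s
        if rec.module == "P06M01" and imaging:
            duration -= sum(max(0.0, _overlap(rec, im)) for im in imaging)
            duration = max(0.0, duration)
        out.setdefault(rec.module, []).append(duration)
    return out
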
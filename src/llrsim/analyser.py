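"""Cohort statistics: module durations/occurrences, phase breakdown, paths.

This is the data-analysis stage of the toolchain: given a verified cohort of
step logs of one surgery category it computes

* per-module duration and occurrence summaries (the published summary-table
  layout): duration mean/SD pooled over per-occurrence attributed durations
  in surgeries where the module occurred at least once, and occurrence
  mean/SD over *all* surgeries (zeros included, so an occurrence mean may be
  below 1);
* the probability of each module occurring once or more in a surgery;
* per-phase durations normalized to the procedure duration (the fat/adhesion
  dissection module P08aM01 is excluded by default because its duration is
  dominated by patient factors; idle and intra-operative complications are
  not surgical phases and are excluded by default);
* empirical module-to-module transition counts and the most probable path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .process_model import IDLE, ProcessGraph, SurgeryCategory, module_phase
from .steplog import SurgeryLog, attribute_parallel_time, collapse_repeats

__all__ = [
    "ModuleStatsTable",
    "PhaseBreakdown",
    "module_stats",
    "occurrence_probabilities",
    "phase_breakdown",
    "average_phase_durations",
    "resection_share_of_treatment",
    "transition_frequencies",
    "most_probable_path",
]

_STAT_COLUMNS = ["duration_mean_s", "duration_sd_s", "occ_mean", "occ_sd", "n_present"]


@dataclass
class ModuleStatsTable:
    """Per-module duration/occurrence summary for one surgery category.

    ``table`` is indexed by module code with columns ``duration_mean_s``,
    ``duration_sd_s`` (NaN when undefined, i.e. the module never occurred or
    occurred once), ``occ_mean``, ``occ_sd`` and ``n_present``.  Idle is a
    per-surgery total, kept separate from the module rows.
    """

    category: SurgeryCategory
    table: pd.DataFrame
    idle_mean_s: float
    idle_sd_s: float
    n_surgeries: int | None = None

    @classmethod
    def from_dict(
        cls,
        category: SurgeryCategory | str,
        modules: Mapping[str, tuple[float, float, float, float]],
        *,
        idle_mean_s: float = 0.0,
        idle_sd_s: float = 0.0,
    ) -> "ModuleStatsTable":
        """Build a table from ``{module: (dur_mean, dur_sd, occ_mean, occ_sd)}``."""
        table = pd.DataFrame.from_dict(
            {m: list(v) + [math.nan] for m, v in modules.items()},
            orient="index",
            columns=_STAT_COLUMNS,
        )
        return cls(SurgeryCategory.coerce(category), table, idle_mean_s, idle_sd_s)

    @property
    def modules(self) -> list[str]:
        return list(self.table.index)

    def row(self, module: str) -> pd.Series:
        return self.table.loc[module]

    def duration_defined(self, module: str) -> bool:
        return bool(np.isfinite(self.table.loc[module, "duration_mean_s"]))

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "module"
        out.to_csv(path, float_format="%.6g")


def _prepare(cohort: Sequence[SurgeryLog]) -> tuple[SurgeryCategory, list[dict[str, list[float]]]]:
    if not cohort:
        raise ValueError("empty cohort")
    categories = {log.category for log in cohort}
    if len(categories) != 1:
        raise ValueError(f"mixed categories in cohort: {sorted(c.value for c in categories)}")
    attributed = [attribute_parallel_time(collapse_repeats(log)) for log in cohort]
    return categories.pop(), attributed


def module_stats(cohort: Sequence[SurgeryLog]) -> ModuleStatsTable:
    """Summarize a one-category cohort the way the study tabulates it.

    Logs are collapsed (consecutive same-module records merge into one
    occurrence) and parallel imaging/planning time attributed before
    counting.  Sample SDs use ddof=1.
    """
    category, attributed = _prepare(cohort)
    n = len(attributed)
    modules = sorted({m for per_surgery in attributed for m in per_surgery if m != IDLE})
    rows = {}
    for module in modules:
        counts = np.array([len(per.get(module, ())) for per in attributed], float)
        durations = [d for per in attributed for d in per.get(module, ())]
        n_present = int(np.count_nonzero(counts))
        rows[module] = {
            "duration_mean_s": float(np.mean(durations)) if durations else math.nan,
            "duration_sd_s": float(np.std(durations, ddof=1)) if len(durations) > 1 else math.nan,
            "occ_mean": float(counts.mean()),
            "occ_sd": float(counts.std(ddof=1)) if n > 1 else 0.0,
            "n_present": n_present,
        }
    idle_totals = np.array([sum(per.get(IDLE, ())) for per in attributed], float)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=_STAT_COLUMNS)
    return ModuleStatsTable(
        category=category,
        table=table,
        idle_mean_s=float(idle_totals.mean()),
        idle_sd_s=float(idle_totals.std(ddof=1)) if n > 1 else 0.0,
        n_surgeries=n,
    )


def occurrence_probabilities(cohort: Sequence[SurgeryLog]) -> dict[str, float]:
    """Fraction of surgeries in which each module occurs once or more."""
    _, attributed = _prepare(cohort)
    n = len(attributed)
    modules = sorted({m for per in attributed for m in per if m != IDLE})
    return {
        m: sum(1 for per in attributed if per.get(m)) / n
        for m in modules
    }


# ---------------------------------------------------------------------------
# phase breakdown

@dataclass
class PhaseBreakdown:
    """Per-phase duration sums and normalized fractions for one category.

    A phase duration is the sum of its modules' mean durations (one mean
    occurrence of each module); fractions are normalized to the sum over
    included phases and add to 1.
    """

    category: SurgeryCategory
    phase_durations_s: dict[str, float]
    fractions: dict[str, float]
    excluded_modules: tuple[str, ...]


def phase_breakdown(
    stats: ModuleStatsTable,
    *,
    exclude_modules: Iterable[str] = ("P08aM01",),
    include_idle: bool = False,
    include_p11: bool = False,
) -> PhaseBreakdown:
    """Phase durations normalized to the procedure duration.

    By default the fat/adhesion dissection module is excluded and idle and
    the complications phase (P11) are not counted as surgical phases; both
    choices are flags.
    """
    excluded = set(exclude_modules)
    durations: dict[str, float] = {}
    for module in stats.modules:
        if module in excluded:
            continue
        phase = module_phase(module)
        if phase == "11" and not include_p11:
            continue
        mean = stats.table.loc[module, "duration_mean_s"]
        if not np.isfinite(mean):
            continue
        durations[phase] = durations.get(phase, 0.0) + float(mean)
    if include_idle:
        durations[IDLE] = durations.get(IDLE, 0.0) + stats.idle_mean_s
    total = sum(durations.values())
    fractions = {p: d / total for p, d in durations.items()} if total > 0 else {}
    return PhaseBreakdown(
        category=stats.category,
        phase_durations_s=durations,
        fractions=fractions,
        excluded_modules=tuple(sorted(excluded)),
    )


def average_phase_durations(breakdowns: Sequence[PhaseBreakdown]) -> dict[str, float]:
    """Unweighted cross-category mean of per-phase durations (seconds)."""
    phases = sorted({p for b in breakdowns for p in b.phase_durations_s})
    return {
        p: float(np.mean([b.phase_durations_s.get(p, 0.0) for b in breakdowns]))
        for p in phases
    }


def resection_share_of_treatment(stats: ModuleStatsTable) -> float:
    """Fraction of the treatment-phase duration allocated to resection."""
    marking = float(stats.table.loc["P10M01", "duration_mean_s"])
    resection = float(stats.table.loc["P10M02", "duration_mean_s"])
    return resection / (marking + resection)


# ---------------------------------------------------------------------------
# sequences

def _collapsed_sequences(cohort: Sequence[SurgeryLog]) -> list[list[str]]:
    seqs = []
    for log in cohort:
        seq = [r.module for r in collapse_repeats(log).steps if r.module != IDLE]
        seqs.append(seq)
    return seqs


def transition_frequencies(cohort: Sequence[SurgeryLog]) -> pd.DataFrame:
    """Counts of ordered adjacent module pairs in collapsed logs.

    Idle records are dropped first (idle is not a surgical step).  Row sums
    equal (steps - 1) summed over surgeries.
    """
    if not cohort:
        raise ValueError("empty cohort")
    seqs = _collapsed_sequences(cohort)
    modules = sorted({m for s in seqs for m in s})
    counts = pd.DataFrame(0, index=modules, columns=modules, dtype=int)
    for seq in seqs:
        for a, b in zip(seq, seq[1:]):
            counts.loc[a, b] += 1
    return counts


def most_probable_path(cohort: Sequence[SurgeryLog], graph: ProcessGraph) -> list[str]:
    """Greedy highest-frequency path through the empirical transitions.

    Starting from the most frequent first module, at each step the most
    frequent remaining transition out of the current module is taken and
    consumed; ties break by module-code order.  Consuming transitions bounds
    the path and lets frequent loops (e.g. resection and duct division)
    appear as often as the cohort supports.
    """
    if not cohort:
        raise ValueError("empty cohort")
    seqs = [s for s in _collapsed_sequences(cohort) if s]
    if not seqs:
        return []
    first_counts: dict[str, int] = {}
    for s in seqs:
        first_counts[s[0]] = first_counts.get(s[0], 0) + 1
    current = min(first_counts, key=lambda m: (-first_counts[m], m))
    remaining: dict[tuple[str, str], int] = {}
    for s in seqs:
        for pair in zip(s, s[1:]):
            remaining[pair] = remaining.get(pair, 0) + 1
    path = [current]
    while True:
        options = [(b, c) for (a, b), c in remaining.items() if a == current and c > 0]
        if not options:
            break
        nxt = min(options, key=lambda bc: (-bc[1], bc[0]))[0]
        remaining[(current, nxt)] -= 1
        path.append(nxt)
        current = nxt
    return path
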
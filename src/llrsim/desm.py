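"""Discrete-event simulation of whole parenchyma-sparing resections.

Each simulated run draws, for every timed module of a category's workflow,
an occurrence count and per-occurrence durations, sums them, and adds two
fixed per-surgery contributions (mean idle time and mean intra-operative
leakage clean-up, neither of which the modelled technology affects).  Two
duration families are supported:

``gaussian``
    a Gaussian fitted to the published mean/SD, truncated at zero (the
    negative tail is ignored, giving a skewed non-symmetrical distribution
    with no point mass at zero);
``uniform``
    uniform between per-module bounds — the observed min/max when raw logs
    are available, otherwise moment-matched bounds
    ``[max(0, mu - sqrt(3) sigma), mu + sqrt(3) sigma]``.

Occurrence counts are the rounded value of a Gaussian fitted to the
published occurrence mean/SD, with negative draws clipped to zero.  Zero
counts are therefore possible even for modules present in every recorded
surgery — that is precisely why the run-level exclusion criteria exist: a
run is excluded when fewer than 3 trocars are placed or when its total
resection time falls below half the minimum resection time observed on
video for that category.  Question (decision) nodes take zero time; repeat
loops ("divide yet another duct?") have count-dependent outcome
probabilities given by the survival function of the occurrence-count
distribution.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .analyser import ModuleStatsTable
from .process_model import IDLE, ProcessGraph, SurgeryCategory
from .reference import min_resection_s

__all__ = [
    "ModelError",
    "ModuleDuration",
    "DurationModel",
    "ModuleOccurrence",
    "OccurrenceModel",
    "ExclusionRule",
    "SimRun",
    "BatchResult",
    "fit_models",
    "sample_duration",
    "sample_occurrences",
    "dynamic_repeat_probability",
    "simulate_run",
    "run_batch",
    "check_convergence",
    "truncated_normal_mean",
]

#: Modules folded into the fixed per-surgery additions rather than sampled.
FIXED_ADDITION_MODULES = frozenset({"P11M02", IDLE})

_SQRT3 = math.sqrt(3.0)


class ModelError(ValueError):
    """A statistics table cannot support the requested model."""


# ---------------------------------------------------------------------------
# duration model

@dataclass(frozen=True)
class ModuleDuration:
    """Per-module duration distribution.

    ``fixed_s`` (set by a technology scenario) replaces sampling entirely;
    ``extra_s`` is added on top of every sampled occurrence (the alternative
    "add" imaging policy).
    """

    mode: str  # "gaussian_trunc" | "uniform"
    mu_s: float = 0.0
    sigma_s: float = 0.0
    lo_s: float = 0.0
    hi_s: float = 0.0
    fixed_s: float | None = None
    extra_s: float = 0.0

    def scaled(self, factor: float) -> "ModuleDuration":
        return replace(
            self,
            mu_s=self.mu_s * factor,
            sigma_s=self.sigma_s * factor,
            lo_s=self.lo_s * factor,
            hi_s=self.hi_s * factor,
        )


@dataclass
class DurationModel:
    """Duration distributions for all sampled modules of one category."""

    category: SurgeryCategory
    mode: str  # "gaussian" | "uniform"
    modules: dict[str, ModuleDuration]
    idle_s: float = 0.0
    leakage_s: float = 0.0


# ---------------------------------------------------------------------------
# occurrence model

@dataclass(frozen=True)
class ModuleOccurrence:
    """Occurrence-count distribution: round(max(0, N(occ_mean, occ_sd)))."""

    occ_mean: float
    occ_sd: float
    presence: float = 1.0

    def pmf(self, k: int) -> float:
        if self.presence == 0.0:
            return 1.0 if k == 0 else 0.0
        if self.occ_sd == 0.0:
            return 1.0 if k == _round_half_away(max(0.0, self.occ_mean)) else 0.0
        z_hi = (k + 0.5 - self.occ_mean) / self.occ_sd
        if k == 0:
            return float(sps.norm.cdf(z_hi))
        z_lo = (k - 0.5 - self.occ_mean) / self.occ_sd
        return float(sps.norm.cdf(z_hi) - sps.norm.cdf(z_lo))

    def survival(self, n: int) -> float:
        """P(count > n); non-increasing in n, 0 beyond the support."""
        if self.presence == 0.0:
            return 0.0
        if self.occ_sd == 0.0:
            return 1.0 if _round_half_away(max(0.0, self.occ_mean)) > n else 0.0
        return float(sps.norm.sf((n + 0.5 - self.occ_mean) / self.occ_sd))


@dataclass
class OccurrenceModel:
    """Occurrence-count distributions for all sampled modules."""

    category: SurgeryCategory
    modules: dict[str, ModuleOccurrence]


def _round_half_away(x):
    """Round half away from zero (platform-independent for .5 ties)."""
    return np.floor(np.asarray(x, float) + 0.5)


# ---------------------------------------------------------------------------
# fitting

def fit_models(
    stats: ModuleStatsTable,
    mode: str = "gaussian",
    *,
    graph: ProcessGraph | None = None,
    observed_minmax: Mapping[str, tuple[float, float]] | None = None,
    leakage_policy: str = "per_surgery",
) -> tuple[DurationModel, OccurrenceModel]:
    """Fit the simulation distributions to a module statistics table.

    ``leakage_policy`` chooses the fixed leakage clean-up addition: the mean
    per-surgery burden ``duration_mean x occ_mean`` (default) or a single
    mean occurrence (``"per_occurrence"``).
    """
    if mode not in ("gaussian", "uniform"):
        raise ModelError(f"unknown duration mode {mode!r}")
    if leakage_policy not in ("per_surgery", "per_occurrence"):
        raise ModelError(f"unknown leakage policy {leakage_policy!r}")
    durations: dict[str, ModuleDuration] = {}
    occurrences: dict[str, ModuleOccurrence] = {}
    for module in stats.modules:
        if module in FIXED_ADDITION_MODULES:
            continue
        row = stats.row(module)
        occ_mean, occ_sd = float(row["occ_mean"]), float(row["occ_sd"])
        if graph is not None:
            try:
                presence = graph.occurrence_probability(module)
            except KeyError:
                presence = 1.0 if occ_mean > 0 else 0.0
        else:
            presence = 1.0 if occ_mean > 0 else 0.0
        mu, sigma = float(row["duration_mean_s"]), float(row["duration_sd_s"])
        if not np.isfinite(mu):
            if occ_mean > 0:
                raise ModelError(
                    f"{module}: occurs (mean {occ_mean}) but has undefined duration statistics"
                )
            mu, sigma = 0.0, 0.0
        if mode == "gaussian":
            durations[module] = ModuleDuration("gaussian_trunc", mu_s=mu, sigma_s=sigma)
        else:
            if observed_minmax and module in observed_minmax:
                lo, hi = observed_minmax[module]
            else:
                lo, hi = max(0.0, mu - _SQRT3 * sigma), mu + _SQRT3 * sigma
            durations[module] = ModuleDuration("uniform", mu_s=mu, sigma_s=sigma, lo_s=lo, hi_s=hi)
        occurrences[module] = ModuleOccurrence(occ_mean, occ_sd, presence)
    leak = stats.row("P11M02") if "P11M02" in stats.modules else None
    if leak is not None:
        leakage_s = float(leak["duration_mean_s"])
        if leakage_policy == "per_surgery":
            leakage_s *= float(leak["occ_mean"])
    else:
        leakage_s = 0.0
    dmodel = DurationModel(
        category=stats.category,
        mode=mode,
        modules=durations,
        idle_s=stats.idle_mean_s,
        leakage_s=leakage_s,
    )
    return dmodel, OccurrenceModel(category=stats.category, modules=occurrences)


# ---------------------------------------------------------------------------
# sampling primitives

def truncated_normal_mean(mu: float, sigma: float) -> float:
    """Closed-form mean of N(mu, sigma) truncated at zero:
    ``mu + sigma * phi(mu/sigma) / Phi(mu/sigma)``."""
    if sigma == 0.0:
        return max(0.0, mu)
    z = mu / sigma
    return mu + sigma * sps.norm.pdf(z) / sps.norm.cdf(z)


def _draw_durations(spec: ModuleDuration, size: int, rng: np.random.Generator) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    if spec.fixed_s is not None:
        return np.full(size, float(spec.fixed_s))
    if spec.mode == "gaussian_trunc":
        if spec.sigma_s == 0.0:
            out = np.full(size, max(0.0, spec.mu_s))
        else:
            a = -spec.mu_s / spec.sigma_s
            out = sps.truncnorm.rvs(
                a, np.inf, loc=spec.mu_s, scale=spec.sigma_s, size=size, random_state=rng
            )
    elif spec.mode == "uniform":
        if spec.hi_s == spec.lo_s:
            out = np.full(size, float(spec.lo_s))
        else:
            out = rng.uniform(spec.lo_s, spec.hi_s, size)
    else:
        raise ModelError(f"unknown duration mode {spec.mode!r}")
    if spec.extra_s:
        out = out + spec.extra_s
    return out


def sample_duration(model: DurationModel, module: str, rng: np.random.Generator) -> float:
    """One per-occurrence duration draw (seconds, always >= 0)."""
    return float(_draw_durations(model.modules[module], 1, rng)[0])


def _draw_counts(spec: ModuleOccurrence, size: int, rng: np.random.Generator) -> np.ndarray:
    if spec.presence == 0.0:
        return np.zeros(size, dtype=np.int64)
    if spec.occ_sd == 0.0:
        x = np.full(size, float(spec.occ_mean))
    else:
        x = rng.normal(spec.occ_mean, spec.occ_sd, size)
    return _round_half_away(np.maximum(x, 0.0)).astype(np.int64)


def sample_occurrences(model: OccurrenceModel, module: str, rng: np.random.Generator) -> int:
    """One occurrence-count draw (non-negative integer)."""
    return int(_draw_counts(model.modules[module], 1, rng)[0])


def dynamic_repeat_probability(model: OccurrenceModel, module: str, n: int) -> float:
    """Probability of repeating a loop module after n executions.

    Evaluated as the survival function P(count > n) of the module's
    occurrence-count distribution: strictly non-increasing in n and zero
    beyond the distribution's support, so the chance of e.g. dividing yet
    another supply duct decays as more ducts have been divided.
    """
    if n < 0:
        raise ValueError("counter must be >= 0")
    return model.modules[module].survival(n)


# ---------------------------------------------------------------------------
# runs and batches

@dataclass(frozen=True)
class ExclusionRule:
    """Post-hoc filters on simulated runs (boundary-inclusive thresholds)."""

    min_trocars: int = 3
    min_resection_total_s: float = 0.0

    @classmethod
    def for_category(cls, category: SurgeryCategory | str) -> "ExclusionRule":
        """Printed thresholds: >= 3 trocars; resection total at least half
        the category's minimum observed resection time."""
        return cls(min_trocars=3,
                   min_resection_total_s=min_resection_s(category) / 2.0)


@dataclass
class SimRun:
    """One simulated procedure."""

    category: SurgeryCategory
    scenario_id: int
    counts: dict[str, int]
    durations_s: dict[str, float]
    idle_s: float
    leakage_s: float
    total_s: float
    excluded: bool
    reason: str | None


@dataclass
class BatchResult:
    """Totals and exclusion flags of a batch; summaries over included runs."""

    category: SurgeryCategory
    scenario_id: int
    mode: str
    totals_s: np.ndarray
    excluded: np.ndarray
    reasons: np.ndarray
    counts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    module_totals_s: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.totals_s.size)

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    @property
    def excluded_fraction(self) -> float:
        return self.n_excluded / self.n

    @property
    def included_totals_s(self) -> np.ndarray:
        return self.totals_s[~self.excluded]

    @property
    def mean_s(self) -> float:
        return float(self.included_totals_s.mean())

    @property
    def sd_s(self) -> float:
        return float(self.included_totals_s.std(ddof=1))

    def peak_s(self) -> float:
        from .scenarios import distribution_peak  # local to avoid a cycle
        return distribution_peak(self.included_totals_s)

    def runs(self) -> Iterable[SimRun]:
        modules = sorted(self.counts)
        for i in range(self.n):
            yield SimRun(
                category=self.category,
                scenario_id=self.scenario_id,
                counts={m: int(self.counts[m][i]) for m in modules},
                durations_s={m: float(self.module_totals_s[m][i]) for m in modules},
                idle_s=float(self.totals_s[i]) - float(
                    sum(self.module_totals_s[m][i] for m in modules)
                ),
                leakage_s=math.nan,  # folded with idle in the reconstruction
                total_s=float(self.totals_s[i]),
                excluded=bool(self.excluded[i]),
                reason=self.reasons[i] if self.excluded[i] else None,
            )

    def summary(self) -> dict:
        return {
            "category": self.category.value,
            "scenario": self.scenario_id,
            "mode": self.mode,
            "n": self.n,
            "n_excluded": self.n_excluded,
            "mean_s": round(self.mean_s, 3),
            "sd_s": round(self.sd_s, 3),
            "peak_s": round(self.peak_s(), 1),
        }


def _sample_batch(
    dmodel: DurationModel,
    omodel: OccurrenceModel,
    exclusion: ExclusionRule,
    n: int,
    rng: np.random.Generator,
    scenario_id: int,
) -> BatchResult:
    totals = np.full(n, dmodel.idle_s + dmodel.leakage_s)
    counts: dict[str, np.ndarray] = {}
    module_totals: dict[str, np.ndarray] = {}
    for module in sorted(omodel.modules):  # fixed order => reproducible streams
        occ = _draw_counts(omodel.modules[module], n, rng)
        spec = dmodel.modules[module]
        total_draws = int(occ.sum())
        draws = _draw_durations(spec, total_draws, rng)
        seg = np.repeat(np.arange(n), occ)
        tot = np.bincount(seg, weights=draws, minlength=n)
        counts[module] = occ
        module_totals[module] = tot
        totals += tot
    trocars = counts.get("P07M01", np.zeros(n, dtype=np.int64))
    resection = module_totals.get("P10M02", np.zeros(n))
    few_trocars = trocars < exclusion.min_trocars
    short_resection = resection < exclusion.min_resection_total_s
    excluded = few_trocars | short_resection
    reasons = np.where(few_trocars, "min_trocars",
                       np.where(short_resection, "min_resection", ""))
    return BatchResult(
        category=dmodel.category,
        scenario_id=scenario_id,
        mode=dmodel.mode,
        totals_s=totals,
        excluded=excluded,
        reasons=reasons,
        counts=counts,
        module_totals_s=module_totals,
    )


def simulate_run(
    graph: ProcessGraph,
    duration_model: DurationModel,
    occurrence_model: OccurrenceModel,
    scenario_id: int,
    exclusion: ExclusionRule,
    rng: np.random.Generator,
) -> SimRun:
    """Sample one procedure (scenario already applied to the models).

    Module order on the workflow graph does not change the total: the run
    total is the sum over modules of their sampled per-occurrence durations
    plus the fixed idle and leakage means.  Question nodes take zero time.
    """
    unknown = set(occurrence_model.modules) - {e.module for e in graph.entries}
    if unknown:
        raise ModelError(f"occurrence model has modules absent from graph: {sorted(unknown)}")
    batch = _sample_batch(duration_model, occurrence_model, exclusion, 1, rng, scenario_id)
    return next(iter(batch.runs()))


def run_batch(
    n_runs: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    duration_model: DurationModel,
    occurrence_model: OccurrenceModel,
    exclusion: ExclusionRule,
    scenario_id: int = 1,
) -> BatchResult:
    """Simulate ``n_runs`` independent procedures from a seeded stream."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _sample_batch(duration_model, occurrence_model, exclusion, n_runs, rng, scenario_id)


# ---------------------------------------------------------------------------
# convergence

@dataclass(frozen=True)
class ConvergenceReport:
    mean_diff_pct: float
    sd_diff_pct: float
    threshold_pct: float

    @property
    def passed(self) -> bool:
        return (self.mean_diff_pct < self.threshold_pct
                and self.sd_diff_pct < self.threshold_pct)


def check_convergence(
    batch1: BatchResult, batch2: BatchResult, threshold_pct: float = 0.5
) -> ConvergenceReport:
    """Relative mean/SD differences (%) between two batches of one design."""
    mean_diff = abs(batch1.mean_s - batch2.mean_s) / batch1.mean_s * 100.0
    sd_diff = abs(batch1.sd_s - batch2.sd_s) / batch1.sd_s * 100.0
    return ConvergenceReport(mean_diff, sd_diff, threshold_pct)
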
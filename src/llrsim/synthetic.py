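"""Synthetic cohorts of surgical step logs.

Generates cohorts whose *observed* statistics match the published summary:
each module is present with its workflow occurrence probability; present
modules get a rounded, minimum-1 Gaussian occurrence count; per-occurrence
durations are zero-truncated Gaussians.  Because truncation and rounding
shift raw Gaussian moments, the generator numerically inverts both
expectations (duration: the zero-truncated-normal mean; count: the exact
expectation of ``round(max(N, 1))``) so that the cohort statistics computed
by :func:`llrsim.analyser.module_stats` converge to the published means as
the cohort grows.

Occurrences are laid out along the category workflow: trocars and
insufflation first, pre-resection dissection/mobilization (for the
gallbladder category the mandatory mobilize-isolate-occlude-divide chain),
marking, resection with the mid-resection duct-division loop interleaved
(segments 5 & 6), then the wrap-up free-order group in a shuffled
round-robin order.  Imaging, planning and intra-operative leakage clean-up
can happen anytime; their occurrences are preferentially placed where two
records of the same module would otherwise touch (consecutive same-module
records would be collapsed into a single occurrence by the registration
rules), with thin idle slices as a fallback, and the remaining idle budget
is emitted as one idle record.  All generated logs verify cleanly against
their category graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

from .process_model import IDLE, ProcessGraph, SurgeryCategory, build_category_graph
from .reference import reference_stats
from .steplog import ZERO_DURATION_OK, StepRecord, SurgeryLog

__all__ = ["ModuleGenParams", "GeneratorParams", "default_params", "generate_cohort"]

_SEPARATOR_MODULES = ("P06M01", "P05M02", "P11M02")  # insertable-anytime pool
_MIN_DURATION_S = 0.1  # serialization grain; also floors non-planning records


@dataclass(frozen=True)
class ModuleGenParams:
    """Target observed statistics for one module."""

    duration_mean_s: float
    duration_sd_s: float
    occ_mean: float
    occ_sd: float
    presence: float


@dataclass
class GeneratorParams:
    """Cohort generator configuration; defaults equal the published tables."""

    category: SurgeryCategory
    modules: dict[str, ModuleGenParams]
    idle_mean_s: float
    idle_sd_s: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.category = SurgeryCategory.coerce(self.category)
        for module, p in self.modules.items():
            if p.duration_mean_s < 0 or p.duration_sd_s < 0 or p.occ_mean < 0 or p.occ_sd < 0:
                raise ValueError(f"{module}: negative mean/SD")
            if not 0.0 <= p.presence <= 1.0:
                raise ValueError(f"{module}: presence {p.presence} outside [0, 1]")


def default_params(category: SurgeryCategory | str) -> GeneratorParams:
    """The published per-category parameter set (durations, occurrences,
    occurrence probabilities, idle)."""
    category = SurgeryCategory.coerce(category)
    stats = reference_stats(category)
    graph = build_category_graph(category)
    modules: dict[str, ModuleGenParams] = {}
    for module in stats.modules:
        row = stats.row(module)
        try:
            presence = graph.occurrence_probability(module)
        except KeyError:
            presence = 1.0 if row["occ_mean"] > 0 else 0.0
        if row["occ_mean"] == 0.0:
            presence = 0.0
        modules[module] = ModuleGenParams(
            duration_mean_s=float(row["duration_mean_s"]),
            duration_sd_s=float(row["duration_sd_s"]),
            occ_mean=float(row["occ_mean"]),
            occ_sd=float(row["occ_sd"]),
            presence=presence,
        )
    return GeneratorParams(
        category=category,
        modules=modules,
        idle_mean_s=stats.idle_mean_s,
        idle_sd_s=stats.idle_sd_s,
    )


# ---------------------------------------------------------------------------
# calibration: invert truncation/rounding biases

def _calibrated_duration_mu(mean: float, sd: float) -> float:
    """mu such that the zero-truncated N(mu, sd) has the target mean."""
    if sd == 0.0 or mean <= 0.0:
        return mean

    def excess(m: float) -> float:
        return m + sd * sps.norm.pdf(m / sd) / sps.norm.cdf(m / sd) - mean

    lo = mean - sd
    while excess(lo) > 0:
        lo -= 4.0 * sd
    return float(brentq(excess, lo, mean))


def _expected_min1_count(mu: float, sd: float) -> float:
    """E[round(max(N(mu, sd), 1))] with round-half-away, computed exactly:
    1 + sum_{k>=2} P(N >= k - 1/2)."""
    k_max = int(math.ceil(mu + 12.0 * sd)) + 2
    ks = np.arange(2, max(3, k_max))
    return 1.0 + float(sps.norm.sf((ks - 0.5 - mu) / sd).sum())


def _calibrated_count_mu(target: float, sd: float) -> float | None:
    """mu such that E[round(max(N(mu, sd), 1))] equals the target conditional
    count; None means the count degenerates to always-1."""
    if sd == 0.0:
        return max(target, 1.0)
    if target <= 1.0 + 1e-9:
        return None

    def excess(m: float) -> float:
        return _expected_min1_count(m, sd) - target

    lo = -10.0 * sd - 5.0
    hi = target + 1.0
    while excess(hi) < 0:
        hi += 2.0 * sd + 1.0
    return float(brentq(excess, lo, hi))


# ---------------------------------------------------------------------------
# sequence layout

def _round_robin(groups: Sequence[tuple[str, int]]) -> list[str]:
    """Cycle through modules in the given order until counts are spent; the
    first occurrences keep the given order (mandatory chains)."""
    remaining = [[m, c] for m, c in groups if c > 0]
    out: list[str] = []
    while remaining:
        for item in list(remaining):
            item[1] -= 1
            out.append(item[0])
        remaining = [it for it in remaining if it[1] > 0]
    return out


def _base_sequence(
    category: SurgeryCategory, counts: dict[str, int], rng: np.random.Generator
) -> list[str]:
    seq: list[str] = []
    # operative field access: first trocar, insufflation, remaining trocars
    trocars = counts.get("P07M01", 0)
    if trocars:
        seq.append("P07M01")
    seq += ["P07M02"] * counts.get("P07M02", 0)
    seq += ["P07M01"] * max(0, trocars - 1)
    # pre-resection destructive isolation
    seq += ["P08aM01"] * counts.get("P08aM01", 0)
    if category is SurgeryCategory.S5GB:
        seq += _round_robin([
            ("P08aM02", counts.get("P08aM02", 0)),
            ("P08aM03", counts.get("P08aM03", 0)),
            ("P08aM05", counts.get("P08aM05", 0)),
            ("P08aM06", counts.get("P08aM06", 0)),
        ])
    else:
        seq += ["P08aM02"] * counts.get("P08aM02", 0)
    # treatment, with the mid-resection duct-division loop for segments 5&6
    seq += ["P10M01"] * counts.get("P10M01", 0)
    resections = counts.get("P10M02", 0)
    duct_tokens: list[str] = []
    if category is SurgeryCategory.S56:
        duct_tokens = _round_robin([
            ("P08aM03", counts.get("P08aM03", 0)),
            ("P08aM05", counts.get("P08aM05", 0)),
            ("P08aM06", counts.get("P08aM06", 0)),
        ])
    if duct_tokens and resections > 1:
        chunks = [list(c) for c in np.array_split(duct_tokens, resections - 1)]
        for i in range(resections):
            seq.append("P10M02")
            if i < resections - 1:
                seq += chunks[i]
    else:
        seq += ["P10M02"] * resections
        seq += duct_tokens
    # wrap-up free-order group: shuffled round-robin
    wrap = [(m, counts.get(m, 0))
            for m in ("P13M02", "P13M03", "P13M04", "P13M05", "P13M06", "P13M07")]
    wrap = [(m, c) for m, c in wrap if c > 0]
    order = rng.permutation(len(wrap))
    seq += _round_robin([wrap[i] for i in order])
    return seq


def _place_floaters(
    seq: list[str], counts: dict[str, int], rng: np.random.Generator
) -> tuple[list[str], int]:
    """Insert anytime-modules, breaking same-module adjacencies first.

    Returns the final token list (with ``IDLE`` slices where no separator
    was available) and the number of idle slices used.
    """
    pool: list[str] = []
    for m in _SEPARATOR_MODULES:
        pool += [m] * counts.get(m, 0)
    rng.shuffle(pool)
    out: list[str] = []
    idle_slices = 0
    for token in seq:
        if out and out[-1] == token:
            if pool:
                out.append(pool.pop())
            else:
                out.append(IDLE)
                idle_slices += 1
        out.append(token)
    # remaining floaters go to random gaps that do not create new adjacencies
    for token in pool:
        gaps = [i for i in range(len(out) + 1)
                if (i == 0 or out[i - 1] != token) and (i == len(out) or out[i] != token)]
        out.insert(int(rng.choice(gaps)), token)
    return out, idle_slices


# ---------------------------------------------------------------------------
# generation

class _ModuleSampler:
    """Per-module calibrated samplers for one parameter set."""

    def __init__(self, params: GeneratorParams):
        self.params = params
        self.duration_mu = {
            m: _calibrated_duration_mu(p.duration_mean_s, p.duration_sd_s)
            for m, p in params.modules.items()
        }
        self.count_mu = {
            m: _calibrated_count_mu(p.occ_mean / p.presence, p.occ_sd)
            for m, p in params.modules.items()
            if p.presence > 0
        }
        self.idle_mu = _calibrated_duration_mu(params.idle_mean_s, params.idle_sd_s)

    def counts(self, rng: np.random.Generator) -> dict[str, int]:
        out: dict[str, int] = {}
        for module, p in self.params.modules.items():
            if p.presence <= 0.0 or (p.presence < 1.0 and rng.random() >= p.presence):
                continue
            mu = self.count_mu[module]
            if mu is None:
                out[module] = 1
            else:
                out[module] = int(max(1.0, math.floor(max(rng.normal(mu, p.occ_sd), 1.0) + 0.5)))
        return out

    def durations(self, module: str, count: int, rng: np.random.Generator) -> list[float]:
        p = self.params.modules[module]
        mu = self.duration_mu[module]
        if p.duration_sd_s == 0.0:
            draws = np.full(count, max(0.0, mu))
        else:
            a = -mu / p.duration_sd_s
            draws = sps.truncnorm.rvs(a, np.inf, loc=mu, scale=p.duration_sd_s,
                                      size=count, random_state=rng)
        draws = np.round(draws, 1)
        if module not in ZERO_DURATION_OK:
            draws = np.maximum(_MIN_DURATION_S, draws)
        return [float(d) for d in draws]

    def idle_total(self, rng: np.random.Generator) -> float:
        if self.params.idle_sd_s == 0.0:
            return max(0.0, self.idle_mu)
        a = -self.idle_mu / self.params.idle_sd_s
        return float(sps.truncnorm.rvs(a, np.inf, loc=self.idle_mu,
                                       scale=self.params.idle_sd_s,
                                       size=1, random_state=rng)[0])


def generate_cohort(
    params: GeneratorParams, n: int, seed: int | None = None
) -> list[SurgeryLog]:
    """Generate ``n`` synthetic surgery logs; identical seeds give identical
    cohorts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sampler = _ModuleSampler(params)
    cohort: list[SurgeryLog] = []
    for i in range(n):
        counts = sampler.counts(rng)
        base = _base_sequence(params.category, counts, rng)
        tokens, idle_slices = _place_floaters(base, counts, rng)
        idle_total = round(sampler.idle_total(rng), 1)
        slice_s = 0.0
        if idle_slices:
            slice_s = max(_MIN_DURATION_S, round(idle_total / (idle_slices + 1), 1))
        pools = {m: sampler.durations(m, c, rng) for m, c in sorted(counts.items())}
        records: list[StepRecord] = []
        t = 0.0
        idle_spent = 0.0
        for token in tokens:
            if token == IDLE:
                d = slice_s
                idle_spent = round(idle_spent + d, 1)
            else:
                d = pools[token].pop()
            records.append(StepRecord(token, t, round(t + d, 1)))
            t = round(t + d, 1)
        remainder = round(idle_total - idle_spent, 1)
        if remainder >= _MIN_DURATION_S:
            gaps = [j for j in range(len(records) + 1)
                    if (j == 0 or records[j - 1].module != IDLE)
                    and (j == len(records) or records[j].module != IDLE)]
            j = int(rng.choice(gaps))
            shifted = []
            t0 = records[j - 1].end_s if j > 0 else 0.0
            shifted.append(StepRecord(IDLE, t0, round(t0 + remainder, 1)))
            for rec in records[j:]:
                shifted.append(StepRecord(rec.module, round(rec.start_s + remainder, 1),
                                          round(rec.end_s + remainder, 1)))
            records = records[:j] + shifted
        cohort.append(SurgeryLog(f"{params.category.value}-{i:04d}", params.category, records))
    return cohort
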
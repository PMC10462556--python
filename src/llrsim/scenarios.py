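"""Navigation-platform scenarios and impact metrics.

Three scenarios describe the introduction of an intra-operative 3D
navigation platform (patient-specific liver model, instrument tracking,
augmented overlay):

1. no navigation platform (baseline);
2. conservative positive effect — resection 10% faster, supply-duct
   isolation 25% faster, physical marking of the resection area eliminated,
   and per model update a computational burden of 60 s segmentation, 120 s
   image-to-3D-model registration and 120 s for taking new images;
3. optimistic positive effect — resection 20% faster, isolation 50% faster,
   segmentation 30 s and registration 60 s (new images still 120 s).

Image-to-patient registration is assumed done before surgery and costs
nothing in-run.  By default each ultrasound imaging event's duration is
*replaced* by the technology-step sum (the platform's updated 3D model takes
over the role of intra-operative ultrasound); the alternative ``add`` policy
keeps ultrasound and adds the technology time on top.  Faster modules are
assumed proportionally less variable: multipliers scale both the mean and
the SD (uniform bounds likewise), preserving the coefficient of variation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .desm import BatchResult, DurationModel, ModuleOccurrence, OccurrenceModel
from .process_model import ProcessGraph

__all__ = [
    "TechStepTimes",
    "ScenarioSpec",
    "scenario_spec",
    "apply_scenario",
    "improvement_percent",
    "distribution_peak",
]

IMAGING = "P05M02"
MARKING = "P10M01"
RESECTION = "P10M02"
ISOLATION = "P08aM03"


@dataclass(frozen=True)
class TechStepTimes:
    """Computational steps of one 3D-model update (seconds)."""

    segmentation_s: float
    model_registration_s: float
    new_images_s: float

    @property
    def total_s(self) -> float:
        return self.segmentation_s + self.model_registration_s + self.new_images_s


@dataclass(frozen=True)
class ScenarioSpec:
    """Duration multipliers, removed modules and technology times."""

    id: int
    duration_multipliers: dict[str, float] = field(default_factory=dict)
    removed_modules: frozenset[str] = frozenset()
    tech: TechStepTimes | None = None
    imaging_policy: str = "replace"  # "replace" | "add"

    @property
    def is_identity(self) -> bool:
        return (not self.duration_multipliers and not self.removed_modules
                and self.tech is None)


def scenario_spec(id: int, imaging_policy: str = "replace") -> ScenarioSpec:
    """The built-in scenario constants (immutable; copy to override)."""
    if imaging_policy not in ("replace", "add"):
        raise ValueError(f"unknown imaging policy {imaging_policy!r}")
    if id == 1:
        return ScenarioSpec(id=1, imaging_policy=imaging_policy)
    if id == 2:
        return ScenarioSpec(
            id=2,
            duration_multipliers={RESECTION: 0.90, ISOLATION: 0.75},
            removed_modules=frozenset({MARKING}),
            tech=TechStepTimes(60.0, 120.0, 120.0),
            imaging_policy=imaging_policy,
        )
    if id == 3:
        return ScenarioSpec(
            id=3,
            duration_multipliers={RESECTION: 0.80, ISOLATION: 0.50},
            removed_modules=frozenset({MARKING}),
            tech=TechStepTimes(30.0, 60.0, 120.0),
            imaging_policy=imaging_policy,
        )
    raise ValueError(f"unknown scenario id {id!r}; expected 1, 2 or 3")


def apply_scenario(
    spec: ScenarioSpec,
    duration_model: DurationModel,
    occurrence_model: OccurrenceModel,
    graph: ProcessGraph,
) -> tuple[DurationModel, OccurrenceModel, ProcessGraph]:
    """Return scenario-modified copies of the models and the graph.

    Scenario 1 is a fixed point.  Occurrence counts are scenario-invariant
    (a run images as often as it would have; each event just costs the
    technology time under the ``replace`` policy).
    """
    dmodel = copy.deepcopy(duration_model)
    omodel = copy.deepcopy(occurrence_model)
    out_graph = copy.deepcopy(graph)
    if spec.is_identity:
        return dmodel, omodel, out_graph
    for module, factor in spec.duration_multipliers.items():
        if module in dmodel.modules:
            dmodel.modules[module] = dmodel.modules[module].scaled(factor)
    for module in spec.removed_modules:
        dmodel.modules.pop(module, None)
        omodel.modules.pop(module, None)
    out_graph.entries = [e for e in out_graph.entries
                         if e.module not in spec.removed_modules]
    out_graph.most_probable_path = [
        lbl for lbl in out_graph.most_probable_path
        if any(e.label == lbl for e in out_graph.entries)
    ]
    if spec.tech is not None and IMAGING in dmodel.modules:
        if spec.imaging_policy == "replace":
            dmodel.modules[IMAGING] = replace(
                dmodel.modules[IMAGING], fixed_s=spec.tech.total_s
            )
        else:
            dmodel.modules[IMAGING] = replace(
                dmodel.modules[IMAGING], extra_s=spec.tech.total_s
            )
    return dmodel, omodel, out_graph


def improvement_percent(batch_x: BatchResult, batch_1: BatchResult) -> float:
    """Percent decrease of the mean total duration relative to baseline:
    ``100 * (1 - mean_x / mean_1)``.  Negative when a scenario lengthens
    surgery."""
    mean_1 = batch_1.mean_s
    if mean_1 == 0:
        raise ZeroDivisionError("baseline batch has zero mean duration")
    return 100.0 * (1.0 - batch_x.mean_s / mean_1)


def peak_improvement_percent(batch_x: BatchResult, batch_1: BatchResult) -> float:
    """Percent decrease of the most probable total duration (KDE peak)."""
    peak_1 = batch_1.peak_s()
    if peak_1 == 0:
        raise ZeroDivisionError("baseline batch has zero peak duration")
    return 100.0 * (1.0 - batch_x.peak_s() / peak_1)


def distribution_peak(samples: np.ndarray) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on a 1-second grid."""
    samples = np.asarray(samples, float)
    if samples.size < 100:
        raise ValueError(f"need >= 100 samples for a peak estimate, got {samples.size}")
    kde = sps.gaussian_kde(samples, bw_method="silverman")
    grid = np.arange(np.floor(samples.min()), np.ceil(samples.max()) + 1.0)
    return float(grid[int(np.argmax(kde(grid)))])
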
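"""End-to-end pipeline: cohort -> statistics -> simulation -> report.

A :class:`PipelineConfig` fully determines a run: the input cohort (a
step-log CSV or a synthetic cohort of a given size), the categories, the
duration-distribution modes, the scenarios, the batch size and the master
seed.  Outputs are deterministic given (config, seed): per-category module
statistics, phase breakdowns and most probable paths; per
category x mode x scenario batch summaries; improvement and convergence
reports; density plots; and a run log with the seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analyser, desm, scenarios as sc, synthetic
from .process_model import SurgeryCategory, build_category_graph
from .reference import reference_stats
from .steplog import read_steplogs, verify_log, write_steplogs

__all__ = ["PipelineConfig", "PipelineError", "simulate_reference", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    outdir: str = "llrsim-out"
    steplog: str | None = None  # input CSV; None -> synthetic cohort
    n_surgeries: int = 200
    categories: list[str] = field(default_factory=lambda: ["S56", "S78", "S5GB"])
    modes: list[str] = field(default_factory=lambda: ["gaussian", "uniform"])
    scenarios: list[int] = field(default_factory=lambda: [1, 2, 3])
    n_runs: int = 45_000
    seed: int = 0
    imaging_policy: str = "replace"
    leakage_policy: str = "per_surgery"
    include_idle: bool = False
    include_p11: bool = False
    plots: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def simulate_reference(
    category: SurgeryCategory | str,
    scenario_id: int = 1,
    mode: str = "gaussian",
    n_runs: int = 45_000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    imaging_policy: str = "replace",
    leakage_policy: str = "per_surgery",
) -> desm.BatchResult:
    """One batch parameterized directly by the published tables."""
    category = SurgeryCategory.coerce(category)
    graph = build_category_graph(category)
    stats = reference_stats(category)
    dmodel, omodel = desm.fit_models(stats, mode, graph=graph,
                                     leakage_policy=leakage_policy)
    spec = sc.scenario_spec(scenario_id, imaging_policy=imaging_policy)
    dmodel, omodel, graph = sc.apply_scenario(spec, dmodel, omodel, graph)
    exclusion = desm.ExclusionRule.for_category(category)
    return desm.run_batch(n_runs, seed, dmodel, omodel, exclusion, scenario_id)


def _dump_json(path: Path, doc) -> None:
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns the map of written artifacts.

    Any stage error aborts with the stage name and cause; artifacts written
    by the failed run are removed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, path: Path) -> Path:
        written[name] = path
        return path

    stage = "setup"
    try:
        master = np.random.SeedSequence(config.seed)
        streams = iter(master.spawn(4096))
        batch_log: list[dict] = []

        stage = "input"
        cohorts: dict[str, list] = {}
        if config.steplog is not None:
            for log in read_steplogs(config.steplog):
                cohorts.setdefault(log.category.value, []).append(log)
        else:
            for cat in config.categories:
                params = synthetic.default_params(cat)
                gen_seed = next(streams)
                cohorts[cat] = synthetic.generate_cohort(
                    params, config.n_surgeries, seed=gen_seed
                )
                path = emit(f"cohort:{cat}", outdir / f"cohort_{cat}.csv")
                write_steplogs(cohorts[cat], path)

        stage = "verify"
        graphs = {cat: build_category_graph(cat) for cat in cohorts}
        for cat, cohort in cohorts.items():
            bad = [(log.surgery_id, rep.violations)
                   for log in cohort
                   for rep in [verify_log(log, graphs[cat])] if not rep.ok]
            if bad:
                raise PipelineError(f"{len(bad)} logs failed verification, first: {bad[0]}")

        stage = "analyse"
        all_stats: dict[str, analyser.ModuleStatsTable] = {}
        for cat, cohort in cohorts.items():
            stats = analyser.module_stats(cohort)
            all_stats[cat] = stats
            stats.to_csv(emit(f"stats:{cat}", outdir / f"module_stats_{cat}.csv"))
            breakdown = analyser.phase_breakdown(
                stats, include_idle=config.include_idle, include_p11=config.include_p11
            )
            path_doc = {
                "most_probable_path": analyser.most_probable_path(cohort, graphs[cat]),
                "occurrence_probabilities": analyser.occurrence_probabilities(cohort),
                "phase_fractions": breakdown.fractions,
                "phase_durations_s": breakdown.phase_durations_s,
            }
            _dump_json(emit(f"analysis:{cat}", outdir / f"analysis_{cat}.json"), path_doc)

        stage = "simulate"
        batches: dict[tuple[str, str, int], desm.BatchResult] = {}
        for cat, stats in all_stats.items():
            exclusion = desm.ExclusionRule.for_category(cat)
            for mode in config.modes:
                dmodel, omodel = desm.fit_models(
                    stats, mode, graph=graphs[cat], leakage_policy=config.leakage_policy
                )
                for scenario_id in config.scenarios:
                    spec = sc.scenario_spec(scenario_id, imaging_policy=config.imaging_policy)
                    dm, om, _ = sc.apply_scenario(spec, dmodel, omodel, graphs[cat])
                    stream = next(streams)
                    batch = desm.run_batch(config.n_runs, stream, dm, om,
                                           exclusion, scenario_id)
                    batches[(cat, mode, scenario_id)] = batch
                    batch_log.append({"cell": [cat, mode, scenario_id],
                                      "stream": stream.spawn_key})

        stage = "report"
        summaries = {f"{cat}/{mode}/sc{scen}": b.summary()
                     for (cat, mode, scen), b in batches.items()}
        _dump_json(emit("batches", outdir / "batch_summaries.json"), summaries)

        rows = []
        for (cat, mode, scen), batch in sorted(batches.items()):
            base = batches.get((cat, mode, 1))
            rows.append({
                "category": cat, "mode": mode, "scenario": scen,
                "mean_s": round(batch.mean_s, 3),
                "decrease_pct": (round(sc.improvement_percent(batch, base), 4)
                                 if base is not None else None),
                "peak_s": round(batch.peak_s(), 1),
                "peak_decrease_pct": (round(sc.peak_improvement_percent(batch, base), 4)
                                      if base is not None else None),
            })
        _dump_json(emit("improvements", outdir / "improvements.json"), rows)
        import pandas as pd
        pd.DataFrame(rows).to_csv(emit("improvements_csv", outdir / "improvements.csv"),
                                  index=False)

        convergence = {}
        for cat in all_stats:
            mode = config.modes[0]
            if (cat, mode, 1) not in batches:
                continue
            dmodel, omodel = desm.fit_models(
                all_stats[cat], mode, graph=graphs[cat],
                leakage_policy=config.leakage_policy,
            )
            second = desm.run_batch(config.n_runs, next(streams), dmodel, omodel,
                                    desm.ExclusionRule.for_category(cat), 1)
            rep = desm.check_convergence(batches[(cat, mode, 1)], second)
            convergence[cat] = {
                "mean_diff_pct": round(rep.mean_diff_pct, 5),
                "sd_diff_pct": round(rep.sd_diff_pct, 5),
                "passed": rep.passed,
            }
        _dump_json(emit("convergence", outdir / "convergence.json"), convergence)

        if config.plots:
            stage = "plots"
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            for cat in all_stats:
                for mode in config.modes:
                    fig, ax = plt.subplots(figsize=(6, 4))
                    for scen in config.scenarios:
                        batch = batches[(cat, mode, scen)]
                        totals = batch.included_totals_s / 60.0
                        xs = np.linspace(totals.min(), totals.max(), 512)
                        from scipy import stats as sps
                        ax.plot(xs, sps.gaussian_kde(totals, bw_method="silverman")(xs),
                                label=f"Scenario {scen}")
                    ax.set_xlabel("total duration (min)")
                    ax.set_ylabel("density")
                    ax.set_title(f"{cat}, {mode} durations")
                    ax.legend()
                    fig.tight_layout()
                    fig.savefig(emit(f"plot:{cat}:{mode}",
                                     outdir / f"density_{cat}_{mode}.png"), dpi=120)
                    plt.close(fig)

        stage = "log"
        _dump_json(emit("runlog", outdir / "run_log.json"), {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "batches": batch_log,
        })
    except Exception as exc:
        for path in written.values():
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return written
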
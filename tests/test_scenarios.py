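"""Navigation-platform scenarios, impact metrics, density peaks."""

from __future__ import annotations

import numpy as np
import pytest

from llrsim.analyser import ModuleStatsTable
from llrsim.desm import BatchResult, ExclusionRule, fit_models, run_batch
from llrsim.pipeline import simulate_reference
from llrsim.process_model import SurgeryCategory, build_category_graph
from llrsim.reference import reference_stats
from llrsim.scenarios import (
    apply_scenario,
    distribution_peak,
    improvement_percent,
    peak_improvement_percent,
    scenario_spec,
)


def _fake_batch(totals, category="S56", scenario=1):
    totals = np.asarray(totals, float)
    return BatchResult(
        category=SurgeryCategory.coerce(category),
        scenario_id=scenario,
        mode="gaussian",
        totals_s=totals,
        excluded=np.zeros(totals.size, bool),
        reasons=np.full(totals.size, ""),
    )


class TestScenarioSpecs:
    def test_scenario_1_is_identity(self):
        assert scenario_spec(1).is_identity

    def test_scenario_2_constants(self):
        s = scenario_spec(2)
        assert s.duration_multipliers == {"P10M02": 0.90, "P08aM03": 0.75}
        assert s.removed_modules == {"P10M01"}
        assert (s.tech.segmentation_s, s.tech.model_registration_s,
                s.tech.new_images_s) == (60.0, 120.0, 120.0)
        assert s.tech.total_s == 300.0

    def test_scenario_3_constants(self):
        s = scenario_spec(3)
        assert s.duration_multipliers == {"P10M02": 0.80, "P08aM03": 0.50}
        assert (s.tech.segmentation_s, s.tech.model_registration_s,
                s.tech.new_images_s) == (30.0, 60.0, 120.0)
        assert s.tech.total_s == 210.0  # per-imaging technology cost

    def test_unknown_ids_rejected(self):
        with pytest.raises(ValueError):
            scenario_spec(4)
        with pytest.raises(ValueError):
            scenario_spec(2, imaging_policy="subtract")


class TestApplyScenario:
    def test_scenario_1_fixed_point(self, graphs):
        dmodel, omodel = fit_models(reference_stats("S56"), "gaussian",
                                    graph=graphs["S56"])
        dm, om, g = apply_scenario(scenario_spec(1), dmodel, omodel, graphs["S56"])
        assert dm == dmodel and om == omodel and g == graphs["S56"]

    @pytest.mark.parametrize("cat", ["S56", "S78", "S5GB"])
    def test_marking_removed(self, graphs, cat):
        dmodel, omodel = fit_models(reference_stats(cat), "gaussian", graph=graphs[cat])
        dm, om, g = apply_scenario(scenario_spec(2), dmodel, omodel, graphs[cat])
        assert "P10M01" not in dm.modules
        assert "P10M01" not in om.modules
        assert "P10M01" not in {e.module for e in g.entries}

    def test_multipliers_scale_mu_and_sigma(self, graphs):
        dmodel, omodel = fit_models(reference_stats("S56"), "gaussian")
        dm, _, _ = apply_scenario(scenario_spec(3), dmodel, omodel, graphs["S56"])
        assert dm.modules["P10M02"].mu_s == pytest.approx(0.8 * 1343.0)
        assert dm.modules["P10M02"].sigma_s == pytest.approx(0.8 * 951.0)
        assert dm.modules["P08aM03"].mu_s == pytest.approx(0.5 * 400.0)

    def test_imaging_replacement_and_add_policies(self, graphs):
        dmodel, omodel = fit_models(reference_stats("S78"), "gaussian")
        dm, _, _ = apply_scenario(scenario_spec(3), dmodel, omodel, graphs["S78"])
        assert dm.modules["P05M02"].fixed_s == 210.0
        dm2, _, _ = apply_scenario(scenario_spec(3, imaging_policy="add"),
                                   dmodel, omodel, graphs["S78"])
        assert dm2.modules["P05M02"].fixed_s is None
        assert dm2.modules["P05M02"].extra_s == 210.0

    def test_leakage_and_idle_unaffected(self, graphs):
        dmodel, omodel = fit_models(reference_stats("S56"), "gaussian")
        dm, _, _ = apply_scenario(scenario_spec(3), dmodel, omodel, graphs["S56"])
        assert dm.leakage_s == dmodel.leakage_s
        assert dm.idle_s == dmodel.idle_s


class TestImprovement:
    def test_formula(self):
        assert improvement_percent(_fake_batch([70.0] * 4), _fake_batch([100.0] * 4)) \
            == pytest.approx(30.0)

    def test_identical_batches_give_zero(self):
        b = _fake_batch([100.0, 120.0, 140.0])
        assert improvement_percent(b, b) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            improvement_percent(_fake_batch([1.0]), _fake_batch([0.0]))

    def test_single_module_closed_form(self, graphs):
        # resection only, 1000 s, SD 0: scenario 3 multiplies by 0.8 -> 20%
        stats = ModuleStatsTable.from_dict("S56", {"P10M02": (1000.0, 0.0, 1.0, 0.0)})
        dmodel, omodel = fit_models(stats, "gaussian")
        rule = ExclusionRule(min_trocars=0, min_resection_total_s=0.0)
        b1 = run_batch(50, 1, dmodel, omodel, rule, 1)
        dm3, om3, _ = apply_scenario(scenario_spec(3), dmodel, omodel, graphs["S56"])
        b3 = run_batch(50, 1, dm3, om3, rule, 3)
        assert improvement_percent(b3, b1) == pytest.approx(20.0)

    def test_fixed_additive_time_dilutes_percent_decrease(self):
        b1 = _fake_batch(np.full(200, 100.0))
        b2 = _fake_batch(np.full(200, 70.0))
        plain = improvement_percent(b2, b1)
        shifted = improvement_percent(_fake_batch(b2.totals_s + 50.0),
                                      _fake_batch(b1.totals_s + 50.0))
        assert shifted < plain

    def test_matched_seed_scenario_3_dominates_scenario_2(self):
        # identical streams: every scenario-3 run is at most its scenario-2 twin
        b2 = simulate_reference("S56", 2, "gaussian", 2000, 77)
        b3 = simulate_reference("S56", 3, "gaussian", 2000, 77)
        assert np.all(b3.totals_s <= b2.totals_s + 1e-9)


class TestDistributionPeak:
    def test_narrow_unimodal_peak_near_mean(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(5000.0, 30.0, 4000)
        assert distribution_peak(samples) == pytest.approx(5000.0, abs=15.0)

    def test_bimodal_peak_in_heavier_component(self):
        rng = np.random.default_rng(1)
        left = rng.normal(1000.0, 50.0, 1500)
        right = rng.normal(2000.0, 50.0, 3500)
        samples = np.concatenate([left, right])
        peak = distribution_peak(samples)
        brute = None  # grid argmax over a brute-force Gaussian KDE
        from scipy.stats import gaussian_kde
        grid = np.arange(samples.min(), samples.max())
        brute = grid[np.argmax(gaussian_kde(samples, bw_method="silverman")(grid))]
        assert peak == pytest.approx(brute, abs=1.0)
        assert peak > 1800.0

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(6000.0, 400.0, 3000)
        assert distribution_peak(0.8 * samples) == pytest.approx(
            0.8 * distribution_peak(samples), abs=5.0
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            distribution_peak(np.arange(50.0))

    def test_peak_improvement_uses_peaks(self):
        rng = np.random.default_rng(3)
        b1 = _fake_batch(rng.normal(10000.0, 200.0, 2000))
        b2 = _fake_batch(rng.normal(8000.0, 200.0, 2000))
        assert peak_improvement_percent(b2, b1) == pytest.approx(20.0, abs=1.0)
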
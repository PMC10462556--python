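"""Simulation engine: samplers, exclusion rules, batches, convergence."""

from __future__ import annotations

import numpy as np
import pytest

from llrsim import desm
from llrsim.analyser import ModuleStatsTable
from llrsim.desm import (
    ExclusionRule,
    ModelError,
    ModuleOccurrence,
    OccurrenceModel,
    check_convergence,
    dynamic_repeat_probability,
    fit_models,
    run_batch,
    sample_duration,
    sample_occurrences,
    simulate_run,
    truncated_normal_mean,
)
from llrsim.pipeline import simulate_reference
from llrsim.process_model import build_category_graph
from llrsim.reference import reference_stats


def _toy_stats(**overrides):
    """Deterministic five-module toy table (all SDs zero)."""
    modules = {
        "P05M02": (300.0, 0.0, 2.0, 0.0),
        "P07M01": (100.0, 0.0, 3.0, 0.0),
        "P10M01": (200.0, 0.0, 1.0, 0.0),
        "P10M02": (900.0, 0.0, 2.0, 0.0),
        "P11M02": (50.0, 0.0, 2.0, 0.0),
    }
    modules.update(overrides)
    return ModuleStatsTable.from_dict("S56", modules, idle_mean_s=120.0)


class TestDurationSampling:
    def test_zero_sigma_is_deterministic(self):
        stats = reference_stats("S56")
        dmodel, _ = fit_models(stats, "gaussian")
        rng = np.random.default_rng(0)
        dmodel.modules["P10M01"] = desm.ModuleDuration("gaussian_trunc", 176.0, 0.0)
        assert sample_duration(dmodel, "P10M01", rng) == 176.0

    def test_truncated_normal_matches_closed_form(self):
        # E[X | X >= 0] = mu + sigma phi(mu/sigma) / Phi(mu/sigma)
        mu, sigma, n = 1343.0, 951.0, 100_000
        rng = np.random.default_rng(7)
        draws = desm._draw_durations(
            desm.ModuleDuration("gaussian_trunc", mu, sigma), n, rng
        )
        assert draws.min() >= 0.0
        expected = truncated_normal_mean(mu, sigma)
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 4 * se

    @pytest.mark.parametrize("mu,sigma", [(10.0, 100.0), (0.0, 50.0), (500.0, 20.0)])
    def test_samples_always_non_negative(self, mu, sigma):
        rng = np.random.default_rng(1)
        draws = desm._draw_durations(
            desm.ModuleDuration("gaussian_trunc", mu, sigma), 5000, rng
        )
        assert draws.min() >= 0.0

    def test_uniform_moment_match(self):
        # bounds [mu - sqrt(3) sigma, mu + sqrt(3) sigma] give mean mu, SD sigma
        dmodel, _ = fit_models(_toy_stats(P10M02=(900.0, 100.0, 2.0, 0.0)), "uniform")
        spec = dmodel.modules["P10M02"]
        assert (spec.lo_s + spec.hi_s) / 2 == pytest.approx(900.0)
        assert (spec.hi_s - spec.lo_s) / np.sqrt(12) == pytest.approx(100.0)

    def test_uniform_uses_observed_minmax_when_supplied(self):
        dmodel, _ = fit_models(
            reference_stats("S56"), "uniform",
            observed_minmax={"P10M02": (476.0, 3000.0)},
        )
        spec = dmodel.modules["P10M02"]
        assert (spec.lo_s, spec.hi_s) == (476.0, 3000.0)

    def test_uniform_zero_sigma_collapses(self):
        dmodel, _ = fit_models(_toy_stats(), "uniform")
        spec = dmodel.modules["P10M01"]
        assert spec.lo_s == spec.hi_s == 200.0


class TestOccurrenceSampling:
    def test_degenerate_count_is_constant(self):
        model = OccurrenceModel("S5GB", {"P07M01": ModuleOccurrence(4.0, 0.0)})
        rng = np.random.default_rng(0)
        assert all(sample_occurrences(model, "P07M01", rng) == 4 for _ in range(20))

    def test_absent_module_never_occurs(self):
        model = OccurrenceModel("S78", {"P08aM03": ModuleOccurrence(0.0, 0.0, presence=0.0)})
        rng = np.random.default_rng(0)
        assert all(sample_occurrences(model, "P08aM03", rng) == 0 for _ in range(20))

    def test_trocar_count_mean_matches_distribution(self):
        spec = ModuleOccurrence(3.6, 0.5)
        exact = sum(k * spec.pmf(k) for k in range(30))
        assert exact == pytest.approx(3.6, abs=0.01)
        rng = np.random.default_rng(3)
        draws = desm._draw_counts(spec, 100_000, rng)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - exact) < 3 * se

    def test_counts_are_non_negative_integers(self):
        rng = np.random.default_rng(5)
        draws = desm._draw_counts(ModuleOccurrence(0.2, 0.4), 5000, rng)
        assert draws.dtype.kind == "i" and draws.min() >= 0


class TestDynamicRepeat:
    def test_monotone_non_increasing_to_zero(self):
        stats = reference_stats("S56")
        _, omodel = fit_models(stats, "gaussian", graph=build_category_graph("S56"))
        probs = [dynamic_repeat_probability(omodel, "P08aM06", n) for n in range(80)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        assert probs[-1] == pytest.approx(0.0, abs=1e-12)

    def test_certain_first_execution_for_degenerate_count(self):
        omodel = OccurrenceModel("S5GB", {"P07M01": ModuleOccurrence(4.0, 0.0)})
        assert dynamic_repeat_probability(omodel, "P07M01", 0) == 1.0
        assert dynamic_repeat_probability(omodel, "P07M01", 4) == 0.0


class TestFitModels:
    def test_gaussian_parameters_pass_through(self):
        dmodel, omodel = fit_models(reference_stats("S56"), "gaussian")
        assert dmodel.modules["P10M02"].mu_s == 1343.0
        assert dmodel.modules["P10M02"].sigma_s == 951.0
        assert omodel.modules["P10M02"].occ_mean == 2.6

    def test_fixed_additions(self):
        dmodel, _ = fit_models(_toy_stats(), "gaussian")
        assert dmodel.leakage_s == 100.0  # 50 s x 2 occurrences per surgery
        assert dmodel.idle_s == 120.0
        dmodel2, _ = fit_models(_toy_stats(), "gaussian", leakage_policy="per_occurrence")
        assert dmodel2.leakage_s == 50.0

    def test_undefined_duration_with_occurrences_rejected(self):
        stats = _toy_stats(P10M02=(float("nan"), float("nan"), 2.0, 0.0))
        with pytest.raises(ModelError, match="P10M02"):
            fit_models(stats, "gaussian")


class TestSimulateRun:
    def test_deterministic_sum_oracle(self, graphs):
        # all SDs zero -> the total is the exact hand sum:
        # idle 120 + leakage 50*2 + imaging 300*2 + trocars 100*3
        # + marking 200 + resection 900*2 = 3120
        dmodel, omodel = fit_models(_toy_stats(), "gaussian")
        run = simulate_run(graphs["S56"], dmodel, omodel, 1,
                           ExclusionRule(3, 0.0), np.random.default_rng(0))
        assert run.total_s == pytest.approx(3120.0)
        assert not run.excluded

    def test_two_trocars_excluded(self, graphs):
        dmodel, omodel = fit_models(_toy_stats(P07M01=(100.0, 0.0, 2.0, 0.0)), "gaussian")
        run = simulate_run(graphs["S56"], dmodel, omodel, 1,
                           ExclusionRule(3, 238.0), np.random.default_rng(0))
        assert run.excluded and run.reason == "min_trocars"

    @pytest.mark.parametrize("resection_s,expect_excluded", [
        (237.0, True),   # below half the observed minimum
        (238.0, False),  # exactly at the threshold: boundary-inclusive
        (476.0, False),
    ])
    def test_resection_threshold(self, graphs, resection_s, expect_excluded):
        stats = _toy_stats(P10M02=(resection_s, 0.0, 1.0, 0.0))
        dmodel, omodel = fit_models(stats, "gaussian")
        run = simulate_run(graphs["S56"], dmodel, omodel, 1,
                           ExclusionRule(3, 238.0), np.random.default_rng(0))
        assert run.excluded is expect_excluded

    def test_printed_exclusion_thresholds(self):
        assert ExclusionRule.for_category("S56").min_resection_total_s == 238.0
        assert ExclusionRule.for_category("S78").min_resection_total_s == 270.0
        assert ExclusionRule.for_category("S5GB").min_resection_total_s == 461.0
        assert ExclusionRule.for_category("S56").min_trocars == 3


class TestRunBatch:
    def test_same_seed_identical(self):
        dmodel, omodel = fit_models(reference_stats("S78"), "gaussian")
        rule = ExclusionRule.for_category("S78")
        a = run_batch(500, 9, dmodel, omodel, rule)
        b = run_batch(500, 9, dmodel, omodel, rule)
        assert np.array_equal(a.totals_s, b.totals_s)
        assert np.array_equal(a.excluded, b.excluded)

    def test_summary_over_included_runs_only(self):
        dmodel, omodel = fit_models(reference_stats("S56"), "gaussian")
        rule = ExclusionRule.for_category("S56")
        batch = run_batch(4000, 11, dmodel, omodel, rule)
        assert batch.n_excluded + batch.included_totals_s.size == batch.n
        assert batch.mean_s == pytest.approx(batch.totals_s[~batch.excluded].mean())
        assert batch.n_excluded > 0

    def test_n_runs_below_one_rejected(self):
        dmodel, omodel = fit_models(_toy_stats(), "gaussian")
        with pytest.raises(ValueError):
            run_batch(0, 0, dmodel, omodel, ExclusionRule())


class TestConvergence:
    def test_identical_batches_differ_by_zero(self):
        dmodel, omodel = fit_models(_toy_stats(P10M02=(900.0, 100.0, 2.0, 1.0)), "gaussian")
        batch = run_batch(500, 3, dmodel, omodel, ExclusionRule())
        rep = check_convergence(batch, batch)
        assert rep.mean_diff_pct == 0.0 and rep.sd_diff_pct == 0.0 and rep.passed

    def test_small_batches_fluctuate_more_than_large(self):
        small = [simulate_reference("S56", 1, "gaussian", 200, s) for s in (21, 22)]
        big = [simulate_reference("S56", 1, "gaussian", 20_000, s) for s in (23, 24)]
        rep_small = check_convergence(*small)
        rep_big = check_convergence(*big)
        assert rep_small.mean_diff_pct > rep_big.mean_diff_pct
        assert rep_small.sd_diff_pct > rep_big.sd_diff_pct
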
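"""Fit orchestration: caching, persistence, parallelism, convergence
detection and best-model selection."""

import math

import numpy as np
import pytest

from ephysfit.fitness import FitnessReport
from ephysfit.model_spec import ParamDef, ParamSet
from ephysfit.optimize import (
    ConvergenceCriteria,
    EvalContext,
    FitHistory,
    FitRecord,
    canonical_key,
    check_convergence,
    do_fit,
    evaluate_population,
    select_best,
)
from ephysfit.simulator import SimConfig, StimulusProtocol
from ephysfit.synthetic import generate_recordings, meta_for_protocol

from conftest import passive_neuron

WEIGHTS = {
    "baseline_pre": 1, "baseline_post": 1, "voltage_response": 1,
    "falling_curve": 1, "histogram": 1,
}


@pytest.fixture(scope="module")
def passive_problem():
    """Tiny passive fit problem: one hyperpolarizing trace, RM free."""
    neuron = passive_neuron(R_in=100e6, tau_m=10e-3)
    proto = StimulusProtocol(amplitude=-50e-12, onset=0.02, offset=0.12, duration=0.15)
    data = generate_recordings(neuron, [proto], noise_sd=0.0, seed=0)
    params = ParamSet([ParamDef("RM", initial=2.0, min=0.2, max=4.0)])
    ctx = EvalContext(
        neuron=neuron, param_names=params.names, param_set=params,
        data=data, weights=WEIGHTS,
    )
    return neuron, data, params, ctx


class TestConvergence:
    def test_constant_series_converged(self):
        res = check_convergence(np.full(25, 0.3))
        assert res and res.slope == pytest.approx(0.0, abs=1e-12)

    def test_linear_decline_not_converged(self):
        series = 1.0 - 0.01 * np.arange(25)
        assert not check_convergence(series)

    def test_crafted_series_within_thresholds(self):
        series = 0.3 + 0.0015 * np.arange(25)
        res = check_convergence(series)
        assert res.converged
        assert res.slope == pytest.approx(0.0015, abs=1e-9)
        assert res.sd < 0.06

    def test_short_history_flagged(self):
        res = check_convergence(np.full(10, 0.3))
        assert not res
        assert "10 generations" in res.reason

    def test_steep_improvement_is_not_convergence(self):
        # the slope criterion is taken in magnitude: a run still improving
        # at -0.005/generation has not converged even though its sd is small
        series = 1.0 - 0.005 * np.arange(25)
        assert np.std(series) < 0.06
        assert not check_convergence(series)

    def test_drop_then_plateau_fires_only_after_plateau(self):
        # 40 generations of steady improvement, then a plateau: the detector
        # must stay quiet during the decline and fire only once the window
        # is dominated by plateau generations
        series = np.concatenate([0.7 - 0.01 * np.arange(40), np.full(40, 0.3)])
        fired_at = None
        for g in range(25, len(series) + 1):
            if check_convergence(series[:g]):
                fired_at = g
                break
        assert fired_at is not None
        assert 55 <= fired_at <= 65
        # pure linear decline never fires
        decline = 5.0 - 0.01 * np.arange(200)
        for g in range(25, 201):
            assert not check_convergence(decline[:g])


def _history_of(n, fitness=None):
    rng = np.random.default_rng(0)
    fs = fitness if fitness is not None else rng.random(n)
    records = [
        FitRecord(params={"x": float(i)}, report=FitnessReport({}, float(f)),
                  generation=i // 8, eval_index=i)
        for i, f in enumerate(fs)
    ]
    return FitHistory(records=records)


class TestSelectBest:
    @pytest.mark.parametrize("n,expected", [(1600, 40), (2400, 50), (10, 1),
                                            (2000, 50), (2001, 50), (41, 2)])
    def test_selection_counts(self, n, expected):
        best = select_best(_history_of(n))
        assert len(best) == expected

    def test_selects_lowest_fitness(self):
        h = _history_of(100)
        best = select_best(h)
        cutoff = max(r.fitness for r in best)
        others = [r.fitness for r in h.records if r not in best]
        assert all(f >= cutoff for f in others)


class TestEvaluatePopulation:
    def test_duplicate_candidate_simulated_once(self, passive_problem, tmp_path):
        _, _, _, ctx = passive_problem
        cands = [{"RM": 1.0}, {"RM": 1.0}, {"RM": 2.0}]
        reports = evaluate_population(cands, ctx, tmp_path, save_traces=False)
        assert reports[0].total == reports[1].total
        assert len(list((tmp_path / "evals").iterdir())) == 2  # unique keys only

    def test_cache_used_across_calls(self, passive_problem, tmp_path):
        _, _, _, ctx = passive_problem
        first = evaluate_population([{"RM": 1.5}], ctx, tmp_path, save_traces=False)
        # poison the context: a cache hit must not re-simulate
        import copy

        broken = copy.copy(ctx)
        broken.simulate = None  # would raise if called
        second = evaluate_population([{"RM": 1.5}], broken, tmp_path, save_traces=False)
        assert second[0].total == pytest.approx(first[0].total, abs=1e-12)

    def test_serial_matches_parallel(self, passive_problem, tmp_path):
        _, _, _, ctx = passive_problem
        cands = [{"RM": v} for v in (0.5, 1.0, 1.5, 2.5)]
        serial = evaluate_population(cands, ctx, tmp_path / "s", workers=1,
                                     save_traces=False)
        parallel = evaluate_population(cands, ctx, tmp_path / "p", workers=2,
                                       save_traces=False)
        for a, b in zip(serial, parallel):
            assert a.total == b.total

    def test_simulation_failure_yields_inf_and_continues(self, passive_problem,
                                                         tmp_path, monkeypatch):
        from ephysfit import optimize as opt_mod
        from ephysfit.simulator import SimulationError

        _, _, _, ctx = passive_problem
        real = EvalContext.simulate

        def flaky(self, params):
            if params["RM"] == 1.0:
                raise SimulationError(7)
            return real(self, params)

        monkeypatch.setattr(EvalContext, "simulate", flaky)
        reports = evaluate_population([{"RM": 1.0}, {"RM": 2.0}], ctx, tmp_path,
                                      save_traces=False)
        assert math.isinf(reports[0].total)
        assert "failed" in reports[0].note
        assert math.isfinite(reports[1].total)

    def test_kernel_nan_abort_is_reported(self):
        """A non-finite model state aborts integration with the step index."""
        from ephysfit.simulator import SimulationError, run

        neuron = passive_neuron()
        object.__setattr__(neuron.passive, "E_leak", float("nan"))
        proto = StimulusProtocol(amplitude=0.0, onset=0.0, offset=0.01, duration=0.02)
        with pytest.raises(SimulationError):
            run(neuron, proto)

    def test_canonical_key_fixed_precision(self):
        a = canonical_key({"RM": 1.0000000000001, "NaF_0": 100.0})
        b = canonical_key({"NaF_0": 100.0, "RM": 1.0000000000001004})
        assert a == b
        assert "NaF_0" in a and a.index("NaF_0") < a.index("RM")


class TestDoFit:
    def test_eval_count_is_generations_times_popsize(self, passive_problem, tmp_path):
        neuron, data, params, _ = passive_problem
        h = do_fit(neuron, data, params, WEIGHTS, generations=2, popsize=8,
                   seed=0, store_dir=tmp_path, save_traces=False)
        assert len(h) == 16
        assert len(h.generation_means) == 2
        assert (tmp_path / "history.csv").exists()

    def test_deterministic_rerun(self, passive_problem, tmp_path):
        neuron, data, params, _ = passive_problem
        h1 = do_fit(neuron, data, params, WEIGHTS, generations=3, popsize=4,
                    seed=7, store_dir=tmp_path / "a", save_traces=False)
        h2 = do_fit(neuron, data, params, WEIGHTS, generations=3, popsize=4,
                    seed=7, store_dir=tmp_path / "b", save_traces=False)
        for r1, r2 in zip(h1.records, h2.records):
            assert r1.params == r2.params  # bit-identical parameters
            assert r1.fitness == pytest.approx(r2.fitness, abs=1e-12)

    def test_resume_from_storage_hits_cache(self, passive_problem, tmp_path):
        neuron, data, params, _ = passive_problem
        h1 = do_fit(neuron, data, params, WEIGHTS, generations=2, popsize=4,
                    seed=3, store_dir=tmp_path, save_traces=False)
        n_dirs = len(list((tmp_path / "evals").iterdir()))
        h2 = do_fit(neuron, data, params, WEIGHTS, generations=2, popsize=4,
                    seed=3, store_dir=tmp_path, save_traces=False)
        assert len(list((tmp_path / "evals").iterdir())) == n_dirs  # no new sims
        for r1, r2 in zip(h1.records, h2.records):
            assert r1.fitness == pytest.approx(r2.fitness, abs=1e-12)

    def test_best_so_far_monotone(self, passive_problem, tmp_path):
        neuron, data, params, _ = passive_problem
        h = do_fit(neuron, data, params, WEIGHTS, generations=4, popsize=4,
                   seed=1, store_dir=tmp_path, save_traces=False)
        best = h.best_so_far
        assert np.all(np.diff(best) <= 0)

    def test_fit_to_self_approaches_zero(self, passive_problem, tmp_path):
        """The truth parameters are in the search space, so the optimum is 0."""
        neuron, data, params, _ = passive_problem
        h = do_fit(neuron, data, params, WEIGHTS, generations=10, popsize=8,
                   seed=0, store_dir=tmp_path, save_traces=False)
        assert h.best.fitness < 1e-3
        assert h.best.params["RM"] == pytest.approx(1.0, rel=0.05)

    def test_every_evaluation_persisted(self, passive_problem, tmp_path):
        neuron, data, params, _ = passive_problem
        h = do_fit(neuron, data, params, WEIGHTS, generations=2, popsize=4,
                   seed=2, store_dir=tmp_path, save_traces=True)
        for record in h.records:
            assert record.path is not None
            from pathlib import Path

            d = Path(record.path)
            assert (d / "params.yaml").exists()
            assert (d / "fitness.yaml").exists()
            assert (d / "traces" / "meta.yaml").exists()
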
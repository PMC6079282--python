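"""Fit orchestration: evaluate populations, persist every evaluation, track
history, and detect convergence.

Each CMA-ES generation asks for a population of candidate parameter
vectors; every candidate is turned into a neuron (via
:func:`ephysfit.model_spec.apply_params`), simulated under the recorded
protocols, and scored against the recordings with the feature-based
fitness.  Every evaluation is written to the storage directory before it
is reported, keyed by a canonical fixed-precision serialization of the
parameter map so that re-encountered parameter vectors are returned from
the cache without re-simulation.  Population evaluation may be parallel
(one simulation per worker process); results are independent of the
degree of parallelism.

Convergence follows the mean-fitness plateau rule: over a window of 25
generations, the least-squares slope of the per-generation mean fitness
must be below 0.002 in magnitude and its standard deviation below 0.06.
"""

from __future__ import annotations

import hashlib
import math
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .cmaes import CMAConfig, CMAES
from .features import SpikeConfig
from .fitness import FeatureWeights, FitnessReport, fitness_report
from .model_spec import NeuronSpec, ParamSet, apply_params
from .simulator import SimConfig, SimulationError, Trace, run_protocol_set
from .trace_io import TraceSet, save_trace_set

__all__ = [
    "FitRecord",
    "FitHistory",
    "ConvergenceCriteria",
    "ConvergenceResult",
    "evaluate_population",
    "do_fit",
    "check_convergence",
    "select_best",
]


@dataclass
class FitRecord:
    params: dict[str, float]
    report: FitnessReport
    generation: int
    eval_index: int
    path: Optional[str] = None

    @property
    def fitness(self) -> float:
        return self.report.total


@dataclass
class FitHistory:
    records: list[FitRecord] = field(default_factory=list)

    @property
    def generation_means(self) -> np.ndarray:
        """Per-generation mean fitness (non-finite evaluations excluded)."""
        if not self.records:
            return np.array([])
        ngen = max(r.generation for r in self.records) + 1
        means = np.empty(ngen)
        for g in range(ngen):
            fs = [r.fitness for r in self.records
                  if r.generation == g and math.isfinite(r.fitness)]
            means[g] = float(np.mean(fs)) if fs else math.inf
        return means

    @property
    def best_so_far(self) -> np.ndarray:
        fs = np.array([r.fitness for r in self.records])
        return np.minimum.accumulate(fs)

    @property
    def best(self) -> FitRecord:
        return min(self.records, key=lambda r: r.fitness)

    def __len__(self):
        return len(self.records)


@dataclass(frozen=True)
class ConvergenceCriteria:
    window: int = 25          # generations
    slope_tol: float = 0.002  # fitness / generation
    sd_tol: float = 0.06      # fitness

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.slope_tol <= 0 or self.sd_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class ConvergenceResult:
    converged: bool
    slope: Optional[float] = None
    sd: Optional[float] = None
    reason: str = ""

    def __bool__(self) -> bool:
        return self.converged


def check_convergence(
    history: FitHistory | np.ndarray,
    criteria: ConvergenceCriteria = ConvergenceCriteria(),
) -> ConvergenceResult:
    """Plateau detection on the per-generation mean fitness series.

    True iff, over the last ``window`` generations, |least-squares slope|
    < ``slope_tol`` and the standard deviation < ``sd_tol``.  The slope is
    taken in magnitude: a run still improving steeply has not converged.
    """
    means = history.generation_means if isinstance(history, FitHistory) else np.asarray(history, float)
    W = criteria.window
    if len(means) < W:
        return ConvergenceResult(False, reason=f"only {len(means)} generations (< window {W})")
    tail = means[-W:]
    if not np.all(np.isfinite(tail)):
        return ConvergenceResult(False, reason="non-finite mean fitness in window")
    x = np.arange(W, dtype=float)
    slope = float(np.polyfit(x, tail, 1)[0])
    sd = float(np.std(tail))
    ok = abs(slope) < criteria.slope_tol and sd < criteria.sd_tol
    return ConvergenceResult(ok, slope=slope, sd=sd)


def select_best(history: FitHistory) -> list[FitRecord]:
    """The best-model subset used for post-hoc analysis.

    The 50 lowest-fitness records when more than 2,000 evaluations were
    performed, else the lowest 2.5% (rounded up, at least one record).
    """
    if not history.records:
        raise ValueError("empty history")
    n = len(history.records)
    k = 50 if n > 2000 else max(1, math.ceil(0.025 * n))
    return sorted(history.records, key=lambda r: r.fitness)[:k]


# ---------------------------------------------------------------------------
# evaluation and persistence
# ---------------------------------------------------------------------------

def canonical_key(params: dict[str, float]) -> str:
    """Canonical 12-significant-digit serialization; the cache key."""
    return ";".join(f"{name}={params[name]:.12g}" for name in sorted(params))


def _eval_dir(store_dir: Path, key: str) -> Path:
    digest = hashlib.sha256(key.encode()).hexdigest()[:16]
    return store_dir / "evals" / digest


@dataclass
class EvalContext:
    """Everything a worker needs to score one parameter vector."""

    neuron: NeuronSpec
    param_names: list[str]
    param_set: ParamSet
    data: TraceSet
    weights: FeatureWeights
    sim_config: SimConfig = SimConfig()
    spike_cfg: SpikeConfig = SpikeConfig()

    def simulate(self, params: dict[str, float]) -> TraceSet:
        model = apply_params(self.neuron, params, self.param_set)
        protocols = [
            meta.protocol(float(tr.times[-1]) + tr.dt) for tr, meta in self.data
        ]
        traces = run_protocol_set(model, protocols, self.sim_config)
        members = [(trace, meta) for trace, (_, meta) in zip(traces, self.data)]
        return TraceSet(members=members, neuron="sim")


def _score_one(ctx: EvalContext, params: dict[str, float]) -> tuple[FitnessReport, Optional[TraceSet]]:
    try:
        sim = ctx.simulate(params)
        return fitness_report(sim, ctx.data, ctx.weights, ctx.spike_cfg), sim
    except (SimulationError, FloatingPointError, ValueError) as exc:
        return (
            FitnessReport(per_feature={}, total=math.inf, note=f"simulation failed: {exc}"),
            None,
        )


def _worker(args):
    ctx, key, params = args
    report, sim = _score_one(ctx, params)
    return key, report, sim


def _persist(
    store_dir: Path,
    key: str,
    params: dict[str, float],
    report: FitnessReport,
    sim: Optional[TraceSet],
    save_traces: bool,
) -> str:
    d = _eval_dir(store_dir, key)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "params.yaml", "w") as fh:
        yaml.safe_dump({"key": key, "params": {k: float(v) for k, v in params.items()}}, fh)
    with open(d / "fitness.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "total": None if not math.isfinite(report.total) else float(report.total),
                "failed": not math.isfinite(report.total),
                "note": report.note,
                "per_feature": {k: float(v) for k, v in report.per_feature.items()},
            },
            fh,
        )
    if save_traces and sim is not None:
        traces_dir = d / "traces"
        if not traces_dir.exists():
            save_trace_set(sim, traces_dir)
    return str(d)


def _load_cached(store_dir: Path, key: str) -> Optional[FitnessReport]:
    d = _eval_dir(store_dir, key)
    fpath = d / "fitness.yaml"
    if not fpath.exists():
        return None
    with open(fpath) as fh:
        doc = yaml.safe_load(fh)
    total = math.inf if doc.get("failed") else float(doc["total"])
    return FitnessReport(
        per_feature=doc.get("per_feature", {}), total=total, note=doc.get("note", "")
    )


def evaluate_population(
    candidates: list[dict[str, float]],
    ctx: EvalContext,
    store_dir: Path,
    workers: int = 1,
    save_traces: bool = True,
) -> list[FitnessReport]:
    """Score a population, using the on-disk cache and an optional worker pool.

    Duplicate candidates (and candidates already evaluated in a previous
    run over the same storage directory) are simulated once.
    """
    store_dir = Path(store_dir)
    keys = [canonical_key(p) for p in candidates]
    results: dict[str, FitnessReport] = {}
    todo: dict[str, dict[str, float]] = {}
    for key, params in zip(keys, candidates):
        if key in results or key in todo:
            continue
        cached = _load_cached(store_dir, key)
        if cached is not None:
            results[key] = cached
        else:
            todo[key] = params
    jobs = [(ctx, key, params) for key, params in todo.items()]
    if workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            outs = list(pool.map(_worker, jobs))
    else:
        outs = [_worker(j) for j in jobs]
    for key, report, sim in outs:
        # persisted before being reported
        _persist(store_dir, key, todo[key], report, sim, save_traces)
        results[key] = report
    return [results[k] for k in keys]


def do_fit(
    neuron: NeuronSpec,
    data: TraceSet,
    params: ParamSet,
    weights: FeatureWeights,
    generations: int,
    popsize: int = 8,
    seed: int = 0,
    store_dir: Path | str = "fit-results",
    sigma0: float = 0.3,
    workers: int = 1,
    sim_config: SimConfig = SimConfig(),
    save_traces: bool = True,
    criteria: Optional[ConvergenceCriteria] = None,
    stop_on_convergence: bool = False,
) -> FitHistory:
    """Run a CMA-ES fit of ``params`` to the recorded ``data``.

    Exactly ``generations × popsize`` evaluations are performed (cache
    hits included in the count); every evaluation is persisted under
    ``store_dir`` and the run can be resumed from there.
    """
    store_dir = Path(store_dir)
    store_dir.mkdir(parents=True, exist_ok=True)
    ctx = EvalContext(
        neuron=neuron,
        param_names=params.names,
        param_set=params,
        data=data,
        weights=weights,
        sim_config=sim_config,
    )
    opt = CMAES(
        params.initials,
        CMAConfig(popsize=popsize, sigma0=sigma0, seed=seed),
        bounds=params.bounds,
    )
    history = FitHistory()
    eval_index = 0
    for gen in range(generations):
        xs = opt.ask()
        cands = [dict(zip(params.names, x)) for x in xs]
        reports = evaluate_population(
            cands, ctx, store_dir, workers=workers, save_traces=save_traces
        )
        fitnesses = [r.total for r in reports]
        opt.tell(xs, fitnesses)
        for cand, report in zip(cands, reports):
            history.records.append(
                FitRecord(
                    params=cand,
                    report=report,
                    generation=gen,
                    eval_index=eval_index,
                    path=str(_eval_dir(store_dir, canonical_key(cand))),
                )
            )
            eval_index += 1
        if stop_on_convergence and criteria is not None:
            if check_convergence(history, criteria):
                break
    _write_history_csv(history, store_dir / "history.csv")
    return history


def _write_history_csv(history: FitHistory, path: Path) -> None:
    import pandas as pd

    rows = []
    for r in history.records:
        row = {"eval": r.eval_index, "generation": r.generation, "fitness": r.fitness}
        row.update(r.params)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_history_fitness(store_dir: Path | str) -> np.ndarray:
    """Fitness column of a persisted history (for `history` CLI export)."""
    import pandas as pd

    return pd.read_csv(Path(store_dir) / "history.csv")["fitness"].to_numpy()
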
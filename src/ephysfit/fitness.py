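"""Feature-based fitness: normalized differences and their combination.

Every feature difference between a simulated and a recorded trace is made
dimensionless by dividing by the sum of magnitudes,
f = |m − d| / (|m| + |d|), so that features measured in seconds (spike
width) and volts (spike height) contribute comparably.  Vector features
use the mean of point-wise normalized differences; occupancy histograms
use half the L1 distance between the two probability vectors.

Per-feature fitnesses are combined into a single value as a weighted
root-mean-square, total = sqrt(Σ w_i f_i² / N) over the N features with
positive weight.  Tabulated per-feature values from best-model populations
are treated as already weight-scaled, so re-combining them uses unit
weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .features import FeatureVector, SpikeConfig, extract_features
from .trace_io import TraceSet

__all__ = [
    "FeatureWeights",
    "FitnessReport",
    "normalized_difference",
    "vector_difference",
    "histogram_difference",
    "feature_fitness",
    "combine",
    "SPN_WEIGHTS",
    "GPE_WEIGHTS",
]

# Presets for the two neuron families: striatal spiny projection neurons
# (silent at rest, fit with depolarizing and hyperpolarizing steps) and
# external globus pallidus neurons (spontaneously firing, fit with
# hyperpolarizing steps plus a zero-current trace).
SPN_WEIGHTS: dict[str, float] = {
    "baseline_pre": 1, "baseline_post": 1, "rectification": 0,
    "falling_curve": 1, "voltage_response": 1, "latency": 1,
    "spike_time": 0, "spike_width": 1, "spike_height": 1,
    "spike_count": 1, "ahp_depth": 1, "ahp_curve": 4,
    "histogram": 1, "charging_curve": 1,
}
GPE_WEIGHTS: dict[str, float] = {
    "baseline_pre": 0, "baseline_post": 1, "rectification": 2,
    "falling_curve": 1, "voltage_response": 1, "latency": 0,
    "spike_time": 0.5, "spike_width": 1, "spike_height": 0.5,
    "spike_count": 1, "ahp_depth": 1, "ahp_curve": 1,
    "histogram": 1, "charging_curve": 0,
}

FeatureWeights = dict


@dataclass
class FitnessReport:
    """Per-feature normalized fitnesses and their combined total."""

    per_feature: dict[str, float]
    total: float
    per_trace: list[dict[str, float]] = field(default_factory=list)
    note: str = ""


def normalized_difference(m: float, d: float) -> float:
    """Fractional, unitless difference |m − d| / (|m| + |d|); 0 when both are 0."""
    denom = abs(m) + abs(d)
    if denom == 0:
        return 0.0
    return abs(m - d) / denom


def vector_difference(m: np.ndarray, d: np.ndarray) -> float:
    """Mean point-wise normalized difference of two equal-length vectors."""
    m = np.asarray(m, dtype=float)
    d = np.asarray(d, dtype=float)
    if m.shape != d.shape:
        raise ValueError("vector features must have equal length")
    denom = np.abs(m) + np.abs(d)
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = np.abs(m - d)[nz] / denom[nz]
    return float(np.mean(out))


def histogram_difference(m: np.ndarray, d: np.ndarray) -> float:
    """Half the L1 distance between two probability vectors (in [0, 1])."""
    return float(0.5 * np.sum(np.abs(np.asarray(m) - np.asarray(d))))


def combine(per_feature: dict[str, float], weights: Optional[FeatureWeights] = None) -> float:
    """Weighted root-mean-square combination of per-feature fitnesses.

    ``total = sqrt(Σ_i w_i f_i² / N)`` over the N features with w_i > 0.
    With ``weights=None`` all features count with unit weight.
    """
    terms = []
    for name, f in per_feature.items():
        if f is None:
            continue
        w = 1.0 if weights is None else float(weights.get(name, 0.0))
        if w > 0:
            terms.append(w * f * f)
    if not terms:
        raise ValueError("no defined features with positive weight")
    return math.sqrt(sum(terms) / len(terms))


def _trace_fitness(
    sim_fv: FeatureVector, data_fv: FeatureVector
) -> dict[str, float]:
    """Per-feature normalized differences for one matched trace pair."""
    out: dict[str, float] = {}
    scalar_feats = [
        "baseline_pre", "baseline_post", "voltage_response",
        "rectification", "falling_curve", "latency", "ahp_depth",
    ]
    for name in scalar_feats:
        m = getattr(sim_fv, name)
        d = getattr(data_fv, name)
        if m is not None and d is not None:
            out[name] = normalized_difference(m, d)
    if sim_fv.spike_count is not None and data_fv.spike_count is not None:
        out["spike_count"] = normalized_difference(sim_fv.spike_count, data_fv.spike_count)
    # per-spike features paired over the first min(n_sim, n_data) spikes
    for name in ("spike_times", "spike_width", "spike_height"):
        m = getattr(sim_fv, name)
        d = getattr(data_fv, name)
        if m is not None and d is not None and len(m) and len(d):
            n = min(len(m), len(d))
            key = "spike_time" if name == "spike_times" else name
            out[key] = float(
                np.mean([normalized_difference(m[i], d[i]) for i in range(n)])
            )
    for name in ("ahp_curve", "charging_curve"):
        m = getattr(sim_fv, name)
        d = getattr(data_fv, name)
        if m is not None and d is not None:
            out[name] = vector_difference(m, d)
    if sim_fv.histogram is not None and data_fv.histogram is not None:
        out["histogram"] = histogram_difference(sim_fv.histogram, data_fv.histogram)
    return out


def _match_key(meta) -> tuple[str, float]:
    return (meta.label, round(meta.injection_amplitude, 15))


def feature_fitness(
    sim: TraceSet,
    data: TraceSet,
    spike_cfg: SpikeConfig = SpikeConfig(),
) -> dict[str, float]:
    """Per-feature fitness averaged over matched traces.

    Simulated and recorded traces are matched one-to-one by (label,
    injection amplitude); a feature contributes on a trace only when it is
    defined on both sides.
    """
    sim_by_key = {_match_key(meta): (tr, meta) for tr, meta in sim}
    data_by_key = {_match_key(meta): (tr, meta) for tr, meta in data}
    unmatched = set(sim_by_key) ^ set(data_by_key)
    if unmatched:
        raise ValueError(f"unmatched traces between sim and data: {sorted(unmatched)}")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    details = []
    for key in data_by_key:
        sim_tr, sim_meta = sim_by_key[key]
        data_tr, data_meta = data_by_key[key]
        sim_fv = extract_features(sim_tr, sim_meta, spike_cfg)
        data_fv = extract_features(data_tr, data_meta, spike_cfg)
        per = _trace_fitness(sim_fv, data_fv)
        details.append(per)
        for name, f in per.items():
            sums[name] = sums.get(name, 0.0) + f
            counts[name] = counts.get(name, 0) + 1
    result = {name: sums[name] / counts[name] for name in sums}
    result["_per_trace"] = details  # type: ignore[assignment]
    return result


def fitness_report(
    sim: TraceSet,
    data: TraceSet,
    weights: FeatureWeights,
    spike_cfg: SpikeConfig = SpikeConfig(),
) -> FitnessReport:
    """Full report: per-feature fitnesses (weight-scaled as √w·f) and total."""
    per = feature_fitness(sim, data, spike_cfg)
    details = per.pop("_per_trace", [])
    total = combine(per, weights)
    scaled = {
        name: math.sqrt(weights.get(name, 0.0)) * f
        for name, f in per.items()
        if weights.get(name, 0.0) > 0
    }
    return FitnessReport(per_feature=scaled, total=total, per_trace=details)
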
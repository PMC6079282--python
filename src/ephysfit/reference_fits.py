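"""Reference benchmark values from a published best-model analysis.

Mean per-feature fitness values of the 50 best-fitting models per
recorded neuron, as reported for six striatal spiny projection neurons
(three D1-type, three D2-type) and seven external globus pallidus neurons
(four prototypical, three arkypallidal), together with the reported
combined totals.  These tabulated values are already weight-scaled, so
the combined total is reproduced by the unit-weight root-mean-square
combination (:func:`ephysfit.fitness.combine` with ``weights=None``).

Used as worked examples validating the fitness-combination operator.
"""

from __future__ import annotations

SPN_FEATURE_ORDER = [
    "voltage_response", "baseline_pre", "baseline_post", "falling_curve",
    "spike_width", "spike_height", "latency", "spike_count",
    "ahp_depth", "ahp_curve", "charging_curve", "histogram",
]

# mean per-feature fitness over the 50 best models, one column per neuron
SPN_BEST_MODEL_FEATURES: dict[str, list[float]] = {
    "D1_051811": [0.996, 0.018, 0.016, 0.233, 0.253, 0.203, 0.207, 1.077, 0.187, 2.434, 0.147, 0.591],
    "D1_042811": [0.057, 0.072, 0.057, 0.058, 0.171, 0.096, 0.311, 1.066, 0.019, 2.618, 0.174, 0.075],
    "D1_010612": [0.228, 0.044, 0.039, 0.273, 0.055, 0.123, 0.332, 1.021, 0.342, 3.750, 0.056, 0.357],
    "D2_081011": [0.243, 0.110, 0.004, 0.393, 0.141, 0.187, 0.339, 0.958, 0.184, 3.336, 0.094, 0.392],
    "D2_051311": [0.414, 0.015, 0.013, 0.294, 0.040, 0.191, 0.153, 0.946, 0.256, 3.437, 0.058, 0.601],
    "D2_010612": [0.944, 0.073, 0.061, 0.076, 0.241, 0.191, 0.313, 0.908, 0.170, 2.744, 0.170, 0.441],
}

SPN_REPORTED_TOTALS: dict[str, float] = {
    "D1_051811": 0.851,
    "D1_042811": 0.826,
    "D1_010612": 1.142,
    "D2_081011": 1.027,
    "D2_051311": 1.060,
    "D2_010612": 0.899,
}

GPE_FEATURE_ORDER = [
    "voltage_response", "baseline_post", "rectification", "falling_curve",
    "spike_time", "spike_width", "spike_height", "spike_count",
    "ahp_depth", "ahp_curve", "histogram",
]

GPE_BEST_MODEL_FEATURES: dict[str, list[float]] = {
    "proto154F": [0.367, 0.086, 0.261, 0.222, 0.058, 0.450, 0.075, 0.144, 0.070, 0.693, 0.299],
    "proto144F": [0.154, 0.093, 0.324, 0.132, 0.065, 0.548, 0.089, 0.148, 0.112, 0.516, 0.239],
    "proto122F": [0.289, 0.084, 1.318, 0.298, 0.075, 0.325, 0.332, 0.121, 0.104, 0.534, 0.329],
    "proto079F": [0.272, 0.125, 0.705, 0.321, 0.118, 0.277, 0.258, 0.378, 0.115, 0.904, 0.478],
    "arky140F":  [0.240, 0.050, 0.540, 0.227, 0.052, 0.455, 0.077, 0.103, 0.074, 0.616, 0.146],
    "arky138F":  [0.565, 0.066, 0.853, 0.256, 0.164, 0.464, 0.156, 0.306, 0.104, 0.714, 0.332],
    "arky120F":  [0.273, 0.079, 0.511, 0.155, 0.087, 0.278, 0.287, 0.326, 0.094, 0.712, 0.271],
}

GPE_REPORTED_TOTALS: dict[str, float] = {
    "proto154F": 0.316,
    "proto144F": 0.281,
    "proto122F": 0.484,
    "proto079F": 0.448,
    "arky140F": 0.310,
    "arky138F": 0.445,
    "arky120F": 0.348,
}


def combined_total(neuron: str) -> float:
    """Recompute a neuron's combined total from its per-feature means."""
    from .fitness import combine

    table = SPN_BEST_MODEL_FEATURES if neuron in SPN_BEST_MODEL_FEATURES else GPE_BEST_MODEL_FEATURES
    order = SPN_FEATURE_ORDER if neuron in SPN_BEST_MODEL_FEATURES else GPE_FEATURE_ORDER
    values = dict(zip(order, table[neuron]))
    return combine(values, weights=None)
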
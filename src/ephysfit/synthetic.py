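"""Ground-truth models and synthetic current-clamp "recordings".

Two reference neurons are shipped, each a 4-compartment (spherical soma +
3-compartment dendrite) conductance-based model:

``spiker``
    Striatal-projection-neuron-like: silent at rest, inward-rectifier-free
    but carrying a slowly inactivating A-type potassium current that
    delays the first spike by tens of milliseconds near rheobase.
``pauser``
    Pallidal-like: depolarized leak reversal drives spontaneous firing at
    zero injected current; a calcium pool fed by a high-voltage-activated
    calcium current activates a BK-type calcium-dependent potassium
    current that shapes the afterhyperpolarization.

Recordings are the clean simulated traces plus additive zero-mean
Gaussian noise (default sd 0.5 mV, representative of whole-cell noise),
fully reproducible from (kind, seed).  The recovery experiment fits free
parameters of the same model family back to these recordings and reports
per-parameter recovery errors — the case where a known solution exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .fitness import SPN_WEIGHTS, FeatureWeights
from .model_spec import (
    CalciumSpec,
    ChannelSpec,
    GateRateSpec,
    GateSpec,
    MorphSegment,
    NeuronSpec,
    ParamDef,
    ParamSet,
    PassiveSpec,
)
from .optimize import ConvergenceCriteria, FitHistory, do_fit
from .simulator import SimConfig, StimulusProtocol, run_protocol_set
from .trace_io import ProtocolMeta, TraceSet, save_trace_set

__all__ = [
    "make_reference_neuron",
    "reference_protocols",
    "reference_metas",
    "generate_recordings",
    "RecoveryConfig",
    "RecoveryResult",
    "recovery_experiment",
    "default_recovery_params",
]

E_NA = 0.050    # V
E_K = -0.090    # V


def _const(value: float) -> GateRateSpec:
    """Constant rate/time-constant in the five-parameter form (C=0 ⇒ exp≈1)."""
    return GateRateSpec(A=value, B=0.0, C=0.0, D=0.0, F=1e9)


def _boltzmann(half_mV: float, slope_mV: float) -> GateRateSpec:
    """x_inf(V) = 1 / (1 + exp((V − half)/k)); slope > 0 ⇒ increases with V."""
    return GateRateSpec(A=1.0, B=0.0, C=1.0, D=-half_mV * 1e-3, F=-slope_mV * 1e-3)


def _tau_inf_gate(name, power, half_mV, slope_mV, tau_s, tau_min=1e-5) -> GateSpec:
    return GateSpec(
        name=name,
        power=power,
        form="tau-inf",
        forward=_boltzmann(half_mV, slope_mV),
        backward=_const(tau_s),
        tau_min=tau_min,
    )


def _channels(kind: str) -> list[ChannelSpec]:
    # Kinetics chosen so that the spiker reproduces the hallmark
    # spiny-projection-neuron phenotype (silence at rest, long and
    # amplitude-dependent first-spike latency from the slowly inactivating
    # A-current, then repetitive firing) and the pauser fires tonically.
    naf = ChannelSpec(
        name="NaF",
        E_rev=E_NA,
        gates=(
            _tau_inf_gate("m", 3, half_mV=-45.0, slope_mV=5.0, tau_s=1e-4),
            _tau_inf_gate("h", 1, half_mV=-55.0, slope_mV=-7.0, tau_s=1.5e-3),
        ),
    )
    kdr = ChannelSpec(
        name="KDr",
        E_rev=E_K,
        gates=(_tau_inf_gate("n", 2, half_mV=-28.0, slope_mV=9.0, tau_s=3e-3),),
    )
    ka = ChannelSpec(
        name="KA",
        E_rev=E_K,
        gates=(
            _tau_inf_gate("a", 2, half_mV=-42.0, slope_mV=12.0, tau_s=1.5e-3),
            _tau_inf_gate("b", 1, half_mV=-85.0, slope_mV=-6.0, tau_s=50e-3),
        ),
    )
    chans = [naf, kdr, ka]
    if kind == "pauser":
        car = ChannelSpec(
            name="CaR",
            E_rev="calcium-nernst",
            gates=(_tau_inf_gate("c", 2, half_mV=-30.0, slope_mV=8.0, tau_s=1e-3),),
            carries_calcium=True,
        )
        bk = ChannelSpec(
            name="BK",
            E_rev=E_K,
            gates=(
                GateSpec(
                    name="z",
                    power=1,
                    form="calcium-dependent",
                    ca_half=2e-3,  # mM
                    ca_slope=2.0,
                    tau_min=2e-3,
                ),
            ),
        )
        chans += [car, bk]
    return chans


def _morphology() -> list[MorphSegment]:
    # spherical soma (16 µm) and a 3-compartment dendrite (4 µm × 100 µm each)
    return [
        MorphSegment(id="soma", parent=None, length=0.0, diameter=16e-6, is_spherical=True),
        MorphSegment(id="dend1", parent="soma", length=100e-6, diameter=4e-6),
        MorphSegment(id="dend2", parent="dend1", length=100e-6, diameter=4e-6),
        MorphSegment(id="dend3", parent="dend2", length=100e-6, diameter=4e-6),
    ]


# Ground-truth conductance densities (S/m²) per (channel, region).
# Region 0 = soma, 1 = proximal dendrite, 2 = distal.
SPIKER_DENSITIES: dict[tuple[str, int], float] = {
    ("NaF", 0): 3500.0, ("NaF", 1): 120.0, ("NaF", 2): 60.0,
    ("KDr", 0): 600.0, ("KDr", 1): 60.0, ("KDr", 2): 30.0,
    ("KA", 0): 300.0, ("KA", 1): 100.0, ("KA", 2): 50.0,
}
PAUSER_DENSITIES: dict[tuple[str, int], float] = {
    ("NaF", 0): 2200.0, ("NaF", 1): 150.0, ("NaF", 2): 80.0,
    ("KDr", 0): 900.0, ("KDr", 1): 90.0, ("KDr", 2): 40.0,
    ("KA", 0): 200.0, ("KA", 1): 60.0, ("KA", 2): 30.0,
    ("CaR", 0): 40.0, ("CaR", 1): 20.0, ("CaR", 2): 10.0,
    ("BK", 0): 100.0, ("BK", 1): 33.0, ("BK", 2): 16.0,
}


def make_reference_neuron(kind: str) -> NeuronSpec:
    """Build the shipped ground-truth model of the given ``kind``."""
    if kind not in ("spiker", "pauser"):
        raise ValueError(f"unknown reference kind {kind!r}")
    passive = PassiveSpec(
        RM=1.0,        # Ω·m²
        CM=0.01,       # F/m²
        RA=1.0,        # Ω·m
        E_leak=-0.080 if kind == "spiker" else -0.045,
    )
    calcium = CalciumSpec(
        tau_ca=0.02, B_ca=3e6, ca_base=5e-5, enabled=(kind == "pauser")
    )
    return NeuronSpec(
        morphology=_morphology(),
        region_thresholds=(60e-6, 180e-6),
        channels=_channels(kind),
        conductances=dict(SPIKER_DENSITIES if kind == "spiker" else PAUSER_DENSITIES),
        passive=passive,
        calcium=calcium,
    )


def reference_protocols(kind: str) -> list[StimulusProtocol]:
    """Default current-clamp protocol families for each reference kind.

    The spiker is probed like a striatal projection neuron (400 ms steps:
    one hyperpolarizing, one subthreshold and two suprathreshold
    depolarizing); the pauser like a pallidal neuron (1 s hyperpolarizing
    steps plus a zero-current trace capturing spontaneous firing).
    """
    if kind == "spiker":
        onset, offset, dur = 0.05, 0.45, 0.5
        amps = [-100e-12, 80e-12, 180e-12, 220e-12]
        return [
            StimulusProtocol(a, onset, offset, dur, label=f"inj{int(a * 1e12):+d}pA")
            for a in amps
        ]
    onset, offset, dur = 0.1, 1.1, 1.2
    protos = [
        StimulusProtocol(a, onset, offset, dur, label=f"inj{int(a * 1e12):+d}pA")
        for a in (-200e-12, -100e-12)
    ]
    protos.append(StimulusProtocol(0.0, onset, offset, dur, label="inj+0pA"))
    return protos


def meta_for_protocol(p: StimulusProtocol, sampling_rate: float = 1e4) -> ProtocolMeta:
    """Measurement windows derived from the protocol timing."""
    span = p.offset - p.onset
    return ProtocolMeta(
        injection_start=p.onset,
        injection_end=p.offset,
        injection_amplitude=p.amplitude,
        baseline_pre=(0.0, max(p.onset - 0.005, p.onset * 0.5)),
        baseline_post=(min(p.offset + 0.02, p.duration), p.duration),
        steady_state=(p.onset + 0.75 * span, p.offset - 0.01 * span),
        sampling_rate=sampling_rate,
        label=p.label,
    )


def reference_metas(kind: str) -> list[ProtocolMeta]:
    return [meta_for_protocol(p) for p in reference_protocols(kind)]


def generate_recordings(
    neuron: NeuronSpec,
    protocols: Sequence[StimulusProtocol],
    noise_sd: float = 0.5e-3,
    seed: int = 0,
    out_dir: Optional[Path | str] = None,
    sim_config: SimConfig = SimConfig(),
    neuron_label: str = "synthetic",
) -> TraceSet:
    """Simulate protocols and add seeded Gaussian noise; optionally save."""
    traces = run_protocol_set(neuron, list(protocols), sim_config)
    rng = np.random.default_rng(seed)
    members = []
    for trace, proto in zip(traces, protocols):
        if noise_sd > 0:
            trace.Vm = trace.Vm + rng.normal(0.0, noise_sd, size=len(trace.Vm))
        meta = meta_for_protocol(proto, sampling_rate=1.0 / sim_config.record_dt)
        members.append((trace, meta))
    out = TraceSet(members=members, neuron=neuron_label)
    if out_dir is not None:
        save_trace_set(out, out_dir)
    return out


def default_recovery_params(kind: str = "spiker") -> ParamSet:
    """The standard recovery problem: somatic spiking densities plus RM.

    Truth values sit strictly inside the bounds; initial values are
    deliberately displaced from the truth.
    """
    truth = SPIKER_DENSITIES if kind == "spiker" else PAUSER_DENSITIES
    return ParamSet(
        [
            ParamDef("NaF_0", initial=2000.0, min=200.0, max=6000.0),
            ParamDef("KDr_0", initial=1000.0, min=50.0, max=2500.0),
            ParamDef("KA_0", initial=600.0, min=20.0, max=1500.0),
            ParamDef("RM", initial=2.0, min=0.2, max=4.0),
        ]
    )


@dataclass
class RecoveryConfig:
    kind: str = "spiker"
    params: Optional[ParamSet] = None
    protocols: Optional[list[StimulusProtocol]] = None
    weights: FeatureWeights = field(default_factory=lambda: dict(SPN_WEIGHTS))
    noise_sd: float = 0.0
    seeds: tuple[int, ...] = (0, 1, 2)
    generations: int = 50
    popsize: int = 8
    sigma0: float = 0.3
    sim_config: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if self.params is None:
            self.params = default_recovery_params(self.kind)
        if self.protocols is None:
            self.protocols = reference_protocols(self.kind)


@dataclass
class RecoveryResult:
    truth: dict[str, float]
    per_seed: list[dict]
    histories: list[FitHistory]

    @property
    def median_best_fitness(self) -> float:
        return float(np.median([s["best_fitness"] for s in self.per_seed]))

    def median_relative_error(self, name: str) -> float:
        return float(np.median([s["relative_error"][name] for s in self.per_seed]))


def _truth_values(neuron: NeuronSpec, params: ParamSet) -> dict[str, float]:
    from .model_spec import PASSIVE_NAMES, split_param_name

    out = {}
    for p in params:
        base, region = split_param_name(p.name)
        if p.name in PASSIVE_NAMES:
            out[p.name] = getattr(neuron.passive, p.name)
        elif region is not None:
            out[p.name] = neuron.density(base, region)
        else:
            out[p.name] = neuron.density(p.name, 0)
    return out


def recovery_experiment(
    config: RecoveryConfig, store_root: Path | str = "recovery-runs"
) -> RecoveryResult:
    """Fit the free parameters back to synthetic recordings of the truth model.

    One optimization per seed; reports best fitness and per-parameter
    relative recovery error for each seed (medians via the result object).
    """
    neuron = make_reference_neuron(config.kind)
    truth = _truth_values(neuron, config.params)
    for name, value in truth.items():
        p = config.params.get(name)
        if not p.min < value < p.max:
            raise ValueError(f"truth value for {name} not strictly inside bounds")
    store_root = Path(store_root)
    per_seed, histories = [], []
    for seed in config.seeds:
        data = generate_recordings(
            neuron,
            config.protocols,
            noise_sd=config.noise_sd,
            seed=seed,
            sim_config=config.sim_config,
        )
        history = do_fit(
            neuron,
            data,
            config.params,
            config.weights,
            generations=config.generations,
            popsize=config.popsize,
            seed=seed,
            store_dir=store_root / f"seed{seed}",
            sigma0=config.sigma0,
            sim_config=config.sim_config,
            save_traces=False,
        )
        best = history.best
        rel_err = {
            name: abs(best.params[name] - truth[name]) / abs(truth[name])
            for name in truth
        }
        per_seed.append(
            {
                "seed": seed,
                "best_fitness": best.fitness,
                "best_params": dict(best.params),
                "relative_error": rel_err,
            }
        )
        histories.append(history)
    return RecoveryResult(truth=truth, per_seed=per_seed, histories=histories)
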
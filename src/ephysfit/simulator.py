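"""Multi-compartment cable-equation integrator for current-clamp protocols.

The membrane equation on the compartment tree is advanced with a backward
(implicit) Euler step: channel conductances are frozen at the current gate
states, the resulting symmetric tree-structured linear system is solved
exactly per step by Hines-ordered elimination, and gate variables are then
advanced by the exponential update x ← x_inf + (x − x_inf)·exp(−dt/τ)
evaluated at the freshly solved voltages.  An optional single-exponential
calcium pool per compartment receives the calcium current and relaxes to
its resting concentration.

The inner loop is compiled with numba; the model is first flattened into
plain arrays (:func:`build_sim_model`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .model_spec import (
    CALCIUM_NERNST,
    NeuronSpec,
    assign_regions,
    gate_equilibrium,
)

__all__ = [
    "StimulusProtocol",
    "SimConfig",
    "Trace",
    "SimulationError",
    "initialize_state",
    "run",
    "run_protocol_set",
]

# Nernst constants for the calcium reversal: RT/2F at ~305 K, external Ca 2 mM
_RT_2F = 8.314462618 * 305.0 / (2 * 96485.332)
_CA_OUT = 2.0  # mM
_CA_FLOOR = 1e-8  # mM, floor inside the Nernst log

FORM_ALPHA_BETA = 0
FORM_TAU_INF = 1
FORM_CALCIUM = 2


class SimulationError(RuntimeError):
    """Integration produced a non-finite state; carries the step index."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite membrane state at integration step {step}")


@dataclass(frozen=True)
class StimulusProtocol:
    """A square current-injection step within a recording of ``duration``."""

    amplitude: float  # A
    onset: float      # s
    offset: float     # s
    duration: float   # s
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.onset < self.offset <= self.duration):
            raise ValueError("protocol requires 0 <= onset < offset <= duration")


@dataclass(frozen=True)
class SimConfig:
    dt: float = 10e-6          # s, integration step
    record_dt: float = 100e-6  # s, output sampling interval
    V_init: Optional[float] = None  # default: leak reversal
    injection_site: Optional[str] = None  # segment id; default: root (soma)
    record_all: bool = False   # keep per-compartment Vm and Ca

    def __post_init__(self):
        if not 0 < self.dt <= self.record_dt:
            raise ValueError("require 0 < dt <= record_dt")


@dataclass
class Trace:
    """A membrane-potential time series recorded at the soma."""

    times: np.ndarray
    Vm: np.ndarray
    protocol: Optional[StimulusProtocol] = None
    Vm_all: Optional[np.ndarray] = None  # (ncomp, nt)
    Ca_all: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.Vm = np.asarray(self.Vm, dtype=float)
        if self.times.shape != self.Vm.shape:
            raise ValueError("times and Vm must have equal length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def __len__(self):
        return len(self.times)


# ---------------------------------------------------------------------------
# model flattening
# ---------------------------------------------------------------------------

@dataclass
class SimModel:
    """A NeuronSpec flattened to contiguous arrays for the compiled kernel."""

    neuron: NeuronSpec
    seg_ids: list[str]
    parent: np.ndarray        # int32, -1 for root
    area: np.ndarray          # m²
    cm: np.ndarray            # F per compartment
    g_leak: np.ndarray        # S per compartment
    g_ax: np.ndarray          # S, coupling to parent (0 at root)
    E_leak: float
    gbar: np.ndarray          # (ncomp, nchan) S
    e_rev: np.ndarray         # (nchan,)
    chan_nernst: np.ndarray   # bool per channel
    chan_carries_ca: np.ndarray
    gate_channel: np.ndarray  # (ngate,) channel index
    gate_power: np.ndarray
    gate_form: np.ndarray
    gate_fwd: np.ndarray      # (ngate, 5)
    gate_bwd: np.ndarray
    gate_tau_min: np.ndarray
    gate_ca_half: np.ndarray
    gate_ca_slope: np.ndarray
    ca_enabled: bool
    ca_tau: float
    ca_B: float
    ca_base: float


def _half_axial_resistance(length, diameter, RA, spherical) -> float:
    radius = diameter / 2.0
    eff_len = radius if spherical else length / 2.0
    return RA * eff_len / (math.pi * radius * radius)


def segment_area(length: float, diameter: float, spherical: bool) -> float:
    """Membrane area: π·d² for a sphere, π·d·L for a cylinder."""
    if spherical:
        return math.pi * diameter * diameter
    return math.pi * diameter * length


def build_sim_model(neuron: NeuronSpec) -> SimModel:
    morph = neuron.morphology
    index = {seg.id: i for i, seg in enumerate(morph)}
    # require parents to precede children (Hines ordering); reorder if needed
    order = []
    placed = set()
    pending = list(morph)
    while pending:
        progressed = False
        rest = []
        for seg in pending:
            if seg.parent is None or seg.parent in placed:
                order.append(seg)
                placed.add(seg.id)
                progressed = True
            else:
                rest.append(seg)
        if not progressed:
            raise ValueError("morphology is not a tree")
        pending = rest
    morph = order
    index = {seg.id: i for i, seg in enumerate(morph)}
    n = len(morph)
    regions = assign_regions(morph, neuron.region_thresholds)
    passive = neuron.passive

    parent = np.full(n, -1, dtype=np.int64)
    area = np.zeros(n)
    g_ax = np.zeros(n)
    for i, seg in enumerate(morph):
        area[i] = segment_area(seg.length, seg.diameter, seg.is_spherical)
        if seg.parent is not None:
            j = index[seg.parent]
            parent[i] = j
            pseg = morph[j]
            r = _half_axial_resistance(
                seg.length, seg.diameter, passive.RA, seg.is_spherical
            ) + _half_axial_resistance(
                pseg.length, pseg.diameter, passive.RA, pseg.is_spherical
            )
            g_ax[i] = 1.0 / r
    cm = passive.CM * area
    g_leak = area / passive.RM

    chans = neuron.channels
    nchan = len(chans)
    gbar = np.zeros((n, nchan))
    e_rev = np.zeros(nchan)
    chan_nernst = np.zeros(nchan, dtype=np.bool_)
    chan_carries = np.zeros(nchan, dtype=np.bool_)
    gate_rows = []
    for c_idx, chan in enumerate(chans):
        if chan.E_rev == CALCIUM_NERNST:
            chan_nernst[c_idx] = True
        else:
            e_rev[c_idx] = float(chan.E_rev)
        chan_carries[c_idx] = chan.carries_calcium
        for i in range(n):
            gbar[i, c_idx] = neuron.density(chan.name, regions[i]) * area[i]
        for g in chan.gates:
            form = {"alpha-beta": FORM_ALPHA_BETA, "tau-inf": FORM_TAU_INF,
                    "calcium-dependent": FORM_CALCIUM}[g.form]
            fwd = g.forward
            bwd = g.backward
            gate_rows.append((
                c_idx, g.power, form,
                [fwd.A, fwd.B, fwd.C, fwd.D, fwd.F] if fwd else [0, 0, 1, 0, 1],
                [bwd.A, bwd.B, bwd.C, bwd.D, bwd.F] if bwd else [0, 0, 1, 0, 1],
                g.tau_min, g.ca_half, g.ca_slope,
            ))
    ngate = len(gate_rows)
    return SimModel(
        neuron=neuron,
        seg_ids=[s.id for s in morph],
        parent=parent,
        area=area,
        cm=cm,
        g_leak=g_leak,
        g_ax=g_ax,
        E_leak=passive.E_leak,
        gbar=gbar,
        e_rev=e_rev,
        chan_nernst=chan_nernst,
        chan_carries_ca=chan_carries,
        gate_channel=np.array([r[0] for r in gate_rows], dtype=np.int64),
        gate_power=np.array([r[1] for r in gate_rows], dtype=np.int64),
        gate_form=np.array([r[2] for r in gate_rows], dtype=np.int64),
        gate_fwd=np.array([r[3] for r in gate_rows], dtype=float).reshape(ngate, 5),
        gate_bwd=np.array([r[4] for r in gate_rows], dtype=float).reshape(ngate, 5),
        gate_tau_min=np.array([r[5] for r in gate_rows], dtype=float),
        gate_ca_half=np.array([r[6] for r in gate_rows], dtype=float),
        gate_ca_slope=np.array([r[7] for r in gate_rows], dtype=float),
        ca_enabled=neuron.calcium.enabled,
        ca_tau=neuron.calcium.tau_ca,
        ca_B=neuron.calcium.B_ca,
        ca_base=neuron.calcium.ca_base,
    )


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rate(A, B, C, D, F, V):
    arg = (V + D) / F
    if arg > 700.0:
        arg = 700.0
    denom = C + math.exp(arg)
    if abs(denom) < 1e-9:
        lo_arg = (V - 1e-5 + D) / F
        hi_arg = (V + 1e-5 + D) / F
        if lo_arg > 700.0:
            lo_arg = 700.0
        if hi_arg > 700.0:
            hi_arg = 700.0
        lo = (A + B * (V - 1e-5)) / (C + math.exp(lo_arg))
        hi = (A + B * (V + 1e-5)) / (C + math.exp(hi_arg))
        return 0.5 * (lo + hi)
    return (A + B * V) / denom


@njit(cache=True)
def _gate_xinf_tau(form, fwd, bwd, tau_min, ca_half, ca_slope, V, Ca):
    if form == 0:  # alpha-beta
        a = _rate(fwd[0], fwd[1], fwd[2], fwd[3], fwd[4], V)
        b = _rate(bwd[0], bwd[1], bwd[2], bwd[3], bwd[4], V)
        s = a + b
        if s <= 0.0:
            return 0.5, tau_min
        tau = 1.0 / s
        if tau < tau_min:
            tau = tau_min
        return a / s, tau
    elif form == 1:  # tau-inf
        xinf = _rate(fwd[0], fwd[1], fwd[2], fwd[3], fwd[4], V)
        if xinf < 0.0:
            xinf = 0.0
        elif xinf > 1.0:
            xinf = 1.0
        tau = _rate(bwd[0], bwd[1], bwd[2], bwd[3], bwd[4], V)
        if tau < tau_min:
            tau = tau_min
        return xinf, tau
    else:  # calcium-dependent Hill activation
        c = Ca
        if c < 0.0:
            c = 0.0
        can = c ** ca_slope
        half = ca_half ** ca_slope
        return can / (can + half), tau_min


@njit(cache=True)
def _integrate(
    parent, cm, g_leak, g_ax, E_leak,
    gbar, e_rev, chan_nernst, chan_carries_ca,
    gate_channel, gate_power, gate_form, gate_fwd, gate_bwd,
    gate_tau_min, gate_ca_half, gate_ca_slope,
    ca_enabled, ca_tau, ca_B, ca_base,
    V, x, Ca,
    dt, nsteps, inj_comp, amplitude, onset_step, offset_step,
    stride, out_V, out_all_V, out_all_Ca, record_all,
):
    n = V.shape[0]
    nchan = gbar.shape[1]
    ngate = gate_channel.shape[0]
    diag = np.empty(n)
    rhs = np.empty(n)
    g_chan = np.empty(nchan)
    nrec = 0
    for step in range(nsteps):
        # channel conductances from current gate states, then implicit solve
        for i in range(n):
            for c in range(nchan):
                g_chan[c] = gbar[i, c]
            for g in range(ngate):
                c = gate_channel[g]
                if gbar[i, c] > 0.0:
                    xv = x[i, g]
                    p = gate_power[g]
                    for _ in range(p):
                        g_chan[c] *= xv
            gtot = g_leak[i]
            gE = g_leak[i] * E_leak
            for c in range(nchan):
                if g_chan[c] > 0.0:
                    gtot += g_chan[c]
                    if chan_nernst[c]:
                        cai = Ca[i]
                        if cai < 1e-8:
                            cai = 1e-8
                        E = _RT_2F * math.log(_CA_OUT / cai)
                    else:
                        E = e_rev[c]
                    gE += g_chan[c] * E
            diag[i] = cm[i] / dt + gtot
            rhs[i] = cm[i] / dt * V[i] + gE
        if onset_step <= step < offset_step:
            rhs[inj_comp] += amplitude
        for i in range(n):
            if parent[i] >= 0:
                diag[i] += g_ax[i]
                diag[parent[i]] += g_ax[i]
        # Hines elimination: children have larger indices than parents
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / diag[i]
            diag[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        V[0] = rhs[0] / diag[0]
        for i in range(1, n):
            V[i] = (rhs[i] + g_ax[i] * V[parent[i]]) / diag[i]
        # gate update (exponential integrator) at the new voltages
        for i in range(n):
            for g in range(ngate):
                xinf, tau = _gate_xinf_tau(
                    gate_form[g], gate_fwd[g], gate_bwd[g],
                    gate_tau_min[g], gate_ca_half[g], gate_ca_slope[g],
                    V[i], Ca[i],
                )
                x[i, g] = xinf + (x[i, g] - xinf) * math.exp(-dt / tau)
        # calcium pool
        if ca_enabled:
            for i in range(n):
                I_ca = 0.0
                for c in range(nchan):
                    if chan_carries_ca[c] and gbar[i, c] > 0.0:
                        gc = gbar[i, c]
                        for g in range(ngate):
                            if gate_channel[g] == c:
                                xv = x[i, g]
                                for _ in range(gate_power[g]):
                                    gc *= xv
                        cai = Ca[i]
                        if cai < 1e-8:
                            cai = 1e-8
                        if chan_nernst[c]:
                            E = _RT_2F * math.log(_CA_OUT / cai)
                        else:
                            E = e_rev[c]
                        I_ca += gc * (V[i] - E)
                # inward calcium current (negative) raises [Ca]
                ca_inf = ca_base + ca_tau * ca_B * (-I_ca)
                Ca[i] = ca_inf + (Ca[i] - ca_inf) * math.exp(-dt / ca_tau)
                if Ca[i] < 0.0:
                    Ca[i] = 0.0
        if (step + 1) % stride == 0:
            if not math.isfinite(V[0]):
                return step
            out_V[nrec] = V[0]
            if record_all:
                for i in range(n):
                    out_all_V[i, nrec] = V[i]
                    out_all_Ca[i, nrec] = Ca[i]
            nrec += 1
    for i in range(n):
        if not math.isfinite(V[i]):
            return nsteps - 1
    return -1


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class State:
    V: np.ndarray
    x: np.ndarray   # (ncomp, ngate)
    Ca: np.ndarray


def initialize_state(model: SimModel | NeuronSpec, V_init: float) -> State:
    """Uniform voltage, gates at x_inf(V_init, ca_base), calcium at rest."""
    if isinstance(model, NeuronSpec):
        model = build_sim_model(model)
    n = len(model.seg_ids)
    ngate = len(model.gate_channel)
    V = np.full(n, V_init, dtype=float)
    Ca = np.full(n, model.ca_base, dtype=float)
    x = np.zeros((n, ngate))
    for g in range(ngate):
        xinf, _ = _gate_xinf_tau(
            model.gate_form[g], model.gate_fwd[g], model.gate_bwd[g],
            model.gate_tau_min[g], model.gate_ca_half[g], model.gate_ca_slope[g],
            V_init, model.ca_base,
        )
        x[:, g] = xinf
    return State(V=V, x=x, Ca=Ca)


def run(
    neuron: NeuronSpec | SimModel,
    protocol: StimulusProtocol,
    config: SimConfig = SimConfig(),
) -> Trace:
    """Simulate one current-clamp protocol and return the somatic trace."""
    model = neuron if isinstance(neuron, SimModel) else build_sim_model(neuron)
    if config.dt > 100e-6:
        import warnings

        warnings.warn(f"integration step dt={config.dt:g}s is large (> 100 µs)")
    V_init = config.V_init if config.V_init is not None else model.E_leak
    state = initialize_state(model, V_init)
    dt = config.dt
    stride = max(1, int(round(config.record_dt / dt)))
    nsteps = int(round(protocol.duration / dt))
    nrec = nsteps // stride
    inj_comp = 0
    if config.injection_site is not None:
        inj_comp = model.seg_ids.index(config.injection_site)
    out_V = np.empty(nrec)
    if config.record_all:
        out_all_V = np.empty((len(model.seg_ids), nrec))
        out_all_Ca = np.empty((len(model.seg_ids), nrec))
    else:
        out_all_V = np.empty((1, 1))
        out_all_Ca = np.empty((1, 1))
    bad = _integrate(
        model.parent, model.cm, model.g_leak, model.g_ax, model.E_leak,
        model.gbar, model.e_rev, model.chan_nernst, model.chan_carries_ca,
        model.gate_channel, model.gate_power, model.gate_form,
        model.gate_fwd, model.gate_bwd,
        model.gate_tau_min, model.gate_ca_half, model.gate_ca_slope,
        model.ca_enabled, model.ca_tau, model.ca_B, model.ca_base,
        state.V, state.x, state.Ca,
        dt, nsteps, inj_comp, protocol.amplitude,
        int(round(protocol.onset / dt)), int(round(protocol.offset / dt)),
        stride, out_V, out_all_V, out_all_Ca, config.record_all,
    )
    if bad >= 0:
        raise SimulationError(bad)
    times = (np.arange(1, nrec + 1) * stride) * dt
    return Trace(
        times=times,
        Vm=out_V,
        protocol=protocol,
        Vm_all=out_all_V if config.record_all else None,
        Ca_all=out_all_Ca if config.record_all else None,
    )


def run_protocol_set(
    neuron: NeuronSpec | SimModel,
    protocols: list[StimulusProtocol],
    config: SimConfig = SimConfig(),
) -> list[Trace]:
    """Run several independent protocols (state re-initialized for each)."""
    if not protocols:
        raise ValueError("at least one protocol required")
    model = neuron if isinstance(neuron, SimModel) else build_sim_model(neuron)
    return [run(model, p, config) for p in protocols]
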
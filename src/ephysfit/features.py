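"""Spiking and subthreshold feature extraction from current-clamp traces.

Spike threshold follows the derivative criterion: the point on the
upstroke where dV/dt first exceeds 5% of its maximum (taken per spike).
Spike height is peak minus threshold; spike width is full width at half
height with linear interpolation on both flanks.  Subthreshold features
(baselines, steady-state response, sag/rectification, falling-curve time
constant, charging curve) are measured inside the windows declared in the
recording's protocol metadata.

Features that a trace cannot define (no spikes; wrong injection polarity)
are ``None`` — the fitness layer skips them rather than scoring zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .simulator import Trace
from .trace_io import ProtocolMeta

__all__ = [
    "SpikeConfig",
    "SpikeEvent",
    "FeatureVector",
    "detect_spikes",
    "subthreshold_features",
    "spike_features",
    "extract_features",
    "HIST_BINS",
    "HIST_RANGE",
    "CURVE_POINTS",
]

HIST_BINS = 64
HIST_RANGE = (-0.1, 0.05)  # V, span of the membrane-potential occupancy histogram
CURVE_POINTS = 20          # resampled length of AHP and charging curves


@dataclass(frozen=True)
class SpikeConfig:
    peak_min: float = -0.01       # V, minimum peak height to count as a spike
    refractory: float = 2e-3      # s, minimum peak separation
    threshold_fraction: float = 0.05  # of max dV/dt on the upstroke
    ahp_window: float = 20e-3     # s, fallback AHP window after the peak


@dataclass
class SpikeEvent:
    peak_time: float
    peak_index: int
    threshold_time: float
    threshold_V: float
    peak_V: float
    height: float
    width: float
    ahp_min_V: Optional[float]
    ahp_samples: Optional[np.ndarray]  # Vm at CURVE_POINTS normalized times


@dataclass
class FeatureVector:
    """Named features of one trace; undefined entries are ``None``."""

    baseline_pre: Optional[float] = None
    baseline_post: Optional[float] = None
    voltage_response: Optional[float] = None   # steady-state response re baseline
    rectification: Optional[float] = None
    falling_curve: Optional[float] = None      # time constant, s
    charging_curve: Optional[np.ndarray] = None
    latency: Optional[float] = None
    spike_count: Optional[int] = None
    spike_times: Optional[np.ndarray] = None   # s, relative to injection onset
    spike_width: Optional[np.ndarray] = None   # per-spike widths, s
    spike_height: Optional[np.ndarray] = None  # per-spike heights, V
    ahp_depth: Optional[float] = None
    ahp_curve: Optional[np.ndarray] = None
    histogram: Optional[np.ndarray] = None

    def defined(self) -> list[str]:
        return [k for k, v in vars(self).items() if v is not None]


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_spikes(trace: Trace, cfg: SpikeConfig = SpikeConfig()) -> list[SpikeEvent]:
    """Detect action potentials; empty list when the trace never spikes."""
    V = trace.Vm
    t = trace.times
    if len(V) < 5:
        return []
    dt = trace.dt
    distance = max(1, int(round(cfg.refractory / dt)))
    peaks, _ = find_peaks(V, height=cfg.peak_min, distance=distance)
    if len(peaks) == 0:
        return []
    dVdt = np.gradient(V, t)
    events: list[SpikeEvent] = []
    for k, pk in enumerate(peaks):
        seg_start = peaks[k - 1] if k > 0 else 0
        # upstroke begins at the voltage minimum between spikes
        seg_start = seg_start + int(np.argmin(V[seg_start:pk + 1]))
        upstroke = dVdt[seg_start:pk + 1]
        if len(upstroke) < 2:
            continue
        rate_thresh = cfg.threshold_fraction * np.max(upstroke)
        # last sample before the peak where dV/dt first exceeds the threshold:
        # scan backward until the rate drops below it
        thr_idx = seg_start
        for i in range(pk - 1, seg_start - 1, -1):
            if dVdt[i] < rate_thresh:
                thr_idx = i + 1
                break
        thr_V = V[thr_idx]
        peak_V = V[pk]
        height = peak_V - thr_V
        if height <= 0:
            continue
        half = thr_V + height / 2.0
        # rising-flank crossing
        t_rise = t[thr_idx]
        for i in range(thr_idx, pk):
            if V[i] <= half <= V[i + 1]:
                t_rise = _interp_crossing(t[i], t[i + 1], V[i], V[i + 1], half)
                break
        # falling-flank crossing
        seg_end = peaks[k + 1] if k + 1 < len(peaks) else len(V) - 1
        t_fall = t[min(pk + 1, len(t) - 1)]
        fell = False
        for i in range(pk, seg_end):
            if V[i] >= half >= V[i + 1]:
                t_fall = _interp_crossing(t[i], t[i + 1], V[i], V[i + 1], half)
                fell = True
                break
        width = max(t_fall - t_rise, dt) if fell else cfg.refractory
        # AHP window: from the peak to the next upward threshold crossing
        # (capped at the next peak), or a fixed window after the last spike
        cap = peaks[k + 1] if k + 1 < len(peaks) else min(
            pk + int(round(cfg.ahp_window / dt)), len(V) - 1
        )
        ahp_end = cap
        below = False
        for i in range(pk + 1, cap):
            if V[i] < thr_V:
                below = True
            elif below and V[i] >= thr_V:
                ahp_end = i
                break
        if ahp_end > pk + 1:
            seg = V[pk:ahp_end + 1]
            ahp_min = float(np.min(seg))
            pts = np.linspace(0, len(seg) - 1, CURVE_POINTS)
            ahp_samples = np.interp(pts, np.arange(len(seg)), seg)
        else:
            ahp_min = None
            ahp_samples = None
        events.append(
            SpikeEvent(
                peak_time=float(t[pk]),
                peak_index=int(pk),
                threshold_time=float(t[thr_idx]),
                threshold_V=float(thr_V),
                peak_V=float(peak_V),
                height=float(height),
                width=float(width),
                ahp_min_V=ahp_min,
                ahp_samples=ahp_samples,
            )
        )
    return events


def _window_mean(trace: Trace, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    if not mask.any():
        raise ValueError(f"metadata window {window} outside trace time base")
    return float(np.mean(trace.Vm[mask]))


def subthreshold_features(
    trace: Trace,
    meta: ProtocolMeta,
    spikes: Optional[list[SpikeEvent]] = None,
) -> FeatureVector:
    """Baselines, steady-state response, rectification, falling-curve τ, charging curve."""
    fv = FeatureVector()
    fv.baseline_pre = _window_mean(trace, meta.baseline_pre)
    fv.baseline_post = _window_mean(trace, meta.baseline_post)
    v_ss = _window_mean(trace, meta.steady_state)
    fv.voltage_response = v_ss - fv.baseline_pre
    t, V = trace.times, trace.Vm
    onset, offset = meta.injection_start, meta.injection_end
    inj_mask = (t >= onset) & (t <= offset)
    if meta.injection_amplitude < 0 and inj_mask.any():
        v_min = float(np.min(V[inj_mask]))
        # sag: steady state minus minimum deflection, both re baseline
        fv.rectification = (v_ss - fv.baseline_pre) - (v_min - fv.baseline_pre)
        # falling-curve time constant: single-exponential fit from onset to
        # the time of minimum Vm
        idx = np.flatnonzero(inj_mask)
        min_idx = idx[int(np.argmin(V[idx]))]
        start = int(np.searchsorted(t, onset))
        if min_idx - start >= 4:
            tt = t[start:min_idx + 1] - t[start]
            vv = V[start:min_idx + 1]
            span = vv[-1] - vv[0]
            try:
                popt, _ = curve_fit(
                    lambda x, v_inf, amp, tau: v_inf + amp * np.exp(-x / tau),
                    tt, vv,
                    p0=(vv[-1], -span if span != 0 else -1e-3, max(tt[-1] / 3, 1e-4)),
                    bounds=([-1.0, -1.0, 1e-5], [1.0, 1.0, 10.0]),
                    maxfev=5000,
                )
                fv.falling_curve = float(popt[2])
            except (RuntimeError, ValueError):
                pass
    if meta.injection_amplitude > 0:
        if spikes is None:
            spikes = detect_spikes(trace)
        in_window = [s for s in spikes if onset <= s.threshold_time <= offset]
        end = in_window[0].threshold_time if in_window else meta.steady_state[0]
        mask = (t >= onset) & (t <= end)
        if mask.sum() >= 2:
            seg = V[mask]
            pts = np.linspace(0, len(seg) - 1, CURVE_POINTS)
            fv.charging_curve = np.interp(pts, np.arange(len(seg)), seg)
    return fv


def spike_features(
    spikes: list[SpikeEvent], trace: Trace, meta: ProtocolMeta
) -> FeatureVector:
    """Spike-train features; histogram of Vm occupancy during injection."""
    fv = FeatureVector()
    onset, offset = meta.injection_start, meta.injection_end
    fv.spike_count = len(spikes)
    if spikes:
        fv.spike_times = np.array([s.peak_time - onset for s in spikes])
        fv.spike_width = np.array([s.width for s in spikes])
        fv.spike_height = np.array([s.height for s in spikes])
        first = spikes[0]
        if first.threshold_time >= onset:
            fv.latency = first.threshold_time - onset
        depths = [s.threshold_V - s.ahp_min_V for s in spikes if s.ahp_min_V is not None]
        if depths:
            fv.ahp_depth = float(np.mean(depths))
        curves = [s.ahp_samples for s in spikes if s.ahp_samples is not None]
        if curves:
            fv.ahp_curve = np.mean(np.stack(curves), axis=0)
    mask = (trace.times >= onset) & (trace.times <= offset)
    if mask.any():
        counts, _ = np.histogram(trace.Vm[mask], bins=HIST_BINS, range=HIST_RANGE)
        total = counts.sum()
        fv.histogram = counts / total if total > 0 else None
    return fv


def extract_features(
    trace: Trace, meta: ProtocolMeta, cfg: SpikeConfig = SpikeConfig()
) -> FeatureVector:
    """Full feature vector of one trace (subthreshold + spiking)."""
    spikes = detect_spikes(trace, cfg)
    sub = subthreshold_features(trace, meta, spikes=spikes)
    spk = spike_features(spikes, trace, meta)
    merged = FeatureVector()
    for k, v in vars(sub).items():
        if v is not None:
            setattr(merged, k, v)
    for k, v in vars(spk).items():
        if v is not None:
            setattr(merged, k, v)
    return merged
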
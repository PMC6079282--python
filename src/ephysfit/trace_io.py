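"""Reading and writing current-clamp traces with protocol metadata.

Traces are stored one per CSV file (header ``time,voltage``, seconds and
volts), with a per-directory YAML sidecar (``meta.yaml``) describing each
trace's injection protocol and measurement windows.  Millivolt-scaled
files are auto-detected (|values| > 1 V is not a physiological membrane
potential) and converted with a warning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulator import StimulusProtocol, Trace

__all__ = ["ProtocolMeta", "TraceSet", "read_csv_trace", "write_csv_trace",
           "load_trace_set", "save_trace_set"]

log = logging.getLogger(__name__)

_TIME_JITTER = 1e-6  # s, tolerated non-uniformity of the time base


@dataclass(frozen=True)
class ProtocolMeta:
    """Injection protocol and measurement windows for one recording."""

    injection_start: float            # s
    injection_end: float              # s
    injection_amplitude: float        # A
    baseline_pre: tuple[float, float]      # s
    baseline_post: tuple[float, float]     # s
    steady_state: tuple[float, float]      # s
    sampling_rate: Optional[float] = None  # Hz, for voltage-only files
    label: str = ""

    def __post_init__(self):
        if not self.injection_start < self.injection_end:
            raise ValueError("injection_start must precede injection_end")

    def protocol(self, duration: float) -> StimulusProtocol:
        """The simulator protocol that reproduces this recording."""
        return StimulusProtocol(
            amplitude=self.injection_amplitude,
            onset=self.injection_start,
            offset=self.injection_end,
            duration=duration,
            label=self.label,
        )


@dataclass
class TraceSet:
    """Ordered recordings from one neuron: (Trace, ProtocolMeta) pairs."""

    members: list[tuple[Trace, ProtocolMeta]]
    neuron: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError("TraceSet requires at least one member")

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)


def read_csv_trace(path, meta: Optional[ProtocolMeta] = None) -> Trace:
    """Read one trace CSV (``time,voltage`` or voltage-only + sampling rate)."""
    df = pd.read_csv(path)
    if not np.issubdtype(df.dtypes.iloc[-1], np.number):
        raise ValueError(f"{path}: non-numeric rows in trace file")
    if "time" in df.columns and "voltage" in df.columns:
        times = df["time"].to_numpy(dtype=float)
        volts = df["voltage"].to_numpy(dtype=float)
        dts = np.diff(times)
        if len(dts) and (dts.max() - dts.min()) > _TIME_JITTER:
            raise ValueError(f"{path}: non-uniform time base (jitter > 1 µs)")
    elif "voltage" in df.columns or df.shape[1] == 1:
        if meta is None or meta.sampling_rate is None:
            raise ValueError(f"{path}: voltage-only file requires sampling_rate metadata")
        volts = df.iloc[:, -1].to_numpy(dtype=float)
        times = np.arange(len(volts)) / meta.sampling_rate
    else:
        raise ValueError(f"{path}: expected columns time,voltage")
    if not np.all(np.isfinite(volts)):
        raise ValueError(f"{path}: non-finite voltage samples")
    if np.max(np.abs(volts)) > 1.0:
        log.warning("%s: voltage magnitudes exceed 1; assuming mV and converting to V", path)
        volts = volts * 1e-3
    protocol = None
    if meta is not None:
        duration = float(times[-1]) + (float(times[1] - times[0]) if len(times) > 1 else 0.0)
        if meta.injection_end <= duration:
            protocol = meta.protocol(duration)
    return Trace(times=times, Vm=volts, protocol=protocol)


def write_csv_trace(trace: Trace, path) -> None:
    """Write a trace as ``time,voltage`` CSV; refuses to append to a trace file."""
    path = Path(path)
    if path.exists():
        raise FileExistsError(f"{path} exists; one trace per file")
    df = pd.DataFrame({"time": trace.times, "voltage": trace.Vm})
    df.to_csv(path, index=False, float_format="%.12g")


def _meta_to_dict(meta: ProtocolMeta) -> dict:
    return {
        "injection_start": meta.injection_start,
        "injection_end": meta.injection_end,
        "injection_amplitude": meta.injection_amplitude,
        "baseline_pre": list(meta.baseline_pre),
        "baseline_post": list(meta.baseline_post),
        "steady_state": list(meta.steady_state),
        "sampling_rate": meta.sampling_rate,
        "label": meta.label,
    }


def _meta_from_dict(d: dict) -> ProtocolMeta:
    return ProtocolMeta(
        injection_start=float(d["injection_start"]),
        injection_end=float(d["injection_end"]),
        injection_amplitude=float(d["injection_amplitude"]),
        baseline_pre=tuple(d["baseline_pre"]),
        baseline_post=tuple(d["baseline_post"]),
        steady_state=tuple(d["steady_state"]),
        sampling_rate=d.get("sampling_rate"),
        label=str(d.get("label", "")),
    )


def save_trace_set(traces: TraceSet, directory) -> None:
    """Write a recording directory: one CSV per trace plus ``meta.yaml``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = {}
    for i, (trace, meta) in enumerate(traces):
        name = meta.label or f"trace{i:02d}"
        fname = f"{name}.csv"
        write_csv_trace(trace, directory / fname)
        entries[fname] = _meta_to_dict(meta)
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump({"neuron": traces.neuron, "traces": entries}, fh, sort_keys=False)


def load_trace_set(directory) -> TraceSet:
    """Read a recording directory written by :func:`save_trace_set`."""
    directory = Path(directory)
    with open(directory / "meta.yaml") as fh:
        doc = yaml.safe_load(fh)
    members = []
    for fname, meta_doc in doc["traces"].items():
        meta = _meta_from_dict(meta_doc)
        members.append((read_csv_trace(directory / fname, meta), meta))
    return TraceSet(members=members, neuron=str(doc.get("neuron", "")))
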
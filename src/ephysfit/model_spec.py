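"""Declarative specification of multi-compartment conductance-based neuron models.

A model is assembled from small, independently specified pieces: ion-channel
kinetics (Hodgkin–Huxley gates parameterized by the classic five-parameter
rate function), a morphology (GENESIS ``.p`` or SWC), per-region maximal
conductance densities, passive membrane properties, and an optional
single-time-constant calcium pool.  Everything is stored in SI units
internally (volts, seconds, amperes, S/m², F/m², Ω·m², Ω·m; calcium in mM);
morphology files use µm and are converted at parse time.

The tunable surface of a model is an ordered :class:`ParamSet` of named,
bounded parameters.  Names are either channel names (optionally suffixed
``_0``/``_1``/``_2`` to address one of the three neuron regions: soma,
proximal, distal) or passive names (``RM``, ``CM``, ``RA``, ``E_leak``).
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import yaml

__all__ = [
    "GateRateSpec",
    "GateSpec",
    "ChannelSpec",
    "MorphSegment",
    "PassiveSpec",
    "CalciumSpec",
    "NeuronSpec",
    "ParamDef",
    "ParamSet",
    "rate_value",
    "gate_equilibrium",
    "parse_p_file",
    "write_p_file",
    "parse_swc",
    "write_swc",
    "assign_regions",
    "apply_params",
    "load_neuron",
    "save_neuron",
]

PASSIVE_NAMES = ("RM", "CM", "RA", "E_leak")

CALCIUM_NERNST = "calcium-nernst"


class SpecificationError(ValueError):
    """A model file or parameter set violates the declarative contract."""


class ParseError(SpecificationError):
    """A morphology file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# channel kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateRateSpec:
    """Five-parameter rate function (A + B·V) / (C + exp((V + D)/F)).

    A is a rate offset (1/s), B a rate slope (1/(s·V)), C a dimensionless
    denominator offset, D a voltage shift (V) and F a voltage scale (V).
    This single form expresses constant, linear, sigmoid and exponential
    rates, which covers the standard compartmental-modeling channel
    libraries.
    """

    A: float
    B: float
    C: float
    D: float
    F: float

    def __post_init__(self):
        if self.F == 0:
            raise SpecificationError("rate function requires F != 0")


_DENOM_EPS = 1e-9
_SING_DV = 1e-5  # V, offset used to interpolate across a denominator zero


def _rate_raw(spec: GateRateSpec, V: float) -> tuple[float, float]:
    arg = (V + spec.D) / spec.F
    # protect exp from overflow; the denominator then dominates and the
    # rate underflows to 0, which is the correct limit
    arg = min(arg, 700.0)
    denom = spec.C + math.exp(arg)
    return spec.A + spec.B * V, denom


def rate_value(spec: GateRateSpec, V: float) -> float:
    """Evaluate the rate function at membrane potential ``V`` (volts).

    Where the denominator passes through zero (removable singularity for
    the classic linoid form) the value is linearly interpolated from
    ``V ± 10 µV``.
    """
    num, denom = _rate_raw(spec, V)
    if abs(denom) < _DENOM_EPS:
        lo = rate_value(spec, V - _SING_DV)
        hi = rate_value(spec, V + _SING_DV)
        value = 0.5 * (lo + hi)
    else:
        value = num / denom
    if not math.isfinite(value):
        raise SpecificationError(
            f"rate function {spec} is non-finite at V={V:g} V after singularity guarding"
        )
    return value


GATE_FORMS = ("alpha-beta", "tau-inf", "calcium-dependent")


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin–Huxley gating variable x with dx/dt = (x_inf − x)/τ_x.

    ``alpha-beta`` gates derive x_inf = α/(α+β) and τ = 1/(α+β) from the
    forward (α) and backward (β) rate functions.  ``tau-inf`` gates read
    x_inf from the forward function (dimensionless) and τ (seconds) from
    the backward function.  ``calcium-dependent`` gates (e.g. the BK
    channel's activation) use a Hill function of the calcium pool,
    x_inf = Ca^n / (Ca^n + ca_half^n), with a fixed time constant
    ``tau_min``.
    """

    name: str
    power: int
    form: str
    forward: Optional[GateRateSpec] = None
    backward: Optional[GateRateSpec] = None
    ca_half: float = 0.0       # mM
    ca_slope: float = 1.0      # Hill exponent
    tau_min: float = 1e-4      # s, floor on the time constant

    def __post_init__(self):
        if self.form not in GATE_FORMS:
            raise SpecificationError(f"unknown gate form {self.form!r}")
        if self.power < 0:
            raise SpecificationError(f"gate {self.name}: power must be >= 0")
        if self.tau_min <= 0:
            raise SpecificationError(f"gate {self.name}: tau_min must be > 0")
        if self.form == "calcium-dependent":
            if self.ca_half <= 0:
                raise SpecificationError(
                    f"calcium-dependent gate {self.name} requires ca_half > 0"
                )
        elif self.forward is None or self.backward is None:
            raise SpecificationError(
                f"gate {self.name}: form {self.form} requires forward and backward rates"
            )


def gate_equilibrium(gate: GateSpec, V: float, Ca: float = 0.0) -> tuple[float, float]:
    """Return (x_inf, tau) for a gate at voltage ``V`` and calcium ``Ca``."""
    if gate.form == "alpha-beta":
        a = rate_value(gate.forward, V)
        b = rate_value(gate.backward, V)
        s = a + b
        if s <= 0:
            # degenerate: both rates vanish; hold the current state by
            # pinning tau at the floor and x_inf at 1/2 (limit undefined)
            return 0.5, gate.tau_min
        return a / s, max(1.0 / s, gate.tau_min)
    if gate.form == "tau-inf":
        xinf = rate_value(gate.forward, V)
        tau = rate_value(gate.backward, V)
        return min(max(xinf, 0.0), 1.0), max(tau, gate.tau_min)
    # calcium-dependent
    can = max(Ca, 0.0) ** gate.ca_slope
    half = gate.ca_half ** gate.ca_slope
    return can / (can + half), gate.tau_min


@dataclass(frozen=True)
class ChannelSpec:
    """A voltage- (or calcium-) gated channel: reversal potential and gates.

    ``E_rev`` is a reversal potential in volts, or the tag
    ``"calcium-nernst"`` for calcium channels whose reversal follows the
    Nernst potential of the calcium pool.  ``carries_calcium`` marks
    currents that feed the calcium pool.
    """

    name: str
    E_rev: Union[float, str]
    gates: tuple[GateSpec, ...]
    carries_calcium: bool = False

    def __post_init__(self):
        if not self.gates:
            raise SpecificationError(f"channel {self.name}: at least one gate required")
        if isinstance(self.E_rev, str) and self.E_rev != CALCIUM_NERNST:
            raise SpecificationError(
                f"channel {self.name}: E_rev must be a voltage or {CALCIUM_NERNST!r}"
            )


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

@dataclass
class MorphSegment:
    id: str
    parent: Optional[str]       # None for the root
    length: float               # m (0 for a spherical soma)
    diameter: float             # m
    path_distance: float = 0.0  # m, from the soma center to segment midpoint
    is_spherical: bool = False
    kind: Optional[str] = None  # SWC type code, preserved as a label


def _finish_tree(segments: list[MorphSegment]) -> list[MorphSegment]:
    """Validate tree structure and fill in path distances."""
    by_id = {}
    for seg in segments:
        if seg.id in by_id:
            raise ParseError(f"duplicate segment id {seg.id!r}")
        by_id[seg.id] = seg
    roots = [s for s in segments if s.parent is None]
    if len(roots) != 1:
        raise ParseError(f"expected exactly one root segment, found {len(roots)}")
    for seg in segments:
        if seg.diameter <= 0:
            raise ParseError(f"segment {seg.id!r}: non-positive diameter")
        if not seg.is_spherical and seg.length <= 0:
            raise ParseError(f"segment {seg.id!r}: non-positive length")
        if seg.parent is not None and seg.parent not in by_id:
            raise ParseError(f"segment {seg.id!r}: dangling parent {seg.parent!r}")
    # path distance from soma center to segment midpoint, walking the tree;
    # detects cycles as a side effect
    dist_to_end: dict[str, float] = {}

    def end_distance(seg: MorphSegment, stack: set[str]) -> float:
        if seg.id in dist_to_end:
            return dist_to_end[seg.id]
        if seg.id in stack:
            raise ParseError(f"cyclic parent chain through {seg.id!r}")
        stack.add(seg.id)
        base = 0.0 if seg.parent is None else end_distance(by_id[seg.parent], stack)
        d = base + (0.0 if seg.is_spherical else seg.length)
        stack.discard(seg.id)
        dist_to_end[seg.id] = d
        return d

    for seg in segments:
        end = end_distance(seg, set())
        seg.path_distance = end - (0.0 if seg.is_spherical else seg.length / 2.0)
    return segments


def parse_p_file(text: str) -> list[MorphSegment]:
    """Parse a GENESIS ``.p`` morphology (subset).

    Supported: ``//`` comments, ``*relative`` / ``*absolute`` directives,
    and 6-column rows ``name parent x y z diameter`` with coordinates and
    diameters in µm.  A root row with zero extent is a spherical soma.
    """
    relative = True
    positions: dict[str, np.ndarray] = {}
    segments: list[MorphSegment] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("//", 1)[0].strip()
        if not line:
            continue
        if line.startswith("*"):
            directive = line.split()[0]
            if directive == "*relative":
                relative = True
            elif directive == "*absolute":
                relative = False
            else:
                raise ParseError(f"unknown directive {directive!r}", lineno)
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ParseError(f"expected 6 columns, got {len(parts)}", lineno)
        name, parent = parts[0], parts[1]
        try:
            x, y, z, diam = (float(v) for v in parts[2:])
        except ValueError:
            raise ParseError("non-numeric coordinate or diameter", lineno) from None
        if diam <= 0:
            raise ParseError(f"non-positive diameter for {name!r}", lineno)
        coords = np.array([x, y, z]) * 1e-6
        if parent in ("none", "None", "-1"):
            positions[name] = coords if not relative else np.zeros(3)
            extent = float(np.linalg.norm(coords)) if relative else 0.0
            segments.append(
                MorphSegment(
                    id=name,
                    parent=None,
                    length=extent,
                    diameter=diam * 1e-6,
                    is_spherical=extent == 0.0,
                )
            )
            continue
        if parent == ".":
            parent = segments[-1].id if segments else parent
        if parent not in positions:
            raise ParseError(f"segment {name!r}: dangling parent {parent!r}", lineno)
        if relative:
            delta = coords
            positions[name] = positions[parent] + delta
        else:
            delta = coords - positions[parent]
            positions[name] = coords
        length = float(np.linalg.norm(delta))
        segments.append(
            MorphSegment(id=name, parent=parent, length=length, diameter=diam * 1e-6)
        )
    if not segments:
        raise ParseError("no segments in morphology file")
    return _finish_tree(segments)


def write_p_file(segments: list[MorphSegment]) -> str:
    """Serialize a segment tree as a relative-coordinate GENESIS ``.p`` file.

    Segments are laid out along the x axis; only topology, lengths and
    diameters are preserved (original 3-D coordinates are not stored).
    """
    lines = ["// written by ephysfit", "*relative"]
    for seg in segments:
        parent = seg.parent if seg.parent is not None else "none"
        x_um = seg.length * 1e6
        lines.append(
            f"{seg.id} {parent} {x_um:.9g} 0 0 {seg.diameter * 1e6:.9g}"
        )
    return "\n".join(lines) + "\n"


def parse_swc(text: str) -> list[MorphSegment]:
    """Parse standard 7-column SWC (id, type, x, y, z, radius, parent; µm)."""
    points: dict[int, tuple[int, np.ndarray, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ParseError(f"expected 7 columns, got {len(parts)}", lineno)
        try:
            idx = int(parts[0])
            kind = int(parts[1])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])]) * 1e-6
            radius = float(parts[5]) * 1e-6
            parent = int(parts[6])
        except ValueError:
            raise ParseError("non-numeric SWC field", lineno) from None
        if radius <= 0:
            raise ParseError(f"non-positive radius for point {idx}", lineno)
        points[idx] = (kind, xyz, radius, parent)
        order.append(idx)
    roots = [i for i in order if points[i][3] == -1]
    if len(roots) != 1:
        raise ParseError(f"expected exactly one SWC root, found {len(roots)}")
    segments = []
    for idx in order:
        kind, xyz, radius, parent = points[idx]
        if parent == -1:
            segments.append(
                MorphSegment(
                    id=str(idx),
                    parent=None,
                    length=0.0,
                    diameter=2 * radius,
                    is_spherical=True,
                    kind=str(kind),
                )
            )
        else:
            if parent not in points:
                raise ParseError(f"point {idx}: missing parent {parent}")
            length = float(np.linalg.norm(xyz - points[parent][1]))
            segments.append(
                MorphSegment(
                    id=str(idx),
                    parent=str(parent),
                    length=length,
                    diameter=2 * radius,
                    kind=str(kind),
                )
            )
    return _finish_tree(segments)


def write_swc(segments: list[MorphSegment]) -> str:
    """Serialize a segment tree as SWC, laying points out along x."""
    index = {seg.id: i + 1 for i, seg in enumerate(segments)}
    xpos: dict[str, float] = {}
    lines = ["# written by ephysfit"]
    for seg in segments:
        if seg.parent is None:
            x = 0.0
        else:
            x = xpos[seg.parent] + seg.length * 1e6
        xpos[seg.id] = x
        kind = seg.kind if seg.kind is not None else ("1" if seg.parent is None else "3")
        parent = index[seg.parent] if seg.parent is not None else -1
        lines.append(
            f"{index[seg.id]} {kind} {x:.9g} 0 0 {seg.diameter / 2 * 1e6:.9g} {parent}"
        )
    return "\n".join(lines) + "\n"


def assign_regions(
    morph: list[MorphSegment], thresholds: tuple[float, float]
) -> list[int]:
    """Assign each segment to a neuron region.

    Region 0 is the soma (path distance 0), region 1 covers path distances
    up to the first threshold, region 2 everything beyond.  The second
    threshold is accepted for interface compatibility (some conductance
    maps distinguish a third, most-distal band) but with three regions only
    the first is load-bearing.
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise SpecificationError("region thresholds must satisfy t1 < t2")
    out = []
    for seg in morph:
        if seg.path_distance == 0.0:
            out.append(0)
        elif seg.path_distance <= t1:
            out.append(1)
        else:
            out.append(2)
    return out


# ---------------------------------------------------------------------------
# passive, calcium, conductances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveSpec:
    RM: float          # Ω·m², specific membrane resistance
    CM: float          # F/m², specific membrane capacitance
    RA: float          # Ω·m, axial resistivity
    E_leak: float      # V

    def __post_init__(self):
        for name in ("RM", "CM", "RA"):
            if getattr(self, name) <= 0:
                raise SpecificationError(f"passive parameter {name} must be > 0")


@dataclass(frozen=True)
class CalciumSpec:
    """Single-exponential calcium pool: d[Ca]/dt = −([Ca]−base)/τ + B·(−I_Ca)."""

    tau_ca: float = 0.02     # s
    B_ca: float = 2e6        # mM/(A·s); folds shell volume and Faraday constant
    ca_base: float = 5e-5    # mM resting concentration
    enabled: bool = False    # the calYN switch

    def __post_init__(self):
        if self.tau_ca <= 0:
            raise SpecificationError("tau_ca must be > 0")
        if self.ca_base < 0:
            raise SpecificationError("ca_base must be >= 0")


@dataclass
class NeuronSpec:
    """A complete declarative neuron model.

    ``conductances`` maps (channel name, region index) to a maximal
    conductance density in S/m².  Explicit spines are out of scope, so
    ``spineYN`` must remain False.
    """

    morphology: list[MorphSegment]
    region_thresholds: tuple[float, float]
    channels: list[ChannelSpec]
    conductances: dict[tuple[str, int], float]
    passive: PassiveSpec
    calcium: CalciumSpec = field(default_factory=CalciumSpec)
    spineYN: bool = False

    def __post_init__(self):
        if self.spineYN:
            raise SpecificationError("explicit spines are not supported (spineYN must be False)")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise SpecificationError("channel names must be unique")
        known = set(names)
        for (chan, region), dens in self.conductances.items():
            if chan not in known:
                raise SpecificationError(f"conductance entry names unknown channel {chan!r}")
            if region not in (0, 1, 2):
                raise SpecificationError(f"conductance region must be 0/1/2, got {region}")
            if dens < 0:
                raise SpecificationError(f"negative conductance density for {chan}_{region}")

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def density(self, channel: str, region: int) -> float:
        return self.conductances.get((channel, region), 0.0)


# ---------------------------------------------------------------------------
# tunable parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDef:
    name: str
    initial: float
    min: float
    max: float

    def __post_init__(self):
        if not self.min <= self.initial <= self.max:
            raise SpecificationError(
                f"parameter {self.name}: initial {self.initial} outside [{self.min}, {self.max}]"
            )


@dataclass
class ParamSet:
    """Ordered list of tunable parameters with bounds."""

    params: list[ParamDef]

    def __post_init__(self):
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise SpecificationError("duplicate parameter names in ParamSet")
        for p in self.params:
            base, region = split_param_name(p.name)
            if base not in PASSIVE_NAMES and p.min < 0:
                raise SpecificationError(
                    f"conductance parameter {p.name}: min must be >= 0"
                )

    def __iter__(self):
        return iter(self.params)

    def __len__(self):
        return len(self.params)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def initials(self) -> np.ndarray:
        return np.array([p.initial for p in self.params])

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [(p.min, p.max) for p in self.params]

    def get(self, name: str) -> ParamDef:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)


_REGION_SUFFIX = re.compile(r"^(.*)_([012])$")


def split_param_name(name: str) -> tuple[str, Optional[int]]:
    """Split ``KaS_0`` → (``KaS``, 0); names without a suffix → (name, None)."""
    m = _REGION_SUFFIX.match(name)
    if m:
        return m.group(1), int(m.group(2))
    return name, None


def apply_params(
    neuron: NeuronSpec,
    values: dict[str, float],
    params: Optional[ParamSet] = None,
) -> NeuronSpec:
    """Return a copy of ``neuron`` with named parameter values applied.

    A bare channel name sets the density in all three regions; a
    ``_0``/``_1``/``_2`` suffix sets only that region; passive names
    replace the corresponding :class:`PassiveSpec` field.  When a
    :class:`ParamSet` is given, names must be declared and values must lie
    within bounds.  The input spec is never modified.
    """
    if params is not None:
        declared = set(params.names)
        for name, value in values.items():
            if name not in declared:
                raise SpecificationError(f"unknown parameter {name!r}")
            p = params.get(name)
            if not p.min <= value <= p.max:
                raise SpecificationError(
                    f"parameter {name}={value:g} outside bounds [{p.min:g}, {p.max:g}]"
                )
    out = copy.deepcopy(neuron)
    channel_names = {c.name for c in out.channels}
    passive_kwargs: dict[str, float] = {}
    for name, value in values.items():
        if name in PASSIVE_NAMES:
            passive_kwargs[name] = value
            continue
        base, region = split_param_name(name)
        if base in channel_names and region is not None:
            out.conductances[(base, region)] = value
        elif name in channel_names:
            for r in (0, 1, 2):
                out.conductances[(name, r)] = value
        else:
            raise SpecificationError(f"unknown parameter {name!r}")
        if value < 0:
            raise SpecificationError(f"negative conductance for parameter {name!r}")
    if passive_kwargs:
        out.passive = replace(out.passive, **passive_kwargs)
    return out


# ---------------------------------------------------------------------------
# YAML loading / saving
# ---------------------------------------------------------------------------

def _gate_to_dict(g: GateSpec) -> dict:
    d: dict = {"name": g.name, "power": g.power, "form": g.form}
    if g.forward is not None:
        d["forward"] = vars(g.forward).copy()
    if g.backward is not None:
        d["backward"] = vars(g.backward).copy()
    if g.form == "calcium-dependent":
        d["ca_half"] = g.ca_half
        d["ca_slope"] = g.ca_slope
    d["tau_min"] = g.tau_min
    return d


def _gate_from_dict(d: dict) -> GateSpec:
    fwd = GateRateSpec(**d["forward"]) if "forward" in d else None
    bwd = GateRateSpec(**d["backward"]) if "backward" in d else None
    return GateSpec(
        name=d["name"],
        power=int(d["power"]),
        form=d["form"],
        forward=fwd,
        backward=bwd,
        ca_half=float(d.get("ca_half", 0.0)),
        ca_slope=float(d.get("ca_slope", 1.0)),
        tau_min=float(d.get("tau_min", 1e-4)),
    )


def neuron_to_dict(neuron: NeuronSpec) -> dict:
    return {
        "morphology_p": write_p_file(neuron.morphology),
        "region_thresholds_um": [t * 1e6 for t in neuron.region_thresholds],
        "passive": vars(neuron.passive).copy(),
        "calcium": {
            "calYN": neuron.calcium.enabled,
            "tau_ca": neuron.calcium.tau_ca,
            "B_ca": neuron.calcium.B_ca,
            "ca_base": neuron.calcium.ca_base,
        },
        "spineYN": neuron.spineYN,
        "channels": [
            {
                "name": c.name,
                "E_rev": c.E_rev,
                "carries_calcium": c.carries_calcium,
                "gates": [_gate_to_dict(g) for g in c.gates],
            }
            for c in neuron.channels
        ],
        "conductances": {
            f"{chan}_{region}": dens
            for (chan, region), dens in sorted(neuron.conductances.items())
        },
    }


def neuron_from_dict(doc: dict) -> NeuronSpec:
    morphology = parse_p_file(doc["morphology_p"])
    channels = [
        ChannelSpec(
            name=c["name"],
            E_rev=c["E_rev"],
            gates=tuple(_gate_from_dict(g) for g in c["gates"]),
            carries_calcium=bool(c.get("carries_calcium", False)),
        )
        for c in doc["channels"]
    ]
    conductances = {}
    for key, dens in doc.get("conductances", {}).items():
        base, region = split_param_name(key)
        if region is None:
            raise SpecificationError(f"conductance key {key!r} lacks a region suffix")
        conductances[(base, region)] = float(dens)
    ca = doc.get("calcium", {})
    return NeuronSpec(
        morphology=morphology,
        region_thresholds=tuple(t * 1e-6 for t in doc["region_thresholds_um"]),
        channels=channels,
        conductances=conductances,
        passive=PassiveSpec(**doc["passive"]),
        calcium=CalciumSpec(
            tau_ca=float(ca.get("tau_ca", 0.02)),
            B_ca=float(ca.get("B_ca", 2e6)),
            ca_base=float(ca.get("ca_base", 5e-5)),
            enabled=bool(ca.get("calYN", False)),
        ),
        spineYN=bool(doc.get("spineYN", False)),
    )


def save_neuron(neuron: NeuronSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(neuron_to_dict(neuron), fh, sort_keys=False)


def load_neuron(path) -> NeuronSpec:
    with open(path) as fh:
        return neuron_from_dict(yaml.safe_load(fh))
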
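"""Declarative model specification: rates, gates, morphology, parameters."""

import math

import mpmath
import numpy as np
import pytest

from ephysfit.model_spec import (
    ChannelSpec,
    GateRateSpec,
    GateSpec,
    MorphSegment,
    NeuronSpec,
    ParamDef,
    ParamSet,
    PassiveSpec,
    SpecificationError,
    apply_params,
    assign_regions,
    gate_equilibrium,
    neuron_from_dict,
    neuron_to_dict,
    parse_p_file,
    parse_swc,
    rate_value,
    write_p_file,
    write_swc,
)


class TestRateValue:
    def test_constant_numerator(self):
        # exp term ~ 1, so value = A / (C + 1)
        spec = GateRateSpec(A=5, B=0, C=1, D=0, F=1e9)
        assert rate_value(spec, 0.0) == pytest.approx(2.5, rel=1e-6)

    def test_sigmoid_midpoint(self):
        spec = GateRateSpec(A=2, B=0, C=1, D=0.01, F=0.01)
        assert rate_value(spec, -0.01) == pytest.approx(1.0, rel=1e-12)

    def test_grid_matches_high_precision_oracle(self):
        # independent evaluation of (A + B V)/(C + exp((V+D)/F)) at 40 digits
        mpmath.mp.dps = 40
        specs = [
            GateRateSpec(A=-11286.0, B=-380000.0, C=-1.0, D=0.0297, F=-0.010),
            GateRateSpec(A=15200.0, B=0.0, C=0.0, D=0.0547, F=0.018),
            GateRateSpec(A=1.0, B=0.0, C=1.0, D=0.045, F=-0.005),
        ]
        for spec in specs:
            for V in np.arange(-0.10, 0.05, 1e-4):
                num = mpmath.mpf(spec.A) + mpmath.mpf(spec.B) * mpmath.mpf(V)
                den = mpmath.mpf(spec.C) + mpmath.e ** (
                    (mpmath.mpf(V) + mpmath.mpf(spec.D)) / mpmath.mpf(spec.F)
                )
                if abs(den) < 1e-9:
                    continue  # singularity guard region, checked separately
                expected = float(num / den)
                assert rate_value(spec, float(V)) == pytest.approx(expected, rel=1e-9)

    def test_singularity_guard_is_finite_and_continuous(self):
        # classic linoid: 0.38e6 (V + 29.7 mV) / (1 - exp(-(V + 29.7 mV)/10 mV))
        # has a removable singularity at V = -29.7 mV with limit B*F = 3800/s
        spec = GateRateSpec(A=-11286.0, B=-380000.0, C=-1.0, D=0.0297, F=-0.010)
        at_sing = rate_value(spec, -0.0297)
        assert math.isfinite(at_sing)
        assert at_sing == pytest.approx(3800.0, rel=1e-4)
        near = rate_value(spec, -0.0297 + 2e-5)
        assert at_sing == pytest.approx(near, rel=1e-2)

    def test_f_zero_rejected(self):
        with pytest.raises(SpecificationError):
            GateRateSpec(A=1, B=0, C=1, D=0, F=0)


class TestGateEquilibrium:
    def test_alpha_beta_balanced(self):
        g = GateSpec(
            name="x", power=1, form="alpha-beta",
            forward=GateRateSpec(A=100, B=0, C=0, D=0, F=1e9),
            backward=GateRateSpec(A=100, B=0, C=0, D=0, F=1e9),
            tau_min=1e-5,
        )
        xinf, tau = gate_equilibrium(g, -0.07)
        assert xinf == pytest.approx(0.5, rel=1e-6)
        assert tau == pytest.approx(0.005, rel=1e-6)

    def test_alpha_only(self):
        g = GateSpec(
            name="x", power=1, form="alpha-beta",
            forward=GateRateSpec(A=100, B=0, C=0, D=0, F=1e9),
            backward=GateRateSpec(A=0, B=0, C=0, D=0, F=1e9),
            tau_min=1e-5,
        )
        xinf, tau = gate_equilibrium(g, -0.07)
        assert xinf == pytest.approx(1.0, rel=1e-6)
        assert tau == pytest.approx(0.01, rel=1e-6)

    def test_calcium_half_activation(self):
        g = GateSpec(name="z", power=1, form="calcium-dependent",
                     ca_half=0.001, ca_slope=2.0, tau_min=1e-3)
        xinf, tau = gate_equilibrium(g, -0.07, Ca=0.001)
        assert xinf == pytest.approx(0.5)
        assert tau == 1e-3

    def test_xinf_in_unit_interval_for_shipped_channels(self, spiker, pauser):
        for neuron in (spiker, pauser):
            for chan in neuron.channels:
                for gate in chan.gates:
                    for V in np.linspace(-0.15, 0.10, 251):
                        xinf, tau = gate_equilibrium(gate, float(V), Ca=1e-4)
                        assert 0.0 <= xinf <= 1.0
                        assert tau > 0


class TestMorphologyParsing:
    def test_p_file_single_sphere(self):
        segs = parse_p_file("*absolute\nsoma none 14 0 0 14\n")
        assert len(segs) == 1
        assert segs[0].is_spherical
        assert segs[0].diameter == pytest.approx(14e-6)

    def test_p_file_relative_lengths_match_hand_computation(self):
        text = """// three compartments
*relative
soma none 0 0 0 16
dend1 soma 30 40 0 4
dend2 dend1 0 12 5 2
"""
        segs = parse_p_file(text)
        by_id = {s.id: s for s in segs}
        assert by_id["dend1"].length == pytest.approx(50e-6)  # 3-4-5 triangle
        assert by_id["dend2"].length == pytest.approx(13e-6)  # 5-12-13
        assert by_id["soma"].is_spherical

    def test_p_file_errors(self):
        with pytest.raises(SpecificationError, match="line"):
            parse_p_file("*bogus\nsoma none 14 0 0 14\n")
        with pytest.raises(SpecificationError, match="dangling"):
            parse_p_file("*relative\nsoma none 0 0 0 14\ndend other 10 0 0 2\n")
        with pytest.raises(SpecificationError, match="diameter"):
            parse_p_file("*relative\nsoma none 0 0 0 -14\n")

    def test_swc_single_point_soma(self):
        segs = parse_swc("1 1 0 0 0 7 -1\n")
        assert len(segs) == 1
        assert segs[0].is_spherical
        assert segs[0].diameter == pytest.approx(14e-6)

    def test_swc_chain_lengths(self):
        text = "1 1 0 0 0 7 -1\n2 3 30 40 0 2 1\n3 3 30 40 12 1 2\n"
        segs = parse_swc(text)
        assert len(segs) == 3
        assert segs[1].length == pytest.approx(50e-6)
        assert segs[2].length == pytest.approx(12e-6)
        assert segs[1].diameter == pytest.approx(4e-6)

    def test_swc_missing_root(self):
        with pytest.raises(SpecificationError):
            parse_swc("1 1 0 0 0 7 5\n")

    @pytest.mark.parametrize("fmt", ["p", "swc"])
    def test_round_trip_preserves_tree(self, fmt):
        text = """*relative
soma none 0 0 0 16
d1 soma 50 0 0 4
d2 d1 80 0 0 3
d3 d1 40 30 0 2
"""
        segs = parse_p_file(text)
        if fmt == "p":
            again = parse_p_file(write_p_file(segs))
        else:
            again = parse_swc(write_swc(segs))
        assert len(again) == len(segs)
        for a, b in zip(segs, again):
            assert a.parent is None if b.parent is None else True
            assert a.length == pytest.approx(b.length, abs=1e-12)
            assert a.diameter == pytest.approx(b.diameter, abs=1e-15)
            assert a.is_spherical == b.is_spherical
        # second round trip is exactly stable
        if fmt == "p":
            third = parse_p_file(write_p_file(again))
        else:
            third = parse_swc(write_swc(again))
        for b, c in zip(again, third):
            assert b.length == c.length and b.diameter == c.diameter


class TestRegions:
    def test_soma_is_region_zero(self):
        segs = parse_p_file("*relative\nsoma none 0 0 0 16\n")
        assert assign_regions(segs, (60e-6, 120e-6)) == [0]

    def test_proximal_within_threshold(self):
        text = "*relative\nsoma none 0 0 0 16\nd1 soma 60 0 0 4\n"
        segs = parse_p_file(text)
        # midpoint at 30 um <= 60 um threshold -> region 1
        assert assign_regions(segs, (60e-6, 120e-6)) == [0, 1]

    def test_path_distance_matches_graph_search_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(42)
        lines = ["*relative", "soma none 0 0 0 16"]
        names = ["soma"]
        for i in range(1, 20):
            parent = names[rng.integers(0, len(names))]
            name = f"s{i}"
            dx, dy, dz = rng.uniform(5, 80, size=3)
            lines.append(f"{name} {parent} {dx:.3f} {dy:.3f} {dz:.3f} 2")
            names.append(name)
        segs = parse_p_file("\n".join(lines))
        g = nx.Graph()
        by_id = {s.id: s for s in segs}
        for s in segs:
            if s.parent is not None:
                # edge weight: half of parent (0 if soma) + half of child
                parent = by_id[s.parent]
                w = (0.0 if parent.is_spherical else parent.length / 2) + s.length / 2
                g.add_edge(s.parent, s.id, weight=w)
        dist = nx.single_source_dijkstra_path_length(g, "soma")
        for s in segs:
            if s.id != "soma":
                assert s.path_distance == pytest.approx(dist[s.id], rel=1e-9)


def _toy_neuron():
    from ephysfit.synthetic import make_reference_neuron

    return make_reference_neuron("spiker")


class TestApplyParams:
    def test_unsuffixed_sets_all_regions(self):
        n = _toy_neuron()
        out = apply_params(n, {"NaF": 2000.0})
        for r in (0, 1, 2):
            assert out.density("NaF", r) == 2000.0
        # original untouched
        assert n.density("NaF", 0) != 2000.0 or n.density("NaF", 1) != 2000.0

    def test_suffixed_sets_one_region(self):
        n = _toy_neuron()
        before = {r: n.density("KA", r) for r in (0, 1, 2)}
        out = apply_params(n, {"KA_0": 10.0})
        assert out.density("KA", 0) == 10.0
        assert out.density("KA", 1) == before[1]
        assert out.density("KA", 2) == before[2]

    def test_passive_override(self):
        n = _toy_neuron()
        out = apply_params(n, {"RM": 2.5, "E_leak": -0.075})
        assert out.passive.RM == 2.5
        assert out.passive.E_leak == -0.075
        assert n.passive.RM != 2.5

    def test_bound_violation_rejected(self):
        n = _toy_neuron()
        pset = ParamSet([ParamDef("RM", initial=1.0, min=0.0, max=4.0)])
        with pytest.raises(SpecificationError, match="RM"):
            apply_params(n, {"RM": -1.0}, pset)

    def test_unknown_name_rejected(self):
        n = _toy_neuron()
        with pytest.raises(SpecificationError, match="NoSuchChan"):
            apply_params(n, {"NoSuchChan": 5.0})

    def test_idempotent_and_leaves_others_bitwise(self):
        n = _toy_neuron()
        once = apply_params(n, {"KDr_1": 42.0})
        twice = apply_params(once, {"KDr_1": 42.0})
        assert once.conductances == twice.conductances
        for key, val in n.conductances.items():
            if key != ("KDr", 1):
                assert once.conductances[key] == val


class TestYamlRoundTrip:
    def test_neuron_dict_round_trip(self, spiker):
        doc = neuron_to_dict(spiker)
        again = neuron_from_dict(doc)
        assert again.conductances == spiker.conductances
        assert again.passive == spiker.passive
        assert len(again.morphology) == len(spiker.morphology)
        assert [c.name for c in again.channels] == [c.name for c in spiker.channels]
        assert again.calcium == spiker.calcium


class TestParamSet:
    def test_conductance_min_nonnegative(self):
        with pytest.raises(SpecificationError):
            ParamSet([ParamDef("NaF", initial=0.0, min=-1.0, max=10.0)])

    def test_initial_within_bounds(self):
        with pytest.raises(SpecificationError):
            ParamDef("RM", initial=5.0, min=0.0, max=4.0)

    def test_spine_flag_rejected(self):
        seg = [MorphSegment(id="soma", parent=None, length=0.0, diameter=1e-5,
                            is_spherical=True)]
        with pytest.raises(SpecificationError):
            NeuronSpec(
                morphology=seg, region_thresholds=(1e-5, 2e-5), channels=[],
                conductances={}, passive=PassiveSpec(1, 0.01, 1, -0.07),
                spineYN=True,
            )
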
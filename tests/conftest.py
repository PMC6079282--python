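import math

import numpy as np
import pytest

from ephysfit.model_spec import (
    ChannelSpec,
    GateRateSpec,
    GateSpec,
    MorphSegment,
    NeuronSpec,
    PassiveSpec,
)


def passive_neuron(
    R_in=100e6, tau_m=10e-3, RM=1.0, RA=1.0, E_leak=-0.070
) -> NeuronSpec:
    """Single spherical compartment with the requested input resistance.

    R_in = RM / area fixes the diameter; tau_m = RM * CM fixes CM.
    """
    area = RM / R_in
    d = math.sqrt(area / math.pi)
    seg = [MorphSegment(id="soma", parent=None, length=0.0, diameter=d, is_spherical=True)]
    return NeuronSpec(
        morphology=seg,
        region_thresholds=(60e-6, 180e-6),
        channels=[],
        conductances={},
        passive=PassiveSpec(RM=RM, CM=tau_m / RM, RA=RA, E_leak=E_leak),
    )


def random_passive_tree(rng: np.random.Generator, n_segments: int) -> NeuronSpec:
    """Random-topology passive tree with varied lengths and diameters."""
    segs = [
        MorphSegment(id="soma", parent=None, length=0.0, diameter=16e-6, is_spherical=True)
    ]
    for i in range(1, n_segments):
        parent = segs[rng.integers(0, i)].id
        segs.append(
            MorphSegment(
                id=f"seg{i}",
                parent=parent,
                length=float(rng.uniform(20e-6, 150e-6)),
                diameter=float(rng.uniform(1e-6, 6e-6)),
            )
        )
    return NeuronSpec(
        morphology=segs,
        region_thresholds=(60e-6, 180e-6),
        channels=[],
        conductances={},
        passive=PassiveSpec(RM=1.0, CM=0.01, RA=1.0, E_leak=-0.070),
    )


@pytest.fixture(scope="session")
def spiker():
    from ephysfit.synthetic import make_reference_neuron

    return make_reference_neuron("spiker")


@pytest.fixture(scope="session")
def pauser():
    from ephysfit.synthetic import make_reference_neuron

    return make_reference_neuron("pauser")


@pytest.fixture(scope="session")
def spiker_recordings():
    """Noiseless synthetic recordings of the spiker truth model."""
    from ephysfit.synthetic import (
        generate_recordings,
        make_reference_neuron,
        reference_protocols,
    )

    neuron = make_reference_neuron("spiker")
    return generate_recordings(neuron, reference_protocols("spiker"), noise_sd=0.0, seed=0)
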
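"""Shared fixtures: the common topology, a complete-CoW patient network,
default boundary conditions, and a builder for small hand-made test
networks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from willisflow.boundaries import (
    InflowWaveform,
    area_proportional_split,
    initialize_terminals,
)
from willisflow.network import (
    ArterySegment,
    BloodProperties,
    Network,
    NetworkTopology,
    PatientGeometry,
    build_patient_network,
)
from willisflow.units import MMHG_TO_PA

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blood() -> BloodProperties:
    return BloodProperties()


@pytest.fixture(scope="session")
def topology() -> NetworkTopology:
    return NetworkTopology.default()


@pytest.fixture(scope="session")
def complete_network(topology, blood) -> Network:
    """All 33 segments present at their default diameters."""
    geometry = PatientGeometry("complete", {}, heart_period=0.8)
    return build_patient_network(topology, geometry, blood)


@pytest.fixture(scope="session")
def waveform() -> InflowWaveform:
    return InflowWaveform(heart_period=0.8, stroke_volume=70e-6)


@pytest.fixture(scope="session")
def default_terminals(complete_network, waveform):
    splits = area_proportional_split(complete_network, waveform.mean_flow)
    return initialize_terminals(complete_network, 93 * MMHG_TO_PA, splits)


def make_toy_network(
    edges,
    inlet: str,
    terminals: list[str],
    blood: BloodProperties | None = None,
) -> Network:
    """Small ad-hoc network from (name, prox, dist, diameter_m, length_m)."""
    blood = blood or BloodProperties()
    segments = [
        ArterySegment(
            name=name,
            group="systemic",
            length=length,
            proximal_node=prox,
            distal_node=dist,
            point_diameters=(d,),
            effective_diameter=d,
        )
        for name, prox, dist, d, length in edges
    ]
    return Network(segments, inlet, terminals, blood)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
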
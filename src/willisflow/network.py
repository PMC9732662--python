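"""Arterial network model.

Every artery segment is represented as a uniform, thin-walled, homogeneous
deformable tube.  A segment measured at several points along its course is
collapsed to a single *volume-equivalent* diameter, i.e. the diameter of the
uniform tube with the same lumen volume.  Each present segment then maps to
the three elements of the electrical analog of laminar tube flow:

* resistance  ``R = 128 mu l / (pi d^4)``  (Hagen-Poiseuille),
* inertance   ``L = 4 rho l / (pi d^2)``   (blood momentum),
* compliance  ``C = pi d^3 l / (4 E h)``   (thin-wall elastic tube law,
  wall thickness ``h = wall_thickness_ratio * d``).

The common topology holds 18 intracranial segments (the circle of Willis
proper) and 15 main-body segments that provide the background circulation.
A measured diameter of 0 encodes an absent segment, which is *removed* from
the network (never represented as a zero-resistance element).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .units import MM_TO_M

CEREBRAL = "cerebral"
SYSTEMIC = "systemic"

#: Default elastic modulus of the arterial wall before calibration, Pa.
#: Calibration re-fits the moduli, so this value only seeds the iteration.
DEFAULT_YOUNGS_MODULUS = 0.4e6

#: Default wall thickness as a fraction of the lumen diameter (h/d).
DEFAULT_WALL_THICKNESS_RATIO = 0.1


class SegmentAbsentError(ValueError):
    """Raised when an R/L/C element is requested for an absent segment."""


class NonPerfusableTerritoryError(ValueError):
    """Raised when pruning absent segments disconnects a terminal from the inlet."""

    def __init__(self, terminals: Sequence[str]):
        self.terminals = tuple(terminals)
        super().__init__(
            "pruning disconnected terminal(s) from the inlet: "
            + ", ".join(self.terminals)
        )


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties used by the Hagen-Poiseuille and inertance laws."""

    dynamic_viscosity: float = 3.5e-3  # Pa s
    density: float = 1060.0  # kg/m^3

    def __post_init__(self) -> None:
        if not (self.dynamic_viscosity > 0 and self.density > 0):
            raise ValueError("blood viscosity and density must be strictly positive")


@dataclass(frozen=True)
class SegmentRLC:
    """Electrical-analog elements of one present segment (SI units)."""

    resistance: float  # Pa s / m^3
    inertance: float  # Pa s^2 / m^3
    compliance: float  # m^3 / Pa


@dataclass(frozen=True)
class ArterySegment:
    """One vessel segment of the common network.

    ``point_diameters`` holds the raw measured diameters (m); the
    ``effective_diameter`` is the volume-equivalent diameter derived from
    them.  A segment is absent iff ``effective_diameter == 0``.
    """

    name: str
    group: str
    length: float
    proximal_node: str
    distal_node: str
    point_diameters: tuple[float, ...] = ()
    effective_diameter: float = 0.0
    youngs_modulus: float = DEFAULT_YOUNGS_MODULUS
    wall_thickness_ratio: float = DEFAULT_WALL_THICKNESS_RATIO
    segment_id: int = -1

    def __post_init__(self) -> None:
        if self.group not in (CEREBRAL, SYSTEMIC):
            raise ValueError(f"unknown segment group {self.group!r}")
        if not self.length > 0:
            raise ValueError(f"segment {self.name}: length must be > 0")
        if any(d < 0 for d in self.point_diameters):
            raise ValueError(f"segment {self.name}: negative point diameter")
        if self.effective_diameter < 0:
            raise ValueError(f"segment {self.name}: negative effective diameter")
        if not self.youngs_modulus > 0:
            raise ValueError(f"segment {self.name}: Young's modulus must be > 0")

    @property
    def is_present(self) -> bool:
        return self.effective_diameter > 0.0

    @property
    def cross_section(self) -> float:
        """Lumen cross-section area of the equivalent uniform tube, m^2."""
        return math.pi * self.effective_diameter**2 / 4.0


def volume_equivalent_diameter(
    point_diameters: Sequence[float], sub_lengths: Sequence[float] | None = None
) -> float:
    """Diameter of the uniform tube with the same lumen volume.

    ``d_eq = sqrt(sum(d_i^2 l_i) / sum(l_i))``.  With equal sub-lengths this
    is the root-mean-square of the point diameters.  Returns 0 iff all point
    diameters are 0 (absent segment).
    """
    d = np.asarray(point_diameters, dtype=float)
    if d.size == 0:
        raise ValueError("point_diameters must be non-empty")
    if np.any(d < 0):
        raise ValueError("point diameters must be >= 0")
    if sub_lengths is None:
        w = np.full(d.size, 1.0 / d.size)
    else:
        l = np.asarray(sub_lengths, dtype=float)
        if l.shape != d.shape:
            raise ValueError("point_diameters and sub_lengths must have equal length")
        if np.any(l < 0) or l.sum() <= 0:
            raise ValueError("sub_lengths must be >= 0 with positive total")
        w = l / l.sum()
    return float(np.sqrt(np.sum(w * d**2)))


def segment_rlc(segment: ArterySegment, blood: BloodProperties) -> SegmentRLC:
    """R, L, C of a present segment from its effective diameter and wall law."""
    if not segment.is_present:
        raise SegmentAbsentError(
            f"segment {segment.name} is absent; prune it instead of building RLC"
        )
    d = segment.effective_diameter
    l = segment.length
    mu = blood.dynamic_viscosity
    rho = blood.density
    h = segment.wall_thickness_ratio * d
    resistance = 128.0 * mu * l / (math.pi * d**4)
    inertance = 4.0 * rho * l / (math.pi * d**2)
    compliance = math.pi * d**3 * l / (4.0 * segment.youngs_modulus * h)
    return SegmentRLC(resistance=resistance, inertance=inertance, compliance=compliance)


@dataclass(frozen=True)
class NetworkTopology:
    """The common 33-segment topology with default geometry.

    Segment stubs carry default lengths and diameters; a patient geometry
    overrides the diameters per investigation.
    """

    segments: tuple[ArterySegment, ...]
    inlet_node: str
    terminal_nodes: tuple[str, ...]
    name: str = "common-cow-33"
    schema_version: int = 1

    def __post_init__(self) -> None:
        n_cer = sum(1 for s in self.segments if s.group == CEREBRAL)
        n_sys = sum(1 for s in self.segments if s.group == SYSTEMIC)
        if (n_cer, n_sys) != (18, 15):
            raise ValueError(
                f"common topology requires 18 cerebral + 15 systemic segments, "
                f"got {n_cer} + {n_sys}"
            )
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names in topology")
        g = nx.Graph()
        for s in self.segments:
            g.add_edge(s.proximal_node, s.distal_node)
        if not nx.is_connected(g):
            raise ValueError("topology graph is not connected with all segments present")
        for t in self.terminal_nodes:
            if t not in g:
                raise ValueError(f"terminal node {t} not present in topology graph")
        if self.inlet_node not in g:
            raise ValueError("inlet node missing from topology graph")

    @property
    def nodes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.proximal_node)
            seen.setdefault(s.distal_node)
        return tuple(seen)

    def segment(self, name: str) -> ArterySegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @classmethod
    def from_json(cls, path) -> "NetworkTopology":
        with open(path) as fh:
            return cls._from_payload(json.load(fh))

    @classmethod
    def default(cls) -> "NetworkTopology":
        payload = json.loads(
            resources.files("willisflow.data").joinpath("topology.json").read_text()
        )
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: Mapping) -> "NetworkTopology":
        segments = []
        for raw in payload["segments"]:
            d = raw["default_diameter_mm"] * MM_TO_M
            n_points = 2 if raw["name"] == "ba" else 3
            segments.append(
                ArterySegment(
                    name=raw["name"],
                    group=raw["group"],
                    length=raw["default_length_m"],
                    proximal_node=raw["proximal_node"],
                    distal_node=raw["distal_node"],
                    point_diameters=(d,) * n_points,
                    effective_diameter=d,
                    segment_id=raw["id"],
                )
            )
        return cls(
            segments=tuple(segments),
            inlet_node=payload["inlet_node"],
            terminal_nodes=tuple(payload["terminal_nodes"]),
            name=payload.get("name", "common-cow-33"),
            schema_version=payload.get("schema_version", 1),
        )


@dataclass(frozen=True)
class PatientGeometry:
    """Measured point diameters for one investigation.

    ``point_diameters`` maps segment name to measured diameters in metres;
    a segment whose diameters are all 0 is absent.  Segments not listed fall
    back to the topology defaults (main-body segments are normally not
    measured).
    """

    investigation_id: str
    point_diameters: Mapping[str, tuple[float, ...]]
    heart_period: float = 0.8

    def __post_init__(self) -> None:
        if not self.heart_period > 0:
            raise ValueError("heart period must be > 0")
        for name, pts in self.point_diameters.items():
            if any(d < 0 for d in pts):
                raise ValueError(f"segment {name}: negative measured diameter")


class Network:
    """A pruned, patient-specific arterial network with attached RLC elements."""

    def __init__(
        self,
        segments: Iterable[ArterySegment],
        inlet_node: str,
        terminal_nodes: Sequence[str],
        blood: BloodProperties,
    ):
        self.blood = blood
        self.inlet_node = inlet_node
        self.terminal_nodes = tuple(terminal_nodes)
        self.segments: dict[str, ArterySegment] = {}
        for s in segments:
            if not s.is_present:
                continue
            self.segments[s.name] = s
        if not self.segments:
            raise ValueError("network has no present segments")
        self.graph = nx.Graph()
        for s in self.segments.values():
            self.graph.add_edge(s.proximal_node, s.distal_node, name=s.name)
        if self.inlet_node not in self.graph:
            raise NonPerfusableTerritoryError(self.terminal_nodes)
        reachable = nx.node_connected_component(self.graph, self.inlet_node)
        lost = [t for t in self.terminal_nodes if t not in reachable]
        if lost:
            raise NonPerfusableTerritoryError(lost)
        # Segments in disconnected islands carry no flow; drop them so the
        # state-space assembly stays non-singular.
        self.segments = {
            n: s
            for n, s in self.segments.items()
            if s.proximal_node in reachable and s.distal_node in reachable
        }
        self.graph = nx.Graph()
        for s in self.segments.values():
            self.graph.add_edge(s.proximal_node, s.distal_node, name=s.name)
        self.nodes: tuple[str, ...] = tuple(self.graph.nodes)
        self.rlc: dict[str, SegmentRLC] = {
            n: segment_rlc(s, blood) for n, s in self.segments.items()
        }

    def __contains__(self, segment_name: str) -> bool:
        return segment_name in self.segments

    def feeding_segment(self, terminal_node: str) -> ArterySegment:
        """The unique present segment whose distal end is the terminal node."""
        feeders = [
            s for s in self.segments.values() if s.distal_node == terminal_node
        ]
        if len(feeders) != 1:
            raise ValueError(
                f"terminal {terminal_node} has {len(feeders)} feeding segments"
            )
        return feeders[0]

    def node_degree(self, node: str) -> int:
        return int(self.graph.degree(node))

    def with_modulus_scaling(
        self, cerebral: float = 1.0, systemic: float = 1.0
    ) -> "Network":
        """A copy with group-wise Young's moduli multiplied (compliance ~ 1/E)."""
        if not (cerebral > 0 and systemic > 0):
            raise ValueError("modulus multipliers must be > 0")
        scaled = []
        for s in self.segments.values():
            m = cerebral if s.group == CEREBRAL else systemic
            scaled.append(replace(s, youngs_modulus=s.youngs_modulus * m))
        return Network(scaled, self.inlet_node, self.terminal_nodes, self.blood)


def build_patient_network(
    topology: NetworkTopology,
    geometry: PatientGeometry,
    blood: BloodProperties | None = None,
    youngs_moduli: Mapping[str, float] | None = None,
) -> Network:
    """Instantiate the patient network from measured diameters.

    Measured segments get their volume-equivalent diameter; unmeasured
    segments keep the topology defaults.  Absent segments (all-zero
    diameters) are pruned.  Raises :class:`NonPerfusableTerritoryError` if
    pruning disconnects any terminal from the inlet.
    """
    blood = blood or BloodProperties()
    segments = []
    for stub in topology.segments:
        pts = geometry.point_diameters.get(stub.name, stub.point_diameters)
        pts = tuple(float(p) for p in pts)
        d_eq = volume_equivalent_diameter(pts) if pts else 0.0
        e = (youngs_moduli or {}).get(stub.name, stub.youngs_modulus)
        segments.append(
            replace(stub, point_diameters=pts, effective_diameter=d_eq, youngs_modulus=e)
        )
    return Network(segments, topology.inlet_node, topology.terminal_nodes, blood)
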
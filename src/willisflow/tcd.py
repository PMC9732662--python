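"""Transcranial Doppler observation model.

Maps simulation output onto the nine standard TCD insonation sites
(bilateral distal cervical ICA, proximal MCA, ACA, PCA, and the basilar
artery) and produces the simulated analog of a TCD report.  Velocity is the
lumen-average ``v = Q / A`` of the mapped segment, with ``A`` the segment's
volume-equivalent cross-section; mean, systolic and diastolic values are
taken over the final (periodic) cycle.

The ACA insonation is ambiguous between the pre-communicating (A1) and
post-communicating (A2) parts; the proximal A1 segment is the default
mapping, and overrides are supported so the effect of that choice can be
studied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .network import Network, NetworkTopology, SegmentAbsentError
from .solver import SimulationResult, cycle_statistics
from .units import M_S_TO_CM_S

#: The nine insonation sites of the measurement protocol.
SITE_IDS = (
    "L_ICA",
    "R_ICA",
    "L_MCA",
    "R_MCA",
    "L_ACA",
    "R_ACA",
    "BA",
    "L_PCA",
    "R_PCA",
)

#: Artery class of each site (used to stratify the agreement statistics).
SITE_ARTERY_CLASS = {
    "L_ICA": "ICA",
    "R_ICA": "ICA",
    "L_MCA": "MCA",
    "R_MCA": "MCA",
    "L_ACA": "ACA",
    "R_ACA": "ACA",
    "BA": "BA",
    "L_PCA": "PCA",
    "R_PCA": "PCA",
}

_DEFAULT_MAP = {
    "L_ICA": "l_ica",
    "R_ICA": "r_ica",
    "L_MCA": "l_m1",
    "R_MCA": "r_m1",
    "L_ACA": "l_a1",  # proximal (pre-communicating) insonation by default
    "R_ACA": "r_a1",
    "BA": "ba",
    "L_PCA": "l_p1",
    "R_PCA": "r_p1",
}

#: Cerebral terminal territory constrained by each site's velocity during
#: calibration.  ICA and BA feed several territories jointly and therefore
#: do not pin a single terminal.
SITE_TERMINAL = {
    "L_MCA": "l_mca_end",
    "R_MCA": "r_mca_end",
    "L_ACA": "l_aca_end",
    "R_ACA": "r_aca_end",
    "L_PCA": "l_pca_end",
    "R_PCA": "r_pca_end",
}


@dataclass(frozen=True)
class TCDSite:
    site_id: str
    mapped_segment: str

    def __post_init__(self) -> None:
        if self.site_id not in SITE_IDS:
            raise ValueError(f"unknown TCD site {self.site_id!r}")


@dataclass(frozen=True)
class VelocityRecord:
    """One site's velocity report in cm/s (clinical convention)."""

    site: TCDSite
    mean_velocity: float
    systolic_velocity: float | None = None
    diastolic_velocity: float | None = None
    source: str = "simulated"

    def __post_init__(self) -> None:
        if self.mean_velocity <= 0:
            raise ValueError("mean velocity must be positive")
        if (
            self.systolic_velocity is not None
            and self.diastolic_velocity is not None
            and not (
                self.systolic_velocity >= self.mean_velocity >= self.diastolic_velocity
            )
        ):
            raise ValueError("velocities must satisfy systolic >= mean >= diastolic")


def site_segment_map(
    topology: NetworkTopology | None = None,
    overrides: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Site-to-segment mapping covering all nine sites, with overrides."""
    mapping = dict(_DEFAULT_MAP)
    if overrides:
        mapping.update(overrides)
    if topology is not None:
        known = {s.name for s in topology.segments}
        for site, seg in mapping.items():
            if seg not in known:
                raise ValueError(f"site {site} maps to unknown segment {seg!r}")
    return mapping


def extract_velocity(
    result: SimulationResult,
    site: TCDSite,
    network: Network,
) -> VelocityRecord:
    """Simulated velocity report at one site, final cycle, in cm/s."""
    if site.mapped_segment not in network:
        raise SegmentAbsentError(
            f"site {site.site_id}: mapped segment {site.mapped_segment} is absent"
        )
    seg = network.segments[site.mapped_segment]
    stats = cycle_statistics(result, site.mapped_segment)
    a = seg.cross_section
    return VelocityRecord(
        site=site,
        mean_velocity=stats.mean / a * M_S_TO_CM_S,
        systolic_velocity=stats.systolic_max / a * M_S_TO_CM_S,
        diastolic_velocity=stats.diastolic_min / a * M_S_TO_CM_S,
        source="simulated",
    )


def simulated_report(
    result: SimulationResult,
    network: Network,
    mapping: Mapping[str, str] | None = None,
) -> tuple[list[VelocityRecord], list[str]]:
    """Velocity records for every available site; absent sites are skipped.

    Returns the records and the list of skipped sites with reasons.
    """
    mapping = mapping or site_segment_map()
    records: list[VelocityRecord] = []
    skipped: list[str] = []
    for site_id in SITE_IDS:
        site = TCDSite(site_id, mapping[site_id])
        try:
            records.append(extract_velocity(result, site, network))
        except SegmentAbsentError as exc:
            skipped.append(str(exc))
    return records, skipped
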
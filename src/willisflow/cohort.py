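"""Virtual aSAH cohort generator.

Builds synthetic patients that emulate the study population the model is
meant for: circle-of-Willis anatomical variants (absent communicating or
pre-communicating segments), vasospastic narrowing of cerebral segments,
elevated blood pressure, and noisy TCD/diameter observations.  Every
patient carries its ground-truth hemodynamic parameters (WK3 terminals,
wall-stiffness multipliers, inflow) together with the forward-simulated
"measurements", so each pipeline stage can be tested for parameter and
velocity recovery without clinical data.

All randomness flows from the single cohort seed: patient ``i`` of seed
``s`` is generated from ``SeedSequence([s, i])`` and is bit-reproducible in
isolation.

The observation model: TCD velocity errors are a common multiplicative
log-normal gain per site (an insonation-angle error scales the whole
envelope), diameters get additive Gaussian noise truncated above zero, and
absent segments stay exactly zero.  The "DCI-like" label marks patients
whose cerebral peripheral resistances deviate most from the
area-proportional (Hagen-Poiseuille consistent) allocation - a modelling
convention to exercise the subgroup statistics, not a clinical claim.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .agreement import ICCResult, LogLoA, icc_consistency, log_bland_altman
from .boundaries import InflowWaveform, WK3Terminal, area_proportional_split, initialize_terminals
from .calibration import (
    CalibrationConfig,
    CalibrationInput,
    CalibrationResult,
    VelocityTarget,
    _terminal_compliance_scaled,
    calibrate,
    step1_peripheral_resistance,
)
from .network import (
    CEREBRAL,
    Network,
    NetworkTopology,
    NonPerfusableTerritoryError,
    PatientGeometry,
    build_patient_network,
)
from .solver import cycle_statistics, dc_solve, pressure_statistics, run_simulation
from .tcd import SITE_ARTERY_CLASS, SITE_IDS, SITE_TERMINAL, site_segment_map
from .units import M_TO_MM, MM_TO_M, MMHG_TO_PA, PA_TO_MMHG

#: Segments that may be congenitally absent, with default probabilities
#: (literature-typical incompleteness rates of the circle of Willis).
DEFAULT_VARIANT_PROBABILITIES = {
    "acoa": 0.10,
    "l_pcoma": 0.25,
    "r_pcoma": 0.25,
    "l_a1": 0.05,
    "r_a1": 0.05,
    "l_p1": 0.15,
    "r_p1": 0.15,
}



@dataclass(frozen=True)
class VasospasmSpec:
    probability: float = 0.6
    max_segments: int = 3
    reduction_range: tuple[float, float] = (0.2, 0.5)


@dataclass(frozen=True)
class BloodPressureSpec:
    """Cuff-pressure sampling in mmHg (aSAH patients run hypertensive)."""

    sbp_mean: float = 145.0
    sbp_sd: float = 15.0
    dbp_mean: float = 80.0
    dbp_sd: float = 10.0


@dataclass(frozen=True)
class NoiseSpec:
    velocity_sd: float = 0.10  # multiplicative log-normal sigma
    diameter_sd_mm: float = 0.1  # additive Gaussian, truncated above 0


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 20
    seed: int = 0
    variant_probabilities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_PROBABILITIES)
    )
    vasospasm: VasospasmSpec = field(default_factory=VasospasmSpec)
    bp: BloodPressureSpec = field(default_factory=BloodPressureSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    hr_mean: float = 75.0
    hr_sd: float = 10.0
    stroke_volume_mean_ml: float = 70.0
    stroke_volume_sd_ml: float = 7.0
    cerebral_flow_boost: float = 1.5  # cerebral flow vs pure area share
    cerebral_flow_patient_sd: float = 0.10
    territory_flow_sd: float = 0.25  # per-territory demand scatter
    min_velocity_cm_s: float = 10.0  # TCD detectability threshold
    diameter_patient_sd: float = 0.08
    diameter_taper_sd: float = 0.05
    systemic_stiffness_sd: float = 0.15
    terminal_compliance_sd: float = 0.20
    cerebral_stiffness_log_mean: float = 0.14  # ln 1.15: mildly stiffened bed
    cerebral_stiffness_sd: float = 0.25
    dci_threshold: float = 0.35

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for k, p in self.variant_probabilities.items():
            if not 0 <= p <= 1:
                raise ValueError(f"variant probability {k}={p} outside [0, 1]")
        lo, hi = self.vasospasm.reduction_range
        if not 0 < lo <= hi < 1:
            raise ValueError("vasospasm reduction range must lie in (0, 1)")
        if self.noise.velocity_sd < 0 or self.noise.diameter_sd_mm < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def spec_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TruthParameters:
    terminals: dict[str, WK3Terminal]
    systemic_modulus_multiplier: float
    systemic_compliance_multiplier: float
    cerebral_modulus_multiplier: float
    waveform: InflowWaveform
    site_velocities: dict[str, VelocityTarget]  # exact forward-model output, m/s
    systolic_bp: float  # Pa, simulated aortic root
    diastolic_bp: float
    mean_bp: float
    sampled_sbp: float  # Pa, the cuff-pressure draw seeding the allocation
    sampled_dbp: float
    resistance_scatter: float  # log-deviation from area-proportional allocation


@dataclass
class Observations:
    measurements: pd.DataFrame  # site, v_mean_cm_s, v_sys_cm_s, v_dia_cm_s
    vitals: dict[str, float]  # sbp_mmHg, dbp_mmHg, map_mmHg, hr_bpm, sv_ml
    point_diameters: dict[str, tuple[float, ...]]  # metres, noisy, 0 = absent


@dataclass
class VirtualPatient:
    investigation_id: str
    geometry: PatientGeometry  # true geometry
    network: Network  # true network
    truth: TruthParameters
    observations: Observations
    labels: dict[str, object]


def draw_variants(spec: CohortSpec, rng: np.random.Generator) -> dict[str, bool]:
    """Independent absence draws for the variant-prone segments."""
    return {
        name: bool(rng.random() < p)
        for name, p in spec.variant_probabilities.items()
    }


def _draw_geometry(
    spec: CohortSpec, topology: NetworkTopology, rng: np.random.Generator
) -> tuple[dict[str, tuple[float, ...]], dict[str, float]]:
    """True cerebral point diameters (m) and the vasospasm reduction map."""
    for _ in range(20):
        absences = draw_variants(spec, rng)
        # Bilateral fetal-PCA (both P1 absent) leaves the basilar artery a
        # dead end in a network without cerebellar side branches; redraw.
        if absences.get("l_p1") and absences.get("r_p1"):
            continue
        points: dict[str, tuple[float, ...]] = {}
        present_cerebral: list[str] = []
        for seg in topology.segments:
            if seg.group != CEREBRAL:
                continue
            if absences.get(seg.name, False):
                points[seg.name] = (0.0,) * len(seg.point_diameters)
                continue
            patient_factor = rng.lognormal(0.0, spec.diameter_patient_sd)
            base = seg.effective_diameter * patient_factor
            points[seg.name] = tuple(
                base * rng.lognormal(0.0, spec.diameter_taper_sd)
                for _ in seg.point_diameters
            )
            present_cerebral.append(seg.name)
        spasm: dict[str, float] = {}
        if rng.random() < spec.vasospasm.probability:
            k = int(rng.integers(1, spec.vasospasm.max_segments + 1))
            k = min(k, len(present_cerebral))
            lo, hi = spec.vasospasm.reduction_range
            for name in rng.choice(present_cerebral, size=k, replace=False):
                red = float(rng.uniform(lo, hi))
                spasm[str(name)] = red
                points[str(name)] = tuple(d * (1 - red) for d in points[str(name)])
        geometry = PatientGeometry("candidate", points, 0.8)
        try:
            build_patient_network(topology, geometry)
        except NonPerfusableTerritoryError:
            continue
        return points, spasm
    raise RuntimeError("could not draw a perfusable anatomy in 20 attempts")


def generate_patient(
    spec: CohortSpec,
    index: int,
    topology: NetworkTopology | None = None,
    calib_config: CalibrationConfig | None = None,
) -> VirtualPatient:
    """One virtual patient, deterministic in (spec.seed, index)."""
    topology = topology or NetworkTopology.default()
    calib_config = calib_config or CalibrationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))
    mapping = site_segment_map(topology)

    hr = float(np.clip(rng.normal(spec.hr_mean, spec.hr_sd), 45.0, 120.0))
    period = 60.0 / hr
    sv = float(
        np.clip(
            rng.normal(spec.stroke_volume_mean_ml, spec.stroke_volume_sd_ml),
            45.0,
            110.0,
        )
    ) * 1e-6
    inv_id = f"P{index:04d}"
    waveform = InflowWaveform(period, sv)

    sbp = float(np.clip(rng.normal(spec.bp.sbp_mean, spec.bp.sbp_sd), 100.0, 220.0))
    dbp = float(np.clip(rng.normal(spec.bp.dbp_mean, spec.bp.dbp_sd), 50.0, sbp - 25.0))
    sbp_pa, dbp_pa = sbp * MMHG_TO_PA, dbp * MMHG_TO_PA
    map_pa = dbp_pa + (sbp_pa - dbp_pa) / 3.0

    # TCD velocity targets must carry the anatomy's signature: with a
    # permissive anterior communicating artery the junction pressures pin
    # the territory split, and independently sampled velocities are usually
    # infeasible.  So the generator samples scattered *territory flow
    # demands* (the hallmark of this population: peripheral resistances far
    # from the conventional area-proportional allocation), runs the linear
    # DC model forward, and reads the site velocity targets off that
    # anatomy-consistent solution.  Vasospastic site segments then show
    # elevated velocities automatically (same flow, narrowed lumen).
    q_mean = sv / period
    lo_r, hi_r = calib_config.resistance_bounds
    terminals = None
    for geometry_try in range(5):
        points, spasm = _draw_geometry(spec, topology, rng)
        geometry = PatientGeometry(inv_id, points, period)
        network = build_patient_network(topology, geometry)
        splits0 = area_proportional_split(network, q_mean)
        cerebral_terms_all = [
            t
            for t in network.terminal_nodes
            if network.feeding_segment(t).group == CEREBRAL
        ]
        for attempt in range(8):
            flow_sd = spec.territory_flow_sd * (0.7**attempt)
            boost = spec.cerebral_flow_boost * rng.lognormal(
                0.0, spec.cerebral_flow_patient_sd
            )
            demand = {
                t: splits0[t] * boost * rng.lognormal(0.0, flow_sd)
                for t in cerebral_terms_all
            }
            remainder = q_mean - sum(demand.values())
            if remainder < 0.3 * q_mean:  # keep a physiologic systemic share
                continue
            sys_terms = [t for t in network.terminal_nodes if t not in demand]
            sys_area = sum(
                network.feeding_segment(t).cross_section for t in sys_terms
            )
            for t in sys_terms:
                demand[t] = (
                    remainder * network.feeding_segment(t).cross_section / sys_area
                )
            scattered = initialize_terminals(
                network,
                map_pa,
                demand,
                proximal_fraction=calib_config.proximal_fraction,
                venous_pressure=calib_config.venous_pressure,
                seed_time_constant=calib_config.seed_time_constant,
            )
            dc0 = dc_solve(network, scattered, q_mean)
            # Sites with reversed or near-stagnant flow (vasospastic steal)
            # fall below the TCD detectability threshold and go unreported;
            # their terminals stay on the conventional allocation.
            v_min = spec.min_velocity_cm_s * 1e-2
            targets = {}
            for site in SITE_TERMINAL:
                seg = mapping[site]
                if seg not in network:
                    continue
                v_site = (
                    dc0.segment_flow[seg] / network.segments[seg].cross_section
                )
                if v_site >= v_min:
                    targets[site] = VelocityTarget(v_site)
            if len(targets) < 3:
                continue
            alloc_input = CalibrationInput(
                systolic_bp=sbp_pa,
                diastolic_bp=dbp_pa,
                heart_period=period,
                tcd_targets=targets,
                mean_bp=map_pa,
                stroke_volume=sv,
            )
            cand, diag = step1_peripheral_resistance(
                network, alloc_input, calib_config, mapping
            )
            at_bound = any(
                not (1.5 * lo_r < wk.total_resistance < hi_r / 1.5)
                for wk in cand.values()
            )
            if diag.converged and not at_bound:
                terminals = cand
                break
        if terminals is not None:
            break
    if terminals is None:
        raise RuntimeError(
            f"patient {index}: no feasible anatomy/demand draw"
        )

    # Resistance-scatter score vs the conventional area-proportional
    # allocation; large deviations earn the DCI-like label.
    conventional = initialize_terminals(
        network,
        map_pa,
        area_proportional_split(network, waveform.mean_flow),
        proximal_fraction=calib_config.proximal_fraction,
        venous_pressure=calib_config.venous_pressure,
        seed_time_constant=calib_config.seed_time_constant,
    )
    cerebral_terms = [
        t
        for t in network.terminal_nodes
        if network.feeding_segment(t).group == CEREBRAL
    ]
    log_dev = [
        math.log(
            terminals[t].total_resistance / conventional[t].total_resistance
        )
        for t in cerebral_terms
    ]
    scatter = float(np.std(log_dev))

    a = float(np.clip(rng.lognormal(0.0, spec.systemic_stiffness_sd), 0.5, 2.0))
    b = float(np.clip(rng.lognormal(0.0, spec.terminal_compliance_sd), 0.5, 2.0))
    m = float(
        np.clip(
            rng.lognormal(spec.cerebral_stiffness_log_mean, spec.cerebral_stiffness_sd),
            0.5,
            2.5,
        )
    )
    true_net = network.with_modulus_scaling(systemic=a, cerebral=m)
    true_terms = _terminal_compliance_scaled(
        terminals, true_net, systemic_factor=b, cerebral_factor=1.0 / m
    )

    # Forward-simulate the truth; its outputs are the noise-free observables.
    sim = run_simulation(true_net, true_terms, waveform, calib_config.simulation)
    root = pressure_statistics(sim, network.inlet_node)
    dc = dc_solve(network, terminals, waveform.mean_flow)
    true_velocities: dict[str, VelocityTarget] = {}
    for site in SITE_IDS:
        seg = mapping[site]
        if seg not in network:
            continue
        stats = cycle_statistics(sim, seg)
        area = network.segments[seg].cross_section
        if stats.mean / area < spec.min_velocity_cm_s * 1e-2:
            continue  # reversed or stagnant site: below TCD detectability
        if stats.diastolic_min > 0:
            true_velocities[site] = VelocityTarget(
                mean=stats.mean / area,
                systolic=stats.systolic_max / area,
                diastolic=stats.diastolic_min / area,
            )
        else:
            # diastolic reversal: report the mean only (envelope dropout)
            true_velocities[site] = VelocityTarget(mean=stats.mean / area)

    truth = TruthParameters(
        terminals=true_terms,
        systemic_modulus_multiplier=a,
        systemic_compliance_multiplier=b,
        cerebral_modulus_multiplier=m,
        waveform=waveform,
        site_velocities=true_velocities,
        systolic_bp=root.systolic_max,
        diastolic_bp=root.diastolic_min,
        mean_bp=dc.node_pressure[network.inlet_node],
        sampled_sbp=sbp_pa,
        sampled_dbp=dbp_pa,
        resistance_scatter=scatter,
    )

    # Noisy observations.  One log-normal gain per site scales the whole
    # velocity envelope (insonation-angle error); diameter noise is additive
    # Gaussian truncated above zero; absent segments stay exactly 0.
    rows = []
    for site, v in true_velocities.items():
        gain = rng.lognormal(0.0, spec.noise.velocity_sd)
        rows.append(
            {
                "investigation_id": inv_id,
                "site": site,
                "v_mean_cm_s": v.mean * gain * 1e2,
                "v_sys_cm_s": v.systolic * gain * 1e2 if v.systolic else np.nan,
                "v_dia_cm_s": v.diastolic * gain * 1e2 if v.diastolic else np.nan,
            }
        )
    measurements = pd.DataFrame(rows)
    obs_points: dict[str, tuple[float, ...]] = {}
    for name, pts in points.items():
        if all(p == 0 for p in pts):
            obs_points[name] = pts
            continue
        sd = spec.noise.diameter_sd_mm * MM_TO_M
        obs_points[name] = tuple(
            max(p + rng.normal(0.0, sd), 0.3 * MM_TO_M) for p in pts
        )
    vitals = {
        "sbp_mmHg": root.systolic_max * PA_TO_MMHG,
        "dbp_mmHg": root.diastolic_min * PA_TO_MMHG,
        "map_mmHg": dc.node_pressure[network.inlet_node] * PA_TO_MMHG,
        "hr_bpm": hr,
        "stroke_volume_ml": sv * 1e6,
    }

    fisher = int(rng.choice([1, 2, 3, 4], p=[0.03, 0.06, 0.455, 0.455]))
    labels = {
        "dci_like": bool(scatter > spec.dci_threshold),
        "fisher_grade": fisher,
        "aneurysm_location": "anterior" if rng.random() < 0.72 else "posterior",
    }
    return VirtualPatient(
        investigation_id=inv_id,
        geometry=geometry,
        network=network,
        truth=truth,
        observations=Observations(measurements, vitals, obs_points),
        labels=labels,
    )


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list[VirtualPatient]

    def manifest(self) -> dict:
        return {
            "seed": self.spec.seed,
            "n_patients": self.spec.n_patients,
            "spec_hash": self.spec.spec_hash(),
            "schema_version": 1,
        }

    def geometry_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for seg, pts in sorted(p.observations.point_diameters.items()):
                if all(d == 0 for d in pts):
                    rows.append(
                        {
                            "investigation_id": p.investigation_id,
                            "segment_name": seg,
                            "point_index": 0,
                            "diameter_mm": 0.0,
                        }
                    )
                    continue
                for i, d in enumerate(pts):
                    rows.append(
                        {
                            "investigation_id": p.investigation_id,
                            "segment_name": seg,
                            "point_index": i,
                            "diameter_mm": d * M_TO_MM,
                        }
                    )
        return pd.DataFrame(rows)

    def measurements_frame(self) -> pd.DataFrame:
        return pd.concat(
            [p.observations.measurements for p in self.patients], ignore_index=True
        )

    def vitals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"investigation_id": p.investigation_id, **p.observations.vitals}
                for p in self.patients
            ]
        )

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"investigation_id": p.investigation_id, **p.labels}
                for p in self.patients
            ]
        )


def generate_cohort(
    spec: CohortSpec,
    topology: NetworkTopology | None = None,
    calib_config: CalibrationConfig | None = None,
) -> Cohort:
    if spec.n_patients == 0:
        raise ValueError("cannot generate an empty cohort")
    patients = [
        generate_patient(spec, i, topology, calib_config)
        for i in range(spec.n_patients)
    ]
    return Cohort(spec, patients)


@dataclass
class EndToEndResult:
    table: pd.DataFrame
    icc: ICCResult
    loa: LogLoA
    n_failures: int
    failed_patients: tuple[str, ...]
    calibrations: dict[str, CalibrationResult]


def end_to_end_agreement(
    cohort: Cohort | CohortSpec,
    topology: NetworkTopology | None = None,
    calib_config: CalibrationConfig | None = None,
) -> EndToEndResult:
    """Calibrate every patient from its noisy observations and pool the
    paired (TCD, simulated) mean velocities into ICC and limits of
    agreement - the synthetic twin of the clinical validation design."""
    if isinstance(cohort, CohortSpec):
        cohort = generate_cohort(cohort, topology, calib_config)
    topology = topology or NetworkTopology.default()
    calib_config = calib_config or CalibrationConfig()
    mapping = site_segment_map(topology)
    rows = []
    failures: list[str] = []
    calibrations: dict[str, CalibrationResult] = {}
    for p in cohort.patients:
        try:
            obs_geom = PatientGeometry(
                p.investigation_id,
                p.observations.point_diameters,
                p.geometry.heart_period,
            )
            net = build_patient_network(topology, obs_geom)
            targets = {}
            for _, r in p.observations.measurements.iterrows():
                if np.isfinite(r["v_sys_cm_s"]) and np.isfinite(r["v_dia_cm_s"]):
                    targets[r["site"]] = VelocityTarget(
                        mean=r["v_mean_cm_s"] * 1e-2,
                        systolic=r["v_sys_cm_s"] * 1e-2,
                        diastolic=r["v_dia_cm_s"] * 1e-2,
                    )
                else:
                    targets[r["site"]] = VelocityTarget(mean=r["v_mean_cm_s"] * 1e-2)
            vit = p.observations.vitals
            inp = CalibrationInput(
                systolic_bp=vit["sbp_mmHg"] * MMHG_TO_PA,
                diastolic_bp=vit["dbp_mmHg"] * MMHG_TO_PA,
                heart_period=60.0 / vit["hr_bpm"],
                tcd_targets=targets,
                mean_bp=vit["map_mmHg"] * MMHG_TO_PA,
                stroke_volume=vit["stroke_volume_ml"] * 1e-6,
            )
            result = calibrate(net, inp, calib_config, mapping)
        except Exception:  # noqa: BLE001 - per-patient failures are reported
            failures.append(p.investigation_id)
            continue
        calibrations[p.investigation_id] = result
        for site, rec in result.simulated_velocities.items():
            v_tcd = float(
                p.observations.measurements.set_index("site").loc[site, "v_mean_cm_s"]
            )
            rows.append(
                {
                    "investigation_id": p.investigation_id,
                    "site": site,
                    "artery_class": SITE_ARTERY_CLASS[site],
                    "v_tcd": v_tcd,
                    "v_sim": rec.mean_velocity,
                    "dci_like": p.labels["dci_like"],
                    "high_bp": p.observations.vitals["sbp_mmHg"] > 140.0,
                    "fisher_high": p.labels["fisher_grade"] >= 3,
                    "aneurysm_location": p.labels["aneurysm_location"],
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("no patient calibrated successfully")
    return EndToEndResult(
        table=table,
        icc=icc_consistency(table),
        loa=log_bland_altman(table),
        n_failures=len(failures),
        failed_patients=tuple(failures),
        calibrations=calibrations,
    )
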
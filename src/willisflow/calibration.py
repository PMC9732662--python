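"""Three-step personalized calibration from blood pressure and TCD.

Step 1 fixes the peripheral (WK3) resistances with the linear DC circuit:
TCD mean velocities at the MCA, ACA and PCA sites are converted to mean
flows through the insonated segments and drive a fixed-point iteration of
the resistive nodal solve, anchored to the measured mean arterial pressure.
Terminals without an instrumented site keep the conventional
area-proportional allocation of the remaining cardiac output.

Step 2 fits two systemic multipliers - one on the Young's modulus of the
main-body segments, one on the main-body terminal compliances - so the
simulated aortic-root systolic and diastolic pressures match the cuff
measurements.

Step 3 fits one multiplier on the stiffness of the cerebral bed (segment
Young's moduli up, cerebral terminal compliances down by the same factor)
so the simulated systolic/diastolic flow-rate ratios at the instrumented
sites match the TCD envelope ratios in the least-squares sense.  Mean flows
are untouched: resistances are frozen after step 1 and the mean of the
periodic state depends only on resistances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import scipy.optimize

from .boundaries import (
    DEFAULT_PROXIMAL_FRACTION,
    DEFAULT_SEED_TIME_CONSTANT,
    DEFAULT_VENOUS_PRESSURE,
    InflowWaveform,
    WK3Terminal,
    area_proportional_split,
    initialize_terminals,
)
from .network import CEREBRAL, Network
from .solver import (
    SimulationConfig,
    cycle_statistics,
    dc_solve,
    pressure_statistics,
    run_simulation,
)
from .tcd import SITE_IDS, SITE_TERMINAL, site_segment_map


@dataclass(frozen=True)
class VelocityTarget:
    """Per-site TCD velocities in SI (m/s); systolic/diastolic optional."""

    mean: float
    systolic: float | None = None
    diastolic: float | None = None

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError("mean velocity target must be > 0")
        if (self.systolic is None) != (self.diastolic is None):
            raise ValueError("systolic and diastolic targets must come together")
        if self.systolic is not None and not self.systolic > self.diastolic > 0:
            raise ValueError("need systolic > diastolic > 0")


@dataclass(frozen=True)
class CalibrationInput:
    """Patient measurements driving the calibration (SI units)."""

    systolic_bp: float  # Pa
    diastolic_bp: float  # Pa
    heart_period: float  # s
    tcd_targets: Mapping[str, VelocityTarget]
    mean_bp: float | None = None  # Pa; defaults to DBP + pulse/3
    stroke_volume: float = 70e-6  # m^3

    def __post_init__(self) -> None:
        if not self.systolic_bp > self.diastolic_bp > 0:
            raise ValueError("need systolic > diastolic > 0")
        if not self.heart_period > 0:
            raise ValueError("heart period must be > 0")
        for site in self.tcd_targets:
            if site not in SITE_IDS:
                raise ValueError(f"unknown TCD site {site!r}")

    @property
    def map_bp(self) -> float:
        if self.mean_bp is not None:
            return self.mean_bp
        return self.diastolic_bp + (self.systolic_bp - self.diastolic_bp) / 3.0


@dataclass(frozen=True)
class CalibrationConfig:
    step1_tolerance: float = 1e-3
    step1_max_iter: int = 100
    step23_tolerance: float = 1e-2
    resistance_bounds: tuple[float, float] = (1e6, 1e12)
    multiplier_bounds: tuple[float, float] = (0.1, 10.0)
    proximal_fraction: float = DEFAULT_PROXIMAL_FRACTION
    venous_pressure: float = DEFAULT_VENOUS_PRESSURE
    seed_time_constant: float = DEFAULT_SEED_TIME_CONSTANT
    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            n_cycles=40,
            samples_per_cycle=160,
            periodicity_tolerance=1e-4,
        )
    )


@dataclass
class StepDiagnostics:
    iterations: int
    converged: bool
    residuals: dict
    messages: list[str] = field(default_factory=list)


@dataclass
class CalibrationResult:
    """Calibrated boundary conditions and wall parameters with diagnostics."""

    terminals: dict[str, WK3Terminal]
    network: Network
    systemic_modulus_multiplier: float
    systemic_compliance_multiplier: float
    cerebral_modulus_multiplier: float
    step_diagnostics: dict[str, StepDiagnostics]
    residuals: dict[str, float]
    simulated_velocities: dict[str, "object"]
    converged: bool


def velocities_to_flows(
    tcd_targets: Mapping[str, VelocityTarget],
    network: Network,
    mapping: Mapping[str, str] | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Mean-flow targets ``Q = v * pi d_eq^2 / 4`` per instrumented site.

    Sites whose mapped segment is absent are skipped with a warning message
    (returned alongside the flows).
    """
    mapping = mapping or site_segment_map()
    flows: dict[str, float] = {}
    skipped: list[str] = []
    for site, target in tcd_targets.items():
        seg_name = mapping[site]
        if seg_name not in network:
            msg = f"site {site}: segment {seg_name} absent; target skipped"
            warnings.warn(msg, stacklevel=2)
            skipped.append(msg)
            continue
        flows[site] = target.mean * network.segments[seg_name].cross_section
    return flows, skipped


def _with_totals(
    terminals: Mapping[str, WK3Terminal],
    totals: Mapping[str, float],
    proximal_fraction: float,
) -> dict[str, WK3Terminal]:
    return {
        t: replace(
            wk,
            proximal_resistance=proximal_fraction * totals[t],
            distal_resistance=(1 - proximal_fraction) * totals[t],
        )
        for t, wk in terminals.items()
    }


def _terminal_compliance_scaled(
    terminals: Mapping[str, WK3Terminal],
    network: Network,
    systemic_factor: float = 1.0,
    cerebral_factor: float = 1.0,
) -> dict[str, WK3Terminal]:
    out = {}
    for t, wk in terminals.items():
        group = network.feeding_segment(t).group
        f = cerebral_factor if group == CEREBRAL else systemic_factor
        out[t] = replace(wk, compliance=wk.compliance * f)
    return out


def step1_peripheral_resistance(
    network: Network,
    inp: CalibrationInput,
    config: CalibrationConfig | None = None,
    mapping: Mapping[str, str] | None = None,
) -> tuple[dict[str, WK3Terminal], StepDiagnostics]:
    """Fit the WK3 total resistances with the linear DC circuit.

    Fixed-point iteration: solve the resistive network, then update each
    instrumented cerebral terminal's resistance so the flow through its TCD
    site segment moves onto the measured value, and each remaining
    terminal's resistance so it carries its area-proportional share of the
    residual cardiac output.  A uniform additive resistance shift anchors
    the aortic-root mean pressure to the measured MAP every iteration.
    """
    config = config or CalibrationConfig()
    mapping = mapping or site_segment_map()
    q_total = inp.stroke_volume / inp.heart_period
    p_ven = config.venous_pressure
    messages: list[str] = []

    site_flows, skipped = velocities_to_flows(inp.tcd_targets, network, mapping)
    messages.extend(skipped)
    # Sites that constrain a single terminal territory (MCA/ACA/PCA).
    fit_sites = {
        s: q for s, q in site_flows.items() if s in SITE_TERMINAL
    }
    instrumented_terminals = {SITE_TERMINAL[s]: s for s in fit_sites}
    if not fit_sites:
        raise ValueError("step 1 requires at least one MCA/ACA/PCA velocity target")
    free_terminals = [
        t for t in network.terminal_nodes if t not in instrumented_terminals
    ]
    if free_terminals and q_total - sum(fit_sites.values()) <= 0:
        raise ValueError(
            "TCD-implied cerebral flow exceeds the cardiac output; "
            "check stroke volume and velocity units"
        )
    free_areas = {t: network.feeding_segment(t).cross_section for t in free_terminals}
    area_sum = sum(free_areas.values())

    def free_split(pool: float) -> dict[str, float]:
        return {t: pool * free_areas[t] / area_sum for t in free_terminals}

    # Initial pool: remainder of the cardiac output after the site flows.
    # Re-estimated every iteration from the instrumented terminals' implied
    # targets, because a site (segment) flow differs from its terminal flow
    # by whatever the communicating arteries carry.
    free_targets = free_split(q_total - sum(fit_sites.values()))

    seed_splits = dict(free_targets)
    for t, s in instrumented_terminals.items():
        seed_splits[t] = fit_sites[s]
    terminals = initialize_terminals(
        network,
        inp.map_bp,
        seed_splits,
        proximal_fraction=config.proximal_fraction,
        venous_pressure=p_ven,
        seed_time_constant=config.seed_time_constant,
    )

    lo, hi = config.resistance_bounds
    clipped: set[str] = set()
    term_order = list(network.terminal_nodes)

    def flow_residual_vector(terms: Mapping[str, WK3Terminal]):
        """Log-flow residuals (sites first, then free terminals) and the dc."""
        dc = dc_solve(network, terms, q_total)
        inst_targets = {}
        for t, site in instrumented_terminals.items():
            ratio = dc.segment_flow[mapping[site]] / fit_sites[site]
            inst_targets[t] = dc.terminal_flow[t] / ratio
        free_now = free_split(q_total - sum(inst_targets.values()))
        def safe_log_ratio(q, q_ref):
            # a transiently reversed flow maps to a large negative residual
            return math.log(max(q / q_ref, 1e-3))

        res = [
            safe_log_ratio(dc.segment_flow[mapping[s]], fit_sites[s])
            for s in fit_sites
        ] + [
            safe_log_ratio(dc.terminal_flow[t], free_now[t]) for t in free_terminals
        ]
        return np.array(res), dc, free_now

    converged = False
    iteration = 0
    residuals: dict[str, float] = {}
    for iteration in range(1, config.step1_max_iter + 1):
        res_vec, dc, free_targets = flow_residual_vector(terminals)
        residuals = {
            f"mean_flow:{site}": abs(math.expm1(res_vec[i]))
            for i, site in enumerate(fit_sites)
        }
        for j, t in enumerate(free_terminals):
            residuals[f"mean_flow:{t}"] = abs(math.expm1(res_vec[len(fit_sites) + j]))
        residuals["map"] = abs(
            dc.node_pressure[network.inlet_node] / inp.map_bp - 1.0
        )
        if max(residuals.values()) < config.step1_tolerance:
            converged = True
            break
        # Newton step on log total resistances: the anterior/posterior
        # communicating shunts couple the terminals strongly enough that a
        # per-terminal (diagonal) update stalls.
        x = np.array([math.log(terminals[t].total_resistance) for t in term_order])
        eps = 1e-6
        jac = np.empty((len(res_vec), len(term_order)))
        for j, t in enumerate(term_order):
            perturbed = dict(terminals)
            perturbed[t] = replace(
                terminals[t],
                proximal_resistance=terminals[t].proximal_resistance * math.exp(eps),
                distal_resistance=terminals[t].distal_resistance * math.exp(eps),
            )
            res_p, _, _ = flow_residual_vector(perturbed)
            jac[:, j] = (res_p - res_vec) / eps
        # rcond truncates the near-null "uniform pressure level" direction
        # (raising every resistance by dP/Q_i changes no flow); that mode is
        # controlled by the MAP anchor below, not by the flow fit.
        step, *_ = np.linalg.lstsq(jac, -res_vec, rcond=1e-3)
        step = np.clip(step, -1.5, 1.5)
        # Backtracking line search on the flow residual norm.
        base_norm = float(np.linalg.norm(res_vec))
        log_lo, log_hi = math.log(lo), math.log(hi)
        best = None
        for damp in (1.0, 0.5, 0.25, 0.1):
            x_try = np.clip(x + damp * step, log_lo, log_hi)
            trial = _with_totals(
                terminals,
                {t: float(np.exp(x_try[j])) for j, t in enumerate(term_order)},
                config.proximal_fraction,
            )
            res_try, _, _ = flow_residual_vector(trial)
            norm_try = float(np.linalg.norm(res_try))
            if best is None or norm_try < best[0]:
                best = (norm_try, trial)
            if norm_try < base_norm:
                break
        terminals = best[1]
        # Anchor the aortic-root mean pressure to the measured MAP: with the
        # flows of the updated network, a per-terminal shift dR_i = dP/Q_i
        # raises every nodal pressure by dP exactly while leaving all flows
        # unchanged.  The shift is capped at a factor of 2 per iteration so a
        # transiently mis-allocated terminal cannot be driven negative.
        dc_mid = dc_solve(network, terminals, q_total)
        dp = inp.map_bp - dc_mid.node_pressure[network.inlet_node]
        new_totals = {}
        for t in term_order:
            r_old = terminals[t].total_resistance
            r = r_old + dp / dc_mid.terminal_flow[t]
            r = min(max(r, 0.5 * r_old), 2.0 * r_old)
            if not lo <= r <= hi:
                clipped.add(t)
                r = min(max(r, lo), hi)
            new_totals[t] = r
        terminals = _with_totals(terminals, new_totals, config.proximal_fraction)

    worst = max(residuals.values())
    if clipped:
        messages.append(
            "resistance clipped to bounds at: " + ", ".join(sorted(clipped))
        )
    if not converged:
        messages.append(
            f"step 1 did not converge in {config.step1_max_iter} iterations; "
            f"worst residual {worst:.3e}"
        )
    return terminals, StepDiagnostics(iteration, converged, residuals, messages)


def _waveform_for(inp: CalibrationInput) -> InflowWaveform:
    return InflowWaveform(
        heart_period=inp.heart_period, stroke_volume=inp.stroke_volume
    )


def step2_systemic_compliance(
    network: Network,
    terminals: Mapping[str, WK3Terminal],
    inp: CalibrationInput,
    config: CalibrationConfig | None = None,
) -> tuple[Network, dict[str, WK3Terminal], tuple[float, float], StepDiagnostics]:
    """Fit systemic wall stiffness and peripheral compliance to SBP/DBP.

    Two-parameter root find in log space: a multiplier on the main-body
    segments' Young's moduli and a multiplier on the main-body terminal
    compliances, targeting the aortic-root systolic and diastolic pressures.
    """
    config = config or CalibrationConfig()
    waveform = _waveform_for(inp)
    sim_cfg = replace(config.simulation, run_to_convergence=True)
    lo, hi = config.multiplier_bounds
    log_lo, log_hi = math.log(lo), math.log(hi)
    n_eval = 0

    def press(a: float, b: float) -> tuple[float, float]:
        net = network.with_modulus_scaling(systemic=a)
        terms = _terminal_compliance_scaled(terminals, net, systemic_factor=b)
        res = run_simulation(net, terms, waveform, sim_cfg)
        stats = pressure_statistics(res, network.inlet_node)
        return stats.systolic_max, stats.diastolic_min

    def residual(logx: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        a = math.exp(min(max(logx[0], log_lo), log_hi))
        b = math.exp(min(max(logx[1], log_lo), log_hi))
        sbp, dbp = press(a, b)
        return np.array(
            [sbp / inp.systolic_bp - 1.0, dbp / inp.diastolic_bp - 1.0]
        )

    sol = scipy.optimize.root(residual, np.zeros(2), method="hybr", tol=1e-10)
    a = math.exp(min(max(sol.x[0], log_lo), log_hi))
    b = math.exp(min(max(sol.x[1], log_lo), log_hi))
    res = residual(sol.x)
    residuals = {"sbp": abs(res[0]), "dbp": abs(res[1])}
    converged = max(residuals.values()) < config.step23_tolerance
    messages = []
    if not converged:
        messages.append(
            "step 2 could not match the target pulse pressure within bounds; "
            "best-effort multipliers returned"
        )
    net2 = network.with_modulus_scaling(systemic=a)
    terms2 = _terminal_compliance_scaled(terminals, net2, systemic_factor=b)
    diag = StepDiagnostics(n_eval, converged, residuals, messages)
    return net2, terms2, (a, b), diag


def step3_cerebral_compliance(
    network: Network,
    terminals: Mapping[str, WK3Terminal],
    inp: CalibrationInput,
    config: CalibrationConfig | None = None,
    mapping: Mapping[str, str] | None = None,
    initial: float | None = None,
) -> tuple[Network, dict[str, WK3Terminal], float, StepDiagnostics]:
    """Fit the cerebral stiffness multiplier to the TCD envelope ratios.

    One multiplier ``m`` scales every cerebral segment's Young's modulus by
    ``m`` and every cerebral terminal compliance by ``1/m`` (the downstream
    bed stiffens with the conducting arteries).  The scalar fit matches the
    flow pulsatility index ``PI = (Q_sys - Q_dia) / Q_mean`` at the
    instrumented sites in the least-squares sense; PI carries the same
    information as the measured systolic/diastolic envelope once the means
    are fixed by step 1, but stays numerically stable when diastolic flows
    approach zero.  The squared-residual objective is scanned on a coarse
    log grid and polished with a bounded scalar minimization - inertial
    resonances of the carotid/vertebral paths can give the signed residual
    spurious extra zeros, so a plain root find is not reliable.

    ``initial`` (a multiplier guess, e.g. from a previous refinement pass)
    skips the global scan and searches near the guess.
    """
    config = config or CalibrationConfig()
    mapping = mapping or site_segment_map()
    env_sites = {
        s: t
        for s, t in inp.tcd_targets.items()
        if t.systolic is not None and mapping[s] in network
    }
    if not env_sites:
        raise ValueError("step 3 requires systolic/diastolic velocities at >= 1 site")
    pi_target = {
        s: (t.systolic - t.diastolic) / t.mean for s, t in env_sites.items()
    }
    waveform = _waveform_for(inp)
    sim_cfg = replace(config.simulation, run_to_convergence=True)
    lo, hi = config.multiplier_bounds
    n_eval = 0

    def sum_sq(log_m: float) -> float:
        nonlocal n_eval
        n_eval += 1
        m = math.exp(log_m)
        net = network.with_modulus_scaling(cerebral=m)
        terms = _terminal_compliance_scaled(terminals, net, cerebral_factor=1.0 / m)
        res = run_simulation(net, terms, waveform, sim_cfg)
        out = 0.0
        for s in env_sites:
            stats = cycle_statistics(res, mapping[s])
            pi = (stats.systolic_max - stats.diastolic_min) / stats.mean
            out += (pi / pi_target[s] - 1.0) ** 2
        return out

    messages: list[str] = []
    if initial is not None:
        left = max(math.log(initial) - 0.4, math.log(lo))
        right = min(math.log(initial) + 0.4, math.log(hi))
    else:
        grid = np.log(np.clip([0.25, 0.45, 0.75, 1.0, 1.4, 2.2, 3.5], lo, hi))
        vals = [sum_sq(g) for g in grid]
        i_best = int(np.argmin(vals))
        left = grid[max(i_best - 1, 0)]
        right = grid[min(i_best + 1, len(grid) - 1)]
    opt = scipy.optimize.minimize_scalar(
        sum_sq, bounds=(left, right), method="bounded", options={"xatol": 2e-3}
    )
    log_m = float(opt.x)
    m = math.exp(log_m)
    final_res = math.sqrt(sum_sq(log_m) / len(env_sites))
    converged = final_res < config.step23_tolerance
    if not converged:
        messages.append(
            "step 3 pulsatility targets not matched within tolerance; "
            "best-effort multiplier returned"
        )
    net3 = network.with_modulus_scaling(cerebral=m)
    terms3 = _terminal_compliance_scaled(terminals, net3, cerebral_factor=1.0 / m)
    diag = StepDiagnostics(
        n_eval, converged, {"pulsatility_index": abs(final_res)}, messages
    )
    return net3, terms3, m, diag


def calibrate(
    network: Network,
    inp: CalibrationInput,
    config: CalibrationConfig | None = None,
    mapping: Mapping[str, str] | None = None,
) -> CalibrationResult:
    """Run steps 1-3 in order and verify against every supplied target.

    Deterministic given inputs and configuration.  If no site carries
    systolic/diastolic velocities, step 3 is skipped with a warning and the
    cerebral multiplier stays 1.
    """
    from .tcd import TCDSite, extract_velocity  # local import to avoid cycle

    config = config or CalibrationConfig()
    mapping = mapping or site_segment_map()

    terminals, diag1 = step1_peripheral_resistance(network, inp, config, mapping)
    has_envelope = any(t.systolic is not None for t in inp.tcd_targets.values())

    # Steps 2 and 3 are weakly coupled (the cerebral bed contributes a small
    # share of the total compliance), so a second 2->3 pass removes the bias
    # the uncalibrated cerebral stiffness leaves in the systemic fit.  Each
    # pass fits incremental multipliers starting from the current state.
    net3, terms3 = network, terminals
    a = b = m = 1.0
    diag2 = diag3 = StepDiagnostics(0, True, {})
    n_passes = 2 if has_envelope else 1
    for pass_no in range(n_passes):
        net2, terms2, (da, db), diag2 = step2_systemic_compliance(
            net3, terms3, inp, config
        )
        a *= da
        b *= db
        if has_envelope:
            net3, terms3, dm, diag3 = step3_cerebral_compliance(
                net2,
                terms2,
                inp,
                config,
                mapping,
                initial=1.0 if pass_no > 0 else None,
            )
            m *= dm
        else:
            net3, terms3 = net2, terms2
    if not has_envelope:
        warnings.warn(
            "no systolic/diastolic TCD velocities supplied; step 3 skipped",
            stacklevel=2,
        )
        diag3 = StepDiagnostics(0, True, {}, ["skipped: no envelope targets"])

    # Final verification run against every supplied target.
    waveform = _waveform_for(inp)
    result = run_simulation(net3, terms3, waveform, config.simulation)
    residuals: dict[str, float] = {}
    simulated: dict[str, object] = {}
    for site, target in inp.tcd_targets.items():
        seg = mapping[site]
        if seg not in net3:
            continue
        rec = extract_velocity(result, TCDSite(site, seg), net3)
        simulated[site] = rec
        v_sim = rec.mean_velocity / 100.0  # cm/s -> m/s
        residuals[f"v_mean:{site}"] = abs(v_sim / target.mean - 1.0)
        if target.systolic is not None:
            pi_sim = (
                rec.systolic_velocity - rec.diastolic_velocity
            ) / rec.mean_velocity
            pi_tgt = (target.systolic - target.diastolic) / target.mean
            residuals[f"pulsatility_index:{site}"] = abs(pi_sim / pi_tgt - 1.0)
    stats = pressure_statistics(result, network.inlet_node)
    residuals["sbp"] = abs(stats.systolic_max / inp.systolic_bp - 1.0)
    residuals["dbp"] = abs(stats.diastolic_min / inp.diastolic_bp - 1.0)

    return CalibrationResult(
        terminals=terms3,
        network=net3,
        systemic_modulus_multiplier=a,
        systemic_compliance_multiplier=b,
        cerebral_modulus_multiplier=m,
        step_diagnostics={"step1": diag1, "step2": diag2, "step3": diag3},
        residuals=residuals,
        simulated_velocities=simulated,
        converged=diag1.converged and diag2.converged and diag3.converged,
    )
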
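"""Network solver: DC (mean-flow) solve and transient integration.

The governing equations are the standard RLC-network equations of the
electrical analog: one momentum balance per segment (flow through the
inertance), one volume balance per junction (pressure on the lumped nodal
compliance, half of each incident segment's compliance), and one volume
balance per WK3 compartment.  The arterial wall is treated as viscoelastic
(Voigt model): each nodal compliance carries a small series resistance,
which damps the non-physical high-frequency L-C ringing of a pure RLC
ladder while leaving cardiac-frequency waveforms essentially unchanged.

With fixed parameters the system is linear and time-invariant, driven only
by the prescribed inflow, so the transient solver propagates the state with
the exact matrix exponential of the (augmented) system over each output
step; the inflow is taken as piecewise linear between output samples.  This
handles the wide spread of R*C time constants across the terminals (a very
stiff system) without step-size restrictions.

Cumulative inflow and outflow volumes are carried as two extra states, so
the volume balance (inflow minus outflow minus compliant storage change)
is preserved to machine precision by construction and serves as a strong
internal consistency check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .boundaries import WK3Terminal
from .network import Network
from .units import MMHG_TO_PA

# State scaling applied before exponentiation: pressures in units of P0,
# flows in units of Q0, volumes in units of V0.  Balances the magnitudes in
# the system matrix (SI mixes 1e-13 compliances with 1e9 resistances).
_P0 = MMHG_TO_PA
_Q0 = 1e-6
_V0 = 1e-6


class SimulationDivergedError(RuntimeError):
    """Raised when the integrated state becomes non-finite."""


@dataclass(frozen=True)
class SimulationConfig:
    """Transient-run settings.

    ``n_cycles`` caps the run length (ten cardiac cycles reach the steady
    periodic state on the reference networks); the run stops one cycle after
    the consecutive-cycle residual first drops below
    ``periodicity_tolerance`` unless ``run_to_convergence`` is off.
    """

    n_cycles: int = 10
    samples_per_cycle: int = 200
    periodicity_tolerance: float = 0.01
    solver_method: str = "expm"
    run_to_convergence: bool = True
    wall_viscous_time: float = 0.03

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.samples_per_cycle < 8:
            raise ValueError("samples_per_cycle must be >= 8")
        if not self.periodicity_tolerance > 0:
            raise ValueError("periodicity tolerance must be > 0")
        if self.solver_method != "expm":
            raise ValueError(f"unknown solver method {self.solver_method!r}")


@dataclass(frozen=True)
class DCSolution:
    """Mean (zero-frequency) operating point of the resistive network."""

    node_pressure: Mapping[str, float]
    segment_flow: Mapping[str, float]
    terminal_flow: Mapping[str, float]
    kcl_residual: float  # max nodal current imbalance / inflow


def dc_solve(
    network: Network,
    terminals: Mapping[str, WK3Terminal],
    mean_inflow: float,
) -> DCSolution:
    """Solve the resistive nodal system (inertances shorted, compliances open).

    The mean inflow is injected at the inlet node and leaves through the WK3
    total resistances to the venous reference; Kirchhoff's current law holds
    at every node of the unique solution.
    """
    nodes = list(network.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    g_mat = np.zeros((n, n))
    rhs = np.zeros(n)
    for s in network.segments.values():
        g = 1.0 / network.rlc[s.name].resistance
        i, j = idx[s.proximal_node], idx[s.distal_node]
        g_mat[i, i] += g
        g_mat[j, j] += g
        g_mat[i, j] -= g
        g_mat[j, i] -= g
    for t in network.terminal_nodes:
        wk = terminals[t]
        g = 1.0 / wk.total_resistance
        i = idx[t]
        g_mat[i, i] += g
        rhs[i] += wk.venous_pressure * g
    rhs[idx[network.inlet_node]] += mean_inflow
    try:
        pressure = np.linalg.solve(g_mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular nodal system: network contains an isolated subnetwork"
        ) from exc
    node_pressure = {nd: float(pressure[idx[nd]]) for nd in nodes}
    segment_flow = {
        s.name: (node_pressure[s.proximal_node] - node_pressure[s.distal_node])
        / network.rlc[s.name].resistance
        for s in network.segments.values()
    }
    terminal_flow = {
        t: (node_pressure[t] - terminals[t].venous_pressure)
        / terminals[t].total_resistance
        for t in network.terminal_nodes
    }
    residual = g_mat @ pressure - rhs
    kcl = float(np.max(np.abs(residual)) / abs(mean_inflow)) if mean_inflow else 0.0
    return DCSolution(node_pressure, segment_flow, terminal_flow, kcl)


@dataclass
class ODESystem:
    """Assembled linear state-space system ``x' = A x + b0 + u(t) g``.

    State layout: segment flows, nodal wall-capacitor pressures, WK3
    compartment pressures, cumulative inflow volume, cumulative terminal
    outflow volume (SI).  Because of the viscoelastic (Voigt) wall, luminal
    node pressures are *outputs*: ``P = C_p x + d_p u(t)``.
    """

    a_matrix: np.ndarray
    b_const: np.ndarray
    g_inflow: np.ndarray
    pressure_output: np.ndarray  # (nn, n) luminal pressure read-out matrix
    pressure_feedthrough: np.ndarray  # (nn,) direct inflow contribution
    seg_names: tuple[str, ...]
    node_names: tuple[str, ...]
    term_nodes: tuple[str, ...]
    node_compliance: np.ndarray
    term_compliance: np.ndarray
    waveform: object
    scale: np.ndarray  # per-state scaling used by the exponential propagator

    @property
    def n_states(self) -> int:
        return self.a_matrix.shape[0]

    def state_index(self, kind: str, name: str) -> int:
        nq, nn = len(self.seg_names), len(self.node_names)
        if kind == "flow":
            return self.seg_names.index(name)
        if kind == "capacitor":
            return nq + self.node_names.index(name)
        if kind == "wk3":
            return nq + nn + self.term_nodes.index(name)
        raise KeyError(kind)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.a_matrix @ x + self.b_const + self.waveform.flow(t) * self.g_inflow

    def luminal_pressure(self, x: np.ndarray, u) -> np.ndarray:
        """Node pressures for state(s) ``x`` and inflow value(s) ``u``."""
        x = np.atleast_2d(x)
        u = np.atleast_1d(np.asarray(u, dtype=float))
        return x @ self.pressure_output.T + np.outer(u, self.pressure_feedthrough)

    def dc_state(self, dc: DCSolution, terminals: Mapping[str, WK3Terminal]) -> np.ndarray:
        x = np.zeros(self.n_states)
        for i, name in enumerate(self.seg_names):
            x[i] = dc.segment_flow[name]
        nq = len(self.seg_names)
        for i, name in enumerate(self.node_names):
            x[nq + i] = dc.node_pressure[name]
        nn = len(self.node_names)
        for i, t in enumerate(self.term_nodes):
            wk = terminals[t]
            x[nq + nn + i] = dc.node_pressure[t] - dc.terminal_flow[t] * wk.proximal_resistance
        return x

    def storage(self, x: np.ndarray) -> np.ndarray:
        """Compliant volume stored in nodal and WK3 compliances (m^3)."""
        nq, nn, nt = len(self.seg_names), len(self.node_names), len(self.term_nodes)
        x = np.atleast_2d(x)
        p_nodes = x[:, nq : nq + nn]
        p_wk = x[:, nq + nn : nq + nn + nt]
        s = p_nodes @ self.node_compliance + p_wk @ self.term_compliance
        return s if s.size > 1 else float(s[0])


#: Default viscoelastic (Voigt) wall time constant tau_w = R_visc * C_node, s.
DEFAULT_WALL_VISCOUS_TIME = 0.03


def assemble_odes(
    network: Network,
    terminals: Mapping[str, WK3Terminal],
    waveform,
    wall_viscous_time: float = DEFAULT_WALL_VISCOUS_TIME,
) -> ODESystem:
    """Build the linear viscoelastic-wall RLC state-space system.

    Each node lumps half the compliance of its incident segments, in series
    with a wall-viscosity resistance ``R_v = tau_w / C_n``.  The luminal
    pressure at a node is then ``P_n = y_n + R_v I_n`` with ``y_n`` the
    capacitor (wall) pressure and ``I_n`` the net current charging it; the
    model stays a linear ODE system after eliminating ``I_n``.
    """
    seg_names = tuple(network.segments)
    node_names = tuple(network.nodes)
    term_nodes = tuple(network.terminal_nodes)
    nq, nn, nt = len(seg_names), len(node_names), len(term_nodes)
    n = nq + nn + nt + 2  # + cumulative inflow / outflow volumes
    node_pos = {name: i for i, name in enumerate(node_names)}
    term_pos = {t: i for i, t in enumerate(term_nodes)}

    node_c = np.zeros(nn)
    inc = np.zeros((nn, nq))  # net segment current into each node
    for k, name in enumerate(seg_names):
        s = network.segments[name]
        c_half = network.rlc[name].compliance / 2.0
        node_c[node_pos[s.proximal_node]] += c_half
        node_c[node_pos[s.distal_node]] += c_half
        inc[node_pos[s.proximal_node], k] -= 1.0
        inc[node_pos[s.distal_node], k] += 1.0
    if wall_viscous_time < 0:
        raise ValueError("wall_viscous_time must be >= 0")
    r_visc = wall_viscous_time / node_c

    e_in = np.zeros(nn)
    e_in[node_pos[network.inlet_node]] = 1.0

    # Capacitor charging current I = Kq q + Ky y + Kc pc + ku u
    kq = inc.copy()
    ky = np.zeros((nn, nn))
    kc = np.zeros((nn, nt))
    ku = e_in.copy()
    rp = np.zeros(nt)
    rd = np.zeros(nt)
    cw = np.zeros(nt)
    pv = np.zeros(nt)
    for t, j in term_pos.items():
        wk = terminals[t]
        if wk.proximal_resistance <= 0:
            raise ValueError(f"terminal {t}: proximal resistance must be > 0")
        rp[j], rd[j], cw[j], pv[j] = (
            wk.proximal_resistance,
            wk.distal_resistance,
            wk.compliance,
            wk.venous_pressure,
        )
        i = node_pos[t]
        f = 1.0 / (1.0 + r_visc[i] / rp[j])
        kq[i, :] *= f
        ku[i] *= f
        ky[i, i] = -f / rp[j]
        kc[i, j] = f / rp[j]

    # Luminal pressure P = y + diag(r_visc) I
    rv = r_visc[:, None]
    mq = rv * kq
    my = np.eye(nn) + rv * ky
    mc = rv * kc
    mu = r_visc * ku

    a = np.zeros((n, n))
    b0 = np.zeros(n)
    g = np.zeros(n)
    sl_q = slice(0, nq)
    sl_y = slice(nq, nq + nn)
    sl_c = slice(nq + nn, nq + nn + nt)
    i_vin, i_vout = n - 2, n - 1

    # segment momentum: q' = (P_prox - P_dist - R q)/L
    for k, name in enumerate(seg_names):
        s = network.segments[name]
        rlc = network.rlc[name]
        ip_, id_ = node_pos[s.proximal_node], node_pos[s.distal_node]
        dp_q = mq[ip_, :] - mq[id_, :]
        dp_q[k] -= rlc.resistance
        a[k, sl_q] += dp_q / rlc.inertance
        a[k, sl_y] += (my[ip_, :] - my[id_, :]) / rlc.inertance
        a[k, sl_c] += (mc[ip_, :] - mc[id_, :]) / rlc.inertance
        g[k] += (mu[ip_] - mu[id_]) / rlc.inertance

    # nodal capacitor charge: y' = I / C_n
    a[sl_y, sl_q] = kq / node_c[:, None]
    a[sl_y, sl_y] = ky / node_c[:, None]
    a[sl_y, sl_c] = kc / node_c[:, None]
    g[sl_y] = ku / node_c

    # WK3 compartments: pc' = ((P_t - pc)/Rp - (pc - Pv)/Rd)/Cw
    for t, j in term_pos.items():
        i = node_pos[t]
        row = nq + nn + j
        a[row, sl_q] += mq[i, :] / (rp[j] * cw[j])
        a[row, sl_y] += my[i, :] / (rp[j] * cw[j])
        a[row, sl_c] += mc[i, :] / (rp[j] * cw[j])
        a[row, nq + nn + j] -= 1.0 / (rp[j] * cw[j]) + 1.0 / (rd[j] * cw[j])
        g[row] += mu[i] / (rp[j] * cw[j])
        b0[row] = pv[j] / (rd[j] * cw[j])
        a[i_vout, nq + nn + j] += 1.0 / rd[j]
        b0[i_vout] -= pv[j] / rd[j]

    g[i_vin] = 1.0

    pressure_output = np.zeros((nn, n))
    pressure_output[:, sl_q] = mq
    pressure_output[:, sl_y] = my
    pressure_output[:, sl_c] = mc

    scale = np.concatenate(
        [np.full(nq, _Q0), np.full(nn + nt, _P0), np.full(2, _V0)]
    )
    return ODESystem(
        a_matrix=a,
        b_const=b0,
        g_inflow=g,
        pressure_output=pressure_output,
        pressure_feedthrough=mu,
        seg_names=seg_names,
        node_names=node_names,
        term_nodes=term_nodes,
        node_compliance=node_c,
        term_compliance=cw,
        waveform=waveform,
        scale=scale,
    )


@dataclass
class SimulationResult:
    """Sampled state trajectory of a transient run (SI units)."""

    time: np.ndarray
    states: np.ndarray  # (n_samples, n_states)
    system: ODESystem
    samples_per_cycle: int
    heart_period: float
    converged: bool
    cycles_to_converge: int | None
    cycle_residuals: tuple[float, ...]

    @property
    def n_cycles_run(self) -> int:
        return (len(self.time) - 1) // self.samples_per_cycle

    @property
    def final_cycle(self) -> slice:
        """Index slice covering the last full cycle (inclusive endpoints)."""
        return slice(len(self.time) - self.samples_per_cycle - 1, len(self.time))

    def segment_flow(self, name: str) -> np.ndarray:
        return self.states[:, self.system.state_index("flow", name)]

    def node_pressure(self, name: str) -> np.ndarray:
        """Luminal pressure waveform at a node (includes wall-viscous drop)."""
        u = np.atleast_1d(np.asarray(self.system.waveform.flow(self.time)))
        p = self.system.luminal_pressure(self.states, u)
        return p[:, self.system.node_names.index(name)]

    def capacitor_pressure(self, name: str) -> np.ndarray:
        return self.states[:, self.system.state_index("capacitor", name)]

    def wk3_pressure(self, terminal: str) -> np.ndarray:
        return self.states[:, self.system.state_index("wk3", terminal)]

    @property
    def inflow_volume(self) -> np.ndarray:
        return self.states[:, -2]

    @property
    def outflow_volume(self) -> np.ndarray:
        return self.states[:, -1]

    def volume_balance(self) -> "VolumeBalance":
        """Final-cycle volume audit: inflow - outflow vs compliant storage."""
        sl = self.final_cycle
        x0, x1 = self.states[sl.start], self.states[-1]
        d_in = x1[-2] - x0[-2]
        d_out = x1[-1] - x0[-1]
        d_storage = float(self.system.storage(x1)) - float(self.system.storage(x0))
        residual = d_in - d_out - d_storage
        ref = max(abs(d_in), abs(d_out), 1e-30)
        return VolumeBalance(d_in, d_out, d_storage, residual, residual / ref)


@dataclass(frozen=True)
class VolumeBalance:
    inflow_volume: float
    outflow_volume: float
    storage_change: float
    residual: float
    relative_residual: float


def run_simulation(
    network: Network,
    terminals: Mapping[str, WK3Terminal],
    waveform,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Integrate to the steady periodic state, cycle by cycle.

    The state starts from the DC solution of the mean inflow (so only the
    pulsatile transient must settle), advances with the exact one-step
    propagator of the linear system, and reports the relative L2 difference
    between consecutive cycles' sampled waveforms.  Convergence is declared
    when that residual falls below the periodicity tolerance; one further
    cycle is then run so the final cycle is itself post-convergence.
    """
    config = config or SimulationConfig()
    system = assemble_odes(
        network, terminals, waveform, wall_viscous_time=config.wall_viscous_time
    )
    n = system.n_states
    period = waveform.heart_period
    steps = config.samples_per_cycle
    h = period / steps

    d = system.scale
    a_sc = system.a_matrix * (d[None, :] / d[:, None])
    b_sc = system.b_const / d
    g_sc = system.g_inflow / d

    m = np.zeros((n + 3, n + 3))
    m[:n, :n] = a_sc
    m[:n, n] = g_sc
    m[:n, n + 2] = b_sc
    m[n, n + 1] = 1.0  # inflow value integrates its within-step slope
    prop = scipy.linalg.expm(m * h)
    e_xx = prop[:n, :n]
    e_u = prop[:n, n]
    e_r = prop[:n, n + 1]
    e_1 = prop[:n, n + 2]

    dc = dc_solve(network, terminals, waveform.mean_flow)
    x = system.dc_state(dc, terminals) / d

    t_grid = h * np.arange(config.n_cycles * steps + 1)
    u = np.asarray(waveform.flow(t_grid), dtype=float)

    states = np.empty((config.n_cycles * steps + 1, n))
    states[0] = x
    residuals: list[float] = []
    converged = False
    cycles_to_converge: int | None = None
    cycles_run = 0
    # states used for the periodicity residual: everything except the
    # monotone cumulative-volume integrators
    dyn = slice(0, n - 2)

    for cycle in range(config.n_cycles):
        base = cycle * steps
        for k in range(base, base + steps):
            slope = (u[k + 1] - u[k]) / h
            x = e_xx @ x + e_u * u[k] + e_r * slope + e_1
            states[k + 1] = x
        cycles_run = cycle + 1
        if not np.all(np.isfinite(x)):
            raise SimulationDivergedError(
                f"simulation diverged at t = {t_grid[base + steps]:.4f} s"
            )
        if cycle >= 1:
            cur = states[base + 1 : base + steps + 1, dyn]
            prev = states[base - steps + 1 : base + 1, dyn]
            norm = np.linalg.norm(cur)
            res = np.linalg.norm(cur - prev) / norm if norm > 0 else 0.0
            residuals.append(float(res))
            if (
                config.run_to_convergence
                and not converged
                and res < config.periodicity_tolerance
            ):
                converged = True
                cycles_to_converge = cycle + 1
            elif config.run_to_convergence and converged:
                break  # one post-convergence cycle completed
    if not config.run_to_convergence:
        converged = bool(residuals and residuals[-1] < config.periodicity_tolerance)
        if converged:
            cycles_to_converge = next(
                i + 2
                for i, r in enumerate(residuals)
                if r < config.periodicity_tolerance
            )

    n_keep = cycles_run * steps + 1
    return SimulationResult(
        time=t_grid[:n_keep],
        states=states[:n_keep] * d[None, :],
        system=system,
        samples_per_cycle=steps,
        heart_period=period,
        converged=converged,
        cycles_to_converge=cycles_to_converge,
        cycle_residuals=tuple(residuals),
    )


@dataclass(frozen=True)
class CycleStatistics:
    mean: float
    systolic_max: float
    diastolic_min: float


def cycle_statistics(result: SimulationResult, segment_name: str) -> CycleStatistics:
    """Mean / max / min of a segment's flow over the final cycle."""
    if not result.converged:
        warnings.warn(
            "cycle statistics computed on an unconverged simulation",
            stacklevel=2,
        )
    sl = result.final_cycle
    q = result.segment_flow(segment_name)[sl]
    t = result.time[sl]
    mean = float(np.trapezoid(q, t) / (t[-1] - t[0]))
    return CycleStatistics(mean, float(np.max(q)), float(np.min(q)))


def pressure_statistics(result: SimulationResult, node_name: str) -> CycleStatistics:
    """Mean / systolic / diastolic pressure at a node over the final cycle."""
    sl = result.final_cycle
    p = result.node_pressure(node_name)[sl]
    t = result.time[sl]
    mean = float(np.trapezoid(p, t) / (t[-1] - t[0]))
    return CycleStatistics(mean, float(np.max(p)), float(np.min(p)))
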
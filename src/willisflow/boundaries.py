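"""Boundary conditions: aortic inflow, WK3 outlets, conventional flow split.

A prescribed flow waveform drives the root of the ascending aorta, and each
terminal branch ends in a three-element Windkessel (WK3): a proximal
resistance in series with a parallel distal-resistance/compliance pair,
referenced to venous pressure.  The conventional initialization allocates
the mean inflow across terminals in proportion to the cross-section area of
each terminal's feeding segment; the calibration procedure then replaces
that allocation with patient-specific values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .network import Network
from .units import MMHG_TO_PA

#: Default venous reference pressure, Pa (5 mmHg).
DEFAULT_VENOUS_PRESSURE = 5.0 * MMHG_TO_PA

#: Default share of the WK3 total resistance placed proximally
#: (characteristic-impedance convention).
DEFAULT_PROXIMAL_FRACTION = 0.1

#: Default seed time constant tau = R_d * C of every WK3 outlet, s.  Sets the
#: diastolic decay before calibration; step 2 rescales the compliances.
DEFAULT_SEED_TIME_CONSTANT = 1.3


class UnperfusedTerminalError(ValueError):
    """Raised when a terminal would receive zero mean flow (infinite resistance)."""


@dataclass(frozen=True)
class InflowWaveform:
    """Two-phase template: half-sine systolic ejection, zero-flow diastole.

    The one-period integral equals the stroke volume and the flow is
    non-negative throughout (no regurgitation).
    """

    heart_period: float = 0.8  # s
    stroke_volume: float = 70e-6  # m^3
    systolic_fraction: float = 0.35

    def __post_init__(self) -> None:
        if not self.heart_period > 0:
            raise ValueError("heart period must be > 0")
        if not self.stroke_volume > 0:
            raise ValueError("stroke volume must be > 0")
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic fraction must lie in (0, 1)")

    @property
    def systolic_duration(self) -> float:
        return self.systolic_fraction * self.heart_period

    @property
    def peak_flow(self) -> float:
        """Peak of the half-sine: pi * SV / (2 * t_sys)."""
        return math.pi * self.stroke_volume / (2.0 * self.systolic_duration)

    @property
    def mean_flow(self) -> float:
        return self.stroke_volume / self.heart_period

    def flow(self, t):
        """Instantaneous inflow (m^3/s) at time(s) ``t`` >= 0; periodic."""
        tau = np.mod(np.asarray(t, dtype=float), self.heart_period)
        q = np.where(
            tau < self.systolic_duration,
            self.peak_flow * np.sin(np.pi * tau / self.systolic_duration),
            0.0,
        )
        if np.ndim(t) == 0:
            return float(q)
        return q


@dataclass(frozen=True)
class SinusoidalInflow:
    """Mean + single-harmonic inflow, used for frequency-response checks."""

    heart_period: float
    mean: float
    amplitude: float

    @property
    def mean_flow(self) -> float:
        return self.mean

    def flow(self, t):
        t = np.asarray(t, dtype=float)
        q = self.mean + self.amplitude * np.sin(2.0 * np.pi * t / self.heart_period)
        if q.ndim == 0:
            return float(q)
        return q


@dataclass(frozen=True)
class ConstantInflow:
    """Constant inflow, used for DC consistency checks."""

    heart_period: float
    mean: float

    @property
    def mean_flow(self) -> float:
        return self.mean

    def flow(self, t):
        t = np.asarray(t, dtype=float)
        q = np.full_like(t, self.mean, dtype=float)
        if q.ndim == 0:
            return float(q)
        return q


def aortic_inflow(waveform, t):
    """Prescribed flow rate at the ascending-aorta root (m^3/s)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be >= 0")
    return waveform.flow(t)


@dataclass(frozen=True)
class WK3Terminal:
    """Three-element Windkessel outlet at one terminal branch."""

    terminal_id: str
    proximal_resistance: float  # Pa s / m^3
    distal_resistance: float  # Pa s / m^3
    compliance: float  # m^3 / Pa
    venous_pressure: float = DEFAULT_VENOUS_PRESSURE  # Pa

    def __post_init__(self) -> None:
        if self.proximal_resistance < 0 or self.distal_resistance < 0:
            raise ValueError("WK3 resistances must be >= 0")
        if not self.compliance > 0:
            raise ValueError("WK3 compliance must be > 0")

    @property
    def total_resistance(self) -> float:
        return self.proximal_resistance + self.distal_resistance


def wk3_impedance(terminal: WK3Terminal, angular_frequency: float) -> complex:
    """Input impedance ``Z(w) = R_p + R_d / (1 + i w R_d C)``."""
    if np.any(np.asarray(angular_frequency) < 0):
        raise ValueError("angular frequency must be >= 0")
    w = angular_frequency
    rd = terminal.distal_resistance
    return terminal.proximal_resistance + rd / (1.0 + 1j * w * rd * terminal.compliance)


def area_proportional_split(
    network: Network, total_mean_flow: float
) -> dict[str, float]:
    """Conventional split: terminal mean flow proportional to feeding area.

    ``Q_i = Q_total * A_i / sum(A_j)`` where ``A_i`` is the cross-section of
    the segment feeding terminal ``i``.  The flows sum to ``Q_total`` exactly.
    """
    areas = {
        t: network.feeding_segment(t).cross_section for t in network.terminal_nodes
    }
    total_area = sum(areas.values())
    if total_area <= 0:
        raise ValueError("all terminal feeding areas are zero")
    return {t: total_mean_flow * a / total_area for t, a in areas.items()}


def initialize_terminals(
    network: Network,
    mean_arterial_pressure: float,
    splits: Mapping[str, float],
    proximal_fraction: float = DEFAULT_PROXIMAL_FRACTION,
    venous_pressure: float = DEFAULT_VENOUS_PRESSURE,
    seed_time_constant: float = DEFAULT_SEED_TIME_CONSTANT,
) -> dict[str, WK3Terminal]:
    """Seed WK3 parameters from MAP and a per-terminal mean-flow allocation.

    Total resistance is ``(MAP - P_v) / Q_i``, partitioned by the fixed
    proximal fraction.  Compliance is seeded so every outlet shares the same
    diastolic time constant ``tau = R_d C``, which makes it proportional to
    the allocated flow.
    """
    if mean_arterial_pressure <= venous_pressure:
        raise ValueError("mean arterial pressure must exceed venous pressure")
    if not 0 < proximal_fraction < 1:
        raise ValueError("proximal fraction must lie in (0, 1)")
    terminals: dict[str, WK3Terminal] = {}
    for t in network.terminal_nodes:
        q = splits.get(t, 0.0)
        if q <= 0:
            raise UnperfusedTerminalError(
                f"terminal {t} has zero allocated mean flow (infinite resistance)"
            )
        r_total = (mean_arterial_pressure - venous_pressure) / q
        r_prox = proximal_fraction * r_total
        r_dist = r_total - r_prox
        compliance = seed_time_constant / r_dist
        terminals[t] = WK3Terminal(
            terminal_id=t,
            proximal_resistance=r_prox,
            distal_resistance=r_dist,
            compliance=compliance,
            venous_pressure=venous_pressure,
        )
    return terminals
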
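"""Lumped-capacitance forward model of laser heating and cooling.

A stirred cuvette of suspension under near-infrared irradiation is treated
as a single thermal node with total heat capacity ``ΣmᵢC_p,ᵢ`` (J/K).  The
energy balance is

    ΣmC · dT/dt = Q_NPs + Q_s − hA·(T − T_surr)

where ``Q_NPs = I·(1 − 10^(−A))·η`` is the heat released by the
photothermal agent (laser power ``I`` in W, absorbance ``A`` at the laser
wavelength, conversion efficiency ``η``), ``Q_s`` is the heat deposited in
the solvent while the laser is on, and ``hA`` (W/K) is the lumped product
of the convective heat-transfer coefficient and the container surface
area.  Only the product ``hA`` is identifiable from temperature data, so
the model never separates the two factors.

Within any interval of constant laser power the balance is linear in ``T``
and solves in closed form: the temperature relaxes exponentially toward
``T_surr + Q/hA`` with time constant ``τ = ΣmC/hA``.  The simulator
stitches these per-segment exponentials together, which is exact — a
numeric ODE integrator is used only as an independent cross-check in the
test suite.

Units: temperatures in °C, temperature differences in K, times in
seconds, powers in watts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "ThermalSystem",
    "LaserSegment",
    "LaserProtocol",
    "TemperatureTrace",
    "input_power",
    "steady_state_delta",
    "simulate_trace",
    "analytic_cooling",
]


@dataclass(frozen=True)
class ThermalSystem:
    """Physical parameters of one cuvette experiment.

    Parameters
    ----------
    heat_capacity_total : float
        Total heat capacity ΣmᵢC_p,ᵢ of the irradiated system, J/K.
    hA : float
        Heat-transfer coefficient × container surface area, W/K.
    eta : float
        Photothermal conversion efficiency, dimensionless in [0, 1].
    absorbance : float
        Absorbance of the suspension at the laser wavelength (808 nm).
    solvent_heat : float, optional
        Q_s, heat absorbed by the solvent per second while the laser is
        on, W.  Default 0.
    ambient_temp : float, optional
        Surrounding temperature T_surr, °C.  Default 25.0.
    """

    heat_capacity_total: float
    hA: float
    eta: float
    absorbance: float
    solvent_heat: float = 0.0
    ambient_temp: float = 25.0

    def __post_init__(self) -> None:
        if not (self.heat_capacity_total > 0 and math.isfinite(self.heat_capacity_total)):
            raise InvalidInputError("heat_capacity_total must be positive and finite")
        if not (self.hA > 0 and math.isfinite(self.hA)):
            raise InvalidInputError("hA must be positive and finite")
        if not 0.0 <= self.eta <= 1.0:
            raise InvalidInputError(f"eta must lie in [0, 1], got {self.eta}")
        if self.absorbance < 0:
            raise InvalidInputError("absorbance must be non-negative")
        if self.solvent_heat < 0:
            raise InvalidInputError("solvent_heat must be non-negative")

    @property
    def tau_s(self) -> float:
        """Relaxation time constant τ = ΣmC / hA, seconds."""
        return self.heat_capacity_total / self.hA


@dataclass(frozen=True)
class LaserSegment:
    """One constant-power interval: [start_s, end_s) at power_W watts."""

    start_s: float
    end_s: float
    power_W: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise InvalidInputError(
                f"segment start ({self.start_s}) must precede end ({self.end_s})"
            )
        if self.power_W < 0:
            raise InvalidInputError("laser power must be non-negative")


@dataclass(frozen=True)
class LaserProtocol:
    """Ordered, non-overlapping laser on/off segments.

    Power 0 encodes laser-off.  Time outside every segment is implicitly
    laser-off as well, so a protocol may list only the "on" windows.
    """

    segments: tuple[LaserSegment, ...]

    def __init__(self, segments) -> None:
        segs = tuple(
            s if isinstance(s, LaserSegment) else LaserSegment(*s) for s in segments
        )
        if not segs:
            raise InvalidInputError("protocol needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s:
                raise InvalidInputError(
                    f"segments overlap or are unsorted at t={b.start_s}"
                )
        object.__setattr__(self, "segments", segs)

    @classmethod
    def cycles(
        cls,
        n_cycles: int,
        power_W: float,
        on_s: float = 600.0,
        off_s: float = 600.0,
        start_s: float = 0.0,
    ) -> "LaserProtocol":
        """Repeated on/off cycling, the photostability protocol shape."""
        if n_cycles < 1:
            raise InvalidInputError("n_cycles must be >= 1")
        segs = []
        t = start_s
        for _ in range(n_cycles):
            segs.append(LaserSegment(t, t + on_s, power_W))
            segs.append(LaserSegment(t + on_s, t + on_s + off_s, 0.0))
            t += on_s + off_s
        return cls(segs)

    @property
    def start_s(self) -> float:
        return self.segments[0].start_s

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    def on_segments(self) -> list[LaserSegment]:
        return [s for s in self.segments if s.power_W > 0]

    def power_at(self, t: float) -> float:
        """Laser power at time t; 0 outside every segment."""
        for s in self.segments:
            if s.start_s <= t < s.end_s:
                return s.power_W
        return 0.0

    def on_index_at(self, t: float) -> int:
        """Number of laser-on segments fully completed before time t.

        Equals the 0-based index of the current cycle during cycling
        protocols; used to apply per-cycle photobleaching.
        """
        return sum(1 for s in self.on_segments() if s.end_s <= t)


@dataclass
class TemperatureTrace:
    """A sampled (time, temperature) series — the universal measurement record."""

    times: np.ndarray
    temps: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.ndim != 1 or self.temps.ndim != 1:
            raise InvalidInputError("times and temps must be 1-D")
        if self.times.size != self.temps.size:
            raise InvalidInputError("times and temps must have equal length")
        if self.times.size < 2:
            raise InvalidInputError("a trace needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.temps))):
            raise InvalidInputError("times and temps must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def window(self, t0: float, t1: float, label: str | None = None) -> "TemperatureTrace":
        """Sub-trace with t0 <= time <= t1 (original time axis kept)."""
        mask = (self.times >= t0) & (self.times <= t1)
        from .exceptions import InsufficientDataError

        if mask.sum() < 2:
            raise InsufficientDataError(
                f"fewer than 2 samples in window [{t0}, {t1}] of trace {self.label!r}"
            )
        return TemperatureTrace(
            self.times[mask], self.temps[mask], label=self.label if label is None else label
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "temp_C": self.temps})


def _absorbed_fraction(absorbance: float) -> float:
    return 1.0 - 10.0 ** (-absorbance)


def heat_input(system: ThermalSystem, laser_power: float, eta: float | None = None) -> float:
    """Total heat deposition rate Q (W) at a given laser power.

    Power 0 encodes laser-off, in which case neither the agent nor the
    solvent is heated and Q = 0.  ``eta`` overrides the system efficiency
    (used to impose per-cycle photobleaching in the generator).
    """
    if laser_power < 0:
        raise InvalidInputError("laser power must be non-negative")
    if laser_power == 0:
        return 0.0
    if eta is None:
        eta = system.eta
    return laser_power * _absorbed_fraction(system.absorbance) * eta + system.solvent_heat


def input_power(system: ThermalSystem, laser_power: float) -> float:
    """Q_NPs + Q_s = I·(1 − 10^(−A))·η + Q_s while the laser is on; 0 when off."""
    return heat_input(system, laser_power)


def steady_state_delta(system: ThermalSystem, laser_power: float) -> float:
    """Steady-state temperature rise ΔT_max = (Q_NPs + Q_s) / hA, kelvin.

    At steady state the heat input balances the loss hA·ΔT.
    """
    if system.hA <= 0:
        raise InvalidInputError("hA must be positive")
    return input_power(system, laser_power) / system.hA


def _relax_piecewise(
    system: ThermalSystem,
    intervals: list[tuple[float, float, float]],
    sample_times: np.ndarray,
    initial_temp: float,
) -> np.ndarray:
    """Exact piecewise-exponential solution over contiguous constant-Q intervals.

    ``intervals`` is a list of (t_start, t_end, Q_watts) covering all
    sample times in ascending contiguous order.  Within each interval the
    temperature relaxes toward T_surr + Q/hA with time constant τ; the
    solution is continuous across boundaries.
    """
    tau = system.tau_s
    t_surr = system.ambient_temp
    out = np.empty(sample_times.shape, dtype=float)
    T = float(initial_temp)
    last = len(intervals) - 1
    for i, (a, b, q) in enumerate(intervals):
        t_inf = t_surr + q / system.hA
        if i == last:
            mask = (sample_times >= a) & (sample_times <= b)
        else:
            mask = (sample_times >= a) & (sample_times < b)
        if mask.any():
            dt = sample_times[mask] - a
            out[mask] = t_inf + (T - t_inf) * np.exp(-dt / tau)
        T = t_inf + (T - t_inf) * math.exp(-(b - a) / tau)
    return out


def _protocol_intervals(
    system: ThermalSystem,
    protocol: LaserProtocol,
    t0: float,
    t1: float,
    eta_of_cycle=None,
) -> list[tuple[float, float, float]]:
    """Constant-Q intervals covering [t0, t1], with optional per-cycle η."""
    pts = {t0, t1}
    for s in protocol.segments:
        for p in (s.start_s, s.end_s):
            if t0 < p < t1:
                pts.add(p)
    knots = sorted(pts)
    intervals = []
    for a, b in zip(knots, knots[1:]):
        mid = 0.5 * (a + b)
        power = protocol.power_at(mid)
        eta = None
        if eta_of_cycle is not None and power > 0:
            eta = eta_of_cycle(protocol.on_index_at(mid))
        intervals.append((a, b, heat_input(system, power, eta=eta)))
    if not intervals:  # single sample time == t0 == t1
        intervals.append((t0, t1, heat_input(system, protocol.power_at(t0))))
    return intervals


def simulate_trace(
    system: ThermalSystem,
    protocol: LaserProtocol,
    sample_times,
    initial_temp: float | None = None,
    label: str = "",
    _eta_of_cycle=None,
) -> TemperatureTrace:
    """Noiseless temperature trace under a laser protocol.

    Solves dT/dt = (Q(t) − hA·(T − T_surr)) / ΣmC with the exact
    per-segment closed form.  The initial temperature applies at the first
    sample time (default: ambient).
    """
    t = np.asarray(sample_times, dtype=float)
    if t.size == 0:
        raise InvalidInputError("sample_times must be non-empty")
    if not np.all(np.diff(t) > 0):
        raise InvalidInputError("sample_times must be strictly increasing")
    T0 = system.ambient_temp if initial_temp is None else float(initial_temp)
    t0 = min(float(t[0]), protocol.start_s)
    intervals = _protocol_intervals(system, protocol, t0, float(t[-1]), _eta_of_cycle)
    temps = _relax_piecewise(system, intervals, t, T0)
    return TemperatureTrace(t, temps, label=label)


def analytic_cooling(
    system: ThermalSystem, start_temp: float, times, label: str = ""
) -> TemperatureTrace:
    """Laser-off relaxation T(t) = T_surr + (T₀ − T_surr)·exp(−t/τ)."""
    t = np.asarray(times, dtype=float)
    dT0 = start_temp - system.ambient_temp
    temps = system.ambient_temp + dT0 * np.exp(-t / system.tau_s)
    return TemperatureTrace(t, temps, label=label)
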
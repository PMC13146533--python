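"""Seeded synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:
thermal-imager temperature logs under laser on/off protocols (60-s
sampling by default, matching the experimental logging rate), linear
absorbance–concentration calibration points, and plate-reader viability
tables.  All generators are pure functions of their spec including the
seed, so outputs are bitwise-reproducible.

The temperature generator is the noiseless forward model plus iid
Gaussian measurement noise; optional photobleaching scales the
conversion efficiency by ``(1 − bleaching_per_cycle)`` for every
completed laser-on/off cycle — a phenomenological stand-in for the
monotone per-cycle peak loss of a bleaching dye, not a mechanistic
claim.

The module also ships a demo scenario whose sample trace rises
26.3 → ~62 °C and whose water reference rises 26.3 → 26.8 °C under a
600-s, 2.5-W irradiation, mirroring a realistic ICG-loaded-carbon
experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .thermal import (
    LaserProtocol,
    TemperatureTrace,
    ThermalSystem,
    simulate_trace,
)

__all__ = [
    "TraceGenSpec",
    "TraceGroundTruth",
    "make_trace",
    "make_calibration_points",
    "make_viability_plate",
    "DemoScenario",
    "icg_demo_scenario",
]


@dataclass(frozen=True)
class TraceGenSpec:
    """Everything needed to emulate one thermal-imager log."""

    system: ThermalSystem
    protocol: LaserProtocol
    sampling_interval_s: float = 60.0
    noise_sigma_K: float = 0.2
    bleaching_per_cycle: float = 0.0
    seed: int = 0
    initial_temp: float | None = None
    duration_s: float | None = None  # default: protocol end
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.sampling_interval_s <= 0:
            raise InvalidInputError("sampling_interval_s must be positive")
        if self.noise_sigma_K < 0:
            raise InvalidInputError("noise_sigma_K must be >= 0")
        if not 0.0 <= self.bleaching_per_cycle < 1.0:
            raise InvalidInputError("bleaching_per_cycle must lie in [0, 1)")

    def sample_times(self) -> np.ndarray:
        end = self.protocol.end_s if self.duration_s is None else self.duration_s
        n = int(math.floor(end / self.sampling_interval_s + 1e-9))
        return np.arange(n + 1, dtype=float) * self.sampling_interval_s


@dataclass(frozen=True)
class TraceGroundTruth:
    """The generator's hidden truth, for recovery studies."""

    eta_by_cycle: tuple[float, ...]
    hA: float
    tau_s: float
    noiseless: TemperatureTrace


def make_trace(spec: TraceGenSpec) -> tuple[TemperatureTrace, TraceGroundTruth]:
    """Noiseless forward simulation plus seeded additive Gaussian noise."""
    sys = spec.system
    b = spec.bleaching_per_cycle
    eta_of_cycle = (lambda k: sys.eta * (1.0 - b) ** k) if b > 0 else None
    times = spec.sample_times()
    clean = simulate_trace(
        sys,
        spec.protocol,
        times,
        initial_temp=spec.initial_temp,
        label=spec.label,
        _eta_of_cycle=eta_of_cycle,
    )
    n_cycles = max(len(spec.protocol.on_segments()), 1)
    etas = tuple(sys.eta * (1.0 - b) ** k for k in range(n_cycles))
    rng = np.random.default_rng(spec.seed)
    noisy = clean.temps + rng.normal(0.0, spec.noise_sigma_K, size=times.size)
    trace = TemperatureTrace(times, noisy, label=spec.label)
    truth = TraceGroundTruth(
        eta_by_cycle=etas, hA=sys.hA, tau_s=sys.tau_s, noiseless=clean
    )
    return trace, truth


def make_calibration_points(
    slope: float,
    intercept: float,
    concentrations,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Standards on the line A = slope·c + intercept with Gaussian noise."""
    if slope <= 0:
        raise InvalidInputError("slope must be positive")
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    a = slope * c + intercept + rng.normal(0.0, noise_sigma, size=c.size)
    return [(float(ci), float(ai)) for ci, ai in zip(c, a)]


def make_viability_plate(
    true_viability_by_group: dict[str, float],
    control_absorbance: float = 1.0,
    noise_sigma: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    control_group: str = "control",
) -> pd.DataFrame:
    """Long plate table (group, replicate, absorbance) incl. a control group.

    Sample absorbance = control_absorbance · viability/100 + noise.
    """
    if control_absorbance <= 0:
        raise InvalidInputError("control_absorbance must be positive")
    if any(v < 0 for v in true_viability_by_group.values()):
        raise InvalidInputError("viabilities must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    groups = {control_group: 100.0, **true_viability_by_group}
    for group, viability in groups.items():
        for rep in range(1, replicates + 1):
            a = control_absorbance * viability / 100.0 + rng.normal(0.0, noise_sigma)
            rows.append({"group": group, "replicate": rep, "absorbance": max(a, 0.0)})
    return pd.DataFrame(rows)


# --- demo scenario -----------------------------------------------------------

AMBIENT_C = 26.3          # room temperature of the demo runs, deg C
HEAT_CAPACITY_J_PER_K = 4.18   # ~1 mL water
TAU_S = 120.0             # plateau within the 600-s window, cooled by 600 s off
LASER_POWER_W = 2.5       # 2.5 W/cm2 x 1 cm2 beam
SAMPLE_DT_MAX_K = 35.7    # 26.3 -> 62.0 C
WATER_DT_MAX_K = 0.5      # 26.3 -> 26.8 C
ETA_TRUE = 0.76


@dataclass(frozen=True)
class DemoScenario:
    """Sample + water systems and the single-cycle protocol of the demo."""

    sample_system: ThermalSystem
    water_system: ThermalSystem
    protocol: LaserProtocol
    laser_off_s: float
    laser_power_W: float
    sampling_interval_s: float = 60.0

    @property
    def eta_true(self) -> float:
        return self.sample_system.eta


def icg_demo_scenario(
    on_s: float = 600.0, off_s: float = 600.0, n_cycles: int = 1
) -> DemoScenario:
    """A realistic dye-loaded-carbon scenario with known ground truth.

    Parameters are solved so that the steady-state rises are exactly
    35.7 K (sample) and 0.5 K (water reference): the absorbance is
    derived from the target dye heating rather than hard-coded.
    """
    hA = HEAT_CAPACITY_J_PER_K / TAU_S
    q_s = WATER_DT_MAX_K * hA
    q_nps = SAMPLE_DT_MAX_K * hA - q_s
    absorbed = q_nps / (LASER_POWER_W * ETA_TRUE)   # 1 - 10^(-A)
    absorbance = -math.log10(1.0 - absorbed)
    common = dict(
        heat_capacity_total=HEAT_CAPACITY_J_PER_K,
        hA=hA,
        solvent_heat=q_s,
        ambient_temp=AMBIENT_C,
    )
    sample = ThermalSystem(eta=ETA_TRUE, absorbance=absorbance, **common)
    water = ThermalSystem(eta=0.0, absorbance=absorbance, **common)
    protocol = LaserProtocol.cycles(n_cycles, LASER_POWER_W, on_s=on_s, off_s=off_s)
    return DemoScenario(
        sample_system=sample,
        water_system=water,
        protocol=protocol,
        laser_off_s=on_s,
        laser_power_W=LASER_POWER_W,
    )
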
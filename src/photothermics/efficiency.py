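"""Inverse estimation of τ, hA and the photothermal conversion efficiency η.

The estimator follows the standard cooling-curve procedure for
photothermal agents.  At steady state under irradiation the heat input
balances the loss,

    I·(1 − 10^(−A))·η + Q_s = hA·ΔT_max,mix ,

and the same balance for a pure-water reference under the identical
protocol gives ``Q_s = hA·ΔT_max,H2O``, so

    η = hA·(ΔT_max,mix − ΔT_max,H2O) / (I·(1 − 10^(−A))) .

The lumped loss parameter hA is obtained from the laser-off relaxation:
with the dimensionless driving force θ = (T − T_surr)/(T_max − T_surr),
cooling obeys θ(t) = exp(−t/τ), so ordinary least squares of time against
−ln θ has slope τ and hA = ΣmC/τ.

The statsmodels-style entry point is :class:`PhotothermalEfficiencyModel`
(construct from a sample trace and a water reference trace, call
``fit()``); the individual pipeline stages are exposed as functions for
testing and scripting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateFitError,
    EfficiencyBoundsWarning,
    InsufficientDataError,
    InvalidInputError,
    PlateauFallbackWarning,
)
from .thermal import TemperatureTrace

__all__ = [
    "ThetaSeries",
    "TimeConstantFit",
    "EfficiencyEstimate",
    "PhotothermalEfficiencyModel",
    "extract_cooling",
    "compute_theta",
    "fit_time_constant",
    "compute_hA",
    "compute_eta",
    "plateau_delta",
    "estimate_efficiency",
]

DEFAULT_THETA_FLOOR = 0.05
DEFAULT_PLATEAU_K = 3


@dataclass(frozen=True)
class ThetaSeries:
    """Dimensionless cooling series: times re-zeroed at laser-off, θ ∈ (floor, 1]."""

    times: np.ndarray
    theta: np.ndarray
    theta_floor: float
    n_dropped_low: int = 0
    n_dropped_high: int = 0

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TimeConstantFit:
    """OLS fit of t against −ln θ: slope = τ (s), intercept as diagnostic."""

    tau_s: float
    intercept_s: float
    r_squared: float
    n_points: int
    theta_floor: float
    through_origin: bool = False


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Results of the inverse pipeline with fit diagnostics.

    ``eta`` is reported even when it falls outside [0, 1] (noise can push
    it past the physical bounds); check :attr:`eta_in_bounds` / warnings.
    """

    tau_s: float
    hA: float
    eta: float
    dT_max_mix: float
    dT_max_h2o: float
    laser_power: float
    absorbance: float
    heat_capacity_total: float
    ambient_temp: float
    fit: TimeConstantFit
    warnings: tuple[str, ...] = ()
    theta_series: ThetaSeries | None = field(default=None, repr=False, compare=False)

    @property
    def eta_in_bounds(self) -> bool:
        return 0.0 <= self.eta <= 1.0

    def plot(self, ax=None):
        """Diagnostic plot of the cooling linearization: −ln θ vs time."""
        import matplotlib.pyplot as plt

        if self.theta_series is None:
            raise ValueError("estimate carries no theta series to plot")
        if ax is None:
            _, ax = plt.subplots()
        x = -np.log(self.theta_series.theta)
        ax.plot(x, self.theta_series.times, "o", label="cooling samples")
        xs = np.linspace(0.0, float(x.max()), 50)
        ax.plot(xs, self.fit.tau_s * xs + self.fit.intercept_s, "-",
                label=f"fit: tau = {self.fit.tau_s:.1f} s")
        ax.set_xlabel(r"$-\ln\,\theta$")
        ax.set_ylabel("time since laser off (s)")
        ax.legend()
        return ax

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "tau_s": self.tau_s,
                    "hA_W_per_K": self.hA,
                    "eta": self.eta,
                    "dT_max_mix_K": self.dT_max_mix,
                    "dT_max_h2o_K": self.dT_max_h2o,
                    "r_squared": self.fit.r_squared,
                    "n_points": self.fit.n_points,
                    "warnings": "; ".join(self.warnings),
                }
            ]
        )

    def summary(self) -> str:
        lines = [
            "Photothermal conversion efficiency estimate",
            "===========================================",
            f"time constant tau        {self.tau_s:12.1f} s",
            f"hA                       {self.hA:12.5f} W/K",
            f"eta                      {self.eta:12.3f}",
            f"dT_max (sample)          {self.dT_max_mix:12.2f} K",
            f"dT_max (water)           {self.dT_max_h2o:12.2f} K",
            f"laser power              {self.laser_power:12.3f} W",
            f"absorbance (808 nm)      {self.absorbance:12.3f}",
            f"cooling-fit R^2          {self.fit.r_squared:12.6f}",
            f"cooling-fit n            {self.fit.n_points:12d}",
        ]
        if not self.eta_in_bounds:
            lines.append("NOTE: eta outside [0, 1] — flagged, not rejected")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def extract_cooling(trace: TemperatureTrace, laser_off_s: float) -> TemperatureTrace:
    """Sub-trace at times ≥ laser-off, re-zeroed to the laser-off instant."""
    lo, hi = trace.span
    if not (lo <= laser_off_s <= hi):
        raise InsufficientDataError(
            f"laser-off time {laser_off_s} s outside trace span [{lo}, {hi}]"
        )
    mask = trace.times >= laser_off_s
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} samples after laser-off; need at least 3"
        )
    return TemperatureTrace(
        trace.times[mask] - laser_off_s,
        trace.temps[mask],
        label=f"{trace.label}/cooling" if trace.label else "cooling",
    )


def compute_theta(
    cooling: TemperatureTrace,
    ambient_temp: float,
    max_temp: float,
    theta_floor: float = DEFAULT_THETA_FLOOR,
) -> ThetaSeries:
    """θᵢ = (Tᵢ − T_surr) / (T_max − T_surr); drop θ ≤ floor or θ > 1.

    Points below the floor sit so close to ambient that the noise in
    −ln θ diverges; points above 1 exceed the assumed maximum (sensor
    noise) and would make −ln θ negative.
    """
    if max_temp <= ambient_temp:
        raise InvalidInputError(
            f"max_temp ({max_temp}) must exceed ambient_temp ({ambient_temp})"
        )
    theta = (cooling.temps - ambient_temp) / (max_temp - ambient_temp)
    low = theta <= theta_floor
    high = theta > 1.0
    keep = ~(low | high)
    if not keep.any():
        raise InsufficientDataError("all cooling points dropped by the theta filter")
    return ThetaSeries(
        times=cooling.times[keep],
        theta=theta[keep],
        theta_floor=theta_floor,
        n_dropped_low=int(low.sum()),
        n_dropped_high=int(high.sum()),
    )


def fit_time_constant(
    series: ThetaSeries, through_origin: bool = False
) -> TimeConstantFit:
    """OLS of time against −ln θ; the slope is the time constant τ.

    The default fit includes an intercept, which absorbs any offset in
    the laser-off timestamp; a through-origin mode matches the textbook
    t = −τ·ln θ line exactly.
    """
    if len(series) < 3:
        raise InsufficientDataError(
            f"time-constant fit needs >= 3 retained points, got {len(series)}"
        )
    x = -np.log(series.theta)
    t = series.times
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("all theta values identical; no variance in -ln(theta)")
    if through_origin:
        slope = float(np.dot(x, t) / np.dot(x, x))
        intercept = 0.0
        ss_res = float(np.sum((t - slope * x) ** 2))
        ss_tot = float(np.sum((t - t.mean()) ** 2))
    else:
        res = stats.linregress(x, t)
        slope, intercept = float(res.slope), float(res.intercept)
        ss_res = float(np.sum((t - (slope * x + intercept)) ** 2))
        ss_tot = float(np.sum((t - t.mean()) ** 2))
    if slope <= 0:
        raise DegenerateFitError(f"non-positive fitted time constant ({slope:.3g} s)")
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return TimeConstantFit(
        tau_s=slope,
        intercept_s=intercept,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=len(series),
        theta_floor=series.theta_floor,
        through_origin=through_origin,
    )


def compute_hA(tau_s: float, heat_capacity_total: float) -> float:
    """hA = ΣmC / τ (W/K)."""
    if tau_s <= 0 or heat_capacity_total <= 0:
        raise InvalidInputError("tau_s and heat_capacity_total must be positive")
    return heat_capacity_total / tau_s


def compute_eta(
    hA: float,
    dT_max_mix: float,
    dT_max_h2o: float,
    laser_power: float,
    absorbance: float,
) -> float:
    """η = hA·(ΔT_max,mix − ΔT_max,H2O) / (I·(1 − 10^(−A)))."""
    if laser_power <= 0:
        raise InvalidInputError("laser_power must be positive")
    if absorbance <= 0:
        raise InvalidInputError(
            "absorbance must be positive: 1 - 10^(-A) vanishes at A = 0"
        )
    if dT_max_h2o < 0 or dT_max_mix < dT_max_h2o:
        raise InvalidInputError("require dT_max_mix >= dT_max_h2o >= 0")
    return hA * (dT_max_mix - dT_max_h2o) / (laser_power * (1.0 - 10.0 ** (-absorbance)))


def plateau_delta(
    trace: TemperatureTrace,
    ambient_temp: float,
    window_end_s: float,
    window_start_s: float = -math.inf,
    k: int = DEFAULT_PLATEAU_K,
) -> tuple[float, bool]:
    """Steady-state temperature rise over the laser-on window, kelvin.

    The plateau temperature is the mean of the last ``k`` samples of the
    window (robust to single-sample noise); when fewer than ``k`` samples
    are available the maximum sample is used and a
    :class:`PlateauFallbackWarning` is emitted.  Returns
    ``(delta_T, used_fallback)``.
    """
    mask = (trace.times >= window_start_s) & (trace.times <= window_end_s)
    temps = trace.temps[mask]
    if temps.size == 0:
        raise InsufficientDataError("no samples in the laser-on window")
    if temps.size < k:
        warnings.warn(
            f"laser-on window has {temps.size} < k={k} samples; "
            "using max temperature as plateau",
            PlateauFallbackWarning,
            stacklevel=2,
        )
        return float(temps.max() - ambient_temp), True
    return float(temps[-k:].mean() - ambient_temp), False


class PhotothermalEfficiencyModel:
    """Cooling-curve model for photothermal conversion efficiency.

    Parameters
    ----------
    sample_trace, water_trace : TemperatureTrace
        Temperature logs of the agent suspension and of the pure-solvent
        reference, both under the identical laser protocol.
    laser_off_s : float
        Time (trace clock) at which the laser was shut off.
    heat_capacity_total : float
        ΣmC of the irradiated system, J/K.
    laser_power : float
        Laser power I at the sample, W.
    absorbance : float
        Sample absorbance at the laser wavelength.
    ambient_temp : float, optional
        T_surr, °C; defaults to the first sample of the sample trace
        (cooling may not reach ambient within the log, so the tail is
        not used).
    theta_floor, plateau_k, through_origin : optional
        Estimator knobs; see :func:`compute_theta`, :func:`plateau_delta`
        and :func:`fit_time_constant`.

    Examples
    --------
    >>> model = PhotothermalEfficiencyModel(sample, water, laser_off_s=600,
    ...     heat_capacity_total=4.18, laser_power=2.5, absorbance=0.45)
    >>> res = model.fit()
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(
        self,
        sample_trace: TemperatureTrace,
        water_trace: TemperatureTrace,
        *,
        laser_off_s: float,
        heat_capacity_total: float,
        laser_power: float,
        absorbance: float,
        ambient_temp: float | None = None,
        theta_floor: float = DEFAULT_THETA_FLOOR,
        plateau_k: int = DEFAULT_PLATEAU_K,
        through_origin: bool = False,
    ) -> None:
        if heat_capacity_total <= 0:
            raise InvalidInputError("heat_capacity_total must be positive")
        self.sample_trace = sample_trace
        self.water_trace = water_trace
        self.laser_off_s = float(laser_off_s)
        self.heat_capacity_total = float(heat_capacity_total)
        self.laser_power = float(laser_power)
        self.absorbance = float(absorbance)
        self.ambient_temp = (
            float(sample_trace.temps[0]) if ambient_temp is None else float(ambient_temp)
        )
        self.theta_floor = float(theta_floor)
        self.plateau_k = int(plateau_k)
        self.through_origin = bool(through_origin)

    @classmethod
    def from_csv(cls, sample_path, water_path, **kwargs) -> "PhotothermalEfficiencyModel":
        from .io import read_trace_csv

        return cls(read_trace_csv(sample_path), read_trace_csv(water_path), **kwargs)

    def fit(self) -> EfficiencyEstimate:
        """Run the full pipeline: plateau → cooling → θ → τ → hA → η."""
        notes: list[str] = []

        dT_mix, fb1 = plateau_delta(
            self.sample_trace, self.ambient_temp, self.laser_off_s, k=self.plateau_k
        )
        dT_h2o, fb2 = plateau_delta(
            self.water_trace, self.ambient_temp, self.laser_off_s, k=self.plateau_k
        )
        if fb1 or fb2:
            notes.append("plateau window shorter than k samples; max-temperature fallback")

        cooling = extract_cooling(self.sample_trace, self.laser_off_s)
        series = compute_theta(
            cooling,
            self.ambient_temp,
            self.ambient_temp + dT_mix,
            theta_floor=self.theta_floor,
        )
        if series.n_dropped_high:
            notes.append(f"{series.n_dropped_high} cooling points above theta=1 dropped")
        fit = fit_time_constant(series, through_origin=self.through_origin)
        hA = compute_hA(fit.tau_s, self.heat_capacity_total)
        eta = compute_eta(hA, dT_mix, dT_h2o, self.laser_power, self.absorbance)
        if not 0.0 <= eta <= 1.0:
            warnings.warn(
                f"estimated eta = {eta:.4f} outside [0, 1]",
                EfficiencyBoundsWarning,
                stacklevel=2,
            )
            notes.append(f"eta = {eta:.4f} outside [0, 1]")
        return EfficiencyEstimate(
            tau_s=fit.tau_s,
            hA=hA,
            eta=eta,
            dT_max_mix=dT_mix,
            dT_max_h2o=dT_h2o,
            laser_power=self.laser_power,
            absorbance=self.absorbance,
            heat_capacity_total=self.heat_capacity_total,
            ambient_temp=self.ambient_temp,
            fit=fit,
            warnings=tuple(notes),
            theta_series=series,
        )


def estimate_efficiency(
    sample_trace: TemperatureTrace,
    water_trace: TemperatureTrace,
    laser_off_s: float,
    heat_capacity_total: float,
    laser_power: float,
    absorbance: float,
    ambient_temp: float | None = None,
    **kwargs,
) -> EfficiencyEstimate:
    """Functional wrapper over :class:`PhotothermalEfficiencyModel`."""
    return PhotothermalEfficiencyModel(
        sample_trace,
        water_trace,
        laser_off_s=laser_off_s,
        heat_capacity_total=heat_capacity_total,
        laser_power=laser_power,
        absorbance=absorbance,
        ambient_temp=ambient_temp,
        **kwargs,
    ).fit()
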
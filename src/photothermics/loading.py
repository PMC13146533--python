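"""Dye-loading quantification: calibration curves, DLC and DLE.

The loaded dye mass is inferred from UV-vis absorbance through a linear
Beer–Lambert calibration ``A = slope·c + intercept`` fitted to standard
solutions.  Two measurement modes are supported:

* ``indirect`` — the absorbance of the unloaded supernatant is measured;
  loaded mass = fed mass − supernatant mass.
* ``direct`` — the absorbance of the loaded-particle suspension itself is
  measured; loaded mass = measured mass.

Loading metrics, in weight percent:

* DLE (loading efficiency) = loaded / fed × 100 — how much of the dye
  offered ended up in the carrier.
* DLC (loading content)    = loaded / (carrier + loaded) × 100 — the dye
  fraction of the final dye-loaded particle mass.

The two are linked by DLC = 100·DLE·fed / (100·carrier + DLE·fed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    CalibrationRangeWarning,
    DegenerateFitError,
    InvalidInputError,
    MassBalanceError,
    MassBalanceWarning,
)

__all__ = [
    "CalibrationCurve",
    "LoadingExperiment",
    "LoadingResult",
    "fit_calibration",
    "concentration_from_absorbance",
    "compute_dle",
    "compute_dlc",
    "quantify_loading",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear absorbance–concentration calibration (concentration in µg/mL)."""

    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidInputError("calibration slope must be positive")
        if not self.valid_range[0] < self.valid_range[1]:
            raise InvalidInputError("valid_range must be (min, max) with min < max")

    def absorbance_at(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class LoadingExperiment:
    """Feed masses and one absorbance measurement for a loading run."""

    fed_dye_mg: float
    carrier_mg: float
    measured_absorbance: float
    volume_mL: float
    dilution_factor: float = 1.0
    mode: Literal["direct", "indirect"] = "indirect"

    def __post_init__(self) -> None:
        if self.fed_dye_mg <= 0 or self.carrier_mg <= 0 or self.volume_mL <= 0:
            raise InvalidInputError("masses and volume must be positive")
        if self.dilution_factor < 1:
            raise InvalidInputError("dilution_factor must be >= 1")
        if self.mode not in ("direct", "indirect"):
            raise InvalidInputError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class LoadingResult:
    """Loaded dye mass with DLC and DLE percentages (full precision)."""

    loaded_mg: float
    dlc_percent: float
    dle_percent: float


def fit_calibration(
    points: Sequence[tuple[float, float]], through_origin: bool = False
) -> CalibrationCurve:
    """OLS line absorbance = slope·c + intercept from standard solutions."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateFitError("calibration needs >= 3 (concentration, absorbance) points")
    c, a = pts[:, 0], pts[:, 1]
    if np.ptp(c) == 0.0:
        raise DegenerateFitError("calibration needs >= 2 distinct concentrations")
    if through_origin:
        slope = float(np.dot(c, a) / np.dot(c, c))
        intercept = 0.0
        ss_res = float(np.sum((a - slope * c) ** 2))
    else:
        res = stats.linregress(c, a)
        slope, intercept = float(res.slope), float(res.intercept)
        ss_res = float(np.sum((a - (slope * c + intercept)) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        valid_range=(float(c.min()), float(c.max())),
    )


def concentration_from_absorbance(
    curve: CalibrationCurve, absorbance: float, dilution_factor: float = 1.0
) -> float:
    """Invert the calibration: c = dilution · (A − intercept) / slope, µg/mL.

    Negative implied concentrations are clamped to 0; concentrations
    outside the calibrated range raise a :class:`CalibrationRangeWarning`.
    """
    if curve.slope <= 0:
        raise InvalidInputError("calibration slope must be positive")
    c_measured = (absorbance - curve.intercept) / curve.slope
    if c_measured < 0:
        warnings.warn(
            f"absorbance {absorbance} below calibration intercept; "
            "concentration clamped to 0",
            CalibrationRangeWarning,
            stacklevel=2,
        )
        return 0.0
    lo, hi = curve.valid_range
    if not lo <= c_measured <= hi:
        warnings.warn(
            f"measured concentration {c_measured:.3g} ug/mL outside calibrated "
            f"range [{lo:.3g}, {hi:.3g}]; extrapolating",
            CalibrationRangeWarning,
            stacklevel=2,
        )
    return dilution_factor * c_measured


def compute_dle(loaded_mg: float, fed_mg: float) -> float:
    """Loading efficiency: loaded dye as % of fed dye."""
    if fed_mg <= 0 or loaded_mg < 0:
        raise InvalidInputError("fed mass must be positive and loaded mass >= 0")
    if loaded_mg > fed_mg:
        raise MassBalanceError(
            f"loaded mass {loaded_mg} mg exceeds fed mass {fed_mg} mg"
        )
    return 100.0 * loaded_mg / fed_mg


def compute_dlc(loaded_mg: float, carrier_mg: float) -> float:
    """Loading content: loaded dye as % of the dye-loaded particle mass.

    The denominator is carrier + loaded dye — the mass of the final
    loaded particles, not of the bare carrier.
    """
    if carrier_mg <= 0:
        raise InvalidInputError("carrier mass must be positive")
    if loaded_mg < 0:
        raise InvalidInputError("loaded mass must be >= 0")
    return 100.0 * loaded_mg / (carrier_mg + loaded_mg)


def quantify_loading(exp: LoadingExperiment, curve: CalibrationCurve) -> LoadingResult:
    """Absorbance → concentration → loaded mass → DLE/DLC."""
    conc = concentration_from_absorbance(
        curve, exp.measured_absorbance, exp.dilution_factor
    )
    measured_mg = conc * exp.volume_mL / 1000.0  # ug -> mg
    if exp.mode == "indirect":
        loaded = exp.fed_dye_mg - measured_mg
        if loaded < 0:
            warnings.warn(
                f"supernatant contains {measured_mg:.3g} mg > fed "
                f"{exp.fed_dye_mg} mg; loaded mass clamped to 0",
                MassBalanceWarning,
                stacklevel=2,
            )
            loaded = 0.0
    else:
        loaded = measured_mg
        if loaded > exp.fed_dye_mg:
            raise MassBalanceError(
                f"measured loaded mass {loaded:.3g} mg exceeds fed {exp.fed_dye_mg} mg"
            )
    return LoadingResult(
        loaded_mg=loaded,
        dlc_percent=compute_dlc(loaded, exp.carrier_mg),
        dle_percent=compute_dle(loaded, exp.fed_dye_mg),
    )
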
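"""Bioassay summaries: CCK-8 viability and relative tumor volume (RTV).

Viability is the plate-reader absorbance of treated wells relative to
untreated control wells, in percent.  RTV normalizes each animal's tumor
volume to its own day-0 baseline, so growth curves are comparable across
animals with different starting volumes; tumor volumes themselves are
taken as inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .exceptions import InvalidInputError, ProliferationWarning

__all__ = [
    "PlateMeasurement",
    "TumorRecord",
    "cell_viability",
    "summarize_plate",
    "relative_tumor_volume",
]


@dataclass(frozen=True)
class PlateMeasurement:
    """One well: sample absorbance against a control absorbance."""

    sample_absorbance: float
    control_absorbance: float
    group_label: str = ""
    replicate: int = 1


@dataclass(frozen=True)
class TumorRecord:
    group_label: str
    animal_id: str
    day: float
    volume_mm3: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise InvalidInputError("day must be non-negative")
        if self.volume_mm3 < 0:
            raise InvalidInputError("tumor volume must be non-negative")


def cell_viability(
    sample_absorbance: float,
    control_absorbance: float,
    blank_absorbance: float = 0.0,
) -> float:
    """Viability (%) = 100 · A_sample / A_control, after optional blank subtraction.

    Values above 100% (proliferation) are returned as-is; above 120% a
    :class:`ProliferationWarning` is emitted.
    """
    sample = sample_absorbance - blank_absorbance
    control = control_absorbance - blank_absorbance
    if control <= 0:
        raise InvalidInputError("control absorbance (minus blank) must be positive")
    if sample < 0:
        raise InvalidInputError("sample absorbance (minus blank) must be >= 0")
    v = 100.0 * sample / control
    if v > 120.0:
        warnings.warn(
            f"viability {v:.1f}% exceeds 120% of control",
            ProliferationWarning,
            stacklevel=2,
        )
    return v


def summarize_plate(
    plate: pd.DataFrame,
    control_group: str = "control",
    blank_absorbance: float = 0.0,
) -> pd.DataFrame:
    """Per-group viability from a long plate table (group, replicate, absorbance).

    The control level is the mean absorbance of the control group's
    replicates; every well is then expressed relative to it, and the
    result is aggregated to group mean ± sd.
    """
    required = {"group", "replicate", "absorbance"}
    if not required.issubset(plate.columns):
        raise InvalidInputError(f"plate table needs columns {sorted(required)}")
    ctrl = plate.loc[plate["group"] == control_group, "absorbance"]
    if ctrl.empty:
        raise InvalidInputError(f"no control group {control_group!r} in plate table")
    control_abs = float(ctrl.mean())
    via = plate.assign(
        viability_percent=[
            cell_viability(a, control_abs, blank_absorbance)
            for a in plate["absorbance"]
        ]
    )
    out = (
        via.groupby("group", sort=False)["viability_percent"]
        .agg(mean_viability_percent="mean", sd_viability_percent="std", n="count")
        .reset_index()
    )
    out["sd_viability_percent"] = out["sd_viability_percent"].fillna(0.0)
    return out


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "group": r.group_label,
                    "animal_id": r.animal_id,
                    "day": r.day,
                    "volume_mm3": r.volume_mm3,
                }
                for r in records
            ]
        )
    required = {"group", "animal_id", "day", "volume_mm3"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"tumor table needs columns {sorted(required)}")
    return df


def relative_tumor_volume(records: Iterable[TumorRecord] | pd.DataFrame) -> pd.DataFrame:
    """Group mean ± sd of per-animal RTV = V(day) / V(day 0), per day.

    Every animal must have a positive day-0 baseline volume.
    """
    df = _records_frame(records)
    baselines = {}
    for (group, animal), sub in df.groupby(["group", "animal_id"]):
        base = sub.loc[sub["day"] == 0, "volume_mm3"]
        if base.empty or float(base.iloc[0]) <= 0:
            raise InvalidInputError(
                f"animal {animal!r} in group {group!r} lacks a positive day-0 baseline"
            )
        baselines[(group, animal)] = float(base.iloc[0])
    df = df.assign(
        rtv=[
            v / baselines[(g, a)]
            for g, a, v in zip(df["group"], df["animal_id"], df["volume_mm3"])
        ]
    )
    out = (
        df.groupby(["group", "day"], sort=True)["rtv"]
        .agg(mean_rtv="mean", sd_rtv="std", n="count")
        .reset_index()
    )
    out["sd_rtv"] = out["sd_rtv"].fillna(0.0)
    return out
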
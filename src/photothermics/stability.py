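"""Multi-cycle photostability metrics and power-series summaries.

A photostability run irradiates the sample for a fixed window, lets it
cool with the laser off, and repeats.  A photobleaching agent loses peak
temperature from cycle to cycle; the headline metric is the first-cycle
peak minus the last-cycle peak (positive = degradation).

Cycle boundaries are taken from the laser protocol — the experiment's
on/off times are controlled and known — rather than inferred from the
signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .efficiency import DEFAULT_PLATEAU_K, plateau_delta
from .exceptions import InsufficientDataError, InvalidInputError, MonotonicityWarning
from .thermal import LaserProtocol, TemperatureTrace

__all__ = [
    "CycleSummary",
    "StabilityReport",
    "segment_cycles",
    "summarize_cycles",
    "peak_decay",
    "power_series_summary",
]


@dataclass(frozen=True)
class CycleSummary:
    """Peak/trough of one heating+cooling cycle (1-based index)."""

    index: int
    peak_temp: float
    peak_time_s: float
    trough_temp: float


@dataclass(frozen=True)
class StabilityReport:
    cycles: tuple[CycleSummary, ...]
    peak_decay_K: float
    n_cycles: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cycle": c.index,
                    "peak_temp_C": c.peak_temp,
                    "peak_time_s": c.peak_time_s,
                    "trough_temp_C": c.trough_temp,
                }
                for c in self.cycles
            ]
        )

    def summary(self) -> str:
        out = [self.to_frame().to_string(index=False)]
        out.append(f"peak decay (cycle 1 - cycle {self.n_cycles}): {self.peak_decay_K:.2f} K")
        return "\n".join(out)


def segment_cycles(
    trace: TemperatureTrace, protocol: LaserProtocol
) -> list[tuple[TemperatureTrace, TemperatureTrace | None]]:
    """Split a trace into (heating, cooling) sub-trace pairs, one per laser-on
    segment, at the protocol's on/off boundaries.

    The cooling half runs from the end of each on segment to the start of
    the next (or the trace end).  A cycle whose cooling half holds fewer
    than 2 samples gets ``None`` for cooling and a warning.
    """
    on_segs = protocol.on_segments()
    if not on_segs:
        raise InvalidInputError("protocol has no laser-on segment")
    pairs: list[tuple[TemperatureTrace, TemperatureTrace | None]] = []
    t_end = trace.span[1]
    for i, seg in enumerate(on_segs):
        try:
            heating = trace.window(seg.start_s, seg.end_s, label=f"cycle{i + 1}/heating")
        except InsufficientDataError as exc:
            raise InsufficientDataError(
                f"trace does not cover laser-on segment {i + 1} "
                f"[{seg.start_s}, {seg.end_s}] s"
            ) from exc
        cool_end = on_segs[i + 1].start_s if i + 1 < len(on_segs) else t_end
        cooling: TemperatureTrace | None
        mask = (trace.times > seg.end_s) & (trace.times <= cool_end)
        if mask.sum() >= 2:
            cooling = TemperatureTrace(
                trace.times[mask], trace.temps[mask], label=f"cycle{i + 1}/cooling"
            )
        else:
            cooling = None
            warnings.warn(
                f"cycle {i + 1} has no usable cooling half",
                MonotonicityWarning,
                stacklevel=2,
            )
        pairs.append((heating, cooling))
    return pairs


def summarize_cycles(
    pairs: list[tuple[TemperatureTrace, TemperatureTrace | None]]
) -> list[CycleSummary]:
    """Per-cycle peak (max heating sample) and trough (min cooling sample)."""
    out = []
    for i, (heating, cooling) in enumerate(pairs, start=1):
        j = int(np.argmax(heating.temps))
        trough_src = cooling if cooling is not None else heating
        out.append(
            CycleSummary(
                index=i,
                peak_temp=float(heating.temps[j]),
                peak_time_s=float(heating.times[j]),
                trough_temp=float(trough_src.temps.min()),
            )
        )
    return out


def peak_decay(cycles: list[CycleSummary]) -> float:
    """Peak temperature loss from the first to the last cycle, kelvin."""
    if len(cycles) < 2:
        raise InsufficientDataError("peak decay needs at least 2 cycles")
    return cycles[0].peak_temp - cycles[-1].peak_temp


def analyze_stability(trace: TemperatureTrace, protocol: LaserProtocol) -> StabilityReport:
    """Segment, summarize and compute the peak-decay metric in one call."""
    cycles = summarize_cycles(segment_cycles(trace, protocol))
    decay = peak_decay(cycles) if len(cycles) >= 2 else 0.0
    return StabilityReport(cycles=tuple(cycles), peak_decay_K=decay, n_cycles=len(cycles))


def power_series_summary(
    traces: list[tuple[float, TemperatureTrace]],
    ambient_temp: float,
    plateau_k: int = DEFAULT_PLATEAU_K,
) -> pd.DataFrame:
    """Plateau ΔT_max per laser power density, sorted by power.

    Uses the same last-k-sample plateau rule as the efficiency pipeline.
    Non-monotone ΔT across increasing power is physically unexpected
    (heating scales linearly with power) and is flagged with a warning
    and a ``monotonic`` column.
    """
    if len(traces) < 2:
        raise InsufficientDataError("power series needs at least 2 power levels")
    powers = [p for p, _ in traces]
    if len(set(powers)) != len(powers):
        raise InvalidInputError("duplicate power values in power series")
    rows = []
    for power, trace in sorted(traces, key=lambda pt: pt[0]):
        dT, _ = plateau_delta(trace, ambient_temp, trace.span[1], k=plateau_k)
        rows.append({"power_density_W_per_cm2": power, "dT_max_K": dT})
    df = pd.DataFrame(rows)
    increasing = df["dT_max_K"].diff().dropna() > 0
    df["monotonic"] = True
    if not increasing.all():
        warnings.warn(
            "dT_max is not strictly increasing with laser power",
            MonotonicityWarning,
            stacklevel=2,
        )
        df.loc[increasing[~increasing].index, "monotonic"] = False
    return df
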
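"""CSV formats and report rendering.

One strict dialect everywhere: comma-separated, "." decimal, UTF-8,
required headers.  Thermal-imager exports vary wildly; converting to
`time_s,temp_C` once is simpler than guessing dialects.  All parse errors
carry the file name and the offending row number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .efficiency import EfficiencyEstimate
from .exceptions import ParseError
from .loading import LoadingResult
from .stability import StabilityReport
from .thermal import TemperatureTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_calibration_csv",
    "read_plate_csv",
    "read_tumor_csv",
    "write_report",
    "report_frame",
]

TRACE_COLUMNS = ["time_s", "temp_C"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise ParseError("file not found", path=p)
    try:
        df = pd.read_csv(p)
    except Exception as exc:
        raise ParseError(f"unreadable CSV: {exc}", path=p) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns {missing}", path=p, row=1)
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna()]
    if len(bad):
        # +2: 1-based data rows after the header line
        raise ParseError(
            f"non-numeric value in column {col!r}", path=path, row=int(bad[0]) + 2
        )
    return vals.to_numpy(dtype=float)


def read_trace_csv(path) -> TemperatureTrace:
    """Read a `time_s,temp_C` trace; enforce strictly increasing times."""
    df = _read_csv(path, TRACE_COLUMNS)
    times = _numeric(df, "time_s", path)
    temps = _numeric(df, "temp_C", path)
    if times.size < 2:
        raise ParseError("a trace needs at least 2 rows", path=path)
    steps = np.diff(times)
    if (steps <= 0).any():
        row = int(np.argmax(steps <= 0)) + 3  # second row of the offending pair
        raise ParseError("time_s not strictly increasing", path=path, row=row)
    return TemperatureTrace(times, temps, label=Path(path).stem)


def write_trace_csv(trace: TemperatureTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_calibration_csv(path) -> list[tuple[float, float]]:
    """Read `conc_ug_per_mL,absorbance` calibration standards."""
    df = _read_csv(path, ["conc_ug_per_mL", "absorbance"])
    c = _numeric(df, "conc_ug_per_mL", path)
    a = _numeric(df, "absorbance", path)
    return list(zip(c.tolist(), a.tolist()))


def read_plate_csv(path) -> pd.DataFrame:
    """Read a `group,replicate,absorbance` viability plate table."""
    df = _read_csv(path, ["group", "replicate", "absorbance"])
    df["absorbance"] = _numeric(df, "absorbance", path)
    return df


def read_tumor_csv(path) -> pd.DataFrame:
    """Read a `group,animal_id,day,volume_mm3` tumor-volume table."""
    df = _read_csv(path, ["group", "animal_id", "day", "volume_mm3"])
    df["day"] = _numeric(df, "day", path)
    df["volume_mm3"] = _numeric(df, "volume_mm3", path)
    return df


# documented reporting precision
_PRECISION = {
    "percent": 1,   # any percentage
    "eta": 3,
    "tau_s": 1,
}


def _round_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind not in "fc":
            continue
        if "percent" in col:
            out[col] = out[col].round(_PRECISION["percent"])
        elif col == "eta":
            out[col] = out[col].round(_PRECISION["eta"])
        elif col.startswith("tau"):
            out[col] = out[col].round(_PRECISION["tau_s"])
    return out


def report_frame(result) -> pd.DataFrame:
    """Tabular rendering of any stage's result object."""
    if isinstance(result, pd.DataFrame):
        return result
    if isinstance(result, EfficiencyEstimate):
        return result.to_frame()
    if isinstance(result, StabilityReport):
        return result.to_frame()
    if isinstance(result, LoadingResult):
        return pd.DataFrame(
            [
                {
                    "loaded_mg": result.loaded_mg,
                    "dlc_percent": result.dlc_percent,
                    "dle_percent": result.dle_percent,
                }
            ]
        )
    if isinstance(result, dict):
        return pd.DataFrame([result])
    raise TypeError(f"no report rendering for {type(result).__name__}")


def write_report(result, path, format: str = "csv") -> None:
    """Write a result as CSV or aligned text at documented precision
    (percentages to 1 d.p., η to 3 d.p., τ to 0.1 s)."""
    df = _round_columns(report_frame(result))
    p = Path(path)
    if format == "csv":
        df.to_csv(p, index=False)
    elif format == "text":
        p.write_text(df.to_string(index=False) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
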
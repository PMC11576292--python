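"""Trace containers and CSV round-tripping.

Time is always in seconds relative to treatment (LPS enters the bath at t=0),
so baseline frames carry negative timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Column schema shared by every trace CSV written by this package.
TRACE_COLUMNS = ("time_s", "intensity", "roi_id", "compartment", "condition", "cell_class")


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw mean-intensity time series of one ROI (a.u.)."""

    time: np.ndarray
    intensity: np.ndarray
    roi_id: str = ""
    compartment: str = ""
    condition: str = ""
    cell_class: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time must be uniformly spaced")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity must be finite")

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "intensity": self.intensity,
                "roi_id": self.roi_id,
                "compartment": self.compartment,
                "condition": self.condition,
                "cell_class": self.cell_class,
            }
        )


@dataclass(frozen=True)
class PercentChangeTrace:
    """Baseline-normalised trace: 100 * (F - F0) / F0."""

    time: np.ndarray
    pct: np.ndarray
    baseline_window: tuple[float, float]
    baseline_mean: float
    roi_id: str = ""
    compartment: str = ""
    condition: str = ""
    cell_class: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "pct", np.asarray(self.pct, dtype=float))

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def value_at(self, t: float) -> float:
        """pct at the sample nearest to time t (s)."""
        return float(self.pct[int(np.argmin(np.abs(self.time - t)))])


def write_traces_csv(path: str | Path, traces: list[FluorescenceTrace]) -> None:
    """Write traces in long format (one row per frame per ROI)."""
    frames = [tr.to_frame() for tr in traces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_traces_csv(path: str | Path) -> list[FluorescenceTrace]:
    """Read a long-format trace CSV back into per-ROI/compartment traces."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns: {sorted(missing)}")
    out = []
    for (roi, comp), grp in df.groupby(["roi_id", "compartment"], sort=True):
        grp = grp.sort_values("time_s")
        out.append(
            FluorescenceTrace(
                time=grp["time_s"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                roi_id=str(roi),
                compartment=str(comp),
                condition=str(grp["condition"].iloc[0]),
                cell_class=str(grp["cell_class"].iloc[0]),
            )
        )
    return out
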
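"""Trace kinetics: percent change, rate of change, slope angle, state detection.

The ΔΨm response of a microglia is summarized as a sequence of *progressive
states*: maximal intervals of steep rise in the percent-change trace,
separated from their neighbours by plateaus.  The detector thresholds the
smoothed rate-of-change trace (default 0.25 %/s), treats sub-threshold gaps
shorter than the minimum plateau duration as part of the same state, and
discards runs shorter than the minimum state duration.  Thresholds are
calibrated so the canonical noise-free LPS trace yields exactly the three
reported states; all are configurable.

Slope angles are reported in degrees of ``arctan`` of the percent-per-minute
slope (a package convention — the quantity has no universally agreed unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .traces import FluorescenceTrace, PercentChangeTrace

DEFAULT_BASELINE_WINDOW = (-300.0, 0.0)
DEFAULT_SMOOTH_WINDOW = 30.0  # s


def percent_change(
    trace: FluorescenceTrace,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> PercentChangeTrace:
    """Percent change from baseline: 100 * (F(t) - F0) / F0.

    F0 is the mean intensity over ``baseline_window`` (s, half-open
    ``[w0, w1)``), which must contain at least 3 samples and have positive
    mean.
    """
    w0, w1 = baseline_window
    if w1 <= w0:
        raise ValueError("baseline window must have positive length")
    sel = (trace.time >= w0) & (trace.time < w1)
    if np.count_nonzero(sel) < 3:
        raise ValueError("baseline window must contain at least 3 samples")
    f0 = float(trace.intensity[sel].mean())
    if f0 <= 0:
        raise ValueError("baseline mean must be > 0")
    return PercentChangeTrace(
        time=trace.time,
        pct=100.0 * (trace.intensity - f0) / f0,
        baseline_window=(w0, w1),
        baseline_mean=f0,
        roi_id=trace.roi_id,
        compartment=trace.compartment,
        condition=trace.condition,
        cell_class=trace.cell_class,
    )


def _moving_average(y: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if n <= 1:
        return y.astype(float)
    kernel = np.ones(n) / n
    sm = np.convolve(y, kernel, mode="same")
    # correct edge windows for the missing samples
    counts = np.convolve(np.ones_like(y), kernel, mode="same")
    return sm / counts


def _smooth_samples(pct: PercentChangeTrace, smooth_window: float) -> int:
    dt = pct.frame_interval
    if smooth_window < dt:
        raise ValueError("smooth_window must be at least one sampling interval")
    n = int(round(smooth_window / dt))
    return n + 1 - n % 2  # force odd so the window is centered


def smoothed_pct(pct: PercentChangeTrace, smooth_window: float = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    return _moving_average(pct.pct, _smooth_samples(pct, smooth_window))


def rate_of_change(
    pct: PercentChangeTrace, smooth_window: float = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """Rate of change (%/s): moving-average smoothing then central differences.

    Returns an array aligned with ``pct.time``; endpoints use one-sided
    differences.
    """
    n = _smooth_samples(pct, smooth_window)
    if pct.pct.size <= n:
        raise ValueError("trace shorter than the smoothing window")
    sm = _moving_average(pct.pct, n)
    return np.gradient(sm, pct.time)


def slope_angle(pct: PercentChangeTrace, interval: tuple[float, float]) -> float:
    """Least-squares slope angle (degrees) of pct vs time-in-minutes.

    45° corresponds to a rise of 1 %/min.
    """
    t0, t1 = interval
    sel = (pct.time >= t0) & (pct.time <= t1)
    if np.count_nonzero(sel) < 2:
        raise ValueError("interval must contain at least 2 samples")
    t_min = pct.time[sel] / 60.0
    if np.ptp(t_min) == 0:
        raise ValueError("zero time variance in interval")
    slope = np.polyfit(t_min, pct.pct[sel], 1)[0]
    return float(np.degrees(np.arctan(slope)))


@dataclass(frozen=True)
class State:
    """One detected progressive-depolarization state."""

    onset: float  # s post-treatment
    duration: float  # s
    pct_change: float  # % gained within the state
    pct_cumulative: float  # % above baseline at state end
    max_slope_angle: float  # degrees
    mean_rate: float  # %/s


@dataclass(frozen=True)
class StateSegmentation:
    states: tuple[State, ...] = ()
    roi_id: str = ""
    compartment: str = ""
    condition: str = ""
    cell_class: str = ""

    @property
    def n_states(self) -> int:
        return len(self.states)

    def onsets(self) -> np.ndarray:
        return np.array([s.onset for s in self.states])

    def durations(self) -> np.ndarray:
        return np.array([s.duration for s in self.states])

    def to_records(self) -> list[dict]:
        return [
            {"roi_id": self.roi_id, "compartment": self.compartment,
             "condition": self.condition, "cell_class": self.cell_class,
             "state": i + 1, **asdict(s)}
            for i, s in enumerate(self.states)
        ]


@dataclass(frozen=True)
class DetectorConfig:
    """State-detector thresholds; defaults resolve the three canonical states."""

    rate_threshold: float = 0.25  # %/s
    min_state_dur: float = 60.0  # s
    min_plateau_dur: float = 45.0  # s
    max_states: int = 3
    smooth_window: float = DEFAULT_SMOOTH_WINDOW  # s


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True values."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_states(
    pct: PercentChangeTrace, config: DetectorConfig = DetectorConfig()
) -> StateSegmentation:
    """Detect progressive rising states in a percent-change trace.

    A state is a maximal post-treatment run of supra-threshold smoothed rate
    lasting at least ``min_state_dur``; sub-threshold gaps shorter than
    ``min_plateau_dur`` do not terminate a state (a plateau, by definition,
    lasts at least that long).  If more than ``max_states`` candidates
    survive, the ones with the largest within-state gain are kept (earliest
    onset breaks ties).  A flat trace yields an empty segmentation.
    """
    dt = pct.frame_interval
    if pct.time[-1] < 600.0:
        raise ValueError("trace must cover at least 600 s post-treatment")
    rate = rate_of_change(pct, config.smooth_window)
    sm = smoothed_pct(pct, config.smooth_window)

    post = pct.time >= 0.0
    i0 = int(np.argmax(post))
    supra = (rate > config.rate_threshold) & post

    runs = _runs(supra[i0:])
    runs = [(a + i0, b + i0) for a, b in runs]
    # merge runs separated by gaps shorter than a plateau
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) * dt < config.min_plateau_dur:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    merged = [(a, b) for a, b in merged if (b - a) * dt >= config.min_state_dur]

    def gain(run: tuple[int, int]) -> float:
        a, b = run
        return float(sm[min(b, sm.size - 1)] - sm[a])

    if len(merged) > config.max_states:
        ranked = sorted(merged, key=lambda r: (-gain(r), pct.time[r[0]]))
        merged = sorted(ranked[: config.max_states], key=lambda r: r[0])

    states = []
    for a, b in merged:
        b_in = min(b, pct.time.size - 1)
        onset = float(pct.time[a])
        duration = float((b - a) * dt)
        seg_rate = rate[a:b_in + 1]
        states.append(
            State(
                onset=onset,
                duration=duration,
                pct_change=gain((a, b)),
                pct_cumulative=float(sm[b_in]),
                max_slope_angle=float(np.degrees(np.arctan(np.max(seg_rate) * 60.0))),
                mean_rate=float(np.mean(seg_rate)),
            )
        )
    return StateSegmentation(
        states=tuple(states),
        roi_id=pct.roi_id,
        compartment=pct.compartment,
        condition=pct.condition,
        cell_class=pct.cell_class,
    )


# ---------------------------------------------------------------------------
# per-compartment metrics within whole-cell state windows
# ---------------------------------------------------------------------------

def state_metrics(
    pct_by_compartment: Mapping[str, PercentChangeTrace],
    segmentation: StateSegmentation,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
) -> pd.DataFrame:
    """Per-compartment metrics measured inside whole-cell state windows.

    States are identified once per cell (on the whole-cell trace); each
    compartment's within-state gain, maximum slope angle and mean rate are
    then measured over those windows — compartment-specific rises that never
    cross the detector threshold on their own are still quantified.
    """
    rows = []
    for comp, pct in pct_by_compartment.items():
        sm = smoothed_pct(pct, smooth_window)
        rate = rate_of_change(pct, smooth_window)
        for i, st in enumerate(segmentation.states):
            sel = (pct.time >= st.onset) & (pct.time <= st.onset + st.duration)
            if np.count_nonzero(sel) < 2:
                continue
            idx = np.flatnonzero(sel)
            seg_rate = rate[idx]
            rows.append(
                {
                    "roi_id": pct.roi_id or segmentation.roi_id,
                    "condition": pct.condition or segmentation.condition,
                    "cell_class": pct.cell_class or segmentation.cell_class,
                    "compartment": comp,
                    "state": i + 1,
                    "pct_change": float(sm[idx[-1]] - sm[idx[0]]),
                    "max_slope_angle": float(
                        np.degrees(np.arctan(np.max(seg_rate) * 60.0))
                    ),
                    "mean_rate": float(np.mean(seg_rate)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "roi_id", "condition", "cell_class", "compartment", "state",
            "pct_change", "max_slope_angle", "mean_rate",
        ],
    )


METRIC_COLUMNS = ("pct_change", "max_slope_angle", "mean_rate")


def summarize_states(
    metrics: pd.DataFrame,
    by: Sequence[str] = ("condition", "cell_class", "compartment", "state"),
) -> pd.DataFrame:
    """Group means and SEM of state metrics in long format.

    One row per group x metric with columns n / mean / sem.  Cells missing a
    state simply contribute no rows (absent, not zero).
    """
    if metrics.empty:
        raise ValueError("metrics table is empty")
    long = metrics.melt(
        id_vars=[c for c in metrics.columns if c not in METRIC_COLUMNS],
        value_vars=[c for c in METRIC_COLUMNS if c in metrics.columns],
        var_name="metric",
        value_name="value",
    )
    g = long.groupby([*by, "metric"], sort=True)["value"]
    out = g.agg(n="count", mean="mean", sem="sem").reset_index()
    return out
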
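"""End-to-end orchestration: simulate → segment → kinetics → report.

The per-cell analysis follows the experimental procedure: progressive states
are identified once per cell on the whole-cell percent-change trace, and each
compartment's metrics are then measured inside those state windows.  Total
(whole-window) percent change per compartment is reported alongside as the
``total_pct_change`` metric with state 0.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .kinetics import (
    DetectorConfig,
    StateSegmentation,
    detect_states,
    percent_change,
    smoothed_pct,
    state_metrics,
    summarize_states,
)
from .segment import (
    extract_trace,
    partition_compartments,
    read_stack_tiff,
    save_mask_png,
    segment_cells,
)
from .stats import ScreenReport, screen_report
from .synthdata import ExperimentDesign, generate_cohort
from .traces import FluorescenceTrace, read_traces_csv, write_traces_csv

FINAL_WINDOW_S = 60.0  # averaging window for the endpoint percent change


def total_pct_change(pct, window: float = FINAL_WINDOW_S) -> float:
    """Mean percent change over the last ``window`` seconds of the trace."""
    sel = pct.time >= pct.time[-1] - window
    return float(pct.pct[sel].mean())


def analyze_cell(
    traces: Iterable[FluorescenceTrace],
    baseline_window: tuple[float, float] = (-300.0, 0.0),
    detector: DetectorConfig = DetectorConfig(),
) -> tuple[StateSegmentation | None, pd.DataFrame]:
    """Analyze all compartment traces of one cell.

    Returns the whole-cell state segmentation (None for cells without a
    whole-cell trace, e.g. neurons) and a long metrics table.
    """
    by_comp = {tr.compartment: percent_change(tr, baseline_window) for tr in traces}
    if not by_comp:
        raise ValueError("no traces supplied")
    any_pct = next(iter(by_comp.values()))
    meta = {
        "roi_id": any_pct.roi_id,
        "condition": any_pct.condition,
        "cell_class": any_pct.cell_class,
    }

    rows = [
        {**meta, "compartment": comp, "state": 0, "metric": "total_pct_change",
         "value": total_pct_change(pct)}
        for comp, pct in by_comp.items()
    ]

    seg = None
    if "whole_cell" in by_comp:
        seg = detect_states(by_comp["whole_cell"], detector)
        if seg.n_states:
            sm = state_metrics(by_comp, seg, detector.smooth_window)
            long = sm.melt(
                id_vars=["roi_id", "condition", "cell_class", "compartment", "state"],
                value_vars=["pct_change", "max_slope_angle", "mean_rate"],
                var_name="metric",
                value_name="value",
            )
            rows.extend(long.to_dict("records"))
    return seg, pd.DataFrame(rows)


def analyze_cohort(
    cohort_dir: str | Path,
    baseline_window: tuple[float, float] = (-300.0, 0.0),
    detector: DetectorConfig = DetectorConfig(),
) -> tuple[pd.DataFrame, dict[str, StateSegmentation]]:
    """Analyze every trace CSV in a cohort directory (``traces/*.csv``)."""
    cohort = Path(cohort_dir)
    files = sorted((cohort / "traces").glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no trace CSVs under {cohort / 'traces'}")
    tables = []
    segs: dict[str, StateSegmentation] = {}
    for f in files:
        traces = read_traces_csv(f)
        seg, tbl = analyze_cell(traces, baseline_window, detector)
        if seg is not None:
            segs[traces[0].roi_id] = seg
        tables.append(tbl)
    return pd.concat(tables, ignore_index=True), segs


def analyze_stack(
    stack_path: str | Path,
    out_dir: str | Path,
    min_area_px: int = 50,
    soma_open_radius: float = 3.0,
    endfoot_len: float = 4.0,
) -> pd.DataFrame:
    """Segment a stack, partition cells, extract and save compartment traces."""
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    stack = read_stack_tiff(stack_path)
    labels = segment_cells(stack.morphology_image(), min_area_px=min_area_px)
    rois = []
    for lab in range(1, labels.max() + 1):
        cid = f"cell_{lab:02d}"
        cell_mask = labels == lab
        masks = partition_compartments(
            cell_mask, stack.pixel_size, soma_open_radius, endfoot_len, cell_id=cid
        )
        traces = [
            extract_trace(stack, cell_mask, "TMRE", roi_id=cid, compartment="whole_cell")
        ]
        for comp, m in masks.as_dict().items():
            save_mask_png(out / "masks" / f"{cid}_{comp}.png", m)
            if m.any():
                traces.append(
                    extract_trace(stack, m, "TMRE", roi_id=cid, compartment=comp)
                )
        write_traces_csv(out / "traces" / f"{cid}.csv", traces)
        rois.append({"roi_id": cid, "label": int(lab), "area_px": int(cell_mask.sum())})
    (out / "rois.json").write_text(json.dumps({"rois": rois}, indent=2, sort_keys=True))
    return pd.DataFrame(rois)


def run(config: RunConfig) -> Path:
    """Run the configured pipeline; returns the populated output directory.

    Directory layout: ``traces/`` (simulate), ``metrics/``, ``report/``, and a
    ``run.json`` provenance log (version, seed, full parameter block).
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    cohort_dir = out
    if config.mode in ("simulate", "full"):
        design = ExperimentDesign(
            conditions=tuple(config.simulate.conditions),
            n_per_group=config.simulate.n_per_group,
            n_neurons=config.simulate.n_neurons,
            response_cv=config.simulate.response_cv,
            frame_interval=config.simulate.frame_interval,
            duration=config.simulate.duration,
            treatment_time=config.simulate.treatment_time,
        )
        generate_cohort(design, out, seed=config.seed, overwrite=True)
    else:
        if config.traces is None:
            raise ValueError("analyze mode requires a traces directory")
        cohort_dir = Path(config.traces).parent if Path(config.traces).name == "traces" \
            else Path(config.traces)
        if not cohort_dir.exists():
            raise FileNotFoundError(cohort_dir)

    if config.mode == "simulate":
        _write_log(out, config)
        return out

    detector = DetectorConfig(
        rate_threshold=config.kinetics.rate_threshold,
        min_state_dur=config.kinetics.min_state_dur,
        min_plateau_dur=config.kinetics.min_plateau_dur,
        max_states=config.kinetics.max_states,
        smooth_window=config.kinetics.smooth_window,
    )
    metrics, segs = analyze_cohort(
        cohort_dir, tuple(config.kinetics.baseline_window), detector
    )
    (out / "metrics").mkdir(exist_ok=True)
    metrics.to_csv(out / "metrics" / "metrics.csv", index=False, float_format="%.10g")
    state_rows = metrics[metrics["state"] > 0]
    if not state_rows.empty:
        pivoted = state_rows.pivot_table(
            index=["roi_id", "condition", "cell_class", "compartment", "state"],
            columns="metric", values="value",
        ).reset_index()
        summarize_states(pivoted).to_csv(
            out / "metrics" / "summary.csv", index=False, float_format="%.10g"
        )
    seg_payload = {
        roi: [s.__dict__ | {} for s in seg.states] for roi, seg in sorted(segs.items())
    }
    (out / "metrics" / "segmentations.json").write_text(
        json.dumps(
            {roi: [dict(onset=s.onset, duration=s.duration, pct_change=s.pct_change,
                        pct_cumulative=s.pct_cumulative,
                        max_slope_angle=s.max_slope_angle, mean_rate=s.mean_rate)
                   for s in seg.states]
             for roi, seg in sorted(segs.items())},
            indent=2, sort_keys=True,
        )
    )

    report = None
    if config.mode == "full" or config.report is not None:
        rep_cfg = config.report
        report = screen_report(
            metrics,
            control=rep_cfg.control,
            treatment=rep_cfg.treatment,
            alpha=rep_cfg.alpha,
            adjust=rep_cfg.adjust,
        )
        (out / "report").mkdir(exist_ok=True)
        report.to_json(out / "report" / "screen.json")
        report.comparisons.to_csv(out / "report" / "screen.csv", index=False,
                                  float_format="%.10g")
        (out / "report" / "screen.md").write_text(report.to_markdown())

    _write_log(out, config)
    return out


def _write_log(out: Path, config: RunConfig) -> None:
    log = {
        "package": "mitoscreen",
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
    }
    (out / "run.json").write_text(json.dumps(log, indent=2, sort_keys=True))
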
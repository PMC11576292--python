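"""Plot helpers: percent-change traces with shaded detected states."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .kinetics import StateSegmentation
from .traces import PercentChangeTrace


def plot_trace_with_states(
    pct: PercentChangeTrace,
    segmentation: StateSegmentation | None = None,
    path: str | Path | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    ax.plot(pct.time / 60.0, pct.pct, lw=1.0, color="tab:red")
    ax.axvline(0.0, color="k", ls="--", lw=0.8)
    if segmentation is not None:
        for i, st in enumerate(segmentation.states):
            ax.axvspan(st.onset / 60.0, (st.onset + st.duration) / 60.0,
                       alpha=0.2, color="tab:blue")
            ax.text((st.onset + st.duration / 2) / 60.0, ax.get_ylim()[1] * 0.95,
                    f"S{i + 1}", ha="center", va="top", fontsize=8)
    ax.set_xlabel("time post-treatment (min)")
    ax.set_ylabel("ΔΨm percent change from baseline (%)")
    label = " / ".join(x for x in (pct.roi_id, pct.compartment) if x)
    if label:
        ax.set_title(label, fontsize=9)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
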
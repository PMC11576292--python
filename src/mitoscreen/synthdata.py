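"""Seeded synthetic acute-slice data with ground truth.

Three levels of realism, all driven by :class:`~mitoscreen.params.KineticParameters`:

* :func:`simulate_trace` — one ROI-level fluorescence time series;
* :func:`render_stack` — a two-channel image stack (EGFP morphology + TMRE)
  with per-compartment kinetics painted into rendered microglia/neuron
  geometry, plus a :class:`GroundTruthManifest` of exact masks and noise-free
  traces;
* :func:`generate_cohort` — a reproducible on-disk dataset (trace CSVs or
  TIFF stacks) for a multi-condition experiment, with between-cell response
  variability.

Times follow the experiment convention: treatment at t=0, preceded by a
5-min baseline window.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import morphology

from .params import (
    COMPARTMENTS,
    CONDITIONS,
    KineticParameters,
    make_default_parameters,
)
from .segment import CompartmentMaskSet, ImageStack, write_stack_tiff
from .traces import FluorescenceTrace, write_traces_csv


# ---------------------------------------------------------------------------
# trace-level simulation
# ---------------------------------------------------------------------------

def noise_free_response(params: KineticParameters, compartment: str, time: np.ndarray) -> np.ndarray:
    """Noise-free percent-change response at the given times (s, t=0 = treatment).

    Each progressive state contributes a linear ramp from 0 to its effective
    amplitude between onset and onset+duration; the neuron component ramps to
    ``neuron_amplitude`` by ``neuron_plateau_onset``, holds until
    ``neuron_decline_onset``, and then declines at ``neuron_decline_rate``
    (floored at zero).
    """
    t = np.asarray(time, dtype=float)
    resp = np.zeros_like(t)
    amps = params.compartment_amplitudes(compartment) if params.n_states else []
    for onset, dur, amp in zip(params.state_onsets, params.state_durations, amps):
        resp += amp * np.clip((t - onset) / dur, 0.0, 1.0)
    if params.neuron_amplitude > 0:
        rise = params.neuron_amplitude * np.clip(t / params.neuron_plateau_onset, 0.0, 1.0)
        rise = np.where(t < 0, 0.0, rise)
        decline = params.neuron_decline_rate * np.clip(t - params.neuron_decline_onset, 0.0, None)
        resp += np.clip(rise - decline, 0.0, None)
    return resp


def simulate_trace(
    params: KineticParameters,
    compartment: str = "whole_cell",
    frame_interval: float = 1.0,
    duration: float = 2100.0,
    treatment_time: float = 300.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> FluorescenceTrace:
    """Simulate one ROI fluorescence trace (a.u.).

    The noise-free component is
    ``baseline_intensity * (1 + response(t) / 100)`` with additive Gaussian
    noise of standard deviation ``params.noise_sd`` per frame.  The same seed
    reproduces the trace bit for bit.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if duration <= treatment_time:
        raise ValueError("duration must exceed treatment_time")
    n = int(round(duration / frame_interval))
    t = np.arange(n) * frame_interval - treatment_time
    clean = params.baseline_intensity * (1.0 + noise_free_response(params, compartment, t) / 100.0)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, params.noise_sd, size=n)
    return FluorescenceTrace(
        time=t,
        intensity=clean,
        compartment=compartment,
        condition=params.condition,
        cell_class=params.cell_class,
    )


# ---------------------------------------------------------------------------
# rendered image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Geometry and acquisition settings for a rendered scene.

    Lengths in µm, times in s.  The default 256 px field at 0.5 µm/px and 2 s
    frames keeps a full 35-min recording desk-scale.
    """

    field_px: int = 256
    pixel_size: float = 0.5
    frame_interval: float = 2.0
    duration: float = 2100.0
    treatment_time: float = 300.0
    n_microglia: int = 3
    n_neurons: int = 2
    soma_radius: float = 4.0
    branch_count: int = 4
    branch_length: float = 12.0
    branch_halfwidth: float = 1.0
    endfoot_radius: float = 2.2
    neuron_radius: float = 6.0
    background: float = 10.0
    egfp_intensity: float = 150.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treatment_time < 300.0:
            raise ValueError("treatment_time must allow a full 5-min baseline window")
        if self.duration <= self.treatment_time:
            raise ValueError("duration must exceed treatment_time")
        if 2 * self.cell_extent("microglia") >= self.field_px * self.pixel_size:
            raise ValueError("cell geometry does not fit the field")

    def cell_extent(self, cell_class: str) -> float:
        """Bounding radius (µm) of one rendered cell."""
        if cell_class == "neuron":
            return self.neuron_radius
        return self.soma_radius + self.branch_length + self.endfoot_radius

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def _microglia_masks(
    scene: SceneConfig, center: tuple[float, float], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Ground-truth soma/branches/endfeet masks for one rendered microglia."""
    shape = (scene.field_px, scene.field_px)
    px = scene.pixel_size
    soma = _disk_mask(shape, center, scene.soma_radius / px)
    strokes = np.zeros(shape, dtype=bool)
    blobs = np.zeros(shape, dtype=bool)
    base = rng.uniform(0, 2 * np.pi)
    for k in range(scene.branch_count):
        theta = base + 2 * np.pi * k / scene.branch_count + rng.normal(0, 0.12)
        bend = rng.uniform(-0.35, 0.35)  # mild curvature (rad over the branch)
        t = np.linspace(0.0, 1.0, 200)
        r = (scene.soma_radius * 0.8 + t * scene.branch_length) / px
        ang = theta + bend * t**2
        ys = np.clip(np.round(center[0] + r * np.sin(ang)).astype(int), 0, shape[0] - 1)
        xs = np.clip(np.round(center[1] + r * np.cos(ang)).astype(int), 0, shape[1] - 1)
        stroke = np.zeros(shape, dtype=bool)
        stroke[ys, xs] = True
        strokes |= morphology.dilation(
            stroke, morphology.disk(max(1, int(round(scene.branch_halfwidth / px))))
        )
        blobs |= _disk_mask(shape, (ys[-1], xs[-1]), scene.endfoot_radius / px)
    endfeet = blobs & ~soma
    branches = strokes & ~soma & ~endfeet
    return {"soma": soma, "branches": branches, "endfeet": endfeet}


@dataclass
class CellTruth:
    """Ground truth for one rendered cell: masks plus noise-free pixel traces.

    ``traces`` map compartment name to the exact noise-free pixel value series
    (background included) painted into that compartment.
    """

    cell_id: str
    cell_class: str
    condition: str
    position: tuple[float, float]
    masks: CompartmentMaskSet
    traces: dict[str, np.ndarray]

    @property
    def cell_mask(self) -> np.ndarray:
        return self.masks.cell_mask


@dataclass
class GroundTruthManifest:
    scene: SceneConfig
    cells: list[CellTruth]

    def by_class(self, cell_class: str) -> list[CellTruth]:
        return [c for c in self.cells if c.cell_class == cell_class]


def _place_cells(
    scene: SceneConfig,
    classes: Sequence[str],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    field_um = scene.field_px * scene.pixel_size
    placed: list[tuple[float, float]] = []
    radii: list[float] = []
    for cls in classes:
        r = scene.cell_extent(cls)
        for _ in range(20000):
            y = rng.uniform(r + 1, field_um - r - 1)
            x = rng.uniform(r + 1, field_um - r - 1)
            if all(
                np.hypot(y - py, x - px_) >= r + pr + 1.0
                for (py, px_), pr in zip(placed, radii)
            ):
                placed.append((y, x))
                radii.append(r)
                break
        else:
            raise ValueError(
                f"could not place {len(classes)} cells in a "
                f"{field_um:.0f} µm field without overlap"
            )
    return [(y / scene.pixel_size, x / scene.pixel_size) for y, x in placed]


def render_stack(
    scene: SceneConfig,
    cell_params: Sequence[KineticParameters],
    positions: Sequence[tuple[float, float]] | None = None,
) -> tuple[ImageStack, GroundTruthManifest]:
    """Render a two-channel stack for the given cells.

    Channel 0 (EGFP) is static morphology at constant brightness; channel 1
    (TMRE) paints each compartment with its simulated noise-free trace plus
    background, then adds per-pixel Gaussian noise (sd ``scene.noise_sd``) to
    both channels.  ``positions`` (pixel (y, x) centers) are auto-placed when
    omitted; explicitly supplied positions that collide raise an error listing
    the collisions.
    """
    if not cell_params:
        cell_params = []
    rng = np.random.default_rng(np.random.SeedSequence(scene.seed))
    classes = [p.cell_class for p in cell_params]
    if positions is None:
        positions = _place_cells(scene, classes, rng) if cell_params else []
    elif len(positions) != len(cell_params):
        raise ValueError("positions and cell_params differ in length")

    shape = (scene.field_px, scene.field_px)
    time = np.arange(scene.n_frames) * scene.frame_interval - scene.treatment_time

    cells: list[CellTruth] = []
    for i, (p, pos) in enumerate(zip(cell_params, positions)):
        cid = f"{p.cell_class}_{i:02d}"
        if p.cell_class == "neuron":
            soma = _disk_mask(shape, pos, scene.neuron_radius / scene.pixel_size)
            empty = np.zeros(shape, dtype=bool)
            masks = CompartmentMaskSet(cid, soma=soma, branches=empty, endfeet=empty)
            comps = ["soma"]
        else:
            m = _microglia_masks(scene, pos, rng)
            masks = CompartmentMaskSet(cid, **m)
            comps = ["soma", "branches", "endfeet"]
        traces = {
            c: scene.background
            + p.baseline_intensity * (1.0 + noise_free_response(p, c, time) / 100.0)
            for c in comps
        }
        cells.append(CellTruth(cid, p.cell_class, p.condition, tuple(pos), masks, traces))

    # Collision check across painted cell masks.
    occupancy = np.zeros(shape, dtype=np.int16)
    for c in cells:
        occupancy += c.cell_mask
    if np.any(occupancy > 1):
        colliding = [
            (a.cell_id, b.cell_id)
            for i, a in enumerate(cells)
            for b in cells[i + 1 :]
            if np.any(a.cell_mask & b.cell_mask)
        ]
        raise ValueError(f"cell positions overlap: {colliding}")

    data = np.empty((scene.n_frames, 2, *shape), dtype=np.float32)
    egfp = np.full(shape, scene.background, dtype=np.float32)
    for c in cells:
        egfp[c.cell_mask] = scene.background + scene.egfp_intensity
    data[:, 0] = egfp
    tmre = data[:, 1].reshape(scene.n_frames, -1)
    tmre[:] = scene.background
    for c in cells:
        for comp, trace in c.traces.items():
            idx = np.flatnonzero(c.masks.as_dict()[comp].ravel())
            tmre[:, idx] = trace[:, None].astype(np.float32)
    if scene.noise_sd > 0:
        for ch in range(2):
            data[:, ch] += rng.normal(0.0, scene.noise_sd, size=(scene.n_frames, *shape)).astype(
                np.float32
            )
    np.clip(data, 0.0, None, out=data)

    stack = ImageStack(
        data=data,
        frame_interval=scene.frame_interval,
        pixel_size=scene.pixel_size,
        treatment_time=scene.treatment_time,
    )
    return stack, GroundTruthManifest(scene=scene, cells=cells)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Multi-condition experiment layout for :func:`generate_cohort`.

    ``response_cv`` is the between-cell coefficient of variation of state
    amplitudes (one lognormal factor per cell and state, applied to every
    compartment in that state, so the whole-cell identity is preserved).
    """

    conditions: tuple[str, ...] = ("baseline", "lps", "lps_emapunil", "emapunil_only")
    n_per_group: int = 10
    n_neurons: int = 0
    response_cv: float = 0.25
    frame_interval: float = 1.0
    duration: float = 2100.0
    treatment_time: float = 300.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if self.response_cv < 0:
            raise ValueError("response_cv must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def jittered_cell_parameters(
    base: KineticParameters, rng: np.random.Generator, cv: float
) -> KineticParameters:
    """Per-cell parameter draw: lognormal per-state amplitude factors (mean 1)."""
    p = base
    if base.n_states:
        p = base.scaled(_lognormal_factors(rng, cv, base.n_states))
    if base.neuron_amplitude > 0:
        from dataclasses import replace

        p = replace(p, neuron_amplitude=float(
            base.neuron_amplitude * _lognormal_factors(rng, cv, 1)[0]
        ))
    return p


def generate_cohort(
    design: ExperimentDesign,
    out_dir: str | Path,
    seed: int = 1,
    overwrite: bool = False,
) -> Path:
    """Write a reproducible trace-level cohort dataset.

    Layout: ``traces/<condition>_<class>_<ii>.csv`` (long format, all
    compartments) plus ``manifest.json``.  Per-cell RNG streams are spawned
    deterministically from the master seed, so the same seed yields
    byte-identical manifests and CSVs.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
        shutil.rmtree(out)
    (out / "traces").mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    entries = []
    cell_index = 0
    for condition in design.conditions:
        for cell_class, n in (("microglia", design.n_per_group), ("neuron", design.n_neurons)):
            base = make_default_parameters(condition, cell_class)
            for i in range(n):
                child = np.random.SeedSequence(entropy=seed, spawn_key=(cell_index,))
                rng = np.random.default_rng(child)
                p = jittered_cell_parameters(base, rng, design.response_cv)
                roi = f"{condition}_{cell_class}_{i:02d}"
                comps = (
                    list(COMPARTMENTS) if cell_class == "microglia" else ["soma"]
                )
                traces = []
                for comp in comps:
                    noise_seed = int(rng.integers(2**31))
                    tr = simulate_trace(
                        p,
                        compartment=comp,
                        frame_interval=design.frame_interval,
                        duration=design.duration,
                        treatment_time=design.treatment_time,
                        seed=noise_seed,
                    )
                    traces.append(
                        FluorescenceTrace(
                            time=tr.time,
                            intensity=tr.intensity,
                            roi_id=roi,
                            compartment=comp,
                            condition=condition,
                            cell_class=cell_class,
                        )
                    )
                fname = f"traces/{roi}.csv"
                write_traces_csv(out / fname, traces)
                entries.append(
                    {
                        "file": fname,
                        "roi_id": roi,
                        "condition": condition,
                        "cell_class": cell_class,
                        "cell_index": cell_index,
                        "state_amplitudes": [list(r) for r in np.round(p.effective_amplitudes, 10)]
                        if p.n_states
                        else [],
                        "neuron_amplitude": round(float(p.neuron_amplitude), 10),
                    }
                )
                cell_index += 1

    manifest = {
        "seed": seed,
        "design": asdict(design),
        "n_cells": len(entries),
        "cells": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
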
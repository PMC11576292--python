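"""Morphology-channel segmentation and compartment partitioning.

Microglia are segmented from the (static) EGFP channel by global thresholding
and connected-component labeling.  Each cell mask is then partitioned into
three disjoint, exhaustive compartments:

* **soma** — largest connected component of a morphological opening of the
  cell mask (disc radius ``soma_open_radius``, default 3 µm);
* **endfeet** — pixels of the remainder whose nearest skeleton pixel lies on a
  terminal (leaf) skeleton segment within ``endfoot_len`` (default 4 µm) path
  length of a process tip;
* **branches** — everything else.

The automatic partition substitutes for hand-traced ROIs; user-supplied masks
can bypass it entirely (see :func:`load_mask_png` / :func:`save_mask_png`).
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .traces import FluorescenceTrace

CHANNEL_LABELS = ("EGFP", "TMRE")


@dataclass
class ImageStack:
    """Two-channel time-lapse stack, T x C x Y x X.

    Channel 0 is the morphology reporter (EGFP), channel 1 the potentiometric
    dye (TMRE).  ``treatment_time`` is the recording time (s from the first
    frame) at which treatment enters the bath; trace timestamps are reported
    relative to it.
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float
    treatment_time: float = 0.0
    channels: tuple[str, str] = CHANNEL_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[1] != 2:
            raise ValueError("stack must be T x 2 x Y x X")
        if self.data.shape[0] < 2:
            raise ValueError("stack must have at least 2 frames")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be > 0")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def time(self) -> np.ndarray:
        """Frame timestamps in seconds relative to treatment."""
        return np.arange(self.n_frames) * self.frame_interval - self.treatment_time

    def channel_index(self, channel: str) -> int:
        if channel not in self.channels:
            raise ValueError(f"unknown channel {channel!r}; have {self.channels}")
        return self.channels.index(channel)

    def morphology_image(self) -> np.ndarray:
        """Time-averaged EGFP frame used for segmentation."""
        return self.data[:, self.channel_index("EGFP")].mean(axis=0)


def write_stack_tiff(path: str | Path, stack: ImageStack) -> None:
    meta = {
        "frame_interval_s": stack.frame_interval,
        "pixel_size_um": stack.pixel_size,
        "treatment_time_s": stack.treatment_time,
        "channels": list(stack.channels),
    }
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        metadata=None,
        description=json.dumps(meta, sort_keys=True),
    )


def read_stack_tiff(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    meta = json.loads(desc)
    return ImageStack(
        data=data.reshape(-1, 2, *data.shape[-2:]),
        frame_interval=float(meta["frame_interval_s"]),
        pixel_size=float(meta["pixel_size_um"]),
        treatment_time=float(meta.get("treatment_time_s", 0.0)),
        channels=tuple(meta.get("channels", CHANNEL_LABELS)),
    )


@dataclass
class CompartmentMaskSet:
    """Disjoint soma/branches/endfeet masks of one cell on the Y x X grid."""

    cell_id: str
    soma: np.ndarray
    branches: np.ndarray
    endfeet: np.ndarray

    def __post_init__(self) -> None:
        self.soma = np.asarray(self.soma, dtype=bool)
        self.branches = np.asarray(self.branches, dtype=bool)
        self.endfeet = np.asarray(self.endfeet, dtype=bool)
        if not (self.soma.shape == self.branches.shape == self.endfeet.shape):
            raise ValueError("compartment masks must share one grid")
        if (
            np.any(self.soma & self.branches)
            or np.any(self.soma & self.endfeet)
            or np.any(self.branches & self.endfeet)
        ):
            raise ValueError("compartment masks must be pairwise disjoint")

    @property
    def cell_mask(self) -> np.ndarray:
        return self.soma | self.branches | self.endfeet

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"soma": self.soma, "branches": self.branches, "endfeet": self.endfeet}


def segment_cells(
    morphology_image: np.ndarray,
    min_area_px: int = 50,
    threshold_method: str = "otsu",
) -> np.ndarray:
    """Label cells in a 2-D morphology image (0 = background, 1..K = cells).

    Touching cells merge into one label (no watershed splitting by default).
    An all-zero or constant image yields zero cells.
    """
    img = np.asarray(morphology_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("morphology image must be 2-D")
    if np.any(~np.isfinite(img)):
        raise ValueError("morphology image contains non-finite pixels")
    if np.any(img < 0):
        raise ValueError("morphology image must be non-negative")
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    fg = img > threshold_otsu(img)
    labels, _ = ndi.label(fg)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < int(min_area_px))
    fg[np.isin(labels, small[small > 0])] = False
    return measure.label(fg).astype(np.int32)


def _skeleton_tip_distance(skeleton: np.ndarray, tips: np.ndarray, pixel_size: float) -> np.ndarray:
    """Geodesic path length (µm) along the skeleton from the nearest tip.

    Multi-source Dijkstra on the 8-connected skeleton graph; skeletons are a
    few hundred pixels so a heap walk is plenty.
    """
    dist = np.full(skeleton.shape, np.inf)
    heap: list[tuple[float, int, int]] = []
    for y, x in zip(*np.nonzero(tips)):
        dist[y, x] = 0.0
        heapq.heappush(heap, (0.0, int(y), int(x)))
    steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    ny_, nx_ = skeleton.shape
    while heap:
        d, y, x = heapq.heappop(heap)
        if d > dist[y, x]:
            continue
        for dy, dx in steps:
            yy, xx = y + dy, x + dx
            if 0 <= yy < ny_ and 0 <= xx < nx_ and skeleton[yy, xx]:
                nd = d + pixel_size * (np.sqrt(2.0) if dy and dx else 1.0)
                if nd < dist[yy, xx]:
                    dist[yy, xx] = nd
                    heapq.heappush(heap, (nd, yy, xx))
    return dist


def partition_compartments(
    cell_mask: np.ndarray,
    pixel_size: float,
    soma_open_radius: float = 3.0,
    endfoot_len: float = 4.0,
    cell_id: str = "cell",
) -> CompartmentMaskSet:
    """Partition one cell mask into disjoint soma/branches/endfeet masks.

    Parameters are in µm.  If nothing survives the opening (a cell thinner
    than the opening disc everywhere) the whole mask is assigned to the soma
    and a warning is issued.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("cell_mask must be a non-empty 2-D binary mask")
    if measure.label(mask).max() != 1:
        raise ValueError("cell_mask must be a single connected component")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")

    radius_px = max(1, int(round(soma_open_radius / pixel_size)))
    opened = morphology.opening(mask, morphology.disk(radius_px)) & mask
    if not opened.any():
        warnings.warn(
            f"{cell_id}: no pixels survive soma opening; whole mask assigned to soma",
            stacklevel=2,
        )
        empty = np.zeros_like(mask)
        return CompartmentMaskSet(cell_id, soma=mask, branches=empty, endfeet=empty)

    lab = measure.label(opened)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    soma = lab == int(np.argmax(sizes))

    # Discrete opening leaves thin slivers hugging the soma boundary (and, on
    # a disc-only cell, nothing else): absorb remainder components that never
    # stray farther than the opening radius from the soma.
    dist_to_soma = ndi.distance_transform_edt(~soma, sampling=pixel_size)
    rem_lab, n_rem = ndi.label(mask & ~soma)
    for k in range(1, n_rem + 1):
        comp = rem_lab == k
        if dist_to_soma[comp].max() <= soma_open_radius:
            soma |= comp

    remainder = mask & ~soma
    empty = np.zeros_like(mask)
    if not remainder.any():
        return CompartmentMaskSet(cell_id, soma=soma, branches=empty, endfeet=empty)

    skel = morphology.skeletonize(remainder)
    if not skel.any():
        return CompartmentMaskSet(cell_id, soma=soma, branches=remainder, endfeet=empty)

    # Skeleton endpoints; those close to the soma are branch roots, the rest
    # are process tips.
    neigh = ndi.convolve(skel.astype(int), np.ones((3, 3), dtype=int), mode="constant")
    endpoints = skel & (neigh == 2)  # self + exactly one neighbour
    tips = endpoints & (ndi.distance_transform_edt(~soma, sampling=pixel_size) > endfoot_len)
    if not tips.any():
        return CompartmentMaskSet(cell_id, soma=soma, branches=remainder, endfeet=empty)

    tip_dist = _skeleton_tip_distance(skel, tips, pixel_size)
    leaf = skel & (tip_dist <= endfoot_len)

    # Assign every remainder pixel to its nearest skeleton pixel.
    _, (iy, ix) = ndi.distance_transform_edt(~skel, return_indices=True)
    nearest_is_leaf = leaf[iy, ix]
    endfeet = remainder & nearest_is_leaf
    branches = remainder & ~endfeet
    return CompartmentMaskSet(cell_id, soma=soma, branches=branches, endfeet=endfeet)


def extract_trace(
    stack: ImageStack,
    mask: np.ndarray,
    channel: str = "TMRE",
    **meta: str,
) -> FluorescenceTrace:
    """Per-frame arithmetic mean of one channel over a binary mask."""
    m = np.asarray(mask, dtype=bool)
    if m.shape != stack.shape_yx:
        raise ValueError("mask shape does not match stack Y x X")
    if not m.any():
        raise ValueError("mask is empty")
    ci = stack.channel_index(channel)
    series = stack.data[:, ci][:, m].mean(axis=1)
    return FluorescenceTrace(time=stack.time, intensity=series, **meta)


def save_mask_png(path: str | Path, mask: np.ndarray) -> None:
    from imageio.v3 import imwrite

    imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask_png(path: str | Path) -> np.ndarray:
    from imageio.v3 import imread

    return np.asarray(imread(path)) > 0


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def match_labels_to_masks(labels: np.ndarray, truth_masks: list[np.ndarray]) -> list[int]:
    """For each ground-truth mask, the label with maximal overlap (0 if none)."""
    out = []
    for tm in truth_masks:
        vals, counts = np.unique(labels[np.asarray(tm, dtype=bool)], return_counts=True)
        nz = vals > 0
        out.append(int(vals[nz][np.argmax(counts[nz])]) if nz.any() else 0)
    return out
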
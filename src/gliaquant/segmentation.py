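"""Nucleus and microglia segmentation from fluorescence channels.

The surface (CD45-like) channel is automatically thresholded to isolate
microglial cell bodies; the nuclei (Hoechst-like) channel is thresholded,
hole-filled, and split by a distance-transform watershed.  Thresholding is
Otsu's method applied to the illumination-flattened channel (division by a
large-radius smoothed copy), which makes the result invariant to
multiplying the channel by any positive constant.

Pure Otsu always splits the histogram, so an explicit contrast guard
declares a channel empty when the "foreground" it finds is not separated
from background by a robust margin — without it, a signal-free channel
would segment into noise speckle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .synthetic import FieldImage

__all__ = [
    "LabeledMask",
    "assign_nuclei_to_cells",
    "estimate_background",
    "flatten_illumination",
    "segment_microglia",
    "segment_nuclei",
    "threshold_channel",
]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass
class LabeledMask:
    """Integer-labeled segmentation; 0 is background, labels consecutive."""

    labels: np.ndarray
    kind: str  # "nuclei" | "cells"
    source_field: str = ""

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")


def flatten_illumination(channel: np.ndarray, sigma: float | None = None) -> np.ndarray:
    """Divide out the smooth illumination profile of a channel.

    The profile is the channel smoothed at a scale far larger than any cell
    (default: 1/8 of the smaller image dimension), so foreground objects
    barely perturb it in the sparse-culture regime.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if sigma is None:
        # floor keeps the profile far larger than any cell even on small crops
        sigma = max(min(channel.shape) / 8.0, 32.0)
    profile = ndimage.gaussian_filter(channel, sigma, mode="reflect")
    profile = np.maximum(profile, 1e-9)
    return channel / profile


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map labels to 1..n preserving raster order of first appearance."""
    out = np.zeros_like(labels, dtype=np.int32)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    for new, old in enumerate(np.sort(ids), start=1):
        out[labels == old] = new
    return out


def threshold_channel(
    channel: np.ndarray, *, flatten: bool = True, contrast_sds: float = 4.0
) -> np.ndarray:
    """Otsu foreground mask of a (flattened) channel with an empty-image guard.

    The guard requires the Otsu split to separate the two classes by at
    least ``contrast_sds`` robust standard deviations of the background
    class; otherwise the channel is declared signal-free.
    """
    flat = flatten_illumination(channel) if flatten else np.asarray(channel, float)
    if np.ptp(flat) == 0:
        return np.zeros(flat.shape, dtype=bool)
    t = threshold_otsu(flat)
    mask = flat > t
    if not mask.any() or mask.all():
        return np.zeros(flat.shape, dtype=bool)
    bg_vals = flat[~mask]
    bg_med = np.median(bg_vals)
    bg_sd = 1.4826 * np.median(np.abs(bg_vals - bg_med))
    fg_med = np.median(flat[mask])
    if bg_sd == 0:
        bg_sd = max(np.std(bg_vals), 1e-12)
    if (fg_med - bg_med) < contrast_sds * bg_sd:
        return np.zeros(flat.shape, dtype=bool)
    return mask


def segment_nuclei(
    field: FieldImage,
    min_area: float = 25.0,
    max_area: float = 500.0,
    *,
    seed_min_distance: int = 5,
    channel_role: str = "nuclei",
) -> LabeledMask:
    """Detect nuclei: threshold, fill holes, watershed-split touching blobs.

    Watershed seeds are local maxima of the (lightly smoothed) Euclidean
    distance transform with a minimum separation of one nuclear radius.
    Objects outside ``[min_area, max_area]`` px^2 are dropped; labels are
    relabeled consecutively in raster order.
    """
    channel = field.channel(channel_role)
    mask = threshold_channel(channel)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return LabeledMask(np.zeros(mask.shape, np.int32), "nuclei", field.field_id)

    distance = ndimage.distance_transform_edt(mask)
    smooth_dist = ndimage.gaussian_filter(distance, 1.0)
    peaks = peak_local_max(
        smooth_dist,
        min_distance=seed_min_distance,
        labels=ndimage.label(mask, structure=_EIGHT)[0],
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smooth_dist, markers, mask=mask, connectivity=2)

    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area) | (areas > max_area))
    labels[np.isin(labels, bad[bad > 0])] = 0
    return LabeledMask(_relabel_consecutive(labels), "nuclei", field.field_id)


def segment_microglia(
    field: FieldImage,
    min_area: float = 80.0,
    *,
    channel_role: str = "surface",
) -> LabeledMask:
    """Isolate surface-marker-positive cell bodies by automatic thresholding.

    Global Otsu on the illumination-flattened channel, 8-connected
    components, small-object removal.  Components without an assigned
    nucleus are dropped later, at the assignment step, not here.
    """
    channel = field.channel(channel_role)
    mask = threshold_channel(channel)
    mask = ndimage.binary_fill_holes(mask)
    if min_area > 1:
        mask = remove_small_objects(mask, max_size=int(min_area) - 1)
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    return LabeledMask(_relabel_consecutive(labels), "cells", field.field_id)


@dataclass
class NucleusAssignment:
    """Nucleus <-> cell pairing by maximal area overlap."""

    table: pd.DataFrame  # nucleus_id, cell_id (0 = unassigned), overlap_px
    empty_cells: np.ndarray  # cell labels with no assigned nucleus

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table.cell_id > 0]


def assign_nuclei_to_cells(
    nuclei: LabeledMask, cells: LabeledMask
) -> NucleusAssignment:
    """Assign each nucleus to the cell with which it overlaps most.

    Ties are broken toward the smaller cell label.  Nuclei with zero cell
    overlap are unassigned (``cell_id = 0``) — in this assay they are the
    non-microglial nuclei.  Cells that end up with no nucleus are flagged so
    per-cell assays can exclude them.
    """
    if nuclei.labels.shape != cells.labels.shape:
        raise ValueError("nuclei and cells masks must have the same shape")
    nuc = nuclei.labels
    cel = cells.labels
    n_nuc = int(nuc.max())
    n_cel = int(cel.max())
    rows = []
    if n_nuc:
        both = (nuc > 0) & (cel > 0)
        pair_counts: dict[tuple[int, int], int] = {}
        if both.any():
            pairs = np.stack([nuc[both], cel[both]], axis=1)
            uniq, counts = np.unique(pairs, axis=0, return_counts=True)
            for (ni, ci), cnt in zip(uniq, counts):
                pair_counts[(int(ni), int(ci))] = int(cnt)
        best: dict[int, tuple[int, int]] = {}  # nucleus -> (overlap, cell)
        for (ni, ci), cnt in sorted(pair_counts.items()):
            cur = best.get(ni)
            if cur is None or cnt > cur[0]:  # ties keep smaller cell_id
                best[ni] = (cnt, ci)
        for ni in range(1, n_nuc + 1):
            overlap, ci = best.get(ni, (0, 0))
            rows.append({"nucleus_id": ni, "cell_id": ci, "overlap_px": overlap})
    table = pd.DataFrame(rows, columns=["nucleus_id", "cell_id", "overlap_px"])
    occupied = set(table.cell_id[table.cell_id > 0]) if len(table) else set()
    empty = np.array(sorted(set(range(1, n_cel + 1)) - occupied), dtype=int)
    return NucleusAssignment(table=table, empty_cells=empty)


def estimate_background(
    channel: np.ndarray, cell_mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Robust background level and spread of a channel.

    Median and MAD-derived sd over pixels outside the foreground mask; if no
    mask is given, over the lowest-intensity half of the pixels.  Raises on
    an all-foreground image.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if cell_mask is not None:
        sel = channel[~np.asarray(cell_mask, bool)]
        if sel.size == 0:
            raise ValueError("no background pixels: mask covers the whole image")
    else:
        sel = channel[channel <= np.median(channel)]
    bg_mean = float(np.median(sel))
    bg_sd = float(1.4826 * np.median(np.abs(sel - bg_mean)))
    return bg_mean, bg_sd
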
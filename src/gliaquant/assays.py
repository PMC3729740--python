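"""Marker positivity, counting, proliferation, phagocytosis and intensity.

Turns a segmented field into the biological readouts: how many microglia
are present, which of them express a nuclear or cell-level marker, what
fraction carry phagocytosed cargo, and how bright each marker is.

A cell or nucleus is *positive* for a marker when its background-normalized
compartment intensity exceeds ``k`` robust standard deviations above
background (default k = 3).  Phagocytosis is scored by the fraction of the
cell footprint covered by cargo-positive pixels (default threshold 2% of
the cell area), which is robust to how cargo clumps into puncta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import LabeledMask, NucleusAssignment, estimate_background

__all__ = [
    "PositivityRule",
    "classify_marker",
    "classify_nuclei",
    "count_microglia",
    "marker_intensity",
    "phagocytosis_fraction",
    "proliferation_fraction",
    "region_means",
]


@dataclass(frozen=True)
class PositivityRule:
    """Threshold criterion for calling a cell positive for a marker."""

    marker: str
    compartment: str = "nucleus"  # "nucleus" | "cell"
    statistic: str = "mean"  # "mean" | "median"
    k: float = 3.0  # sd units above background
    min_area_fraction: float = 0.02  # cargo only

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("positivity threshold k must be > 0")
        if self.compartment not in ("nucleus", "cell"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.statistic not in ("mean", "median"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


def region_means(
    intensity: np.ndarray, labels: np.ndarray, statistic: str = "mean"
) -> np.ndarray:
    """Per-label compartment statistic, index i-1 holds label i."""
    n = int(labels.max())
    if n == 0:
        return np.empty(0)
    idx = np.arange(1, n + 1)
    if statistic == "mean":
        return np.asarray(ndimage.mean(intensity, labels=labels, index=idx))
    if statistic == "median":
        return np.asarray(ndimage.median(intensity, labels=labels, index=idx))
    raise ValueError(f"unknown statistic {statistic!r}")


def classify_nuclei(
    channel: np.ndarray,
    nuclei: LabeledMask,
    rule: PositivityRule,
    background: tuple[float, float],
) -> pd.DataFrame:
    """Positivity of every nucleus for a nuclear marker channel."""
    bg_mean, bg_sd = background
    if bg_sd <= 0:
        bg_sd = 1.0  # noise-free image: any excess is decisive
    vals = region_means(channel, nuclei.labels, rule.statistic)
    scores = (vals - bg_mean) / bg_sd
    return pd.DataFrame(
        {
            "nucleus_id": np.arange(1, len(vals) + 1),
            "score": scores,
            "positive": scores > rule.k,
        }
    )


def classify_marker(
    channel: np.ndarray,
    cells: LabeledMask,
    nuclei: LabeledMask,
    assignment: NucleusAssignment,
    rule: PositivityRule,
    background: tuple[float, float] | None = None,
    cell_mask_for_bg: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-microglial-cell positivity call for one marker channel.

    The score is ``(compartment statistic - bg_mean) / bg_sd``; the
    compartment is the cell's own nucleus or its whole body depending on
    the rule.  Only cells with an assigned nucleus are scored.
    """
    if background is None:
        background = estimate_background(channel, cell_mask_for_bg)
    bg_mean, bg_sd = background
    if bg_sd <= 0:
        bg_sd = 1.0
    assigned = assignment.assigned
    if rule.compartment == "nucleus":
        vals_all = region_means(channel, nuclei.labels, rule.statistic)
        vals = vals_all[assigned.nucleus_id.to_numpy(dtype=int) - 1]
    else:
        vals_all = region_means(channel, cells.labels, rule.statistic)
        vals = vals_all[assigned.cell_id.to_numpy(dtype=int) - 1]
    scores = (vals - bg_mean) / bg_sd
    return pd.DataFrame(
        {
            "cell_id": assigned.cell_id.to_numpy(dtype=int),
            "nucleus_id": assigned.nucleus_id.to_numpy(dtype=int),
            "score": scores,
            "positive": scores > rule.k,
        }
    )


def count_microglia(
    nuclei: LabeledMask,
    cells: LabeledMask,
    assignment: NucleusAssignment,
    pu1_positive: pd.DataFrame | None = None,
) -> dict[str, int]:
    """Field-level counts: PU.1+ nuclei, nucleated surface+ cells, all nuclei.

    Both microglia counts the assay uses are reported: nuclei positive for
    the PU.1 channel (if classified) and surface-marker cells that own at
    least one nucleus.
    """
    cd45_cells = int(cells.n_objects - len(assignment.empty_cells))
    counts = {
        "total_nuclei": int(nuclei.n_objects),
        "cd45_cells": cd45_cells,
        "pu1_positive_nuclei": (
            int(pu1_positive.positive.sum()) if pu1_positive is not None else -1
        ),
    }
    return counts


def _fraction(flags: pd.Series | np.ndarray) -> float:
    n = len(flags)
    if n == 0:
        return np.nan  # zero-microglia field: missing, not zero
    return float(np.asarray(flags, dtype=float).mean())


def proliferation_fraction(marker_calls: pd.DataFrame) -> float:
    """Dividing fraction: division-marker-positive microglia / all microglia."""
    return _fraction(marker_calls.positive)


def cargo_area_fractions(
    channel: np.ndarray,
    cells: LabeledMask,
    background: tuple[float, float],
    k: float = 3.0,
) -> np.ndarray:
    """Per-cell fraction of the footprint covered by cargo-positive pixels."""
    bg_mean, bg_sd = background
    cargo_mask = channel > bg_mean + k * max(bg_sd, 1.0)
    n = cells.n_objects
    if n == 0:
        return np.empty(0)
    idx = np.arange(1, n + 1)
    covered = np.asarray(ndimage.mean(cargo_mask.astype(float), cells.labels, idx))
    return covered


def phagocytosis_fraction(
    channel: np.ndarray,
    cells: LabeledMask,
    assignment: NucleusAssignment,
    rule: PositivityRule,
    background: tuple[float, float] | None = None,
    cell_mask_for_bg: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Phagocytic fraction of microglia plus the per-cell cargo table.

    A cell is phagocytic when cargo-positive pixels cover at least
    ``rule.min_area_fraction`` of its area.
    """
    if background is None:
        background = estimate_background(channel, cell_mask_for_bg)
    covered = cargo_area_fractions(channel, cells, background, rule.k)
    cell_ids = assignment.assigned.cell_id.to_numpy(dtype=int)
    frac = covered[cell_ids - 1] if len(cell_ids) else np.empty(0)
    table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cargo_area_fraction": frac,
            "positive": frac >= rule.min_area_fraction,
        }
    )
    return _fraction(table.positive), table


def marker_intensity(
    channel: np.ndarray,
    compartment_labels: np.ndarray,
    ids: np.ndarray,
    background: tuple[float, float],
    positive: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Background-subtracted mean intensity per cell and the field summary.

    The field summary averages over positive cells when a positivity vector
    is given (inducible markers) and over all passed cells otherwise
    (constitutive markers).
    """
    bg_mean, _ = background
    vals_all = region_means(channel, compartment_labels)
    ids = np.asarray(ids, dtype=int)
    vals = vals_all[ids - 1] - bg_mean if len(ids) else np.empty(0)
    table = pd.DataFrame({"id": ids, "intensity": vals})
    sel = vals if positive is None else vals[np.asarray(positive, bool)]
    summary = float(np.mean(sel)) if len(sel) else np.nan
    return table, summary
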
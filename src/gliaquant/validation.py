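"""Recovery metrics: measured results against generator ground truth.

Quantifies how faithfully the pipeline recovers what the generator drew:
object counts, marker fractions, per-cell mask overlap (IoU), shape and
intensity errors.  Used by the `validate` CLI subcommand and the
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import LabeledMask
from .synthetic import _superellipse_mask  # exact re-render of true bodies

__all__ = [
    "cell_iou_table",
    "count_recovery",
    "match_nuclei_to_truth",
]


def match_nuclei_to_truth(
    nuclei: LabeledMask, truth: pd.DataFrame, max_dist: float = 3.0
) -> pd.DataFrame:
    """Greedy nearest-centroid match of detected nuclei to true cells.

    Returns one row per true cell with the matched nucleus label (0 = miss)
    and the centroid distance.
    """
    from scipy import ndimage

    n = nuclei.n_objects
    if n:
        centroids = np.array(
            ndimage.center_of_mass(
                nuclei.labels > 0, nuclei.labels, np.arange(1, n + 1)
            )
        )
    else:
        centroids = np.empty((0, 2))
    taken = np.zeros(n, dtype=bool)
    rows = []
    for _, cell in truth.iterrows():
        target = np.array([cell.row, cell.col])
        if n:
            d = np.linalg.norm(centroids - target, axis=1)
            d[taken] = np.inf
            j = int(np.argmin(d))
            if d[j] <= max_dist:
                taken[j] = True
                rows.append(
                    {"cell_id": cell.cell_id, "nucleus_label": j + 1, "dist": d[j]}
                )
                continue
        rows.append({"cell_id": cell.cell_id, "nucleus_label": 0, "dist": np.inf})
    return pd.DataFrame(rows)


def cell_iou_table(
    cells: LabeledMask, truth: pd.DataFrame, superellipse_exponent: float = 2.5
) -> pd.DataFrame:
    """Intersection-over-union of each true microglial body with its best
    overlapping detected cell."""
    labels = cells.labels
    rows = []
    for _, cell in truth[truth.is_microglia].iterrows():
        mask, (r0, c0) = _superellipse_mask(
            labels.shape,
            (cell.row, cell.col),
            cell.body_a,
            cell.body_b,
            cell.orientation,
            superellipse_exponent,
        )
        window = labels[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        overlapped = window[mask]
        overlapped = overlapped[overlapped > 0]
        if overlapped.size == 0:
            rows.append({"cell_id": cell.cell_id, "label": 0, "iou": 0.0})
            continue
        label = int(np.bincount(overlapped).argmax())
        inter = int((window[mask] == label).sum())
        union = int(mask.sum()) + int((labels == label).sum()) - inter
        rows.append({"cell_id": cell.cell_id, "label": label, "iou": inter / union})
    return pd.DataFrame(rows, columns=["cell_id", "label", "iou"])


def count_recovery(per_field: pd.DataFrame, truths: list[pd.DataFrame]) -> dict:
    """Relative count errors pooled over fields."""
    true_nuclei = sum(len(t) for t in truths)
    true_mg = sum(int(t.is_microglia.sum()) for t in truths)
    got_nuclei = int(per_field.total_nuclei.sum())
    got_mg = int(per_field.cd45_cells.sum())
    return {
        "true_nuclei": true_nuclei,
        "measured_nuclei": got_nuclei,
        "nuclei_count_rel_error": abs(got_nuclei - true_nuclei) / max(true_nuclei, 1),
        "true_microglia": true_mg,
        "measured_microglia": got_mg,
        "microglia_count_rel_error": abs(got_mg - true_mg) / max(true_mg, 1),
    }
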
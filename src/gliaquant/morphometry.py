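"""Per-cell shape descriptors for rod-like microglial morphology.

Two dimensionless descriptors quantify how elongated a segmented cell is:

* **Shape Factor** ``4*pi*A / P**2`` — circularity; 1 for a perfect circle,
  approaching 0 for thin, elongated shapes.  ``A`` is the pixel-count area and
  ``P`` a subpixel contour-length perimeter estimate (Crofton and raw
  boundary-walk estimators are available for sensitivity analysis).
* **Elliptical Form Factor (EFF)** — length/breadth of the cell, >= 1; larger
  values mean a more rod-like cell.  By default it is the axis ratio of the
  moment-equivalent ellipse; a maximum-Feret variant is available behind a
  flag.

Central moments are accumulated in exact integer arithmetic so the only
rounding is the final division; this makes the values reproducible and
directly comparable against a brute-force pixel-summation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = [
    "RegionMorphometry",
    "area_and_central_moments",
    "shape_factor",
    "elliptical_form_factor",
    "measure_cells",
]

#: variance of a unit square about its center; added to the per-pixel point
#: variances so a w x h rectangle has moment-ellipse axis ratio exactly w/h.
_PIXEL_VAR = 1.0 / 12.0


@dataclass(frozen=True)
class RegionMorphometry:
    """Shape measurements of one segmented cell."""

    cell_id: int
    area: float  # px^2
    perimeter: float  # px
    shape_factor: float
    elliptical_form_factor: float
    major_axis: float  # px, full length of the moment-equivalent ellipse
    minor_axis: float  # px
    orientation: float  # radians, CCW from the row axis
    eff_definition: str = "moment"
    perimeter_definition: str = "subpixel"
    degenerate: bool = False  # minor axis hit the 1 px floor
    shape_factor_gt1: bool = False  # discretization pushed SF above 1


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("region mask must be 2-D")
    return mask.astype(bool)


def area_and_central_moments(mask: np.ndarray) -> tuple[int, float, float, float]:
    """Area and central second moments (mu20, mu11, mu02) of a binary mask.

    Moments are pixel-center point moments: ``mu20 = sum((r - rbar)**2)`` over
    foreground pixels, etc.  All accumulation is exact (Python integers); the
    single rounding step is the final division by the area.
    """
    mask = _as_bool_mask(mask)
    rr, cc = np.nonzero(mask)
    n = int(rr.size)
    if n == 0:
        raise ValueError("empty region")
    # exact integer raw moments
    m10 = int(rr.sum(dtype=np.int64))
    m01 = int(cc.sum(dtype=np.int64))
    m20 = int((rr.astype(np.int64) ** 2).sum())
    m02 = int((cc.astype(np.int64) ** 2).sum())
    m11 = int((rr.astype(np.int64) * cc.astype(np.int64)).sum())
    mu20 = (n * m20 - m10 * m10) / n
    mu02 = (n * m02 - m01 * m01) / n
    mu11 = (n * m11 - m10 * m01) / n
    return n, mu20, mu11, mu02


#: pre-smoothing bandwidth and polygon-simplification tolerance of the
#: subpixel perimeter estimator; calibrated on digitized disks (r 20-100,
#: error < 0.5%) without inflating rectangle perimeters.
_SUBPIXEL_SIGMA = 0.7
_SUBPIXEL_TOL = 0.8


def _contour_length(field: np.ndarray, tol: float) -> float:
    total = 0.0
    for contour in measure.find_contours(field, 0.5):
        poly = measure.approximate_polygon(contour, tol) if tol > 0 else contour
        total += float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
    return total


def _perimeter(mask: np.ndarray, method: str) -> float:
    if method == "subpixel":
        # Length of the half-level contour of the lightly smoothed mask,
        # simplified to subpixel polygons.  Staircase artifacts cancel, so
        # smooth blobs (the regime cell bodies live in) are near-unbiased;
        # sharp corners cost a fixed ~1 px deficit each.
        padded = gaussian_filter(
            np.pad(mask.astype(float), 3), _SUBPIXEL_SIGMA, mode="constant"
        )
        return _contour_length(padded, _SUBPIXEL_TOL)
    if method == "crofton":
        return float(measure.perimeter_crofton(mask, directions=4))
    if method == "contour":
        # raw boundary walk along the half-level staircase contour;
        # overestimates curved boundaries, kept for sensitivity analysis
        return _contour_length(np.pad(mask.astype(float), 1), 0.0)
    raise ValueError(f"unknown perimeter method {method!r}")


def shape_factor(mask: np.ndarray, perimeter_method: str = "subpixel") -> float:
    """Circularity ``4*pi*A/P**2`` of a single connected region.

    Values slightly above 1 can occur for small digitized disks; they are
    reported as-is (flagged downstream), never clamped.
    """
    mask = _as_bool_mask(mask)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty region")
    perim = _perimeter(mask, perimeter_method)
    if perim == 0:
        raise ValueError("degenerate region with zero perimeter")
    return 4.0 * np.pi * area / perim**2


def _moment_axes(mask: np.ndarray) -> tuple[float, float, float, bool]:
    """Axis lengths and orientation of the moment-equivalent ellipse.

    Per-pixel point variances get the unit-square correction so finite-width
    shapes never collapse; a 1 px floor on the minor axis guards pathological
    masks and is flagged.
    """
    n, mu20, mu11, mu02 = area_and_central_moments(mask)
    vrr = mu20 / n + _PIXEL_VAR
    vcc = mu02 / n + _PIXEL_VAR
    vrc = mu11 / n
    common = np.sqrt((vrr - vcc) ** 2 + 4.0 * vrc**2)
    l1 = (vrr + vcc + common) / 2.0
    l2 = (vrr + vcc - common) / 2.0
    major = 4.0 * np.sqrt(max(l1, 0.0))
    minor = 4.0 * np.sqrt(max(l2, 0.0))
    degenerate = minor < 1.0
    minor = max(minor, 1.0)
    orientation = 0.5 * np.arctan2(2.0 * vrc, vrr - vcc)
    return major, minor, orientation, degenerate


def _feret_axes(mask: np.ndarray) -> tuple[float, float]:
    """Maximum Feret diameter and the caliper breadth perpendicular to it."""
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("empty region")
    # pixel corners so single-pixel-wide shapes have finite extent
    pts = np.column_stack([rr, cc]).astype(float)
    corners = np.concatenate(
        [pts + off for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    if rr.size > 2:
        try:
            corners = corners[ConvexHull(corners).vertices]
        except Exception:
            pass
    diff = corners[:, None, :] - corners[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length = float(np.sqrt(d2[i, j]))
    axis = corners[j] - corners[i]
    axis /= np.linalg.norm(axis)
    perp = np.array([-axis[1], axis[0]])
    proj = corners @ perp
    breadth = float(proj.max() - proj.min())
    return length, max(breadth, 1.0)


def elliptical_form_factor(mask: np.ndarray, definition: str = "moment") -> float:
    """Elongation (length/breadth) of a single connected region, >= ~1."""
    mask = _as_bool_mask(mask)
    if definition == "moment":
        major, minor, _, _ = _moment_axes(mask)
        return major / minor
    if definition == "feret":
        length, breadth = _feret_axes(mask)
        return length / breadth
    raise ValueError(f"unknown EFF definition {definition!r}")


def _touches_border(slc: tuple[slice, slice], shape: tuple[int, int]) -> bool:
    return (
        slc[0].start == 0
        or slc[1].start == 0
        or slc[0].stop == shape[0]
        or slc[1].stop == shape[1]
    )


def measure_cells(
    labels: np.ndarray,
    *,
    eff_definition: str = "moment",
    perimeter_method: str = "subpixel",
    exclude_border: bool = True,
) -> list[RegionMorphometry]:
    """Morphometry of every labeled cell, ordered by label.

    Labels touching the image border are skipped by default: truncated shapes
    bias both area and perimeter.  An empty mask yields an empty list.
    """
    labels = np.asarray(labels)
    out: list[RegionMorphometry] = []
    for region in measure.regionprops(labels):
        if exclude_border and _touches_border(region.slice, labels.shape):
            continue
        mask = region.image
        area = int(region.area)
        perim = _perimeter(mask, perimeter_method)
        sf = 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan
        major, minor, orientation, degenerate = _moment_axes(mask)
        if eff_definition == "moment":
            eff = major / minor
        else:
            length, breadth = _feret_axes(mask)
            eff = length / breadth
        out.append(
            RegionMorphometry(
                cell_id=int(region.label),
                area=float(area),
                perimeter=float(perim),
                shape_factor=float(sf),
                elliptical_form_factor=float(eff),
                major_axis=float(major),
                minor_axis=float(minor),
                orientation=float(orientation),
                eff_definition=eff_definition,
                perimeter_definition=perimeter_method,
                degenerate=degenerate,
                shape_factor_gt1=bool(sf > 1.0),
            )
        )
    return out
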
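"""Per-nucleus shape descriptors, the megakaryocyte filter, and cell density.

Megakaryocytes are identified purely geometrically: their nuclei are
large and lobulated, so among detected nuclei they stand out by high
ellipse-equivalent eccentricity and a large maximum caliper (Feret)
diameter.  The filter thresholds default to eccentricity > 0.8 and
caliper > 20 µm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = [
    "NucleusShape",
    "shape_descriptors",
    "filter_megakaryocytes",
    "cell_density",
    "max_caliper_px",
]


@dataclass(frozen=True)
class NucleusShape:
    """Morphometry record for one nucleus.

    ``circularity`` is 4π·area/perimeter² (1 for a disc); ``eccentricity``
    is the ellipse-equivalent definition √(1−(b/a)²) computed from central
    second moments (0 for a disc, → 1 for a line); ``max_caliper_um`` is
    the maximum Feret diameter.
    """

    area_um2: float
    perimeter_um: float
    circularity: float
    eccentricity: float
    max_caliper_um: float
    label: int = 0


def _boundary_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner coordinates (row, col) of all foreground pixel squares.

    Using pixel *corners* rather than centers makes the caliper of an
    n-pixel line n·px (not (n−1)·px), matching the physical extent of the
    rasterised region.
    """
    rr, cc = np.nonzero(mask)
    pts = np.empty((rr.size * 4, 2), dtype=float)
    k = 0
    for dr, dc in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)):
        pts[k : k + rr.size, 0] = rr + dr
        pts[k : k + rr.size, 1] = cc + dc
        k += rr.size
    return pts


def max_caliper_px(mask: np.ndarray) -> float:
    """Maximum Feret diameter of a binary region, in pixels.

    Computed as the maximum pairwise distance between convex-hull
    vertices of the pixel-corner point set (equal to the all-pairs
    maximum over every boundary point, by convexity).
    """
    pts = _boundary_corner_points(mask)
    if pts.shape[0] == 0:
        raise ValueError("empty region")
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # degenerate (collinear) point sets
        verts = pts
    diff = verts[:, None, :] - verts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def shape_descriptors(
    mask: np.ndarray, pixel_size_um: float, label: int = 0
) -> NucleusShape:
    """Measure one nucleus region given its binary mask.

    Area is pixel count · pixel_size²; perimeter is the Crofton
    (projection-based) estimate, which is close to unbiased for smooth
    outlines — the estimator matters because circularity 4πA/P² is
    threshold-sensitive to it; eccentricity comes from the
    ellipse-equivalent central second moments.

    Raises ``ValueError`` for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty region")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = n_px * pixel_size_um**2
    perimeter = props.perimeter_crofton * pixel_size_um
    if perimeter > 0:
        # capped at 1: the perimeter estimate can undershoot on tiny
        # regions, and no physical region is rounder than a disc
        circularity = min(4.0 * np.pi * area / perimeter**2, 1.0)
    else:  # single pixel / degenerate dot
        circularity = 1.0
    eccentricity = float(props.eccentricity)
    caliper = max_caliper_px(mask) * pixel_size_um
    return NucleusShape(
        area_um2=float(area),
        perimeter_um=float(perimeter),
        circularity=float(circularity),
        eccentricity=eccentricity,
        max_caliper_um=caliper,
        label=label,
    )


def filter_megakaryocytes(
    shapes: Sequence[NucleusShape],
    ecc_min: float = 0.8,
    caliper_min_um: float = 20.0,
) -> list[NucleusShape]:
    """Keep shapes with eccentricity > ecc_min AND caliper > caliper_min_um.

    Order-preserving; idempotent (a filtered list filters to itself).
    """
    return [
        s
        for s in shapes
        if s.eccentricity > ecc_min and s.max_caliper_um > caliper_min_um
    ]


def cell_density(
    all_shapes: Sequence[NucleusShape], mk_shapes: Sequence[NucleusShape]
) -> float:
    """Megakaryocyte nuclear area over total nuclear area, in [0, 1].

    Raises ``ValueError`` when the total nuclear area is zero.
    """
    total = sum(s.area_um2 for s in all_shapes)
    if total <= 0:
        raise ValueError("total nuclear area is zero; cell density undefined")
    mk = sum(s.area_um2 for s in mk_shapes)
    return float(mk / total)
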
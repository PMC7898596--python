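"""Gap analysis: maximal inscribed circles in matrix-free space.

Gaps between fibres are characterised by iteratively fitting the largest
circle that fits entirely in the background of the fibre mask: the
Euclidean distance transform of the free space (fibres, previously placed
circles and — by default — the image border count as obstacles) is
maximised, a circle of that radius is placed at the maximum, added to the
obstacle set, and the process repeats while the circle diameter stays at or
above the user's minimum gap size.  The resulting list of circle sizes per
image lets downstream analysis look at the mean gap, the distribution
shape, or the tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["GapCircle", "max_inscribed_circles", "gap_statistics", "circles_to_rows"]


@dataclass(frozen=True)
class GapCircle:
    """One inscribed circle in matrix-free space."""

    centre: tuple[float, float]  # (row, col)
    radius_px: float

    @property
    def area_px2(self) -> float:
        return float(np.pi * self.radius_px**2)


def max_inscribed_circles(
    mask: np.ndarray,
    min_gap_diameter_px: float,
    border_is_obstacle: bool = True,
    max_circles: int = 10_000,
) -> list[GapCircle]:
    """Iteratively extract maximal inscribed circles from mask background.

    ``mask`` foreground (True) is fibre; circles are fitted into the
    background.  Returned in extraction order, radii non-increasing.  Ties
    in the distance transform break to the smallest (row, col), so output is
    deterministic.  An all-foreground mask yields an empty list.
    """
    if min_gap_diameter_px <= 0:
        raise ValueError("min_gap_diameter_px must be positive")
    obstacles = np.asarray(mask, dtype=bool).copy()
    h, w = obstacles.shape
    rr, cc = np.mgrid[0:h, 0:w]

    circles: list[GapCircle] = []
    while len(circles) < max_circles:
        free = ~obstacles
        if not free.any():
            break
        if border_is_obstacle:
            padded = np.pad(free, 1, constant_values=False)
            dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
        else:
            dist = ndi.distance_transform_edt(free)
        radius = float(dist.max())
        if 2.0 * radius < min_gap_diameter_px:
            break
        # np.argmax returns the first maximum in C order = smallest (row, col)
        r0, c0 = np.unravel_index(int(np.argmax(dist)), dist.shape)
        circles.append(GapCircle(centre=(float(r0), float(c0)), radius_px=radius))
        # conservative rasterisation keeps placed circles strictly non-overlapping
        obstacles |= (rr - r0) ** 2 + (cc - c0) ** 2 <= np.ceil(radius) ** 2
    return circles


def gap_statistics(circles: list[GapCircle]) -> dict[str, float]:
    """Summary of gap areas: count, mean/median/max, 5th/95th percentiles.

    An empty list gives count 0 and missing (nan) statistics.
    """
    n = len(circles)
    if n == 0:
        nan = float("nan")
        return {
            "gap_count": 0,
            "mean_gap_area": nan,
            "median_gap_area": nan,
            "max_gap_area": nan,
            "p5_gap_area": nan,
            "p95_gap_area": nan,
        }
    areas = np.array(sorted(c.area_px2 for c in circles))
    return {
        "gap_count": n,
        "mean_gap_area": float(areas.mean()),
        "median_gap_area": float(np.median(areas)),
        "max_gap_area": float(areas.max()),
        "p5_gap_area": float(np.percentile(areas, 5)),
        "p95_gap_area": float(np.percentile(areas, 95)),
    }


def circles_to_rows(circles: list[GapCircle]) -> list[dict]:
    """Rows for the per-image gap CSV (circle_id, row, col, radius, area)."""
    return [
        {
            "circle_id": i,
            "row": c.centre[0],
            "col": c.centre[1],
            "radius_px": c.radius_px,
            "area_px2": c.area_px2,
        }
        for i, c in enumerate(circles)
    ]
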
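"""Per-fibre metrics of a detected fibre network.

Counts of end points (E) and branch points (B), total fibre length (L), the
hyphal growth unit (HGU), average fibre length, fibre thickness, windowed
curvature, and the normalisations that remove the dependence of E, B and L
on image size:

* ``norm_endpoints``  = E / L   (end points per unit length — the inverse
  of the HGU)
* ``norm_branchpoints`` = B / L
* ``norm_length``     = L / image area, reported per 1000 px^2 so values
  have readable magnitudes (the scale is stated in the CSV header).

HGU is returned as L / E — fibre length per end point, the classical
hyphal-growth-unit convention, which makes the normalised end-point metric
literally its inverse.  Set ``hgu_convention="endpoints_per_length"`` for
the reciprocal.

Curvature is the mean absolute change in direction while stepping along
each fibre polyline in arc-length increments of the curvature window; small
windows sense fine waviness, large windows coarse bends.  By default every
chord pair is weighted equally (long fibres contribute more pairs); a
per-fibre mean is available via ``per_fibre=True``.

Missing values (e.g. HGU of a network with no end points) are ``nan``,
written as empty CSV cells — never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .ridge import JUNCTION_TOL, FibreNetwork

__all__ = [
    "MetricsRecord",
    "count_endpoints",
    "count_branchpoints",
    "total_length",
    "hgu",
    "avg_fibre_length",
    "fibre_thickness",
    "curvature",
    "curvature_sweep",
    "normalise_record",
    "network_record",
]

#: scale factor for norm_length (L per 1000 px^2 of image)
NORM_LENGTH_SCALE = 1000.0


@dataclass
class MetricsRecord:
    """One row of the summary table for one image."""

    image_id: str = ""
    endpoints: int = 0
    branchpoints: int = 0
    total_length: float = 0.0
    hgu: float = np.nan
    avg_fibre_length: float = np.nan
    fibre_thickness: float = np.nan
    curvature_by_window: dict = field(default_factory=dict)
    alignment: float = np.nan
    hdm: float = np.nan
    fractal_dim: float = np.nan
    lacunarity: float = np.nan
    norm_endpoints: float = np.nan
    norm_branchpoints: float = np.nan
    norm_length: float = np.nan
    #: gap-analysis summary (gap_count, mean_gap_area, ...) when enabled
    gap_stats: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {}
        for f in fields(self):
            if f.name in ("curvature_by_window", "gap_stats"):
                continue
            row[f.name] = getattr(self, f.name)
        for w in sorted(self.curvature_by_window):
            row[f"curvature_w{w}"] = self.curvature_by_window[w]
        row.update(self.gap_stats)
        return row


def _termini(net: FibreNetwork) -> np.ndarray:
    """All open-fibre termini (closed loops contribute none)."""
    pts = [v for f in net.fibres if not f.is_closed for v in (f.vertices[0], f.vertices[-1])]
    return np.array(pts).reshape(-1, 2)


def count_endpoints(net: FibreNetwork) -> int:
    """Fibre termini not coincident (within 1.5 px) with any junction."""
    pts = _termini(net)
    if len(pts) == 0:
        return 0
    if len(net.junctions) == 0:
        return len(pts)
    d = np.linalg.norm(pts[:, None, :] - net.junctions[None, :, :], axis=2)
    return int((d.min(axis=1) > JUNCTION_TOL).sum())


def count_branchpoints(net: FibreNetwork) -> int:
    """Number of distinct intersection loci (a 4-way crossing counts once)."""
    return len(net.junctions)


def total_length(net: FibreNetwork) -> float:
    """Sum of all fibre polyline lengths, in um if calibrated else px."""
    length = net.total_length_px()
    if net.pixel_size_um is not None:
        length *= net.pixel_size_um
    return length


def hgu(endpoints: int, length: float, convention: str = "length_per_endpoint") -> float:
    """Hyphal growth unit.

    Default convention: L / E, fibre length per end point (so that the
    normalised end-point metric E / L is its inverse).  With
    ``convention="endpoints_per_length"`` returns E / L instead.  Undefined
    (nan) when the needed denominator is zero.
    """
    if convention == "length_per_endpoint":
        return length / endpoints if endpoints > 0 else float("nan")
    if convention == "endpoints_per_length":
        return endpoints / length if length > 0 else float("nan")
    raise ValueError(f"unknown HGU convention {convention!r}")


def avg_fibre_length(length: float, endpoints: int, branchpoints: int) -> float:
    """L / (0.5 (E + B)): each branch is assumed to start one fibre."""
    denom = 0.5 * (endpoints + branchpoints)
    return length / denom if denom > 0 else float("nan")


def fibre_thickness(hdm_area: float, length: float) -> float:
    """Matrix area (HDM fraction x image area) divided by fibre length."""
    return hdm_area / length if length > 0 else float("nan")


def _resample_arclength(vertices: np.ndarray, step: float) -> np.ndarray:
    """Points along the polyline at arc-length intervals of ``step``."""
    d = np.hypot(*np.diff(vertices, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] < step:
        return vertices[:1]
    targets = np.arange(0.0, s[-1] + 1e-9, step)
    out = np.empty((len(targets), 2))
    for k in range(2):
        out[:, k] = np.interp(targets, s, vertices[:, k])
    return out


def _turning_angles(points: np.ndarray) -> np.ndarray:
    """Absolute turning angle (degrees) between consecutive chords."""
    chords = np.diff(points, axis=0)
    norms = np.hypot(chords[:, 0], chords[:, 1])
    ok = norms > 1e-12
    chords, norms = chords[ok], norms[ok]
    if len(chords) < 2:
        return np.empty(0)
    u = chords / norms[:, None]
    dots = np.clip((u[:-1] * u[1:]).sum(axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def curvature(net: FibreNetwork, window_px: int, per_fibre: bool = False) -> float:
    """Mean absolute turning angle (degrees) at one curvature window.

    Each fibre is resampled at arc-length steps of ``window_px``; fibres
    shorter than two windows contribute nothing.  ``nan`` when no fibre is
    long enough.
    """
    if window_px < 2:
        raise ValueError("window_px must be >= 2")
    pooled: list[np.ndarray] = []
    for f in net.fibres:
        ang = _turning_angles(_resample_arclength(f.vertices, float(window_px)))
        if len(ang):
            pooled.append(ang)
    if not pooled:
        return float("nan")
    if per_fibre:
        return float(np.mean([a.mean() for a in pooled]))
    return float(np.concatenate(pooled).mean())


def curvature_sweep(
    net: FibreNetwork, window_min: int, window_max: int, step: int = 10
) -> dict[int, float]:
    """Curvature at each window in [window_min, window_max] (inclusive)."""
    if window_min > window_max:
        raise ValueError("window_min must not exceed window_max")
    if step < 1:
        raise ValueError("step must be >= 1")
    windows = list(range(window_min, window_max + 1, step))
    if windows[-1] != window_max:
        windows.append(window_max)
    return {w: curvature(net, w) for w in windows}


def normalise_record(rec: MetricsRecord, image_area_px: float) -> MetricsRecord:
    """Fill the normalised metric fields from the raw ones (in place).

    With L = 0 the normalised fields stay missing (nan).
    """
    if rec.total_length > 0:
        rec.norm_endpoints = rec.endpoints / rec.total_length
        rec.norm_branchpoints = rec.branchpoints / rec.total_length
        rec.norm_length = rec.total_length / image_area_px * NORM_LENGTH_SCALE
    return rec


def network_record(
    net: FibreNetwork,
    image_id: str = "",
    hdm_fraction: float | None = None,
    curvature_windows: tuple[int, int, int] = (40, 40, 10),
) -> MetricsRecord:
    """Assemble the per-fibre metrics of one network into a record."""
    rec = MetricsRecord(image_id=image_id)
    rec.endpoints = count_endpoints(net)
    rec.branchpoints = count_branchpoints(net)
    rec.total_length = total_length(net)
    rec.hgu = hgu(rec.endpoints, rec.total_length)
    rec.avg_fibre_length = avg_fibre_length(rec.total_length, rec.endpoints, rec.branchpoints)
    wmin, wmax, wstep = curvature_windows
    rec.curvature_by_window = curvature_sweep(net, wmin, wmax, wstep)
    h, w = net.image_shape
    if hdm_fraction is not None:
        rec.hdm = hdm_fraction
        area = h * w * (net.pixel_size_um**2 if net.pixel_size_um else 1.0)
        rec.fibre_thickness = fibre_thickness(hdm_fraction * area, rec.total_length)
    normalise_record(rec, h * w)
    return rec
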
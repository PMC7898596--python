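"""Synthetic fibre scenes and pattern fixtures with known ground truth.

Every stage of the pipeline is testable without external data: this module
renders parameterised fibre fields (straight, sine-wave or arc fibres;
aligned with orientation jitter, or isotropic), analytic oracle patterns
(gratings, concentric rings, Sierpinski carpets, grids, annular gaps), a
self-similar cross hierarchy that emulates how higher-resolution imaging
reveals proportionally more fine structure, and the image degradations used
for robustness checks (Gaussian blur of 2-3 px radius, additive noise,
downsampling, under-exposure).

Fibres are rendered anti-aliased: each pixel is supersampled 4x4 and the
fibre coverage (distance to the centreline <= width/2) averaged, so the
stated width has a precise sub-pixel meaning for detector validation.  All
generators are seed-deterministic and return machine-checkable ground
truth (centreline polylines, orientations, end-point/branch-point counts,
total length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString
from shapely.strtree import STRtree

from .image import GrayImage

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "render_cross_hierarchy",
    "make_stripes",
    "make_rings",
    "make_sierpinski",
    "make_grid",
    "make_annulus_gap",
    "degrade",
    "centreline_recovery",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic fibre scene."""

    image_size_px: int = 256
    n_fibres: int = 10
    orientation_mode: str = "isotropic"  # "aligned" | "isotropic"
    mean_orientation_deg: float = 0.0
    jitter_deg: float = 5.0
    fibre_width_px: float = 4.0
    fibre_length_px: float | None = None  # default: 0.6 x image size
    waveform: str = "straight"  # "straight" | "sine" | "arc"
    amplitude_px: float = 8.0
    wavelength_px: float = 64.0
    radius_px: float = 100.0
    background_level: float = 10.0
    fibre_level: float = 200.0
    min_separation_px: float = 0.0  # rejection-sample fibres this far apart
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px < 16:
            raise ValueError("image_size_px must be >= 16")
        if not 0 <= self.jitter_deg <= 180:
            raise ValueError("jitter_deg must lie in [0, 180]")
        if self.fibre_width_px <= 0:
            raise ValueError("fibre_width_px must be positive")
        if self.orientation_mode not in ("aligned", "isotropic"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")
        if self.waveform not in ("straight", "sine", "arc"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    @property
    def length(self) -> float:
        return self.fibre_length_px if self.fibre_length_px else 0.6 * self.image_size_px


@dataclass
class GroundTruth:
    """Machine-checkable truth of a rendered scene."""

    polylines: list = field(default_factory=list)  # (n, 2) row/col arrays
    orientations_deg: list = field(default_factory=list)
    widths_px: list = field(default_factory=list)
    crossings: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def total_length(self) -> float:
        return float(
            sum(np.hypot(*np.diff(p, axis=0).T).sum() for p in self.polylines)
        )

    @property
    def endpoints(self) -> int:
        return 2 * len(self.polylines)

    @property
    def branchpoints(self) -> int:
        return len(self.crossings)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _seg_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _render_polyline(canvas: np.ndarray, polyline: np.ndarray, width: float) -> None:
    """Accumulate 4x4-supersampled coverage of one fibre into the canvas."""
    h, w = canvas.shape
    half = width / 2.0
    pad = half + 2.0
    r0 = max(0, int(np.floor(polyline[:, 0].min() - pad)))
    r1 = min(h, int(np.ceil(polyline[:, 0].max() + pad)) + 1)
    c0 = max(0, int(np.floor(polyline[:, 1].min() - pad)))
    c1 = min(w, int(np.ceil(polyline[:, 1].max() + pad)) + 1)
    if r1 <= r0 or c1 <= c0:
        return
    sub = (np.arange(4) + 0.5) / 4.0 - 0.5
    rs = (np.arange(r0, r1)[:, None] + sub[None, :]).ravel()
    cs = (np.arange(c0, c1)[:, None] + sub[None, :]).ravel()
    dist = np.full((len(rs), len(cs)), np.inf)
    # per-segment distance on the segment's own patch only (polylines are
    # sampled at ~1 px, so patches are tiny and the total work is O(area))
    for a, b in zip(polyline[:-1], polyline[1:]):
        pr0 = np.searchsorted(rs, min(a[0], b[0]) - pad)
        pr1 = np.searchsorted(rs, max(a[0], b[0]) + pad)
        pc0 = np.searchsorted(cs, min(a[1], b[1]) - pad)
        pc1 = np.searchsorted(cs, max(a[1], b[1]) + pad)
        if pr1 <= pr0 or pc1 <= pc0:
            continue
        prr, pcc = np.meshgrid(rs[pr0:pr1], cs[pc0:pc1], indexing="ij")
        pts = np.column_stack([prr.ravel(), pcc.ravel()])
        d = _seg_distance(pts, a, b).reshape(pr1 - pr0, pc1 - pc0)
        np.minimum(dist[pr0:pr1, pc0:pc1], d, out=dist[pr0:pr1, pc0:pc1])
    inside = dist <= half
    cov = inside.reshape(r1 - r0, 4, c1 - c0, 4).mean(axis=(1, 3))
    np.maximum(canvas[r0:r1, c0:c1], cov, out=canvas[r0:r1, c0:c1])


def _fibre_path(spec: SceneSpec, centre: np.ndarray, theta: float) -> np.ndarray:
    """Centreline polyline of one fibre (row/col), sampled at ~1 px steps."""
    d = np.array([np.sin(theta), np.cos(theta)])  # along-fibre direction
    n = np.array([-d[1], d[0]])  # perpendicular
    length = spec.length
    if spec.waveform == "straight":
        t = np.linspace(-length / 2, length / 2, max(2, int(length) + 1))
        return centre + t[:, None] * d
    if spec.waveform == "sine":
        t = np.linspace(-length / 2, length / 2, max(2, 2 * int(length)))
        off = spec.amplitude_px * np.sin(2 * np.pi * t / spec.wavelength_px)
        return centre + t[:, None] * d + off[:, None] * n
    # arc: circular arc of the given radius subtending length/radius radians
    r = spec.radius_px
    phi = np.linspace(-length / (2 * r), length / (2 * r), max(2, 2 * int(length)))
    arc_centre = centre + r * n
    return arc_centre - r * (np.cos(phi)[:, None] * n) + r * (np.sin(phi)[:, None] * d)


def _clip_polyline(poly: np.ndarray, size: int) -> np.ndarray:
    """Keep the longest in-bounds run of the polyline (truth stays honest)."""
    ok = (
        (poly[:, 0] >= 1)
        & (poly[:, 0] <= size - 2)
        & (poly[:, 1] >= 1)
        & (poly[:, 1] <= size - 2)
    )
    if ok.all():
        return poly
    best = (0, 0)
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return poly[best[0] : best[1]]


def _count_crossings(polylines: list[np.ndarray], merge_px: float = 2.0) -> np.ndarray:
    """Distinct pairwise intersection loci of the centrelines."""
    lines = [LineString(np.asarray(p)[:, ::-1]) for p in polylines]  # (x, y)
    pts: list[tuple[float, float]] = []
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            inter = lines[i].intersection(lines[j])
            if inter.is_empty:
                continue
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if g.geom_type == "Point":
                    pts.append((g.y, g.x))  # back to (row, col)
                else:  # overlapping collinear stretch: use its midpoint
                    mid = g.centroid
                    pts.append((mid.y, mid.x))
    if not pts:
        return np.empty((0, 2))
    # merge loci closer than merge_px (a multi-line crossing is one locus)
    merged: list[np.ndarray] = []
    for p in map(np.asarray, pts):
        for q in merged:
            if np.linalg.norm(p - q) <= merge_px:
                break
        else:
            merged.append(p)
    return np.array(merged)


def render_scene(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Render a fibre scene and return the image plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size_px
    truth = GroundTruth()
    canvas = np.zeros((size, size))

    margin = min(size / 2 - 2, spec.length / 2 * 0.75 + spec.fibre_width_px)
    dense_pts: list[np.ndarray] = []
    tree: cKDTree | None = None
    attempts = 0
    while len(truth.polylines) < spec.n_fibres and attempts < 200 * max(spec.n_fibres, 1):
        attempts += 1
        centre = rng.uniform(margin, size - margin, size=2)
        if spec.orientation_mode == "aligned":
            theta_deg = spec.mean_orientation_deg + rng.normal(0.0, spec.jitter_deg)
        else:
            theta_deg = rng.uniform(0.0, 180.0)
        poly = _clip_polyline(_fibre_path(spec, centre, np.radians(theta_deg)), size)
        if len(poly) < 2 or np.hypot(*np.diff(poly, axis=0).T).sum() < 4 * spec.fibre_width_px:
            continue
        if spec.min_separation_px > 0 and tree is not None:
            if tree.query(poly)[0].min() < spec.min_separation_px:
                continue
        truth.polylines.append(poly)
        truth.orientations_deg.append(float(theta_deg % 180.0))
        truth.widths_px.append(spec.fibre_width_px)
        if spec.min_separation_px > 0:
            dense_pts.append(poly)
            tree = cKDTree(np.vstack(dense_pts))

    for poly in truth.polylines:
        _render_polyline(canvas, poly, spec.fibre_width_px)
    truth.crossings = _count_crossings(truth.polylines)
    pixels = spec.background_level + (spec.fibre_level - spec.background_level) * canvas
    return GrayImage(np.clip(pixels, 0, 255)), truth


# ---------------------------------------------------------------------------
# Self-similar cross hierarchy (resolution-dependent complexity)
# ---------------------------------------------------------------------------

def render_cross_hierarchy(
    size_px: int,
    ref_size_px: int = 2048,
    levels: int = 4,
    length_frac: float = 0.3,
    coarse_width_ref_px: float = 4.0,
    fine_width_ref_px: float = 2.0,
    background_level: float = 10.0,
    fibre_level: float = 200.0,
    seed: int = 0,
) -> tuple[GrayImage, GroundTruth]:
    """Render a self-similar field of crossing fibre pairs ("X" units).

    Level k holds 4^k units; each unit is two fibres of physical length
    length_frac/2^k (in units of the field of view) crossing near 90 deg,
    so one branch point and four end points per unit.  The finest level is
    rendered at half the width of the others, putting it below the
    detector's resolvable width when the field is imaged at half of
    ``ref_size_px``.  This emulates how real matrix images reveal
    proportionally more fine structure (and hence more end points, branch
    points and length) at higher pixel counts, while the length-normalised
    metrics stay stable.

    Widths and unit gaps are specified at ``ref_size_px`` and scale with
    the rendered size.  Ground truth covers all rendered fibres; per-level
    unit counts are deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    scale = size_px / ref_size_px
    gap_px = 16.0 * scale
    truth = GroundTruth()
    segments: list[LineString] = []

    for k in range(levels):
        n_units = 4**k
        length = length_frac * size_px / 2**k
        width = (fine_width_ref_px if k == levels - 1 else coarse_width_ref_px) * scale
        placed = 0
        attempts = 0
        while placed < n_units and attempts < 500 * n_units:
            attempts += 1
            margin = length / 2 * 1.05 + 4
            if margin >= size_px / 2:
                break
            centre = rng.uniform(margin, size_px - margin, size=2)
            t1 = rng.uniform(0, np.pi)
            t2 = t1 + np.pi / 2 + rng.uniform(-np.pi / 12, np.pi / 12)
            unit = []
            for theta in (t1, t2):
                d = np.array([np.sin(theta), np.cos(theta)])
                unit.append(np.vstack([centre - d * length / 2, centre + d * length / 2]))
            cand = [LineString(seg[:, ::-1]) for seg in unit]
            if segments:
                tree = STRtree(segments)
                if any(
                    segments[int(i)].distance(c) < gap_px
                    for c in cand
                    for i in tree.query(c.buffer(gap_px))
                ):
                    continue
            for seg, ls in zip(unit, cand):
                truth.polylines.append(seg)
                truth.orientations_deg.append(float(np.degrees(np.arctan2(*np.diff(seg, axis=0)[0])) % 180.0))
                truth.widths_px.append(width)
                segments.append(ls)
            truth.crossings = np.vstack([truth.crossings, centre[None, :]])
            placed += 1

    canvas = np.zeros((size_px, size_px))
    for poly, width in zip(truth.polylines, truth.widths_px):
        _render_polyline(canvas, poly, width)
    pixels = background_level + (fibre_level - background_level) * canvas
    return GrayImage(np.clip(pixels, 0, 255)), truth


# ---------------------------------------------------------------------------
# Analytic oracle patterns
# ---------------------------------------------------------------------------

def make_stripes(size: int, period_px: float, orientation_deg: float = 0.0) -> GrayImage:
    """Sinusoidal grating whose stripes run along ``orientation_deg``.

    The gradient everywhere is perpendicular to the stripe direction, making
    this the analytic oracle for coherency = 1.
    """
    if period_px < 4:
        raise ValueError("period_px < 4 would alias on the pixel grid")
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    theta = np.radians(orientation_deg)
    phase = -rr * np.cos(theta) + cc * np.sin(theta)  # runs perpendicular to stripes
    pix = 127.5 + 127.5 * np.sin(2 * np.pi * phase / period_px)
    return GrayImage(pix)


def make_rings(size: int, period_px: float = 16.0) -> GrayImage:
    """Concentric rings: radially symmetric, all orientations equally present.

    The analytic oracle for coherency = 0.
    """
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    r = np.hypot(rr - (size - 1) / 2, cc - (size - 1) / 2)
    pix = 127.5 + 127.5 * np.sin(2 * np.pi * r / period_px)
    return GrayImage(pix)


def make_sierpinski(depth: int) -> np.ndarray:
    """Sierpinski carpet of side 3**depth (similarity dimension log8/log3)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    cell = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)
    mask = cell.copy()
    for _ in range(depth - 1):
        mask = np.kron(mask, cell)
    return mask


def make_grid(size: int, cell_px: int, line_width_px: int = 1) -> np.ndarray:
    """Regular square grid of fibres with the given cell side."""
    if cell_px < 2:
        raise ValueError("cell_px must be >= 2")
    mask = np.zeros((size, size), dtype=bool)
    for start in range(0, size, cell_px):
        mask[start : start + line_width_px, :] = True
        mask[:, start : start + line_width_px] = True
    return mask


def make_annulus_gap(
    size: int, hole_radius_px: float, centre: tuple[float, float] | None = None
) -> np.ndarray:
    """All-foreground mask with one circular background hole.

    A hole tangent to (or past) the border is simply truncated.  A
    non-positive radius gives a blank (all-foreground) hole-free mask.
    """
    mask = np.ones((size, size), dtype=bool)
    if hole_radius_px <= 0:
        return mask
    if centre is None:
        centre = ((size - 1) / 2, (size - 1) / 2)
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    mask[(rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= hole_radius_px**2] = False
    return mask


# ---------------------------------------------------------------------------
# Degradations
# ---------------------------------------------------------------------------

def degrade(
    img: GrayImage,
    mode: str,
    radius_px: float = 2.0,
    noise_sigma: float = 25.0,
    factor: int = 2,
    exposure_scale: float = 0.25,
    seed: int = 0,
) -> GrayImage:
    """Apply one acquisition degradation: blur, noise, downsample, underexpose.

    Blur uses a Gaussian of the given pixel radius (0 is the identity);
    noise is additive Gaussian with sigma 25 on the 8-bit scale,
    seed-deterministic; downsampling is block-averaging by an integer
    factor (refusing results below 64 px); under-exposure scales all
    intensities down.
    """
    from scipy import ndimage as ndi

    if mode == "blur":
        if radius_px == 0:
            return img.copy(note="blur radius 0 (identity)")
        return img.copy(
            pixels=ndi.gaussian_filter(img.pixels, radius_px, mode="nearest"),
            note=f"blur r={radius_px}",
        )
    if mode == "noise":
        rng = np.random.default_rng(seed)
        noisy = img.pixels + rng.normal(0.0, noise_sigma, img.shape)
        return img.copy(pixels=np.clip(noisy, 0, 255), note=f"noise s={noise_sigma}")
    if mode == "downsample":
        h, w = img.shape
        if h // factor < 64 or w // factor < 64:
            raise ValueError("downsampling below 64 px is not supported")
        h2, w2 = h - h % factor, w - w % factor
        blocks = img.pixels[:h2, :w2].reshape(h2 // factor, factor, w2 // factor, factor)
        out = GrayImage(
            blocks.mean(axis=(1, 3)),
            pixel_size_um=(img.pixel_size_um * factor if img.pixel_size_um else None),
            history=list(img.history) + [f"downsample x{factor}"],
        )
        return out
    if mode == "underexpose":
        return img.copy(pixels=img.pixels * exposure_scale, note=f"underexpose x{exposure_scale}")
    raise ValueError(f"unknown degradation mode {mode!r}")


# ---------------------------------------------------------------------------
# Detector validation helper
# ---------------------------------------------------------------------------

def centreline_recovery(
    truth_polylines: list[np.ndarray],
    detected_polylines: list[np.ndarray],
    tol_px: float = 1.5,
) -> tuple[float, float]:
    """Compare detected centrelines against ground truth.

    Samples the truth at 0.5 px arc-length steps and measures the distance
    from each sample to the nearest densely resampled detected point.
    Returns ``(recovered_fraction, rmse_px)``: the fraction of truth samples
    within ``tol_px`` of a detection, and the RMS distance over the
    recovered samples (nan if nothing recovered).
    """

    def dense(polys, step):
        pts = []
        for p in polys:
            d = np.hypot(*np.diff(p, axis=0).T)
            s = np.concatenate([[0.0], np.cumsum(d)])
            if s[-1] == 0:
                continue
            t = np.arange(0.0, s[-1] + step / 2, step)
            pts.append(np.column_stack([np.interp(t, s, p[:, k]) for k in range(2)]))
        return np.vstack(pts) if pts else np.empty((0, 2))

    truth_pts = dense(truth_polylines, 0.5)
    det_pts = dense(detected_polylines, 0.25)
    if len(truth_pts) == 0:
        return 1.0, 0.0
    if len(det_pts) == 0:
        return 0.0, float("nan")
    dist, _ = cKDTree(det_pts).query(truth_pts)
    recovered = dist <= tol_px
    frac = float(recovered.mean())
    rmse = float(np.sqrt((dist[recovered] ** 2).mean())) if recovered.any() else float("nan")
    return frac, rmse
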
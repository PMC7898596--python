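"""Curvilinear ridge detection: extraction of fibre centrelines.

Matrix fibres appear as ridges — curvilinear intensity maxima — and are
located by second-derivative (Hessian) analysis at a Gaussian scale matched
to the expected line width, in the manner of Steger's unbiased line
detector.  For each pixel the Hessian of the Gaussian-smoothed image is
eigen-decomposed; a ridge point requires a strongly negative second
directional derivative across the line and the subpixel extremum of the
intensity profile (a second-order Taylor step along the principal
eigenvector) to fall within the pixel.  Ridge points are thresholded by
hysteresis on the scale-normalised response, thinned to a one-pixel
skeleton, and traced into fibre polylines whose vertices carry the subpixel
positions; loci where three or more line branches meet are recorded as
junctions.

Multi-width detection runs the detector at line widths from the minimum to
the maximum in increments of five (the maximum always included) and
amalgamates the per-width rasterised masks by pixel-wise union, so that
both thin and thick fibres are represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as _bresenham
from skimage.morphology import closing, disk, remove_small_holes, skeletonize

__all__ = [
    "Fibre",
    "FibreNetwork",
    "RidgeParams",
    "sigma_from_width",
    "detect_lines",
    "prune_short_branches",
    "rasterize",
    "detect_multiscale",
]

#: a fibre terminus within this distance of a junction counts as attached
JUNCTION_TOL = 1.5

#: default hysteresis thresholds as fractions of the peak ridge response
HIGH_FRACTION = 0.25
LOW_FRACTION = 0.06

#: absolute floor on the scale-normalised ridge response (intensity units);
#: suppresses the tiny bias of discretised derivative kernels on flat areas
MIN_RESPONSE = 0.5

#: step between successive line widths in a sweep
WIDTH_INCREMENT = 5


@dataclass
class Fibre:
    """One fibre centreline: an ordered polyline of subpixel (row, col) points."""

    vertices: np.ndarray
    mean_width_px: float | None = None
    #: True when any vertex lies within ~3 sigma of the image border
    touches_border: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 2)
        if len(self.vertices) < 2:
            raise ValueError("a Fibre needs at least 2 vertices")

    @property
    def length_px(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def is_closed(self) -> bool:
        """Closed loop: the two termini coincide (within the junction tolerance).

        Degenerate 2-3 vertex stubs whose ends happen to sit close together
        are not loops.
        """
        return bool(
            len(self.vertices) >= 4
            and np.linalg.norm(self.vertices[0] - self.vertices[-1]) <= JUNCTION_TOL
        )


@dataclass
class FibreNetwork:
    """The detected fibre network for one image."""

    fibres: list[Fibre]
    junctions: np.ndarray  # (m, 2) branch loci, row/col
    image_shape: tuple[int, int]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.junctions = np.asarray(self.junctions, dtype=np.float64).reshape(-1, 2)

    @property
    def n_fibres(self) -> int:
        return len(self.fibres)

    def total_length_px(self) -> float:
        return float(sum(f.length_px for f in self.fibres))


@dataclass
class RidgeParams:
    """Detector parameters.

    ``contrast_high`` / ``contrast_low`` are absolute hysteresis thresholds
    on the scale-normalised ridge response (sigma^2 x |second directional
    derivative|, same units as image intensity).  When ``None`` they default
    to fixed fractions of the peak response of the image at hand, which
    adapts to overall contrast without user input.
    """

    line_width_min_px: float = 5.0
    line_width_max_px: float = 5.0
    contrast_high: float | None = None
    contrast_low: float | None = None
    min_branch_px: float = 10.0
    dark_lines: bool = False

    def __post_init__(self) -> None:
        if self.line_width_min_px <= 0 or self.line_width_max_px <= 0:
            raise ValueError("line widths must be positive")
        if self.line_width_min_px > self.line_width_max_px:
            raise ValueError("line_width_min_px must not exceed line_width_max_px")
        if (
            self.contrast_high is not None
            and self.contrast_low is not None
            and self.contrast_low > self.contrast_high
        ):
            raise ValueError("contrast_low must not exceed contrast_high")
        if self.min_branch_px < 0:
            raise ValueError("min_branch_px must be non-negative")

    def widths(self) -> list[float]:
        """Line widths of a sweep: min, min+5, ... with max force-included."""
        w = self.line_width_min_px
        out = []
        while w < self.line_width_max_px:
            out.append(w)
            w += WIDTH_INCREMENT
        out.append(self.line_width_max_px)
        return out


def sigma_from_width(line_width_px: float) -> float:
    """Gaussian derivative scale for a given line width.

    sigma = width / (2*sqrt(3)) + 0.5 — the scale at which the second
    derivative response of a bar profile of that width peaks at its centre,
    the convention of the classical ridge-detection plugin.
    """
    if line_width_px <= 0:
        raise ValueError("line_width_px must be positive")
    return line_width_px / (2.0 * np.sqrt(3.0)) + 0.5


def _ridge_field(pixels: np.ndarray, sigma: float):
    """Hessian ridge analysis of a (bright-line) image at one scale.

    Returns ``(response, candidate, offsets)``: the scale-normalised ridge
    response (>=0 everywhere, 0 where the across-line second derivative is
    non-negative), the boolean ridge-point condition (subpixel extremum
    inside the pixel), and the (H, W, 2) subpixel offset of the line centre
    from each pixel centre.
    """

    def g(order):
        return ndi.gaussian_filter(pixels, sigma, order=order, mode="nearest")

    fr, fc = g((1, 0)), g((0, 1))
    frr, frc, fcc = g((2, 0)), g((1, 1)), g((0, 2))

    # smaller (most negative) eigenvalue of [[frr, frc], [frc, fcc]]
    half_tr = 0.5 * (frr + fcc)
    root = np.sqrt(0.25 * (frr - fcc) ** 2 + frc**2)
    lam = half_tr - root
    lam2 = half_tr + root  # larger eigenvalue (along-line curvature)

    # eigenvector across the line, for lam; stable branch selection
    vr = np.where(np.abs(frc) > 1e-12, frc, np.where(frr <= fcc, 1.0, 0.0))
    vc = np.where(np.abs(frc) > 1e-12, lam - frr, np.where(frr <= fcc, 0.0, 1.0))
    norm = np.hypot(vr, vc)
    norm[norm == 0] = 1.0
    nr, nc = vr / norm, vc / norm

    # Taylor step along n to the profile extremum: t = -(grad . n) / lam
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(lam < 0, -(fr * nr + fc * nc) / np.where(lam < 0, lam, -1.0), 0.0)
    off_r, off_c = t * nr, t * nc
    # 0.6 (not 0.5) keeps lines at shallow angles connected where the
    # centreline passes exactly between two pixel rows/columns
    candidate = (lam < 0) & (np.abs(off_r) <= 0.6) & (np.abs(off_c) <= 0.6)

    response = np.where(lam < 0, -lam * sigma**2, 0.0)
    # where both eigenvalues are strongly negative the point is a 2-D
    # intensity maximum — the core of a line crossing, where the single-line
    # model breaks down; these pixels keep crossing arms connected
    blob = -lam2 * sigma**2
    # subpixel localisation is useful slightly beyond the classification
    # boundary: skeleton pixels one off the centreline still project onto it
    locate = (lam < 0) & (np.abs(off_r) <= 1.0) & (np.abs(off_c) <= 1.0)
    offsets = np.stack([np.where(locate, off_r, 0.0), np.where(locate, off_c, 0.0)], axis=-1)
    return response, candidate, offsets, blob


def _hysteresis(response: np.ndarray, candidate: np.ndarray, high: float, low: float) -> np.ndarray:
    """Keep candidate ridge points >= low that connect to a point >= high."""
    weak = candidate & (response >= low) & (response > 0)
    strong = weak & (response >= high)
    if not strong.any():
        return np.zeros_like(weak)
    labels, _ = ndi.label(weak, structure=np.ones((3, 3), dtype=int))
    keep = np.unique(labels[strong])
    return np.isin(labels, keep[keep > 0])


# ---------------------------------------------------------------------------
# Skeleton tracing
# ---------------------------------------------------------------------------

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_skeleton(skel: np.ndarray, offsets: np.ndarray):
    """Trace a 1-px skeleton into polylines and junction loci.

    Skeleton pixels with >= 3 skeleton neighbours are junction pixels;
    8-connected clusters of them form one junction each (a 4-way crossing is
    a single locus).  Maximal chains of non-junction pixels become fibres;
    a chain end adjacent to a junction cluster is extended to the cluster
    centroid so fibres meet their junctions.  Vertex positions are pixel
    centres plus the detector's subpixel offsets.
    """
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return [], np.empty((0, 2))

    pix = {(int(r), int(c)) for r, c in coords}
    nbrs = {
        p: [q for dr, dc in _NBRS if (q := (p[0] + dr, p[1] + dc)) in pix] for p in pix
    }

    jmask = np.zeros_like(skel)
    for p, ns in nbrs.items():
        if len(ns) >= 3:
            jmask[p] = True
    jlabels, njunc = ndi.label(jmask, structure=np.ones((3, 3), dtype=int))
    centroids = (
        np.array(ndi.center_of_mass(jmask, jlabels, range(1, njunc + 1)))
        if njunc
        else np.empty((0, 2))
    )

    def jlabel(p):
        return int(jlabels[p]) if jmask[p] else 0

    def subpix(p):
        return np.array([p[0] + offsets[p[0], p[1], 0], p[1] + offsets[p[0], p[1], 1]])

    def smooth(verts: np.ndarray) -> np.ndarray:
        # 3-point moving average damps the residual pixel-lattice zigzag of
        # skeleton paths; termini stay fixed so junction gluing is exact
        if len(verts) < 3:
            return verts
        out = verts.copy()
        out[1:-1] = (verts[:-2] + verts[1:-1] + verts[2:]) / 3.0
        return out

    chain_pix = sorted(p for p in pix if not jmask[p])
    cn = {p: [q for q in nbrs[p] if not jmask[q]] for p in chain_pix}
    visited: set = set()
    fibres: list[Fibre] = []

    def build(path):
        """Turn a pixel chain into a Fibre, gluing junction centroids on."""
        verts = [subpix(p) for p in path]
        jl0 = next((jlabel(q) for q in nbrs[path[0]] if jmask[q]), 0)
        jl1 = next((jlabel(q) for q in reversed(nbrs[path[-1]]) if jmask[q]), 0)
        if jl0:
            verts.insert(0, centroids[jl0 - 1])
        if jl1:
            verts.append(centroids[jl1 - 1])
        if len(verts) >= 2:
            fibres.append(Fibre(smooth(np.array(verts))))

    def walk(start, first):
        path = [start, first]
        visited.add(first)
        while True:
            nxt = [q for q in cn[path[-1]] if q != path[-2]]
            if len(nxt) != 1 or nxt[0] in visited:
                break
            path.append(nxt[0])
            visited.add(nxt[0])
        return path

    # open chains: start from chain ends (0 or 1 chain-neighbours, or
    # adjacent to a junction with 2 chain-neighbours where chain passes by)
    for p in chain_pix:
        if p in visited or len(cn[p]) > 1:
            continue
        visited.add(p)
        if len(cn[p]) == 0:
            # single-pixel chain between junctions / isolated pixel
            jls = sorted({jlabel(q) for q in nbrs[p] if jmask[q]})
            if jls:
                verts = [centroids[jls[0] - 1], subpix(p)]
                if len(jls) > 1:
                    verts.append(centroids[jls[-1] - 1])
                if len(jls) > 1 or len(verts) >= 2:
                    fibres.append(Fibre(np.array(verts)))
            continue
        build(walk(p, cn[p][0]))

    # remaining pixels with exactly 2 chain-neighbours form pure cycles
    for p in chain_pix:
        if p in visited:
            continue
        visited.add(p)
        path = walk(p, cn[p][0])
        path.append(p)  # close the loop
        verts = [subpix(q) for q in path]
        if len(verts) >= 3:
            fibres.append(Fibre(smooth(np.array(verts))))

    return fibres, centroids


def detect_lines(
    img, params: RidgeParams | None = None, width_px: float | None = None
) -> FibreNetwork:
    """Detect fibre centrelines at a single line width.

    ``img`` must be polarity-normalised (bright fibres).  Returns the linked
    fibre network; an image with no ridge points yields an empty network.
    """
    from .image import GrayImage  # local to avoid cycle at import time

    if not isinstance(img, GrayImage):
        img = GrayImage(img)
    params = params or RidgeParams()
    width = float(width_px if width_px is not None else params.line_width_min_px)
    if width <= 0:
        raise ValueError("line width must be positive")
    if width > min(img.shape) / 4:
        raise ValueError(
            f"line width {width} too large for image {img.shape} (limit min(dims)/4)"
        )
    sigma = sigma_from_width(width)
    if min(img.shape) < 4 * sigma:
        raise ValueError(f"image {img.shape} smaller than 4 sigma ({4 * sigma:.1f} px)")

    response, candidate, offsets, blob = _ridge_field(img.pixels, sigma)
    candidate &= response >= MIN_RESPONSE
    peak = float(response[candidate].max()) if candidate.any() else 0.0
    if peak <= 0:
        return FibreNetwork([], np.empty((0, 2)), img.shape, img.pixel_size_um)
    high = params.contrast_high if params.contrast_high is not None else HIGH_FRACTION * peak
    low = params.contrast_low if params.contrast_low is not None else LOW_FRACTION * peak

    mask = _hysteresis(response, candidate, high, low)
    if not mask.any():
        return FibreNetwork([], np.empty((0, 2)), img.shape, img.pixel_size_um)
    # bridge crossing cores, where the single-line model breaks down:
    # 2-D maxima next to accepted line points, plus a closing at the
    # detection scale that reconnects arm tips across the core plateau
    bridge = (blob >= min(low, MIN_RESPONSE)) & ndi.binary_dilation(
        mask, structure=np.ones((3, 3), dtype=bool), iterations=2
    )
    mask |= bridge
    mask = closing(mask, disk(max(1, round(sigma))))
    # pinholes in the ridge-point band would skeletonise into spurious
    # micro-loops; real matrix gaps are far larger than 16 px^2
    mask = remove_small_holes(mask, max_size=16)
    skel = skeletonize(mask)
    fibres, junctions = _trace_skeleton(skel, offsets)

    border = 3.0 * sigma
    h, w = img.shape
    for f in fibres:
        v = f.vertices
        f.touches_border = bool(
            (v[:, 0] < border).any()
            or (v[:, 1] < border).any()
            or (v[:, 0] > h - 1 - border).any()
            or (v[:, 1] > w - 1 - border).any()
        )
        f.mean_width_px = width
    return FibreNetwork(fibres, junctions, img.shape, img.pixel_size_um)


# ---------------------------------------------------------------------------
# Branch pruning
# ---------------------------------------------------------------------------

def _attachments(net: FibreNetwork):
    """For each fibre end, the index of the junction it attaches to (or -1)."""
    att = np.full((len(net.fibres), 2), -1, dtype=int)
    if len(net.junctions) == 0:
        return att
    for i, f in enumerate(net.fibres):
        for e, v in ((0, f.vertices[0]), (1, f.vertices[-1])):
            d = np.linalg.norm(net.junctions - v, axis=1)
            j = int(np.argmin(d))
            if d[j] <= JUNCTION_TOL:
                att[i, e] = j
    return att


def prune_short_branches(net: FibreNetwork, min_branch_px: float) -> FibreNetwork:
    """Remove terminal twigs shorter than ``min_branch_px``.

    A fibre is a prunable twig when at least one end is free (not attached
    to a junction) and its length is below the minimum.  After removal,
    junctions left with two attached fibre ends are dissolved by merging the
    two fibres into one through-fibre; junctions with fewer attachments are
    dropped.  Repeats until stable.
    """
    if min_branch_px <= 0 or not net.fibres:
        return net
    fibres = list(net.fibres)
    junctions = list(np.asarray(net.junctions, dtype=float).reshape(-1, 2))

    def current():
        return FibreNetwork(
            fibres, np.array(junctions).reshape(-1, 2), net.image_shape, net.pixel_size_um
        )

    while True:
        att = _attachments(current())

        # 1) drop free-ended twigs below the minimum length
        # twig: a free end, or a degenerate self-loop on a single junction
        def _twig(i: int, f: Fibre) -> bool:
            if f.is_closed or f.length_px >= min_branch_px:
                return False
            return att[i, 0] < 0 or att[i, 1] < 0 or att[i, 0] == att[i, 1]

        keep = [i for i, f in enumerate(fibres) if not _twig(i, f)]
        removed_twig = len(keep) < len(fibres)
        fibres = [fibres[i] for i in keep]
        att = att[keep]

        # 2) junction bookkeeping: degree = number of attached fibre ends
        ends_at: dict[int, list[tuple[int, int]]] = {j: [] for j in range(len(junctions))}
        for i in range(len(fibres)):
            for e in (0, 1):
                if att[i, e] >= 0:
                    ends_at[att[i, e]].append((i, e))

        merge = next(
            (
                (j, ends)
                for j, ends in ends_at.items()
                if len(ends) == 2 and ends[0][0] != ends[1][0]
            ),
            None,
        )
        drop = [j for j, ends in ends_at.items() if len(ends) <= 1]

        if merge is not None:
            # dissolve a degree-2 junction: glue the two fibres through it
            j, ((i1, e1), (i2, e2)) = merge
            f1, f2 = fibres[i1], fibres[i2]
            v1 = f1.vertices if e1 == 1 else f1.vertices[::-1]
            v2 = f2.vertices if e2 == 0 else f2.vertices[::-1]
            parts = [v1, v2[1:]] if np.allclose(v1[-1], v2[0]) else [v1, v2]
            glued = Fibre(
                np.vstack(parts),
                mean_width_px=f1.mean_width_px,
                touches_border=f1.touches_border or f2.touches_border,
            )
            fibres = [f for i, f in enumerate(fibres) if i not in (i1, i2)] + [glued]
            junctions = [v for k, v in enumerate(junctions) if k != j]
            continue
        if drop:
            junctions = [v for k, v in enumerate(junctions) if k not in set(drop)]
            continue
        if not removed_twig:
            break

    return current()


def rasterize(net: FibreNetwork) -> np.ndarray:
    """Rasterise the network into a 1-px-wide 8-connected boolean mask."""
    mask = np.zeros(net.image_shape, dtype=bool)
    h, w = net.image_shape
    for f in net.fibres:
        v = np.rint(f.vertices).astype(int)
        v[:, 0] = np.clip(v[:, 0], 0, h - 1)
        v[:, 1] = np.clip(v[:, 1], 0, w - 1)
        for (r0, c0), (r1, c1) in zip(v[:-1], v[1:]):
            rr, cc = _bresenham(r0, c0, r1, c1)
            mask[rr, cc] = True
    return mask


def detect_multiscale(img, params: RidgeParams) -> tuple[np.ndarray, list[FibreNetwork]]:
    """Run the detector at each line width of the sweep and amalgamate.

    Returns the pixel-wise union of the per-width rasterised masks and the
    list of per-width networks (pruned at ``params.min_branch_px``), in
    width order.  Per-fibre metrics should be computed on a single chosen
    width's network; the amalgamated mask serves the global pattern metrics.
    """
    networks = []
    masks = []
    for wpx in params.widths():
        net = detect_lines(img, params, width_px=wpx)
        net = prune_short_branches(net, params.min_branch_px)
        networks.append(net)
        masks.append(rasterize(net))
    amalgam = np.logical_or.reduce(masks) if masks else np.zeros(img.shape, dtype=bool)
    return amalgam, networks
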
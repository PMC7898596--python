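"""Global pattern descriptors: alignment coherency, box-counting fractal
dimension and gliding-box lacunarity.

Alignment is the normalised eigenvalue anisotropy of the gradient structure
tensor

    J = [[<fx,fx>_w, <fx,fy>_w],
         [<fx,fy>_w, <fy,fy>_w]],    a = (lmax - lmin) / (lmax + lmin),

where fx, fy are Gaussian-derivative partials of the image and w a
normalised weighting window (uniform over the full field of view by
default, Gaussian optionally).  a = 0 means a fully isotropic orientation
distribution, a = 1 a single dominant orientation.

Fractal dimension is the box-counting dimension: the least-squares slope of
log N(eps) against log(1/eps), where N(eps) counts grid boxes of side eps
occupied by foreground.  It lies in [1, 2] for fibre masks of a single 2-D
slice.

Lacunarity quantifies gappiness from the per-box mass moments,
Lambda = |s^2/mu^2 - 1| averaged over box sizes (the gliding-box scheme:
overlapping windows at stride half the box size).  Note this printed form
assigns 1 to a perfectly uniform pattern and 0 when s = mu, inverting the
conventional gliding-box ordering (1 + s^2/mu^2) at the low end; the
conventional variant is available via ``convention="plus_one"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .image import GrayImage

__all__ = [
    "StructureTensor",
    "structure_tensor",
    "coherency",
    "alignment_from_image",
    "fractal_dimension",
    "lacunarity",
]


@dataclass(frozen=True)
class StructureTensor:
    """Weighted gradient inner products; x = column axis, y = row axis."""

    jxx: float
    jxy: float
    jyy: float

    def eigenvalues(self) -> tuple[float, float]:
        half_tr = 0.5 * (self.jxx + self.jyy)
        root = float(np.hypot(0.5 * (self.jxx - self.jyy), self.jxy))
        return half_tr + root, half_tr - root  # (lmax, lmin)


def structure_tensor(
    img: GrayImage | np.ndarray,
    gradient_sigma: float = 1.0,
    weight: np.ndarray | str | None = None,
) -> StructureTensor:
    """Global gradient structure tensor of an image.

    ``weight`` is ``None`` for a uniform window over the whole field of
    view, ``"gaussian"`` for a Gaussian window centred on the image (sigma =
    a quarter of the smaller dimension), or an explicit array of the image
    shape.  The window is normalised to sum to 1.
    """
    pix = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    if min(pix.shape) < 4 * gradient_sigma:
        raise ValueError(
            f"image {pix.shape} smaller than 4 x gradient_sigma ({gradient_sigma})"
        )
    fy = ndi.gaussian_filter(pix, gradient_sigma, order=(1, 0), mode="nearest")
    fx = ndi.gaussian_filter(pix, gradient_sigma, order=(0, 1), mode="nearest")

    if weight is None:
        w = np.full(pix.shape, 1.0 / pix.size)
    elif isinstance(weight, str):
        if weight != "gaussian":
            raise ValueError(f"unknown weight spec {weight!r}")
        rr, cc = np.mgrid[0 : pix.shape[0], 0 : pix.shape[1]].astype(float)
        s = min(pix.shape) / 4.0
        w = np.exp(-(((rr - (pix.shape[0] - 1) / 2) ** 2 + (cc - (pix.shape[1] - 1) / 2) ** 2) / (2 * s**2)))
        w /= w.sum()
    else:
        w = np.asarray(weight, dtype=float)
        if w.shape != pix.shape:
            raise ValueError("weight window must match the image shape")
        w = w / w.sum()

    return StructureTensor(
        jxx=float((w * fx * fx).sum()),
        jxy=float((w * fx * fy).sum()),
        jyy=float((w * fy * fy).sum()),
    )


def coherency(tensor: StructureTensor) -> float:
    """(lmax - lmin) / (lmax + lmin) in [0, 1]; 0 for a blank image."""
    lmax, lmin = tensor.eigenvalues()
    total = lmax + lmin
    if total <= 0:
        return 0.0
    return float(np.clip((lmax - lmin) / total, 0.0, 1.0))


def alignment_from_image(img: GrayImage | np.ndarray, gradient_sigma: float = 1.0) -> float:
    """Global alignment score: coherency of the uniformly weighted tensor."""
    return coherency(structure_tensor(img, gradient_sigma=gradient_sigma))


# ---------------------------------------------------------------------------
# Box counting
# ---------------------------------------------------------------------------

def _dyadic_sizes(shape: tuple[int, int]) -> list[int]:
    sizes, eps = [], 2
    while eps <= min(shape) // 4:
        sizes.append(eps)
        eps *= 2
    return sizes


def _box_counts(mask: np.ndarray, eps: int) -> int:
    """Occupied boxes of side eps on a grid anchored at the origin."""
    h, w = mask.shape
    ph, pw = -h % eps, -w % eps
    padded = np.pad(mask, ((0, ph), (0, pw)))
    blocks = padded.reshape(padded.shape[0] // eps, eps, padded.shape[1] // eps, eps)
    return int(blocks.any(axis=(1, 3)).sum())


def fractal_dimension(mask: np.ndarray, box_sizes: list[int] | None = None) -> float:
    """Box-counting dimension of a binary mask.

    The counting grid is anchored at the corner of the foreground bounding
    box (making the value exactly translation-invariant); occupied boxes
    are counted at dyadic sides eps in {2, 4, ..., extent/4}, where extent
    is the larger bounding-box dimension, and the least-squares slope of
    log N(eps) vs log(1/eps) is returned.  ``nan`` for an empty mask or a
    pattern too small to span two scales.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    mask = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    if box_sizes is None:
        extent, box_sizes, eps = max(mask.shape), [], 2
        while eps <= extent // 4:
            box_sizes.append(eps)
            eps *= 2
    if len(box_sizes) < 2:
        return float("nan")
    counts = np.array([_box_counts(mask, s) for s in box_sizes], dtype=float)
    slope = np.polyfit(np.log(1.0 / np.asarray(box_sizes, dtype=float)), np.log(counts), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Lacunarity
# ---------------------------------------------------------------------------

def _gliding_masses(values: np.ndarray, size: int, stride: int) -> np.ndarray:
    """Sums of ``values`` over size x size windows at the given stride."""
    integ = np.zeros((values.shape[0] + 1, values.shape[1] + 1))
    integ[1:, 1:] = values.cumsum(0).cumsum(1)
    r = np.arange(0, values.shape[0] - size + 1, stride)
    c = np.arange(0, values.shape[1] - size + 1, stride)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return (
        integ[rr + size, cc + size]
        - integ[rr, cc + size]
        - integ[rr + size, cc]
        + integ[rr, cc]
    ).ravel()


def lacunarity(
    mask: np.ndarray,
    box_sizes: list[int] | None = None,
    convention: str = "abs_minus_one",
) -> float:
    """Gliding-box lacunarity, averaged over box sizes.

    For each box size, a square window slides at stride size/2 and the
    enclosed foreground mass is recorded; Lambda(size) = |s^2/mu^2 - 1| from
    the per-box masses (population s), and the mean over sizes is returned.
    ``convention="plus_one"`` gives the conventional 1 + s^2/mu^2 instead.
    ``mask`` may be boolean (mass = pixel count) or grayscale.  ``nan`` when
    the mask is empty (mu = 0).
    """
    values = np.asarray(mask, dtype=float)
    if values.sum() <= 0:
        return float("nan")
    if box_sizes is None:
        box_sizes = [s for s in _dyadic_sizes(values.shape) if s >= 4] or [4]
    if max(box_sizes) >= min(values.shape):
        raise ValueError("box sizes must be smaller than the image")
    lams = []
    for size in box_sizes:
        masses = _gliding_masses(values, size, max(1, size // 2))
        mu = masses.mean()
        if mu == 0:
            continue
        ratio = masses.var() / mu**2
        if convention == "abs_minus_one":
            lams.append(abs(ratio - 1.0))
        elif convention == "plus_one":
            lams.append(1.0 + ratio)
        else:
            raise ValueError(f"unknown lacunarity convention {convention!r}")
    return float(np.mean(lams)) if lams else float("nan")
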
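"""Image preparation: grayscale conversion, polarity, contrast saturation,
high-density-matrix (HDM) thresholding and colour deconvolution.

The downstream detector assumes a canonical polarity — fibres bright on a
dark background — so histological images (dark fibres on light background)
are inverted first.  Contrast saturation follows the ImageJ "Enhance
Contrast" convention: a given percentage of pixels is clipped, half at each
histogram tail, and the remainder mapped affinely onto [0, 255].

HDM (high-density matrix) is the fraction of pixels at or above a threshold
on the polarity-normalised, contrast-saturated image: a direct measure of
matrix abundance independent of the fibre mask.

Colour deconvolution unmixes histochemical stains (e.g. Picrosirius red with
a haematoxylin counterstain) in optical-density space using the
Ruifrok–Johnston scheme; stain vectors can be estimated from user-chosen
regions of interest, one per stain/background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .image import GrayImage

__all__ = [
    "StainVectors",
    "to_grayscale",
    "normalise_polarity",
    "contrast_saturate",
    "compute_hdm",
    "estimate_stain_vectors",
    "colour_deconvolve",
    "od_transform",
    "od_to_intensity",
]

#: BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])

#: default HDM threshold on the post-saturation 8-bit scale (bright fibres)
DEFAULT_HDM_THRESHOLD = 185


@dataclass(frozen=True)
class StainVectors:
    """Three unit vectors in optical-density RGB space, one per stain."""

    matrix: np.ndarray
    counterstain: np.ndarray
    background: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """Rows = stains, columns = RGB OD components."""
        return np.vstack([self.matrix, self.counterstain, self.background])


def to_grayscale(rgb: np.ndarray, pixel_size_um: float | None = None) -> GrayImage:
    """Convert an RGB raster to a luminance-weighted :class:`GrayImage`.

    Single-channel input passes through (rescaled onto [0, 255] only if it
    exceeds the 8-bit range).
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr @ _LUMA
    else:
        raise ValueError(
            f"expected a 2-D grayscale or HxWx3 RGB raster, got shape {arr.shape}"
        )
    if gray.max() > 255:
        gray = gray * (255.0 / gray.max())
    return GrayImage(np.clip(gray, 0, 255), pixel_size_um=pixel_size_um)


def normalise_polarity(img: GrayImage, dark_lines: bool) -> GrayImage:
    """Return the image with fibres bright on dark (canonical polarity).

    ``dark_lines=True`` declares that fibres are dark on a light background
    (conventional histology); the intensities are then inverted, v -> 255-v.
    Fluorescence/SHG images (``dark_lines=False``) pass through unchanged.
    """
    if not dark_lines:
        return img
    return img.copy(pixels=255.0 - img.pixels, note="polarity-inverted")


def contrast_saturate(img: GrayImage, saturation_pct: float) -> GrayImage:
    """ImageJ-style "Enhance Contrast" linear stretch.

    ``saturation_pct`` of pixels are clipped, half at each histogram tail;
    the remaining range is mapped affinely onto [0, 255].  ``0`` gives a
    plain min–max stretch.  A constant image is returned unchanged with a
    warning, since the stretch is undefined.
    """
    if not 0 <= saturation_pct < 100:
        raise ValueError("saturation_pct must lie in [0, 100)")
    pix = img.pixels
    lo = float(np.percentile(pix, saturation_pct / 2.0))
    hi = float(np.percentile(pix, 100.0 - saturation_pct / 2.0))
    if hi <= lo:
        warnings.warn(
            "contrast_saturate: image is constant (or saturation leaves no "
            "dynamic range); returning it unchanged",
            stacklevel=2,
        )
        return img.copy(note="contrast-saturate: skipped (no dynamic range)")
    stretched = np.clip((pix - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return img.copy(
        pixels=stretched, note=f"contrast-saturate {saturation_pct}% [{lo:.3g},{hi:.3g}]"
    )


def compute_hdm(
    img: GrayImage, hdm_threshold: int | None = DEFAULT_HDM_THRESHOLD
) -> tuple[float, np.ndarray]:
    """High-density matrix: fraction of pixels at/above the threshold.

    Expects a polarity-normalised, contrast-saturated image.  Returns the
    HDM fraction in [0, 1] and the thresholded boolean raster (the
    "processed image thresholded for HDM" output).  ``hdm_threshold=None``
    selects Otsu's threshold automatically.
    """
    pix = img.pixels
    if hdm_threshold is None:
        try:
            hdm_threshold = float(threshold_otsu(pix))
        except ValueError:  # constant image
            hdm_threshold = DEFAULT_HDM_THRESHOLD
    mask = pix >= hdm_threshold
    return float(mask.mean()), mask


# ---------------------------------------------------------------------------
# Colour deconvolution (Ruifrok–Johnston)
# ---------------------------------------------------------------------------

def od_transform(intensity: np.ndarray) -> np.ndarray:
    """Optical density per channel: OD = -log10((I + 1) / 256).

    The +1 offset avoids log(0) at intensity 0; pure white (255) maps to
    OD exactly 0.
    """
    return -np.log10((np.asarray(intensity, dtype=np.float64) + 1.0) / 256.0)


def od_to_intensity(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`od_transform`."""
    return 256.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - 1.0


def estimate_stain_vectors(
    rgb: np.ndarray,
    rois: tuple[tuple[int, int, int, int], ...],
) -> StainVectors:
    """Estimate stain OD vectors from three rectangular ROIs.

    Each ROI is ``(row0, col0, row1, col1)`` (exclusive upper bounds), chosen
    over pure examples of the matrix stain, the counterstain and the
    background.  The mean OD vector of each ROI, normalised to unit length,
    becomes that stain's vector.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("estimate_stain_vectors requires an HxWx3 RGB raster")
    if len(rois) != 3:
        raise ValueError("exactly three ROIs required (matrix, counterstain, background)")
    vecs = []
    for i, (r0, c0, r1, c1) in enumerate(rois):
        if not (0 <= r0 < r1 <= arr.shape[0] and 0 <= c0 < c1 <= arr.shape[1]):
            raise ValueError(f"ROI {i} {(r0, c0, r1, c1)} lies outside the image")
        if (r1 - r0) * (c1 - c0) < 25:
            raise ValueError(f"ROI {i} has fewer than 25 pixels")
        od = od_transform(arr[r0:r1, c0:c1]).reshape(-1, 3).mean(axis=0)
        norm = float(np.linalg.norm(od))
        if norm < 0.02:
            raise ValueError(
                f"ROI {i} is near-white (OD norm {norm:.2g}); degenerate stain vector"
            )
        vecs.append(od / norm)
    return StainVectors(*vecs)


def _check_invertible(m: np.ndarray) -> None:
    # name the most collinear pair when the matrix is near-singular
    if abs(np.linalg.det(m)) > 1e-4:
        return
    names = ["matrix", "counterstain", "background"]
    worst, pair = 0.0, (0, 1)
    for i in range(3):
        for j in range(i + 1, 3):
            c = abs(float(np.dot(m[i], m[j])))
            if c > worst:
                worst, pair = c, (i, j)
    raise ValueError(
        "stain matrix is singular or near-singular; vectors "
        f"'{names[pair[0]]}' and '{names[pair[1]]}' are near-collinear "
        f"(|cos| = {worst:.4f})"
    )


def deconvolve_od(rgb: np.ndarray, vectors: StainVectors) -> np.ndarray:
    """Per-pixel stain concentrations (OD units), clamped at 0.

    Solves OD = C @ M for C, where M rows are the stain vectors.  Returns an
    HxWx3 array of concentrations in the stain basis.
    """
    m = vectors.as_matrix()
    _check_invertible(m)
    od = od_transform(np.asarray(rgb, dtype=np.float64))
    conc = od.reshape(-1, 3) @ np.linalg.inv(m)
    return np.clip(conc, 0.0, None).reshape(od.shape)


def remix_od(conc: np.ndarray, vectors: StainVectors) -> np.ndarray:
    """Re-mix stain concentrations back into an OD image (round-trip check)."""
    return np.asarray(conc, dtype=np.float64).reshape(-1, 3) @ vectors.as_matrix()


def colour_deconvolve(
    rgb: np.ndarray,
    vectors: StainVectors,
    pixel_size_um: float | None = None,
) -> list[GrayImage]:
    """Unmix an RGB image into three stain channels.

    Each channel's concentration map is rescaled linearly onto [0, 255]
    (max concentration -> 255) and returned as a :class:`GrayImage`, in the
    order matrix, counterstain, background.  Use :func:`deconvolve_od` for
    the raw concentrations.
    """
    conc = deconvolve_od(rgb, vectors)
    channels = []
    for k in range(3):
        c = conc[:, :, k]
        peak = float(c.max())
        scaled = c * (255.0 / peak) if peak > 0 else np.zeros_like(c)
        img = GrayImage(scaled, pixel_size_um=pixel_size_um)
        img.history.append(f"deconvolved channel {k} (peak OD {peak:.4g})")
        channels.append(img)
    return channels
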
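"""Grayscale image container and file I/O.

All pipeline stages operate on :class:`GrayImage`: a 2-D float raster with
intensities on the 8-bit scale [0, 255] (kept as floats so that contrast
stretching and derivative filters do not quantise), plus an optional physical
pixel size in micrometres.  When ``pixel_size_um`` is set, fibre lengths and
gap areas are reported in micrometres / square micrometres; otherwise in
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage

__all__ = ["GrayImage", "read_image", "write_gray"]

#: smallest image dimension the pipeline accepts
MIN_DIM = 16


@dataclass
class GrayImage:
    """A 2-D scalar raster with intensities in [0, 255].

    Parameters
    ----------
    pixels
        2-D float array, row-major, pixel centres at integer coordinates.
    pixel_size_um
        Physical size of one pixel in micrometres, or ``None`` for
        uncalibrated images (all lengths then reported in pixels).
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    #: free-form provenance notes (e.g. "polarity-inverted", "deconvolved")
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"GrayImage requires a 2-D raster, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape
        if h < MIN_DIM or w < MIN_DIM:
            raise ValueError(
                f"image {h}x{w} smaller than minimum {MIN_DIM}px in a dimension"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        return self.pixels.size

    def copy(self, pixels: np.ndarray | None = None, note: str | None = None) -> "GrayImage":
        """Return a copy, optionally with replaced pixels and a history note."""
        out = GrayImage(
            self.pixels.copy() if pixels is None else pixels,
            pixel_size_um=self.pixel_size_um,
            history=list(self.history),
        )
        if note:
            out.history.append(note)
        return out

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels), 0, 255).astype(np.uint8)


def read_image(path: str | Path, pixel_size_um: float | None = None) -> np.ndarray:
    """Read a TIFF/PNG/JPEG image into a float array.

    Returns the raw array (2-D grayscale or HxWx3 RGB); 16-bit data is
    linearly rescaled onto the 8-bit range.  Alpha channels are dropped.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = np.asarray(tifffile.imread(str(path)))
    else:
        with _PILImage.open(path) as im:
            arr = np.asarray(im)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    arr = arr.astype(np.float64)
    if arr.max() > 255:  # 16-bit (or deeper) input
        arr = arr * (255.0 / max(arr.max(), 1.0))
    return arr


def write_gray(path: str | Path, img: GrayImage | np.ndarray) -> None:
    """Write an 8-bit grayscale PNG/TIFF."""
    path = Path(path)
    if isinstance(img, GrayImage):
        data = img.to_uint8()
    else:
        arr = np.asarray(img)
        if arr.dtype == bool:
            data = arr.astype(np.uint8) * 255
        else:
            data = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), data)
    else:
        _PILImage.fromarray(data).save(path)
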
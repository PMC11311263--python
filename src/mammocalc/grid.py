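"""Lightweight image containers shared by every stage of the pipeline.

The package's universal currency is a single-channel 2-D intensity grid with
optional physical pixel spacing.  Intensities are held as floating-point
values end to end; quantization happens only when a file is written.
Coordinates are 0-based, row-major, origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "RGBImage", "as_grid"]


@dataclass
class ImageGrid:
    """Single-channel 2-D intensity grid.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Intensity values, stored as float64.  All values must be finite.
    pixel_spacing : tuple of float, optional
        Physical size of a pixel as (row_mm, col_mm).  ``None`` when the
        image has no physical calibration.
    value_range : float
        Nominal display maximum (e.g. 1.0 or 255.0).  Used by windowing to
        decide what "full brightness" means; actual pixel values may exceed
        it transiently (e.g. filter responses).
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    value_range: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"ImageGrid requires a 2-D array, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("ImageGrid requires at least one row and one column")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImageGrid intensities must be finite")
        if self.pixel_spacing is not None:
            r, c = self.pixel_spacing
            if r <= 0 or c <= 0:
                raise ValueError("pixel_spacing entries must be positive")
            self.pixel_spacing = (float(r), float(c))

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.pixels.copy(), self.pixel_spacing, self.value_range)

    def with_pixels(self, pixels: np.ndarray) -> "ImageGrid":
        """Same metadata, new pixel data (shape may differ)."""
        return ImageGrid(pixels, self.pixel_spacing, self.value_range)


@dataclass
class RGBImage:
    """Three equally shaped channel grids (the "false RGB" input case)."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    value_range: float = 255.0

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=np.float64)
        self.green = np.asarray(self.green, dtype=np.float64)
        self.blue = np.asarray(self.blue, dtype=np.float64)
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("RGB channels must have identical shapes")
        for ch in (self.red, self.green, self.blue):
            if not np.all(np.isfinite(ch)):
                raise ValueError("RGB channel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @classmethod
    def from_array(cls, arr: np.ndarray, **kw) -> "RGBImage":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise ValueError("expected an (rows, cols, 3) array")
        return cls(arr[..., 0], arr[..., 1], arr[..., 2], **kw)


def as_grid(image, value_range: float = 1.0) -> ImageGrid:
    """Coerce an ndarray or ImageGrid into an ImageGrid."""
    if isinstance(image, ImageGrid):
        return image
    return ImageGrid(np.asarray(image, dtype=np.float64), value_range=value_range)
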
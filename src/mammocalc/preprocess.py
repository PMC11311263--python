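"""Input normalization: grayscale, artifact removal, windowing, resizing.

Heterogeneous inputs (false-RGB exports, DICOM with or without VOI-LUT
metadata, PNG/TIFF of varying size) are reduced to a uniform grayscale grid:

1. grayscale conversion with the ITU-R 601 luma weights
   0.2989 R + 0.5870 G + 0.1140 B;
2. artifact removal by a 4-connected island detector that keeps only the
   largest bright component (the breast) and blacks out the rest;
3. contrast windowing (VOI-LUT style linear center/width map, with a
   2nd/98th-percentile fallback when no window is given);
4. bilinear resize to a standard square side (1024 by default), rescaling
   the physical pixel spacing accordingly.

Intensities stay floating point end to end; quantization happens at file
write only.  The default stage order (removal before windowing) is a package
choice and is configurable in :func:`preprocess_pipeline`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .grid import ImageGrid, RGBImage, as_grid

__all__ = [
    "GRAY_WEIGHTS",
    "to_grayscale",
    "resize_to_standard",
    "voi_window",
    "remove_artifacts",
    "preprocess_pipeline",
    "MammogramPreprocessor",
    "read_image",
    "NoForegroundError",
]

#: Luma weights for R, G, B.  Their sum is 0.9999, not 1.
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)


class NoForegroundError(ValueError):
    """No pixel exceeded the foreground threshold (no breast found)."""


def to_grayscale(rgb: RGBImage) -> ImageGrid:
    """Weighted channel sum; output kept as real values."""
    if not isinstance(rgb, RGBImage):
        rgb = RGBImage.from_array(np.asarray(rgb))
    wr, wg, wb = GRAY_WEIGHTS
    gray = wr * rgb.red + wg * rgb.green + wb * rgb.blue
    return ImageGrid(gray, pixel_spacing=rgb.pixel_spacing, value_range=rgb.value_range)


def resize_to_standard(image: ImageGrid | np.ndarray, side: int = 1024) -> ImageGrid:
    """Bilinear resize to side x side; pixel spacing rescaled per axis."""
    image = as_grid(image)
    if image.shape == (side, side):
        return image.copy()
    out = _sk_resize(image.pixels, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    spacing = None
    if image.pixel_spacing is not None:
        sr, sc = image.pixel_spacing
        spacing = (sr * image.rows / side, sc * image.cols / side)
    return ImageGrid(out, pixel_spacing=spacing, value_range=image.value_range)


def voi_window(image: ImageGrid | np.ndarray,
               center: float | None = None,
               width: float | None = None) -> ImageGrid:
    """Linear VOI-LUT windowing.

    Values at or below center - width/2 map to 0, at or above
    center + width/2 map to the image's ``value_range``, linear in between.
    When center/width are omitted the window spans the 2nd-98th intensity
    percentiles of the foreground (pixels > 0); a constant image is returned
    unchanged (degenerate window).
    """
    image = as_grid(image)
    px = image.pixels
    if width is not None and width <= 0:
        raise ValueError("width must be positive")
    if center is None or width is None:
        fg = px[px > 0]
        ref = fg if fg.size else px.ravel()
        lo, hi = np.percentile(ref, [2.0, 98.0])
        if hi <= lo:   # constant (or near-constant) image: nothing to window
            return image.copy()
        center, width = (hi + lo) / 2.0, hi - lo
    lo = center - width / 2.0
    out = np.clip((px - lo) / width, 0.0, 1.0) * image.value_range
    return image.with_pixels(out)


_FOUR_CONNECTED = ndimage.generate_binary_structure(2, 1)


def remove_artifacts(image: ImageGrid | np.ndarray,
                     fg_threshold: float = 0.0) -> tuple[ImageGrid, int]:
    """Keep only the largest 4-connected bright component; zero the rest.

    Components are pixels strictly above ``fg_threshold``.  Area ties are
    broken toward the smallest label in raster order.  Returns the cleaned
    image and the number of removed components.  Raises
    :class:`NoForegroundError` when nothing exceeds the threshold.
    """
    image = as_grid(image)
    fg = image.pixels > fg_threshold
    labels, n = ndimage.label(fg, structure=_FOUR_CONNECTED)
    if n == 0:
        raise NoForegroundError("no foreground pixels above threshold")
    areas = np.bincount(labels.ravel())[1:]          # label order = raster order
    keep = int(np.argmax(areas)) + 1                 # argmax takes first maximum
    out = np.where(labels == keep, image.pixels, 0.0)
    return image.with_pixels(out), n - 1


def preprocess_pipeline(raw,
                        side: int = 1024,
                        window_center: float | None = None,
                        window_width: float | None = None,
                        artifact_removal: bool = True,
                        fg_threshold: float = 0.0,
                        window_before_removal: bool = False) -> ImageGrid:
    """Grayscale -> artifact removal -> window -> resize (default order)."""
    if isinstance(raw, RGBImage):
        img = to_grayscale(raw)
    else:
        arr = raw.pixels if isinstance(raw, ImageGrid) else np.asarray(raw, dtype=np.float64)
        if arr.ndim == 3:
            img = to_grayscale(RGBImage.from_array(
                arr, value_range=getattr(raw, "value_range", 255.0)))
        else:
            img = as_grid(raw)

    stages = []
    if artifact_removal:
        stages.append("remove")
    stages.append("window")
    if window_before_removal and artifact_removal:
        stages = ["window", "remove"]
    for stage in stages:
        if stage == "remove":
            img, _ = remove_artifacts(img, fg_threshold)
        else:
            if window_center is not None or window_width is not None:
                img = voi_window(img, window_center, window_width)
            # no explicit window -> identity; the percentile fallback is
            # opt-in via voi_window directly, keeping the pipeline idempotent
    return resize_to_standard(img, side)


class MammogramPreprocessor:
    """sklearn-style transformer wrapping :func:`preprocess_pipeline`.

    ``transform`` maps a list/array of raw images to a list of
    :class:`ImageGrid`.  Stateless; ``fit`` is a no-op kept for pipeline
    compatibility.
    """

    def __init__(self, side: int = 1024, window_center: float | None = None,
                 window_width: float | None = None, artifact_removal: bool = True,
                 fg_threshold: float = 0.0):
        self.side = side
        self.window_center = window_center
        self.window_width = window_width
        self.artifact_removal = artifact_removal
        self.fg_threshold = fg_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("side", "window_center", "window_width", "artifact_removal", "fg_threshold")}

    def set_params(self, **params) -> "MammogramPreprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "MammogramPreprocessor":
        return self

    def transform(self, X) -> list[ImageGrid]:
        return [preprocess_pipeline(
            x, side=self.side, window_center=self.window_center,
            window_width=self.window_width, artifact_removal=self.artifact_removal,
            fg_threshold=self.fg_threshold) for x in X]

    def fit_transform(self, X, y=None) -> list[ImageGrid]:
        return self.fit(X, y).transform(X)


def read_image(path) -> ImageGrid:
    """Read PNG/TIFF (8/16-bit) or monochrome DICOM into an ImageGrid.

    DICOM inputs honor an embedded VOI-LUT window (center/width applied as in
    :func:`voi_window`) and PixelSpacing when present.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom
        from pydicom.pixels import apply_voi_lut

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        if getattr(ds, "WindowCenter", None) is not None:
            arr = apply_voi_lut(ds.pixel_array, ds).astype(np.float64)
        spacing = None
        if getattr(ds, "PixelSpacing", None) is not None:
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        vmax = float(arr.max()) if arr.max() > 0 else 1.0
        return ImageGrid(arr, pixel_spacing=spacing, value_range=vmax)

    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        vr = 65535.0 if arr.max() > 255 else 255.0
        gray = to_grayscale(RGBImage.from_array(arr, value_range=vr))
        return gray
    vr = 65535.0 if arr.max() > 255 else 255.0
    return ImageGrid(arr, value_range=vr)
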
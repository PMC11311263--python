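"""Candidate microcalcification localization via the white top-hat transform.

Calcifications are small bright structures on a slowly varying tissue
background, so a grayscale opening with a disk just larger than the biggest
expected spot erases them while preserving the background; subtracting the
opened image from the original (the white top-hat, I - I o B) leaves a
non-negative response map that is essentially zero everywhere except at
structures smaller than the disk.  Thresholding that map (default: mean +
3 sigma of its nonzero values), labeling 8-connected blobs and filtering by
area yields ranked candidate regions for a reader to review.

The default disk radius is tied to the largest expected calcification:
ceil(1.0 mm / pixel_spacing / 2) + 1 pixels, so a 1 mm spot still fits
strictly inside the structuring element and is removed by the opening.
Borders are handled by edge replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .grid import ImageGrid, as_grid

__all__ = [
    "StructuringElement",
    "RegionCandidate",
    "disk_se",
    "open_image",
    "white_top_hat",
    "candidate_regions",
    "localize_pipeline",
    "default_se_radius",
    "TopHatLocalizer",
]


@dataclass
class StructuringElement:
    radius: int
    mask: np.ndarray
    shape: str = "disk"


@dataclass
class RegionCandidate:
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]   # (r0, c0, r1, c1), half-open
    area: int
    mean_intensity: float
    score: float                       # peak top-hat response in the region


def disk_se(radius: int) -> StructuringElement:
    """Disk structuring element: {(dr, dc) : dr^2 + dc^2 <= radius^2}."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    mask = dr**2 + dc**2 <= radius**2
    return StructuringElement(radius=r, mask=mask)


def _as_se(se) -> StructuringElement:
    if isinstance(se, StructuringElement):
        return se
    return disk_se(int(se))


def open_image(image, se) -> ImageGrid:
    """Grayscale opening: erosion (min) then dilation (max) over the disk."""
    image = as_grid(image)
    se = _as_se(se)
    if se.mask.shape[0] > image.rows or se.mask.shape[1] > image.cols:
        raise ValueError("structuring element larger than image")
    eroded = ndimage.grey_erosion(image.pixels, footprint=se.mask, mode="nearest")
    opened = ndimage.grey_dilation(eroded, footprint=se.mask, mode="nearest")
    return image.with_pixels(opened)


def white_top_hat(image, se) -> ImageGrid:
    """Original minus opening; non-negative by anti-extensivity."""
    image = as_grid(image)
    opened = open_image(image, se)
    out = image.pixels - opened.pixels
    # anti-extensivity guarantees >= 0 up to float rounding
    return image.with_pixels(np.maximum(out, 0.0))


def candidate_regions(tophat_map, threshold: float | None = None,
                      k_sigma: float = 3.0, min_area: int = 1,
                      max_area: int | None = None) -> list[RegionCandidate]:
    """Extract candidate regions from a top-hat response map.

    Default threshold: mean + k_sigma * std of the nonzero responses.
    Blobs are 8-connected, filtered to [min_area, max_area], and sorted by
    descending peak response.  An empty list is a valid outcome.
    """
    th_map = as_grid(tophat_map).pixels
    if np.any(th_map < 0):
        raise ValueError("top-hat map must be non-negative")
    if max_area is not None and max_area < min_area:
        return []
    if threshold is None:
        nz = th_map[th_map > 0]
        if nz.size == 0:
            return []
        threshold = float(nz.mean() + k_sigma * nz.std())
    binary = th_map > threshold
    labels = measure.label(binary, connectivity=2)
    out: list[RegionCandidate] = []
    for region in measure.regionprops(labels, intensity_image=th_map):
        if region.area < min_area:
            continue
        if max_area is not None and region.area > max_area:
            continue
        r0, c0, r1, c1 = region.bbox
        out.append(RegionCandidate(
            centroid=tuple(region.centroid),
            bbox=(int(r0), int(c0), int(r1), int(c1)),
            area=int(region.area),
            mean_intensity=float(region.intensity_mean),
            score=float(region.intensity_max),
        ))
    out.sort(key=lambda rc: -rc.score)
    return out


def default_se_radius(pixel_spacing: float | None, max_spot_mm: float = 1.0) -> int:
    """Disk radius tied to the largest expected calcification size."""
    if pixel_spacing is None:
        pixel_spacing = 0.07
    return int(np.ceil(max_spot_mm / pixel_spacing / 2.0)) + 1


def overlay_boxes(image, candidates: list[RegionCandidate]) -> np.ndarray:
    """RGB copy of the image with candidate bounding boxes burned in."""
    px = as_grid(image).pixels
    lo, hi = px.min(), px.max()
    norm = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
    rgb = np.stack([norm] * 3, axis=-1)
    for cand in candidates:
        r0, c0, r1, c1 = cand.bbox
        r0, c0 = max(r0 - 1, 0), max(c0 - 1, 0)
        r1, c1 = min(r1 + 1, px.shape[0]), min(c1 + 1, px.shape[1])
        rgb[r0:r1, [c0, c1 - 1], :] = [1.0, 0.0, 0.0]
        rgb[[r0, r1 - 1], c0:c1, :] = [1.0, 0.0, 0.0]
    return rgb


def localize_pipeline(image, se_radius: int | None = None,
                      threshold: float | None = None, k_sigma: float = 3.0,
                      min_area: int = 1, max_area: int | None = None,
                      mask_skin_line: bool = True
                      ) -> tuple[list[RegionCandidate], np.ndarray]:
    """white_top_hat -> candidate_regions -> overlay, on one image.

    The opening cannot reconstruct the breast boundary, so the top-hat map
    carries a bright rim along the skin line.  When the image has a zero
    background, the adaptive threshold is computed from the full response
    map (the rim raises the bar the way bright tissue structure would), but
    candidates are extracted only from the breast interior (foreground
    eroded by the SE radius).  Images with no zero background are processed
    unmasked.
    """
    image = as_grid(image)
    if se_radius is None:
        spacing = image.pixel_spacing[0] if image.pixel_spacing else None
        se_radius = default_se_radius(spacing)
    th = white_top_hat(image, disk_se(se_radius))
    resp = th.pixels
    if threshold is None:
        nz = resp[resp > 0]
        if nz.size == 0:
            return [], overlay_boxes(image, [])
        threshold = float(nz.mean() + k_sigma * nz.std())
    if mask_skin_line:
        fg = image.pixels > 0
        if fg.any() and not fg.all():
            interior = ndimage.binary_erosion(
                fg, structure=disk_se(se_radius).mask)
            resp = np.where(interior, resp, 0.0)
    cands = candidate_regions(resp, threshold=threshold,
                              min_area=min_area, max_area=max_area)
    return cands, overlay_boxes(image, cands)


class TopHatLocalizer:
    """Configured localization front end: ``detect(image)`` -> candidates."""

    def __init__(self, se_radius: int | None = None, k_sigma: float = 3.0,
                 min_area: int = 1, max_area: int | None = None):
        self.se_radius = se_radius
        self.k_sigma = k_sigma
        self.min_area = min_area
        self.max_area = max_area

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("se_radius", "k_sigma", "min_area", "max_area")}

    def set_params(self, **params) -> "TopHatLocalizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def detect(self, image) -> list[RegionCandidate]:
        cands, _ = localize_pipeline(
            image, se_radius=self.se_radius, k_sigma=self.k_sigma,
            min_area=self.min_area, max_area=self.max_area)
        return cands
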
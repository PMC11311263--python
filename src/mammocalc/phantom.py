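"""Synthetic mammographic phantoms with known microcalcification ground truth.

Real mammograms with pixel-level calcification annotations are scarce, so the
package generates its own test inputs: a half-elliptical "breast" of textured
tissue on a black background, with small bright spots (0.1-1 mm equivalent
diameter) planted in the distribution patterns radiologists describe —
scattered, clustered, segmental, linear or regional — plus optional bright
corner annotations that emulate the equipment/label artifacts preprocessing
must remove.  Every phantom carries a truth record listing the planted spots,
so detection and localization can be scored exactly.

Geometry notes: spot diameters are specified in millimetres and converted to
pixels through the spec's pixel spacing (default 0.07 mm/px, typical for
full-field digital mammography, mapping 0.1-1 mm to roughly 1.4-14 px).
Spots are radially symmetric raised-cosine bumps, which avoids the aliasing a
hard disk would show at these scales.  Identical spec + seed produces
bit-identical pixels and truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ImageGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "Spot",
    "PatternPlacementError",
    "generate_phantom",
    "add_artifacts",
    "generate_dataset",
    "breast_mask",
]

PATTERNS = ("scattered", "clustered", "segmental", "linear", "regional")

#: Background intensity is exactly zero; tissue sits on this base level with
#: +/- TEXTURE_AMPLITUDE of low-pass noise, leaving headroom for unit-contrast
#: spots.  Intensity scale is [0, 1].
TISSUE_BASE = 0.35
TEXTURE_AMPLITUDE = 0.08


class PatternPlacementError(RuntimeError):
    """Raised when a spot pattern cannot be placed in the breast geometry."""


@dataclass
class Spot:
    row: float
    col: float
    diameter_px: float
    contrast: float


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``spot_contrast`` is the fractional intensity lift of a spot centre over
    its local tissue background, on the [0, 1] dynamic range.
    """

    width: int = 256
    height: int = 256
    pixel_spacing: float = 0.07          # mm per pixel, isotropic
    n_spots: int = 5
    spot_diameter_range: tuple[float, float] = (0.1, 1.0)   # mm
    pattern: str = "scattered"
    spot_contrast: float = 0.5
    tissue_texture_scale: float = 12.0   # px, low-pass sigma of the tissue noise
    add_artifacts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        lo, hi = self.spot_diameter_range
        if not (0.05 <= lo <= hi <= 2.0):
            raise ValueError("spot_diameter_range must lie within [0.05, 2.0] mm")
        if not (0.0 < self.spot_contrast <= 1.0):
            raise ValueError("spot_contrast must be in (0, 1]")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.n_spots < 0:
            raise ValueError("n_spots must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth for a phantom: class label, planted spots, artifact boxes."""

    label: int
    spots: list[Spot] = field(default_factory=list)
    artifact_boxes: list[tuple[int, int, int, int]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": int(self.label),
                "spots": [asdict(s) for s in self.spots],
                "artifact_boxes": [list(map(int, b)) for b in self.artifact_boxes],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        d = json.loads(text)
        return cls(
            label=int(d["label"]),
            spots=[Spot(**s) for s in d["spots"]],
            artifact_boxes=[tuple(b) for b in d["artifact_boxes"]],
        )


def breast_mask(height: int, width: int, side: str = "left") -> np.ndarray:
    """Half-elliptical breast foreground flush with the left or right edge."""
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    cy = (height - 1) / 2.0
    ry = 0.47 * height
    rx = 0.72 * width
    if side == "left":
        cx = 0.0
    elif side == "right":
        cx = width - 1.0
    else:
        raise ValueError("side must be 'left' or 'right'")
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


def _tissue(height: int, width: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    peak = np.max(np.abs(smooth))
    if peak > 0:
        smooth = smooth / peak
    return TISSUE_BASE + TEXTURE_AMPLITUDE * smooth


def _raised_cosine_bump(shape, row, col, radius_px, height_val) -> np.ndarray:
    """Radially symmetric bump: h/2 * (1 + cos(pi r / R)) for r <= R."""
    r0 = max(int(np.floor(row - radius_px)) - 1, 0)
    r1 = min(int(np.ceil(row + radius_px)) + 2, shape[0])
    c0 = max(int(np.floor(col - radius_px)) - 1, 0)
    c1 = min(int(np.ceil(col + radius_px)) + 2, shape[1])
    out = np.zeros(shape)
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    dist = np.hypot(rr, cc)
    with np.errstate(invalid="ignore"):
        prof = 0.5 * height_val * (1.0 + np.cos(np.pi * np.minimum(dist / radius_px, 1.0)))
    prof[dist > radius_px] = 0.0
    out[r0:r1, c0:c1] = prof
    return out


def _allowed_region(mask: np.ndarray, margin: int) -> np.ndarray:
    """Breast interior eroded so spots (and their support) stay inside."""
    st = ndimage.generate_binary_structure(2, 1)
    return ndimage.binary_erosion(mask, structure=st, iterations=max(margin, 1))


def _sample_centers(spec: PhantomSpec, allowed: np.ndarray, radii_px: np.ndarray,
                    rng: np.random.Generator) -> list[tuple[float, float]]:
    n = spec.n_spots
    coords = np.argwhere(allowed)
    if coords.size == 0:
        raise PatternPlacementError("no interior room for spots in this geometry")
    h, w = allowed.shape
    min_sep = float(np.max(radii_px) * 2.0 + 2.0) if n else 0.0
    disp = 0.08 * min(h, w)  # dispersion radius shared by the grouped patterns

    def ok(pt, accepted, sep):
        r, c = int(round(pt[0])), int(round(pt[1]))
        if not (0 <= r < h and 0 <= c < w and allowed[r, c]):
            return False
        return all(np.hypot(pt[0] - a[0], pt[1] - a[1]) >= sep for a in accepted)

    def anchor():
        return tuple(coords[rng.integers(len(coords))].astype(float))

    if spec.pattern == "scattered":
        centers: list[tuple[float, float]] = []
        for _ in range(n):
            for _try in range(400):
                pt = tuple(coords[rng.integers(len(coords))].astype(float))
                if ok(pt, centers, min_sep):
                    centers.append(pt)
                    break
            else:
                raise PatternPlacementError("scattered placement failed")
        return centers

    if spec.pattern in ("clustered", "regional", "segmental"):
        sigma = {"clustered": disp, "regional": 3.0 * disp}.get(spec.pattern)
        for _attempt in range(60):
            a = anchor()
            theta = rng.uniform(0, np.pi)
            centers = []
            failed = False
            for _ in range(n):
                placed = False
                for _try in range(400):
                    if spec.pattern == "segmental":
                        # anisotropic spread along a random axis (wedge-like)
                        u = rng.normal(0, 3.0 * disp)
                        v = rng.normal(0, 0.6 * disp)
                        pt = (a[0] + u * np.sin(theta) + v * np.cos(theta),
                              a[1] + u * np.cos(theta) - v * np.sin(theta))
                    else:
                        pt = (a[0] + rng.normal(0, sigma), a[1] + rng.normal(0, sigma))
                    if ok(pt, centers, min_sep):
                        centers.append(pt)
                        placed = True
                        break
                if not placed:
                    failed = True
                    break
            if not failed:
                return centers
        raise PatternPlacementError(f"{spec.pattern} placement failed")

    if spec.pattern == "linear":
        base_sep = max(min_sep, 4.0)
        for _attempt in range(160):
            a = anchor()
            theta = rng.uniform(0, np.pi)
            d = (np.sin(theta), np.cos(theta))
            jitter = rng.uniform(-1.5, 1.5, size=n)  # perpendicular, <= 2 px
            # a long bead chain may not fit the breast; shrink the spacing
            # toward a 4 px floor before giving up on this anchor/direction
            for sep in (base_sep, 0.75 * base_sep, 0.5 * base_sep, 4.0):
                offsets = (np.arange(n) - (n - 1) / 2.0) * max(sep, 4.0)
                centers = []
                good = True
                for off, jit in zip(offsets, jitter):
                    pt = (a[0] + off * d[0] + jit * d[1],
                          a[1] + off * d[1] - jit * d[0])
                    if ok(pt, centers, 0.0):
                        centers.append(pt)
                    else:
                        good = False
                        break
                if good:
                    return centers
        raise PatternPlacementError("linear placement failed")

    raise ValueError(f"unknown pattern {spec.pattern!r}")


def generate_phantom(spec: PhantomSpec) -> tuple[ImageGrid, PhantomTruth]:
    """Generate one phantom image and its ground truth.

    Returns an :class:`ImageGrid` on the [0, 1] intensity scale with pixel
    spacing from the spec, and a :class:`PhantomTruth` whose label is positive
    iff at least one spot was planted.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    side = "left" if rng.integers(2) == 0 else "right"
    mask = breast_mask(spec.height, spec.width, side)
    img = np.where(mask, _tissue(spec.height, spec.width, spec.tissue_texture_scale, rng), 0.0)

    spots: list[Spot] = []
    if spec.n_spots > 0:
        lo, hi = spec.spot_diameter_range
        diam_mm = rng.uniform(lo, hi, size=spec.n_spots)
        diam_px = diam_mm / spec.pixel_spacing
        radii = np.maximum(diam_px / 2.0, 1.0)
        margin = int(np.ceil(np.max(radii))) + 2
        allowed = _allowed_region(mask, margin)
        centers = _sample_centers(spec, allowed, radii, rng)
        for (r, c), dpx, rad in zip(centers, diam_px, radii):
            img += _raised_cosine_bump(img.shape, r, c, rad, spec.spot_contrast)
            spots.append(Spot(row=float(r), col=float(c),
                              diameter_px=float(dpx), contrast=spec.spot_contrast))

    truth = PhantomTruth(label=int(len(spots) > 0), spots=spots)
    grid = ImageGrid(img, pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
                     value_range=1.0)
    if spec.add_artifacts:
        grid, boxes = add_artifacts(grid, seed=spec.seed + 1)
        truth.artifact_boxes = boxes
    return grid, truth


def add_artifacts(image: ImageGrid, seed: int = 0) -> tuple[ImageGrid, list[tuple[int, int, int, int]]]:
    """Stamp 1-3 bright text-like blobs onto background regions.

    Emulates the annotation/equipment marks real mammograms carry outside the
    breast.  Blobs are placed only where a dilated breast-foreground mask is
    clear; if no corner has room the image is returned unchanged with an
    empty box list.  Boxes are (r0, c0, r1, c1), half-open.
    """
    rng = np.random.default_rng(seed)
    px = image.pixels.copy()
    h, w = px.shape
    fg = px > 0
    safe = ~ndimage.binary_dilation(fg, iterations=3)

    bh, bw = max(6, h // 16), max(12, w // 8)
    corners = [(2, 2), (2, w - bw - 2), (h - bh - 2, 2), (h - bh - 2, w - bw - 2)]
    rng.shuffle(corners)
    n_want = int(rng.integers(1, 4))
    boxes: list[tuple[int, int, int, int]] = []
    for r0, c0 in corners:
        if len(boxes) == n_want:
            break
        r1, c1 = r0 + bh, c0 + bw
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            continue
        if not np.all(safe[r0:r1, c0:c1]):
            continue
        # text-like blob: coarse random on/off cells, bright
        cells = rng.random((-(-bh // 2), -(-bw // 3))) < 0.45
        stamp = np.kron(cells, np.ones((2, 3)))[:bh, :bw]
        px[r0:r1, c0:c1][stamp > 0] = 0.9
        boxes.append((r0, c0, r1, c1))
    return image.with_pixels(px), boxes


def write_png16(path, pixels: np.ndarray, value_range: float = 1.0) -> None:
    """Quantize [0, value_range] floats to 16-bit PNG (round-half-to-even)."""
    scaled = np.clip(pixels / value_range, 0.0, 1.0) * 65535.0
    iio.imwrite(Path(path), np.rint(scaled).astype(np.uint16), extension=".png")


def read_png16(path) -> np.ndarray:
    """Read a 16-bit PNG back onto the [0, 1] float scale."""
    arr = np.asarray(iio.imread(Path(path)), dtype=np.float64)
    return arr / 65535.0


def generate_dataset(
    n_pos: int,
    n_neg: int,
    out_dir,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a labelled phantom dataset and return its manifest.

    Positives cycle through the five spot patterns; negatives use the same
    template with ``n_spots=0``.  Each image gets its own sub-seed drawn from
    the master seed, a 16-bit PNG, and a JSON truth sidecar.  The manifest
    (columns ``path,label,seed,n_spots``) is also written as manifest.csv.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = spec_template or PhantomSpec()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_pos + n_neg)

    rows = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        spec = PhantomSpec(**{**asdict(template),
                              "n_spots": template.n_spots if positive else 0,
                              "pattern": PATTERNS[i % len(PATTERNS)] if positive else template.pattern,
                              "seed": int(sub_seeds[i])})
        if positive and spec.n_spots == 0:
            spec.n_spots = 5
        grid, truth = generate_phantom(spec)
        name = f"phantom_{i:04d}_{'pos' if positive else 'neg'}"
        img_path = out_dir / f"{name}.png"
        write_png16(img_path, grid.pixels, grid.value_range)
        (out_dir / f"{name}.json").write_text(truth.to_json())
        rows.append({"path": str(img_path), "label": int(positive),
                     "seed": int(sub_seeds[i]), "n_spots": len(truth.spots)})

    manifest = pd.DataFrame(rows, columns=["path", "label", "seed", "n_spots"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
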
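"""Geometric augmentation and the deterministic stratified 70/20/10 split.

Augmentation covers the three transform families used to balance the
classes: isotropic/anisotropic scaling (default factors 0.8, 1.0, 1.2),
right-angle rotations (90/180/270 degrees, exact pixel permutations) and
horizontal/vertical reflections (also exact permutations).  Each transform is
applied to the original independently — no compositions — and the identity
scale emits nothing extra, so the output count per image is
``(#scales - [1.0 in scales]) + #angles + #reflections + 1`` including the
original.

Scaled images are recentred on a fixed canvas of the original size (zero
padding or central cropping) so downstream input shapes stay constant.

The split follows the round-half-up convention: per class,
train = round(n * 0.70), val = round(n * 0.20), test = the remainder; this is
the only rounding rule consistent with both published class rows
(2748 -> 1924/550/274 and 2942 -> 2059/588/295).  Assignment is a seeded
shuffle followed by slicing, so the same seed always yields the same split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ImageGrid, as_grid

__all__ = [
    "AugmentPlan",
    "SplitSpec",
    "scale_image",
    "rotate_image",
    "reflect_image",
    "augment_arrays",
    "augment_set",
    "split_counts",
    "stratified_split",
]


@dataclass
class AugmentPlan:
    scales: tuple[float, ...] = (0.8, 1.0, 1.2)
    angles: tuple[float, ...] = (90.0, 180.0, 270.0)
    reflections: tuple[str, ...] = ("horizontal", "vertical")

    def validate(self) -> None:
        if any(s <= 0 for s in self.scales):
            raise ValueError("scale factors must be positive")
        for ax in self.reflections:
            if ax not in ("horizontal", "vertical"):
                raise ValueError(f"unknown reflection axis {ax!r}")

    def transforms(self) -> list[tuple[str, object]]:
        """Enumerate (kind, parameter) pairs, identity scale omitted."""
        self.validate()
        out: list[tuple[str, object]] = []
        out += [("scale", s) for s in self.scales if s != 1.0]
        out += [("rotate", a) for a in self.angles]
        out += [("reflect", ax) for ax in self.reflections]
        return out


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def validate(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def scale_image(image, sx: float, sy: float) -> ImageGrid:
    """Scale by (sx, sy), then recentre on the original canvas size.

    Bilinear sampling; the scaled content is zero-padded or centre-cropped
    back to the input dimensions so downstream shapes are stable.
    """
    if sx <= 0 or sy <= 0:
        raise ValueError("scale factors must be positive")
    image = as_grid(image)
    if sx == 1.0 and sy == 1.0:
        return image.copy()
    H, W = image.shape
    cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
    # output pixel (r, c) samples the input at the centre-anchored preimage,
    # so scale(s) and scale(1/s) are exact inverse mappings of each other
    matrix = np.diag([1.0 / sy, 1.0 / sx])
    offset = np.array([cr - cr / sy, cc - cc / sx])
    out = ndimage.affine_transform(image.pixels, matrix, offset=offset,
                                   order=1, mode="constant", cval=0.0)
    return image.with_pixels(out)


def rotate_image(image, angle_degrees: float) -> ImageGrid:
    """Rotate counter-clockwise about the image centre.

    Right angles (multiples of 90) are exact pixel permutations via
    quarter-turns; any other angle falls back to bilinear interpolation on a
    fixed canvas.
    """
    image = as_grid(image)
    a = angle_degrees % 360.0
    if a % 90.0 == 0.0:
        out = np.rot90(image.pixels, k=int(a // 90)).copy()
    else:
        out = ndimage.rotate(image.pixels, angle_degrees, reshape=False,
                             order=1, mode="constant", cval=0.0)
    return image.with_pixels(out)


def reflect_image(image, axis: str) -> ImageGrid:
    """Mirror the image: 'horizontal' flips left-right (column flip),
    'vertical' flips top-bottom (row flip).  Exact permutations."""
    image = as_grid(image)
    if axis == "horizontal":
        out = image.pixels[:, ::-1].copy()
    elif axis == "vertical":
        out = image.pixels[::-1, :].copy()
    else:
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    return image.with_pixels(out)


def apply_transform(image, kind: str, param) -> ImageGrid:
    if kind == "scale":
        return scale_image(image, param, param)
    if kind == "rotate":
        return rotate_image(image, param)
    if kind == "reflect":
        return reflect_image(image, param)
    if kind == "identity":
        return as_grid(image).copy()
    raise ValueError(f"unknown transform kind {kind!r}")


def augment_arrays(images, labels, plan: AugmentPlan):
    """Augment in-memory images.

    Returns (images, labels, provenance DataFrame) where provenance has
    columns ``source_id`` and ``transform`` (e.g. ``rotate:90``); originals
    come first with transform ``identity``.
    """
    out_imgs, out_labels, rows = [], [], []
    transforms = plan.transforms()
    for i, (img, lab) in enumerate(zip(images, labels)):
        out_imgs.append(as_grid(img).copy())
        out_labels.append(lab)
        rows.append({"source_id": i, "transform": "identity"})
        for kind, param in transforms:
            out_imgs.append(apply_transform(img, kind, param))
            out_labels.append(lab)
            rows.append({"source_id": i, "transform": f"{kind}:{param}"})
    return out_imgs, out_labels, pd.DataFrame(rows, columns=["source_id", "transform"])


def augment_set(manifest: pd.DataFrame, plan: AugmentPlan, out_dir) -> pd.DataFrame:
    """Augment a file-backed manifest, writing transformed PNGs.

    The input manifest needs ``path`` and ``label`` columns; output rows gain
    ``source_id`` and ``transform`` provenance and labels are inherited.
    """
    from pathlib import Path
    from .phantom import read_png16, write_png16

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    transforms = plan.transforms()
    rows = []
    for i, rec in manifest.iterrows():
        src = Path(rec["path"])
        img = read_png16(src)
        rows.append({"path": str(src), "label": rec["label"],
                     "source_id": i, "transform": "identity"})
        for kind, param in transforms:
            t = apply_transform(img, kind, param)
            name = f"{src.stem}__{kind}_{str(param).replace('.', 'p')}.png"
            dst = out_dir / name
            write_png16(dst, t.pixels)
            rows.append({"path": str(dst), "label": rec["label"],
                         "source_id": i, "transform": f"{kind}:{param}"})
    return pd.DataFrame(rows, columns=["path", "label", "source_id", "transform"])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_counts(n: int, fractions=(0.70, 0.20, 0.10)) -> tuple[int, int, int]:
    """Per-class (train, val, test) counts: round-half-up, remainder to test."""
    f_train, f_val, _ = fractions
    train = _round_half_up(n * f_train)
    val = _round_half_up(n * f_val)
    test = n - train - val
    if test < 0:
        raise ValueError(f"degenerate split for n={n} with fractions {fractions}")
    return train, val, test


def stratified_split(labels, spec: SplitSpec | None = None) -> np.ndarray:
    """Assign each sample to 'train'/'val'/'test', stratified by class.

    Within each class the indices are shuffled with the spec seed and sliced
    by the per-class counts from :func:`split_counts`.  Same seed, same
    assignment; counts are seed-independent.
    """
    spec = spec or SplitSpec()
    spec.validate()
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    assignment = np.empty(labels.shape[0], dtype=object)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if 0 < idx.size < 3 and all(f > 0 for f in spec.fractions):
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
        n_train, n_val, n_test = split_counts(idx.size, spec.fractions)
        perm = rng.permutation(idx)
        assignment[perm[:n_train]] = "train"
        assignment[perm[n_train:n_train + n_val]] = "val"
        assignment[perm[n_train + n_val:]] = "test"
    return assignment.astype(str)
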
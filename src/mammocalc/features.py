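"""Hybrid descriptive features: Prewitt edges, Gabor bank, GLCM texture.

Three kernel families probe the properties that make a microcalcification
stand out — an abrupt intensity gradient (Prewitt), oriented band-pass
texture (a five-orientation Gabor bank at 0/45/90/135/180 degrees), and
local co-occurrence statistics (windowed GLCM with the four Haralick
features: contrast, correlation, energy, homogeneity).

The Gabor bank ships in two modes.  ``canonical`` uses five fixed 5x5
matrices treated as authoritative fixtures (the theta=0 kernel peaks at
0.7726); ``parametric`` evaluates the Gabor function

    G(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(2 pi x' / lambda + psi)

with x' = x cos(theta) + y sin(theta), y' = -x sin(theta) + y cos(theta) on
the integer offsets -2..2, with wavelength lambda = 1/0.625 by default
(frequency 0.625 cycles/px, tuned to the ~1 mm upper calcification size).
The canonical matrices are not reproducible from the parametric form with
any single (sigma, gamma, psi); parametric mode is provided for exploration
and is documented as approximate.

All filter responses are cross-correlations (kernels are not flipped), the
common image-processing convention; 'same'-size outputs use zero padding and
the border ring of width (k-1)/2 is not valid.

The classifier input is an 8-channel stack — 2 Prewitt + 5 Gabor + 1 GLCM
texture map — each channel min-max normalized to [0, 1] and bilinearly
resampled to a common side (508 px by default).
"""

from __future__ import annotations

import json
from collections import namedtuple
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .grid import ImageGrid, as_grid

__all__ = [
    "PREWITT_X",
    "PREWITT_Y",
    "GABOR_ORIENTATIONS",
    "KernelBank",
    "GLCMatrix",
    "FeatureStack",
    "HaralickFeatures",
    "prewitt_response",
    "build_gabor_bank",
    "gabor_responses",
    "glcm_offset",
    "glcm_compute",
    "glcm_features",
    "glcm_texture_samples",
    "glcm_texture_map",
    "quantize",
    "assemble_feature_stack",
    "FeatureStackExtractor",
]

PREWITT_X = np.array([[-1, 0, 1],
                      [-1, 0, 1],
                      [-1, 0, 1]], dtype=np.float64)

PREWITT_Y = np.array([[-1, -1, -1],
                      [0, 0, 0],
                      [1, 1, 1]], dtype=np.float64)

GABOR_ORIENTATIONS = (0, 45, 90, 135, 180)

CHANNEL_NAMES = ("prewitt_x", "prewitt_y", "gabor_0", "gabor_45",
                 "gabor_90", "gabor_135", "gabor_180", "glcm_texture")


def _load_canonical() -> dict[int, np.ndarray]:
    with resources.files("mammocalc.data").joinpath("gabor_canonical.json").open() as fh:
        raw = json.load(fh)
    return {int(k): np.asarray(v, dtype=np.float64) for k, v in raw.items()}


GABOR_CANONICAL: dict[int, np.ndarray] = _load_canonical()


@dataclass
class KernelBank:
    """The Prewitt pair plus the five 5x5 Gabor matrices."""

    prewitt_x: np.ndarray = field(default_factory=lambda: PREWITT_X.copy())
    prewitt_y: np.ndarray = field(default_factory=lambda: PREWITT_Y.copy())
    gabor: dict[int, np.ndarray] = field(default_factory=dict)
    mode: str = "canonical"

    def save(self, path) -> None:
        payload = {
            "mode": self.mode,
            "prewitt_x": self.prewitt_x.tolist(),
            "prewitt_y": self.prewitt_y.tolist(),
            "gabor": {str(k): v.tolist() for k, v in self.gabor.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "KernelBank":
        d = json.loads(Path(path).read_text())
        return cls(
            prewitt_x=np.asarray(d["prewitt_x"], dtype=np.float64),
            prewitt_y=np.asarray(d["prewitt_y"], dtype=np.float64),
            gabor={int(k): np.asarray(v, dtype=np.float64) for k, v in d["gabor"].items()},
            mode=d["mode"],
        )


def _gabor_kernel(theta_deg: float, lam: float, sigma: float, gamma: float,
                  psi: float, half: int = 2) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    y, x = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1),
                       indexing="ij")
    xp = x * np.cos(th) + y * np.sin(th)
    yp = -x * np.sin(th) + y * np.cos(th)
    env = np.exp(-(xp**2 + gamma**2 * yp**2) / (2.0 * sigma**2))
    return env * np.cos(2.0 * np.pi * xp / lam + psi)


def build_gabor_bank(mode: str = "canonical", *, frequency: float = 0.625,
                     sigma: float = 2.0, gamma: float = 1.0,
                     psi: float = 0.0) -> KernelBank:
    """Five-orientation Gabor bank.

    canonical -> the fixed printed matrices; parametric -> evaluation of the
    Gabor function on integer offsets with wavelength 1/frequency.
    """
    if mode == "canonical":
        gabor = {k: v.copy() for k, v in GABOR_CANONICAL.items()}
    elif mode == "parametric":
        lam = 1.0 / frequency
        gabor = {th: _gabor_kernel(th, lam, sigma, gamma, psi)
                 for th in GABOR_ORIENTATIONS}
    else:
        raise ValueError("mode must be 'canonical' or 'parametric'")
    return KernelBank(gabor=gabor, mode=mode)


def _correlate_same(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # cross-correlation, zero-padded 'same' output
    return ndimage.correlate(image, kernel, mode="constant", cval=0.0)


def valid_interior(shape: tuple[int, int], kernel_side: int) -> np.ndarray:
    """Mask of pixels whose kernel support lies fully inside the image."""
    m = np.zeros(shape, dtype=bool)
    h = kernel_side // 2
    if shape[0] > 2 * h and shape[1] > 2 * h:
        m[h:shape[0] - h, h:shape[1] - h] = True
    return m


def prewitt_response(image) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical Prewitt gradient maps (same-size, zero pad)."""
    px = as_grid(image).pixels
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for the Prewitt pair")
    return _correlate_same(px, PREWITT_X), _correlate_same(px, PREWITT_Y)


def gabor_responses(image, bank: KernelBank | None = None) -> dict[int, np.ndarray]:
    """Response maps for the five orientations, keyed by ascending angle."""
    px = as_grid(image).pixels
    if px.shape[0] < 5 or px.shape[1] < 5:
        raise ValueError("image must be at least 5x5 for the Gabor bank")
    bank = bank or build_gabor_bank("canonical")
    return {th: _correlate_same(px, bank.gabor[th]) for th in GABOR_ORIENTATIONS}


# ---------------------------------------------------------------------------
# GLCM

GLCM_ANGLES = (0, 45, 90, 135)

HaralickFeatures = namedtuple("HaralickFeatures",
                              ["contrast", "correlation", "energy", "homogeneity"])


@dataclass
class GLCMatrix:
    counts: np.ndarray
    levels: int
    offset: tuple[int, int]      # (d_col, d_row) = (dx, dy)
    distance: int
    angle: float


def glcm_offset(d: int, theta_deg: float) -> tuple[int, int]:
    """(dx, dy) = d * (cos theta, -sin theta), rounded to integers.

    dx is the column offset, dy the row offset (rows grow downward, so a
    positive angle points up the image).
    """
    th = np.deg2rad(theta_deg)
    return int(np.round(d * np.cos(th))), int(np.round(-d * np.sin(th)))


def quantize(window: np.ndarray, levels: int) -> np.ndarray:
    """Uniform binning of the window onto 0..levels-1 over its min-max."""
    w = np.asarray(window, dtype=np.float64)
    lo, hi = w.min(), w.max()
    if hi <= lo:
        return np.zeros_like(w, dtype=np.intp)
    q = np.floor((w - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def glcm_compute(window: np.ndarray, levels: int = 8, d: int = 1,
                 theta: float = 0.0, symmetric: bool = False,
                 do_quantize: bool = True) -> GLCMatrix:
    """Co-occurrence counts of ordered gray-level pairs at one offset.

    The window is quantized to ``levels`` gray levels over its own min-max
    unless ``do_quantize`` is False (then it must already hold integers in
    0..levels-1).  Counts total exactly the number of in-bounds pixel pairs.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    q = quantize(window, levels) if do_quantize else np.asarray(window, dtype=np.intp)
    dx, dy = glcm_offset(d, theta)
    H, W = q.shape
    if abs(dy) >= H or abs(dx) >= W:
        raise ValueError("window smaller than the requested offset")
    r0, r1 = max(0, -dy), H - max(0, dy)
    c0, c1 = max(0, -dx), W - max(0, dx)
    first = q[r0:r1, c0:c1]
    second = q[r0 + dy:r1 + dy, c0 + dx:c1 + dx]
    counts = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(counts, (first.ravel(), second.ravel()), 1)
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(counts=counts, levels=levels, offset=(dx, dy),
                     distance=d, angle=theta)


def glcm_features(glcm: GLCMatrix | np.ndarray) -> HaralickFeatures:
    """Contrast, correlation, energy, homogeneity from one GLCM.

    The matrix is normalized to probabilities internally.  Correlation is
    defined as 0 when either marginal variance vanishes.
    """
    counts = glcm.counts if isinstance(glcm, GLCMatrix) else np.asarray(glcm)
    total = counts.sum()
    if total == 0:
        raise ValueError("GLCM has no counts")
    p = counts.astype(np.float64) / total
    G = p.shape[0]
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    contrast = float(np.sum(p * (i - j) ** 2))
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mi = float(np.sum(np.arange(G) * pi))
    mj = float(np.sum(np.arange(G) * pj))
    vi = float(np.sum((np.arange(G) - mi) ** 2 * pi))
    vj = float(np.sum((np.arange(G) - mj) ** 2 * pj))
    if vi <= 0 or vj <= 0:
        corr = 0.0
    else:
        corr = float(np.sum(p * (i - mi) * (j - mj)) / np.sqrt(vi * vj))
    return HaralickFeatures(contrast, corr, energy, homogeneity)


def _features_from_counts(counts: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized Haralick features for an array of GLCMs (..., G, G)."""
    total = counts.sum(axis=(-2, -1), keepdims=True)
    safe = np.where(total > 0, total, 1)
    p = counts / safe
    G = p.shape[-1]
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]
    contrast = np.sum(p * (i - j) ** 2, axis=(-2, -1))
    energy = np.sum(p**2, axis=(-2, -1))
    homogeneity = np.sum(p / (1.0 + np.abs(i - j)), axis=(-2, -1))
    lv = np.arange(G, dtype=np.float64)
    pi = p.sum(axis=-1)
    pj = p.sum(axis=-2)
    mi = pi @ lv
    mj = pj @ lv
    vi = np.sum((lv - mi[..., None]) ** 2 * pi, axis=-1)
    vj = np.sum((lv - mj[..., None]) ** 2 * pj, axis=-1)
    num = np.sum(p * (i - mi[..., None, None]) * (j - mj[..., None, None]),
                 axis=(-2, -1))
    denom = np.sqrt(vi * vj)
    corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return {"contrast": contrast, "correlation": corr,
            "energy": energy, "homogeneity": homogeneity}


def _integral(img: np.ndarray) -> np.ndarray:
    s = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=s[1:, 1:])
    return s


def glcm_texture_samples(image, window_side: int = 17, stride: int = 8,
                         levels: int = 8, d: int = 1
                         ) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Windowed GLCM Haralick features on a stride grid of window centres.

    The image is quantized once globally (uniform bins over its min-max);
    window GLCMs are counted with offsets pooled over the four angles 0, 45,
    90 and 135 degrees.  Quantizing globally rather than per window keeps
    neighbouring windows on a common gray scale and lets the counting run
    through integral images.  Returns (centre rows, centre cols, features).
    """
    if window_side % 2 == 0:
        raise ValueError("window_side must be odd")
    px = as_grid(image).pixels
    H, W = px.shape
    if window_side > min(H, W):
        raise ValueError("window larger than image")
    half = window_side // 2
    q = quantize(px, levels)

    centers_r = np.arange(half, H - half, stride)
    centers_c = np.arange(half, W - half, stride)
    nr, nc = len(centers_r), len(centers_c)
    counts = np.zeros((nr, nc, levels, levels), dtype=np.float64)

    for theta in GLCM_ANGLES:
        dx, dy = glcm_offset(d, theta)
        # first-pixel positions valid inside a window [0, ws) x [0, ws):
        # rows rlo..ws-1-rhi etc., identical for every window.
        rlo, rhi = max(0, -dy), max(0, dy)
        clo, chi = max(0, -dx), max(0, dx)
        bh = window_side - rlo - rhi   # box height of valid first pixels
        bw = window_side - clo - chi
        if bh <= 0 or bw <= 0:
            continue
        for a in range(levels):
            mask_a = q == a
            for b in range(levels):
                # indicator of pair (a, b) at this offset, on first-pixel coords
                pair = np.zeros((H, W), dtype=np.float64)
                r0, r1 = max(0, -dy), H - max(0, dy)
                c0, c1 = max(0, -dx), W - max(0, dx)
                pair[r0:r1, c0:c1] = (mask_a[r0:r1, c0:c1]
                                      & (q[r0 + dy:r1 + dy, c0 + dx:c1 + dx] == b))
                S = _integral(pair)
                tr = centers_r - half + rlo        # top row of valid box
                lc = centers_c - half + clo        # left col of valid box
                br = tr + bh
                rc = lc + bw
                counts[:, :, a, b] += (S[np.ix_(br, rc)] - S[np.ix_(tr, rc)]
                                       - S[np.ix_(br, lc)] + S[np.ix_(tr, lc)])

    return centers_r, centers_c, _features_from_counts(counts)


def glcm_texture_map(image, window_side: int = 17, stride: int = 8,
                     feature: str = "contrast", levels: int = 8,
                     d: int = 1) -> np.ndarray:
    """Sliding-window GLCM texture map, bilinearly upsampled to image size.

    See :func:`glcm_texture_samples` for the windowing and quantization
    rules; the chosen Haralick feature (default contrast) is evaluated on
    the stride grid and resampled to the input size.
    """
    if feature not in ("contrast", "correlation", "energy", "homogeneity"):
        raise ValueError(f"unknown feature {feature!r}")
    px = as_grid(image).pixels
    H, W = px.shape
    _, _, feats = glcm_texture_samples(image, window_side=window_side,
                                       stride=stride, levels=levels, d=d)
    feat = feats[feature]
    if feat.shape == (H, W):
        return feat
    return _sk_resize(feat, (H, W), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


# ---------------------------------------------------------------------------
# Feature stack


@dataclass
class FeatureStack:
    """8-channel classifier input: (side, side, 8) array with fixed order."""

    array: np.ndarray
    names: tuple[str, ...] = CHANNEL_NAMES

    @property
    def side(self) -> int:
        return self.array.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.array[..., self.names.index(name)]

    def save(self, path) -> None:
        np.savez(path, array=self.array, names=np.array(self.names))

    @classmethod
    def load(cls, path) -> "FeatureStack":
        d = np.load(path, allow_pickle=False)
        return cls(array=d["array"], names=tuple(str(n) for n in d["names"]))


def _minmax01(ch: np.ndarray) -> np.ndarray:
    lo, hi = ch.min(), ch.max()
    if hi <= lo:
        return np.zeros_like(ch)
    return (ch - lo) / (hi - lo)


def assemble_feature_stack(image, out_side: int = 508,
                           gabor_mode: str = "canonical",
                           glcm_window: int = 17, glcm_stride: int = 8,
                           glcm_feature: str = "contrast") -> FeatureStack:
    """Compute the 8 channels, normalize each to [0, 1], resample to out_side.

    Channel order: prewitt_x, prewitt_y, gabor_0..180, glcm_texture.
    """
    px = as_grid(image).pixels
    if min(px.shape) < glcm_window:
        raise ValueError("image too small for the GLCM window")
    gx, gy = prewitt_response(px)
    bank = build_gabor_bank(gabor_mode)
    gab = gabor_responses(px, bank)
    tex = glcm_texture_map(px, window_side=glcm_window, stride=glcm_stride,
                           feature=glcm_feature)
    channels = [gx, gy] + [gab[th] for th in GABOR_ORIENTATIONS] + [tex]
    out = np.empty((out_side, out_side, len(channels)))
    for k, ch in enumerate(channels):
        n = _minmax01(ch)
        if n.shape != (out_side, out_side):
            n = _sk_resize(n, (out_side, out_side), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
        out[..., k] = np.clip(n, 0.0, 1.0)
    return FeatureStack(array=out)


class FeatureStackExtractor:
    """sklearn-style transformer: images -> (n, side, side, 8) stacks."""

    def __init__(self, out_side: int = 508, gabor_mode: str = "canonical",
                 glcm_window: int = 17, glcm_stride: int = 8,
                 glcm_feature: str = "contrast"):
        self.out_side = out_side
        self.gabor_mode = gabor_mode
        self.glcm_window = glcm_window
        self.glcm_stride = glcm_stride
        self.glcm_feature = glcm_feature

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("out_side", "gabor_mode", "glcm_window", "glcm_stride", "glcm_feature")}

    def set_params(self, **params) -> "FeatureStackExtractor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "FeatureStackExtractor":
        return self

    def transform(self, X) -> np.ndarray:
        stacks = [assemble_feature_stack(
            x, out_side=self.out_side, gabor_mode=self.gabor_mode,
            glcm_window=self.glcm_window, glcm_stride=self.glcm_stride,
            glcm_feature=self.glcm_feature).array for x in X]
        return np.stack(stacks, axis=0)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
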
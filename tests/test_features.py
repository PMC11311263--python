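"""Feature kernels: Prewitt closed forms, Gabor bank, GLCM, feature stack."""

import numpy as np
import pytest

from mammocalc.features import (CHANNEL_NAMES, GABOR_CANONICAL,
                                GABOR_ORIENTATIONS, PREWITT_X, PREWITT_Y,
                                FeatureStackExtractor, KernelBank,
                                assemble_feature_stack, build_gabor_bank,
                                gabor_responses, glcm_compute, glcm_features,
                                glcm_offset, glcm_texture_map,
                                glcm_texture_samples, prewitt_response,
                                quantize)
from mammocalc.phantom import PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# Prewitt

def test_prewitt_kernels_entries():
    np.testing.assert_array_equal(PREWITT_X, [[-1, 0, 1]] * 3)
    np.testing.assert_array_equal(PREWITT_Y, [[-1, -1, -1], [0, 0, 0], [1, 1, 1]])


def test_prewitt_constant_zero():
    gx, gy = prewitt_response(np.full((9, 9), 0.7))
    np.testing.assert_allclose(gx[1:-1, 1:-1], 0.0, atol=1e-12)
    np.testing.assert_allclose(gy[1:-1, 1:-1], 0.0, atol=1e-12)


def test_prewitt_horizontal_ramp():
    """I(r, c) = c gives a horizontal-gradient response of 3*2 = 6."""
    img = np.tile(np.arange(10.0), (10, 1))
    gx, _ = prewitt_response(img)
    np.testing.assert_allclose(gx[1:-1, 1:-1], 6.0)


def test_prewitt_row_step():
    """A single bright row of height h peaks the vertical response at 3h."""
    h = 2.5
    img = np.zeros((11, 11))
    img[5, :] = h
    _, gy = prewitt_response(img)
    assert gy[4, 5] == pytest.approx(3 * h)
    assert gy[6, 5] == pytest.approx(-3 * h)


def test_prewitt_too_small():
    with pytest.raises(ValueError):
        prewitt_response(np.zeros((2, 5)))


# ---------------------------------------------------------------------------
# Gabor bank

def test_canonical_theta0_peak():
    assert GABOR_CANONICAL[0].max() == 0.7726


def test_canonical_theta0_symmetric():
    k = GABOR_CANONICAL[0]
    np.testing.assert_array_equal(k, k.T)
    np.testing.assert_array_equal(k, k[::-1, ::-1])


def test_canonical_bank_orientations():
    bank = build_gabor_bank("canonical")
    assert tuple(sorted(bank.gabor)) == GABOR_ORIENTATIONS
    for k in bank.gabor.values():
        assert k.shape == (5, 5)


def test_bank_save_load_round_trip(tmp_path):
    bank = build_gabor_bank("canonical")
    path = tmp_path / "bank.json"
    bank.save(path)
    loaded = KernelBank.load(path)
    assert loaded.mode == "canonical"
    np.testing.assert_array_equal(loaded.prewitt_x, bank.prewitt_x)
    for th in GABOR_ORIENTATIONS:
        np.testing.assert_array_equal(loaded.gabor[th], bank.gabor[th])


def test_parametric_degenerate_limit():
    bank = build_gabor_bank("parametric", frequency=1e-12, sigma=1e12,
                            gamma=1.0, psi=0.0)
    for k in bank.gabor.values():
        np.testing.assert_allclose(k, 1.0, atol=1e-6)


def test_unknown_mode():
    with pytest.raises(ValueError):
        build_gabor_bank("learned")


def test_gabor_zero_image():
    for m in gabor_responses(np.zeros((8, 8))).values():
        np.testing.assert_array_equal(m, 0.0)


def test_gabor_constant_image_interior():
    c = 0.4
    resp = gabor_responses(np.full((15, 15), c))
    for th, m in resp.items():
        expected = c * GABOR_CANONICAL[th].sum()
        np.testing.assert_allclose(m[2:-2, 2:-2], expected, rtol=1e-10)


def test_gabor_impulse_response_is_reflected_kernel():
    """The impulse response of a cross-correlation (filter convention, no
    kernel flip) is the point-reflected kernel stamped at the impulse."""
    img = np.zeros((11, 11))
    img[5, 5] = 1.0
    resp = gabor_responses(img)
    for th, m in resp.items():
        np.testing.assert_allclose(m[3:8, 3:8], GABOR_CANONICAL[th][::-1, ::-1],
                                   atol=1e-12)


def test_filter_linearity(rng):
    x = rng.random((12, 12))
    y = rng.random((12, 12))
    a, b = 2.5, -1.25
    gx_lin, _ = prewitt_response(a * x + b * y)
    gx_x, _ = prewitt_response(x)
    gx_y, _ = prewitt_response(y)
    np.testing.assert_allclose(gx_lin, a * gx_x + b * gx_y, atol=1e-10)
    r_lin = gabor_responses(a * x + b * y)[45]
    np.testing.assert_allclose(
        r_lin, a * gabor_responses(x)[45] + b * gabor_responses(y)[45], atol=1e-10)


# ---------------------------------------------------------------------------
# GLCM

def test_glcm_two_row_example():
    g = glcm_compute(np.array([[0, 0], [1, 1]]), levels=2, d=1, theta=0,
                     do_quantize=False)
    np.testing.assert_array_equal(g.counts, [[1, 0], [0, 1]])


def test_glcm_constant_window():
    g = glcm_compute(np.full((4, 5), 3.3), levels=8, d=1, theta=0)
    assert g.counts[0, 0] == 4 * 4
    assert g.counts.sum() == 4 * 4


@pytest.mark.parametrize("theta", [0, 45, 90, 135])
@pytest.mark.parametrize("d", [1, 2])
def test_glcm_total_matches_closed_form(rng, theta, d):
    """Total counts equal the in-bounds pair count (H-|dy|)(W-|dx|),
    and the full matrix matches an exhaustive pair enumeration."""
    for _ in range(8):
        H, W = rng.integers(3, 16, size=2)
        win = rng.integers(0, 4, size=(H, W))
        dx, dy = glcm_offset(d, theta)
        if abs(dy) >= H or abs(dx) >= W:
            continue
        g = glcm_compute(win, levels=4, d=d, theta=theta, do_quantize=False)
        assert g.counts.sum() == (H - abs(dy)) * (W - abs(dx))
        brute = np.zeros((4, 4), dtype=int)
        for r in range(H):
            for c in range(W):
                rr, cc = r + dy, c + dx
                if 0 <= rr < H and 0 <= cc < W:
                    brute[win[r, c], win[rr, cc]] += 1
        np.testing.assert_array_equal(g.counts, brute)


def test_glcm_matches_skimage(rng):
    """Independent cross-check against skimage's graycomatrix at theta=0."""
    from skimage.feature import graycomatrix

    win = rng.integers(0, 8, size=(10, 12)).astype(np.uint8)
    ours = glcm_compute(win, levels=8, d=1, theta=0, do_quantize=False)
    theirs = graycomatrix(win, distances=[1], angles=[0], levels=8,
                          symmetric=False, normed=False)[:, :, 0, 0]
    np.testing.assert_array_equal(ours.counts, theirs)


def test_glcm_offset_too_large():
    with pytest.raises(ValueError):
        glcm_compute(np.zeros((2, 2)), levels=2, d=5, theta=0)


def test_glcm_features_identity_diagonal():
    f = glcm_features(np.array([[1, 0], [0, 1]]))
    assert f.contrast == 0.0
    assert f.energy == 0.5
    assert f.homogeneity == 1.0
    assert f.correlation == 1.0


def test_glcm_features_anti_diagonal():
    f = glcm_features(np.array([[0, 1], [1, 0]]))
    assert f.contrast == 1.0
    assert f.correlation == -1.0


def test_glcm_features_constant_window():
    g = glcm_compute(np.full((4, 4), 2.0), levels=8)
    f = glcm_features(g)
    assert f.energy == 1.0
    assert f.contrast == 0.0
    assert f.correlation == 0.0   # defined as 0 at zero marginal variance


def test_glcm_feature_ranges(rng):
    for _ in range(50):
        win = rng.integers(0, 8, size=(6, 6))
        f = glcm_features(glcm_compute(win, levels=8, do_quantize=False))
        assert 0.0 < f.energy <= 1.0
        assert 0.0 < f.homogeneity <= 1.0
        assert f.contrast >= 0.0
        assert -1.0 - 1e-12 <= f.correlation <= 1.0 + 1e-12


def test_glcm_features_empty_rejected():
    with pytest.raises(ValueError):
        glcm_features(np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# texture map

def test_texture_map_constant_zero():
    m = glcm_texture_map(np.full((40, 40), 0.5), window_side=9, stride=4)
    np.testing.assert_array_equal(m, 0.0)


def test_texture_map_checkerboard_contrast():
    img = np.zeros((40, 80))
    img[:, 40:] = np.indices((40, 40)).sum(axis=0) % 2    # checkerboard half
    img[:, :40] = 0.5                                      # smooth half
    m = glcm_texture_map(img, window_side=9, stride=4)
    assert m[:, 48:].mean() > m[:, :32].mean()


def test_texture_map_stride_consistency():
    rng = np.random.default_rng(3)
    img = rng.random((48, 48))
    ws = 9
    r1, c1, f1 = glcm_texture_samples(img, window_side=ws, stride=ws)
    r2, c2, f2 = glcm_texture_samples(img, window_side=ws, stride=1)
    for i, r in enumerate(r1):
        for j, c in enumerate(c1):
            i2 = np.flatnonzero(r2 == r)[0]
            j2 = np.flatnonzero(c2 == c)[0]
            assert f1["contrast"][i, j] == pytest.approx(f2["contrast"][i2, j2])


def test_texture_map_window_too_large():
    with pytest.raises(ValueError):
        glcm_texture_map(np.zeros((8, 8)), window_side=9)


def test_texture_samples_agree_with_glcm_compute(rng):
    """Each window sample equals the pooled per-window GLCM computed directly
    on the globally quantized image."""
    img = rng.random((30, 30))
    ws, half = 9, 4
    q = quantize(img, 8)
    rs, cs, feats = glcm_texture_samples(img, window_side=ws, stride=7)
    for i, r in enumerate(rs):
        for j, c in enumerate(cs):
            win = q[r - half:r + half + 1, c - half:c + half + 1]
            pooled = np.zeros((8, 8), dtype=int)
            for th in (0, 45, 90, 135):
                pooled += glcm_compute(win, levels=8, d=1, theta=th,
                                       do_quantize=False).counts
            expected = glcm_features(pooled).contrast
            assert feats["contrast"][i, j] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# feature stack

def test_stack_zero_image():
    stack = assemble_feature_stack(np.zeros((64, 64)), out_side=32)
    np.testing.assert_array_equal(stack.array, 0.0)


def test_stack_shape_and_range(phantom_pos):
    img, _ = phantom_pos
    stack = assemble_feature_stack(img, out_side=64)
    assert stack.array.shape == (64, 64, 8)
    assert stack.names == CHANNEL_NAMES
    assert stack.array.min() >= 0.0 and stack.array.max() <= 1.0


def test_stack_spot_is_salient(phantom_pos):
    """A planted spot lands in the top 1% of at least one channel."""
    img, truth = phantom_pos
    side = img.shape[0]
    stack = assemble_feature_stack(img, out_side=side)
    spot = truth.spots[0]
    r, c = int(round(spot.row)), int(round(spot.col))
    hit = False
    for k in range(8):
        ch = stack.array[..., k]
        q99 = np.quantile(ch, 0.99)
        if ch[max(r - 2, 0):r + 3, max(c - 2, 0):c + 3].max() >= q99:
            hit = True
            break
    assert hit


def test_stack_save_load(tmp_path, phantom_pos):
    img, _ = phantom_pos
    stack = assemble_feature_stack(img, out_side=32)
    p = tmp_path / "stack.npz"
    stack.save(p)
    from mammocalc.features import FeatureStack
    loaded = FeatureStack.load(p)
    np.testing.assert_array_equal(loaded.array, stack.array)
    assert loaded.names == stack.names


def test_extractor_transform(phantom_pos, phantom_neg):
    fx = FeatureStackExtractor(out_side=32)
    X = fx.transform([phantom_pos[0], phantom_neg[0]])
    assert X.shape == (2, 32, 32, 8)
    assert fx.get_params()["out_side"] == 32
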
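import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shgtex.config import GLCMConfig
from shgtex.errors import EmptyPairError, InvalidParameterError, ShapeError
from shgtex.glcm import (
    PARAM_NAMES,
    THETAS,
    compute_glcm,
    glcm_stack,
    patch_roi_blocks,
    quantize_levels,
    roi_param_map,
    texture_params,
    texture_params_stack,
)

# ---------------------------------------------------------------------------
# independent oracles: literal nested-sum evaluation, written before the
# vectorized implementation and kept deliberately naive
# ---------------------------------------------------------------------------

_OFF = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_glcm(q, d, theta, levels, symmetric):
    """Pair counting with explicit python loops."""
    dr, dc = _OFF[theta][0] * d, _OFF[theta][1] * d
    counts = [[0.0] * levels for _ in range(levels)]
    h, w = q.shape
    total = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c]][q[r2, c2]] += 1
                total += 1
                if symmetric:
                    counts[q[r2, c2]][q[r, c]] += 1
                    total += 1
    return np.array(counts) / total


def oracle_params(p):
    """Literal double-loop evaluation of the eight texture parameters."""
    n = p.shape[0]
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    py = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mu_i = sum(i * px[i] for i in range(n))
    mu_j = sum(j * py[j] for j in range(n))
    si = math.sqrt(sum((i - mu_i) ** 2 * px[i] for i in range(n)))
    sj = math.sqrt(sum((j - mu_j) ** 2 * py[j] for j in range(n)))
    if si * sj > 0:
        correlation = sum(
            (i - mu_i) * (j - mu_j) * p[i][j] for i in range(n) for j in range(n)
        ) / (si * sj)
    else:
        correlation = 0.0
    asm = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(n) for j in range(n))
    idm = sum(p[i][j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    entropy = -sum(
        p[i][j] * math.log(p[i][j])
        for i in range(n)
        for j in range(n)
        if p[i][j] > 0
    )
    pxy = [0.0] * (2 * n - 1)
    for i in range(n):
        for j in range(n):
            pxy[i + j] += p[i][j]
    sum_entropy = -sum(q * math.log(q) for q in pxy if q > 0)
    sum_average = sum(s * pxy[s] for s in range(2 * n - 1))
    sum_variance = sum((s - sum_average) ** 2 * pxy[s] for s in range(2 * n - 1))
    return np.array(
        [correlation, asm, contrast, idm, entropy, sum_entropy, sum_average, sum_variance]
    )


# ---------------------------------------------------------------------------
# quantize_levels
# ---------------------------------------------------------------------------


def test_quantize_constant_endpoint():
    roi = np.full((8, 8), 255)
    assert np.all(quantize_levels(roi, 8) == 7)


def test_quantize_two_levels_boundary():
    # bin edge at 128.0, right-open bins
    assert quantize_levels(np.array([0, 128, 255]), 2).tolist() == [0, 1, 1]


def test_quantize_identity_at_256():
    roi = np.arange(256).reshape(16, 16)
    assert np.array_equal(quantize_levels(roi, 256), roi)


def test_quantize_invalid_levels():
    with pytest.raises(InvalidParameterError):
        quantize_levels(np.zeros((4, 4), dtype=int), 1)


@given(
    values=st.lists(st.integers(0, 255), min_size=2, max_size=30),
    levels=st.integers(2, 64),
)
def test_quantize_order_preserving(values, levels):
    arr = np.array(values)
    q = quantize_levels(arr, levels)
    assert q.min() >= 0 and q.max() <= levels - 1
    order = np.argsort(arr, kind="stable")
    assert np.all(np.diff(q[order]) >= 0)


# ---------------------------------------------------------------------------
# compute_glcm
# ---------------------------------------------------------------------------


def test_glcm_constant_roi_single_entry():
    roi = np.full((8, 8), 100)
    g = compute_glcm(roi, d=1, theta=0, levels=8)
    v = quantize_levels(np.array([100]), 8)[0]
    expected = np.zeros((8, 8))
    expected[v, v] = 1.0
    assert np.allclose(g.p, expected)


def test_glcm_two_by_two_hand_enumeration():
    # [[0,1],[0,1]] at theta=0: ordered pairs (0,1) twice; symmetric doubles
    roi = np.array([[0, 255], [0, 255]])
    g = compute_glcm(roi, d=1, theta=0, levels=2, symmetric=True)
    assert np.allclose(g.p, [[0.0, 0.5], [0.5, 0.0]])


@pytest.mark.parametrize("theta", THETAS)
def test_glcm_sums_to_one(rng, theta):
    roi = rng.integers(0, 256, size=(10, 10))
    g = compute_glcm(roi, d=1, theta=theta, levels=8)
    assert abs(g.p.sum() - 1.0) < 1e-9


@pytest.mark.parametrize("theta", THETAS)
def test_glcm_symmetric_mode_exact(rng, theta):
    roi = rng.integers(0, 256, size=(9, 9))
    g = compute_glcm(roi, d=1, theta=theta, levels=8, symmetric=True)
    assert np.array_equal(g.p, g.p.T)


def test_glcm_empty_pair_error():
    with pytest.raises(EmptyPairError):
        compute_glcm(np.zeros((2, 2), dtype=int), d=2, theta=0, levels=2)


@pytest.mark.parametrize("theta", THETAS)
@pytest.mark.parametrize("symmetric", [True, False])
def test_glcm_matches_pair_counting_oracle(rng, theta, symmetric):
    for _ in range(10):
        side = int(rng.integers(4, 17))
        levels = int(rng.integers(2, 17))
        roi = rng.integers(0, 256, size=(side, side))
        q = quantize_levels(roi, levels)
        g = compute_glcm(roi, d=1, theta=theta, levels=levels, symmetric=symmetric)
        assert np.allclose(g.p, oracle_glcm(q, 1, theta, levels, symmetric), atol=1e-12)


def test_glcm_stack_matches_single(rng):
    blocks = rng.integers(0, 8, size=(12, 8, 8))
    for theta in THETAS:
        stack = glcm_stack(blocks, d=1, theta=theta, levels=8)
        for m in range(12):
            single = compute_glcm(blocks[m], d=1, theta=theta, levels=8, prequantized=True)
            assert np.allclose(stack[m], single.p, atol=1e-14)


# ---------------------------------------------------------------------------
# texture_params
# ---------------------------------------------------------------------------


def test_constant_image_limits():
    v = 3  # quantized level of gray 100 at 8 levels
    g = compute_glcm(np.full((8, 8), 100), d=1, theta=0, levels=8)
    tp = texture_params(g)
    assert tp.asm == pytest.approx(1.0)
    assert tp.idm == pytest.approx(1.0)
    assert tp.contrast == pytest.approx(0.0)
    assert tp.entropy == pytest.approx(0.0)
    assert tp.sum_entropy == pytest.approx(0.0)
    assert tp.sum_average == pytest.approx(2 * v)
    assert tp.sum_variance == pytest.approx(0.0)
    assert tp.correlation == 0.0  # degenerate-sigma convention


def test_two_level_checkerboard_values():
    # hand-evaluated on p = [[0, .5], [.5, 0]]
    p = np.array([[0.0, 0.5], [0.5, 0.0]])
    tp = texture_params(p)
    assert tp.contrast == pytest.approx(1.0)
    assert tp.asm == pytest.approx(0.5)
    assert tp.idm == pytest.approx(0.5)
    assert tp.correlation == pytest.approx(-1.0)
    assert tp.entropy == pytest.approx(math.log(2))
    assert tp.sum_entropy == pytest.approx(0.0)
    assert tp.sum_average == pytest.approx(1.0)
    assert tp.sum_variance == pytest.approx(0.0)


def test_params_match_literal_sum_oracle(rng):
    """Oracle equivalence: >=100 random ROIs, all four thetas, 1e-10."""
    checked = 0
    while checked < 100:
        side = int(rng.integers(4, 17))
        levels = int(rng.integers(2, 17))
        roi = rng.integers(0, 256, size=(side, side))
        for theta in THETAS:
            g = compute_glcm(roi, d=1, theta=theta, levels=levels)
            got = texture_params(g).as_array()
            want = oracle_params(g.p)
            assert np.allclose(got, want, atol=1e-10), (side, levels, theta)
        checked += 1


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_params_invariant_ranges(seed):
    rng = np.random.default_rng(seed)
    levels = int(rng.integers(2, 12))
    roi = rng.integers(0, 256, size=(8, 8))
    tp = texture_params(compute_glcm(roi, levels=levels))
    assert 0 < tp.asm <= 1 + 1e-12
    assert 0 < tp.idm <= 1 + 1e-12
    assert tp.contrast >= 0
    assert tp.entropy >= 0
    assert tp.sum_entropy >= 0
    assert -1 - 1e-12 <= tp.correlation <= 1 + 1e-12
    assert 0 <= tp.sum_average <= 2 * levels - 2 + 1e-12
    assert tp.sum_variance >= 0


def test_asm_never_increases_with_noise_amplitude():
    """Mean ASM over seeds is non-increasing in uniform-noise amplitude."""
    amplitudes = [0, 16, 48, 96, 200]
    means = []
    for amp in amplitudes:
        vals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            roi = np.clip(100 + rng.uniform(0, amp, size=(8, 8)), 0, 255).astype(int)
            vals.append(texture_params(compute_glcm(roi, levels=8)).asm)
        means.append(np.mean(vals))
    assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# roi_param_map
# ---------------------------------------------------------------------------


def test_param_map_constant_patch():
    patch = np.full((64, 64), 120)
    assert np.allclose(roi_param_map(patch, "idm", 0), np.ones((8, 8)))
    assert np.allclose(roi_param_map(patch, "contrast", 0), np.zeros((8, 8)))


def test_param_map_shape_error():
    with pytest.raises(ShapeError):
        roi_param_map(np.zeros((32, 32), dtype=int), "asm", 0)


def test_param_map_unknown_parameter():
    with pytest.raises(InvalidParameterError):
        roi_param_map(np.zeros((64, 64), dtype=int), "energy2", 0)


def test_param_map_dark_disc_has_higher_asm(rng):
    """Constant dark lacuna cells score higher ASM than noisy matrix cells."""
    patch = rng.integers(60, 200, size=(64, 64))
    rr, cc = np.mgrid[0:64, 0:64]
    patch[(rr - 32) ** 2 + (cc - 32) ** 2 <= 12**2] = 2
    amap = roi_param_map(patch, "asm", 0)
    inside = amap[3:5, 3:5].mean()  # cells fully inside the disc
    corners = np.mean([amap[0, 0], amap[0, 7], amap[7, 0], amap[7, 7]])
    assert inside > corners


def test_patch_roi_blocks_layout():
    patch = np.arange(64 * 64).reshape(64, 64)
    blocks = patch_roi_blocks(patch, 8)
    assert blocks.shape == (64, 8, 8)
    # block (a, b) is rows 8a:8a+8, cols 8b:8b+8
    assert np.array_equal(blocks[8 * 2 + 3], patch[16:24, 24:32])


def test_param_names_cover_all_eight():
    assert len(PARAM_NAMES) == 8
    stack = texture_params_stack(np.array([[[0.0, 0.5], [0.5, 0.0]]]))
    assert stack.shape == (1, 8)
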
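"""GLCM, GLRL, Laws, LBP and box-counting against brute-force oracles."""

import math

import numpy as np
import pytest

from octfluid.features import (dbc_box_counts, extract_fd, extract_glcm,
                               extract_glrl, extract_laws, extract_lbp,
                               glcm_matrix, glcm_props, glrl_matrix,
                               glrl_stats, laws_energy_map, lbp_code_map,
                               local_fractal_dimension)
from octfluid.features.texture import (DBC_SCALES, GLCM_LEVELS, GLCM_OFFSETS,
                                       GLRL_LEVELS, LAWS_MAPS)

from conftest import random_blocks

# ---------------------------------------------------------------------------
# oracles


def oracle_glcm_matrix(block, offset, levels=GLCM_LEVELS):
    q = (np.clip(block, 0, 255).astype(int) * levels // 256)
    h, w = q.shape
    dr, dc = offset
    mat = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                mat[q[r, c], q[r2, c2]] += 1
                mat[q[r2, c2], q[r, c]] += 1          # symmetric
    s = mat.sum()
    return mat / s if s else mat


def oracle_glcm_props(mat):
    levels = mat.shape[0]
    contrast = sum(mat[i, j] * (i - j) ** 2
                   for i in range(levels) for j in range(levels))
    energy = sum(mat[i, j] ** 2 for i in range(levels) for j in range(levels))
    homog = sum(mat[i, j] / (1 + abs(i - j))
                for i in range(levels) for j in range(levels))
    pi = mat.sum(axis=1)
    mu = sum(i * pi[i] for i in range(levels))
    var = sum((i - mu) ** 2 * pi[i] for i in range(levels))
    if var > 0:
        corr = sum((i - mu) * (j - mu) * mat[i, j]
                   for i in range(levels) for j in range(levels)) / var
    else:
        corr = 0.0
    return contrast, corr, energy, homog


def oracle_glrl_runs(block, orientation, levels=GLRL_LEVELS):
    """Explicit run enumeration by walking every scan line pixel by pixel."""
    q = (np.clip(block, 0, 255).astype(int) * levels // 256)
    h, w = q.shape
    steps = {0: (0, 1), 90: (1, 0), 135: (1, 1), 45: (-1, 1)}
    dr, dc = steps[orientation]
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    mat = np.zeros((levels, max(h, w)))
    for r0, c0 in starts:
        line = []
        r, c = r0, c0
        while 0 <= r < h and 0 <= c < w:
            line.append(q[r, c])
            r, c = r + dr, c + dc
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            mat[line[i], j - i - 1] += 1
            i = j
    return mat


def oracle_lbp_codes(block, P, R):
    img = np.asarray(block, float)
    h, w = img.shape
    m = int(np.ceil(R))
    out = np.zeros((h - 2 * m, w - 2 * m), dtype=np.int64)
    for r in range(m, h - m):
        for c in range(m, w - m):
            code = 0
            for p in range(P):
                a = 2 * math.pi * p / P
                y = r - R * math.sin(a)
                x = c + R * math.cos(a)
                if abs(y - round(y)) < 1e-9:
                    y = round(y)
                if abs(x - round(x)) < 1e-9:
                    x = round(x)
                y0, x0 = int(math.floor(y)), int(math.floor(x))
                fy, fx = y - y0, x - x0
                y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                val = ((1 - fy) * (1 - fx) * img[y0, x0]
                       + (1 - fy) * fx * img[y0, x1]
                       + fy * (1 - fx) * img[y1, x0]
                       + fy * fx * img[y1, x1])
                if val - img[r, c] >= 0:
                    code |= 1 << p
            out[r - m, c - m] = code
    return out


def oracle_conv_valid(block, kernel):
    kh, kw = kernel.shape
    h, w = block.shape
    out = np.zeros((h - kh + 1, w - kw + 1))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            for i in range(kh):
                for j in range(kw):
                    out[r, c] += kernel[kh - 1 - i, kw - 1 - j] * block[r + i, c + j]
    return out


def oracle_dbc_dimension(window, scales=DBC_SCALES):
    m = window.shape[0]
    xs, ys = [], []
    for s in scales:
        n = m // s
        total = 0
        for bi in range(n):
            for bj in range(n):
                cell = window[bi * s:(bi + 1) * s, bj * s:(bj + 1) * s]
                box_h = s * 256 / m
                total += int((cell.max() - cell.min()) // box_h) + 1
        xs.append(math.log(1 / s))
        ys.append(math.log(total))
    xbar, ybar = sum(xs) / len(xs), sum(ys) / len(ys)
    return (sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
            / sum((x - xbar) ** 2 for x in xs))


# ---------------------------------------------------------------------------
# GLCM


class TestGLCM:
    def test_constant_block(self):
        v = extract_glcm(np.full((8, 8), 50.0))
        contrast, corr, energy, homog = v[:4], v[4:8], v[8:12], v[12:16]
        assert (contrast == 0).all() and (corr == 0).all()
        assert (energy == 1).all() and (homog == 1).all()

    def test_checkerboard_zero_contrast_at_distance_two(self):
        cb = (np.indices((4, 4)).sum(axis=0) % 2) * 255.0
        mat = glcm_matrix(cb, (0, 2))
        assert glcm_props(mat)[0] == 0.0

    @pytest.mark.parametrize("block", random_blocks(8, max_side=6, seed=11))
    def test_matches_pair_counting_oracle(self, block):
        mine = extract_glcm(block)
        expected = []
        props = [oracle_glcm_props(oracle_glcm_matrix(block, off))
                 for off in GLCM_OFFSETS]
        for stat in range(4):
            expected += [props[a][stat] for a in range(4)]
        assert np.allclose(mine, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# GLRL


class TestGLRL:
    def test_constant_block_closed_form_single_orientation(self):
        n = 5
        mat = glrl_matrix(np.full((n, n), 100.0), 0)
        sre, lre, _, rp, *_ = glrl_stats(mat, n * n)
        assert sre == pytest.approx(1 / n**2)
        assert lre == pytest.approx(n**2)
        assert rp == pytest.approx(1 / n)

    def test_alternating_stripes_unit_runs(self):
        stripes = np.tile(np.array([0.0, 255.0]), (4, 3))
        stats = glrl_stats(glrl_matrix(stripes, 0), stripes.size)
        assert stats[0] == 1.0          # SRE: every horizontal run has length 1

    @pytest.mark.parametrize("block", random_blocks(6, max_side=5, seed=21, hi=256))
    def test_matrix_and_stats_match_scanline_oracle(self, block):
        for orient in (0, 45, 90, 135):
            assert np.array_equal(glrl_matrix(block, orient),
                                  oracle_glrl_runs(block, orient))
        summed = sum(oracle_glrl_runs(block, o) for o in (0, 45, 90, 135))
        expected = glrl_stats(summed, 4 * block.size)
        assert np.allclose(extract_glrl(block), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# Laws


class TestLaws:
    def test_constant_block_all_zero(self):
        assert (extract_laws(np.full((9, 9), 31.0)) == 0).all()

    def test_vertical_ramp_responses(self):
        ramp = np.tile(np.arange(20.0)[:, None], (1, 20))
        assert np.abs(laws_energy_map(ramp, "l3e3")).min() > 0
        assert np.abs(laws_energy_map(ramp, "s3s3")).max() == 0
        assert np.abs(laws_energy_map(ramp, "r5r5")).max() == 0

    @pytest.mark.parametrize("block", random_blocks(3, min_side=7, max_side=7, seed=31))
    def test_maps_match_naive_convolution(self, block):
        for name, pairs in LAWS_MAPS:
            expected = np.mean(
                [np.abs(oracle_conv_valid(block, np.outer(v, h)))
                 for v, h in pairs], axis=0)
            assert np.allclose(laws_energy_map(block, name), expected, atol=1e-9)


# ---------------------------------------------------------------------------
# LBP


class TestLBP:
    def test_constant_block_single_all_geq_code(self):
        v = extract_lbp(np.full((20, 20), 9.0))
        means, sds = v[:32], v[32:]
        assert (sds == 0).all()
        # neighbors-major order: first 8 configs are P=4 -> code 15
        assert (means[:8] == 15).all()
        assert (means[8:16] == 255).all()

    def test_hand_computed_5x5_center_code(self):
        block = np.array([[5, 5, 5, 5, 5],
                          [5, 9, 1, 9, 5],
                          [5, 1, 5, 1, 5],
                          [5, 9, 1, 9, 5],
                          [5, 5, 5, 5, 5]], float)
        codes = lbp_code_map(block, 8, 1)
        # center pixel: neighbors E,NE,N,...,SE = 1,9,1,9,1,9,1,9 vs center 5
        # bits (>=): 0,1,0,1,0,1,0,1 -> 0b10101010 = 170
        assert codes[1, 1] == 170

    def test_global_shift_leaves_codes_bit_identical(self, rng):
        block = rng.integers(0, 236, (25, 25)).astype(float)
        assert np.array_equal(extract_lbp(block), extract_lbp(block + 20))

    @pytest.mark.parametrize("P,R", [(4, 1), (8, 1), (8, 2), (12, 2), (16, 3)])
    def test_codes_match_per_pixel_oracle(self, P, R, rng):
        block = rng.integers(0, 256, (12, 12)).astype(float)
        assert np.array_equal(lbp_code_map(block, P, R),
                              oracle_lbp_codes(block, P, R))


# ---------------------------------------------------------------------------
# Fractal dimension


class TestFD:
    def test_flat_surface_dimension_two(self):
        v = extract_fd(np.full((32, 32), 77.0))
        assert v[0] == pytest.approx(2.0, abs=1e-9)
        assert v[1] == 0.0 and v[2] == 0.0

    def test_shift_invariance(self, rng):
        block = rng.integers(0, 200, (32, 32)).astype(float)
        assert np.array_equal(extract_fd(block), extract_fd(block + 30))

    @pytest.mark.parametrize("seed", range(5))
    def test_local_dimension_matches_loop_oracle(self, seed):
        win = np.random.default_rng(seed).integers(0, 256, (16, 16)).astype(float)
        assert local_fractal_dimension(win) == pytest.approx(
            oracle_dbc_dimension(win), abs=1e-9)

    def test_box_counts_match_span_definition(self, rng):
        win = rng.integers(0, 256, (16, 16)).astype(float)
        counts = dbc_box_counts(win, 4)
        for bi in range(4):
            for bj in range(4):
                cell = win[bi * 4:(bi + 1) * 4, bj * 4:(bj + 1) * 4]
                expected = int((cell.max() - cell.min()) // (4 * 256 / 16)) + 1
                assert counts[bi, bj] == expected
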
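"""Matrix- and kernel-based texture descriptors: GLCM, LBP, Laws, DBC, GLRL."""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d

# ---------------------------------------------------------------------------
# Gray-level co-occurrence matrix

GLCM_OFFSETS = ((0, 2), (-2, 2), (-2, 0), (-2, -2))  # 0, 45, 90, 135 degrees
GLCM_LEVELS = 8


def glcm_matrix(block: np.ndarray, offset: tuple[int, int],
                levels: int = GLCM_LEVELS) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one displacement.

    Gray levels are quantized by uniform binning of [0, 255] into ``levels``.
    """
    q = np.clip(np.asarray(block), 0, 255).astype(int) * levels // 256
    dr, dc = offset
    h, w = q.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = q[r0, c0].ravel()
    b = q[r1, c1].ravel()
    mat = np.bincount(a * levels + b, minlength=levels * levels).astype(float)
    mat = mat.reshape(levels, levels)
    mat = mat + mat.T
    total = mat.sum()
    return mat / total if total > 0 else mat


def glcm_props(mat: np.ndarray) -> tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity) of a normalized matrix.

    Energy is the angular second moment; homogeneity uses 1/(1+|i-j|);
    correlation maps the zero-variance case to 0.
    """
    levels = mat.shape[0]
    i, j = np.mgrid[0:levels, 0:levels]
    contrast = float((mat * (i - j) ** 2).sum())
    energy = float((mat**2).sum())
    homogeneity = float((mat / (1.0 + np.abs(i - j))).sum())
    pi = mat.sum(axis=1)
    mu_i = (np.arange(levels) * pi).sum()
    var_i = ((np.arange(levels) - mu_i) ** 2 * pi).sum()
    if var_i > 0:  # symmetric matrix: both marginals identical
        corr = float(((i - mu_i) * (j - mu_i) * mat).sum() / var_i)
    else:
        corr = 0.0
    return contrast, corr, energy, homogeneity


def extract_glcm(block: np.ndarray) -> np.ndarray:
    """16 co-occurrence statistics: 4 properties x 4 angles (distance 2)."""
    props = [glcm_props(glcm_matrix(block, off)) for off in GLCM_OFFSETS]
    out = []
    for stat_idx in range(4):  # contrast, correlation, energy, homogeneity
        out += [props[a][stat_idx] for a in range(4)]
    return np.array(out)


# ---------------------------------------------------------------------------
# Local binary patterns

LBP_NEIGHBORS = (4, 8, 12, 16)
LBP_RADII = tuple(range(1, 9))


def lbp_code_map(block: np.ndarray, n_neighbors: int, radius: float) -> np.ndarray:
    """Rotation-variant LBP codes on the valid interior of the block.

    Neighbor p sits at angle 2*pi*p/P counter-clockwise from east; sampled
    values are bilinearly interpolated.  The comparison is evaluated on
    neighbor-minus-center differences, so a global additive intensity shift
    leaves every code bit-identical.
    """
    img = np.asarray(block, dtype=np.float64)
    h, w = img.shape
    m = int(np.ceil(radius))
    if h - 2 * m < 1 or w - 2 * m < 1:
        raise ValueError(f"block too small for LBP radius {radius}")
    center = img[m:h - m, m:w - m]
    codes = np.zeros(center.shape, dtype=np.int64)
    rr, cc = np.mgrid[m:h - m, m:w - m]
    for p in range(n_neighbors):
        angle = 2.0 * np.pi * p / n_neighbors
        dr = -radius * np.sin(angle)
        dc = radius * np.cos(angle)
        if abs(dr - round(dr)) < 1e-9:
            dr = round(dr)
        if abs(dc - round(dc)) < 1e-9:
            dc = round(dc)
        y = rr + dr
        x = cc + dc
        y0 = np.floor(y).astype(int)
        x0 = np.floor(x).astype(int)
        fy = y - y0
        fx = x - x0
        y1 = np.clip(y0 + 1, 0, h - 1)
        x1 = np.clip(x0 + 1, 0, w - 1)
        # interpolate the neighbor-center difference (exact shift invariance)
        diff = ((1 - fy) * (1 - fx) * (img[y0, x0] - center)
                + (1 - fy) * fx * (img[y0, x1] - center)
                + fy * (1 - fx) * (img[y1, x0] - center)
                + fy * fx * (img[y1, x1] - center))
        codes += (diff >= 0).astype(np.int64) << p
    return codes


def extract_lbp(block: np.ndarray) -> np.ndarray:
    """64 LBP statistics: mean then sd of the code map for each of the 32
    (neighbors, radius) configurations, neighbors-major."""
    means, sds = [], []
    for p in LBP_NEIGHBORS:
        for r in LBP_RADII:
            codes = lbp_code_map(block, p, r).astype(float)
            means.append(codes.mean())
            sds.append(codes.std())
    return np.array(means + sds)


# ---------------------------------------------------------------------------
# Laws texture-energy maps

_K3 = {"l3": np.array([1.0, 2, 1]), "e3": np.array([-1.0, 0, 1]),
       "s3": np.array([-1.0, 2, -1])}
_K5 = {"l5": np.array([1.0, 4, 6, 4, 1]), "e5": np.array([-1.0, -2, 0, 2, 1]),
       "s5": np.array([-1.0, 0, 2, 0, -1]), "r5": np.array([1.0, -4, 6, -4, 1])}

# Within each family every outer product is formed, transposed pairs are
# averaged, and the pure smoothing map (LL) is dropped: 5 maps from the 3x3
# family + 9 from the 5x5 family = 14.  A map name "ab" denotes the pair
# (a vertical, b horizontal) averaged with its transpose when a != b.
_ORDER3 = ["e3e3", "s3s3", "l3e3", "l3s3", "e3s3"]
_ORDER5 = ["e5e5", "s5s5", "r5r5", "l5e5", "l5s5", "l5r5", "e5s5", "e5r5", "s5r5"]
_KERNELS_1D = {**_K3, **_K5}


def _laws_pairs(name: str) -> list[tuple[np.ndarray, np.ndarray]]:
    a, b = name[:2], name[2:]
    pairs = [(_KERNELS_1D[a], _KERNELS_1D[b])]
    if a != b:
        pairs.append((_KERNELS_1D[b], _KERNELS_1D[a]))
    return pairs


LAWS_MAPS = [(n, _laws_pairs(n)) for n in _ORDER3 + _ORDER5]
_BY_NAME = dict(LAWS_MAPS)


def laws_energy_map(block: np.ndarray, name: str) -> np.ndarray:
    """Absolute filter response of one Laws map ('valid' region).

    Transposed kernel pairs are averaged after taking absolute responses.
    """
    block = np.asarray(block, dtype=float)
    responses = []
    for vert, horiz in _BY_NAME[name]:
        kernel = np.outer(vert, horiz)
        responses.append(np.abs(convolve2d(block, kernel, mode="valid")))
    return np.mean(responses, axis=0)


def extract_laws(block: np.ndarray) -> np.ndarray:
    """28 Laws statistics: 14 map means then 14 map standard deviations."""
    means, sds = [], []
    for name, _ in LAWS_MAPS:
        emap = laws_energy_map(block, name)
        means.append(emap.mean())
        sds.append(emap.std())
    return np.array(means + sds)


# ---------------------------------------------------------------------------
# Differential box-counting fractal dimension

DBC_SCALES = (2, 4, 8)
DBC_WINDOW = 16
DBC_STRIDE = 8
_GRAY_LEVELS = 256


def dbc_box_counts(window: np.ndarray, scale: int) -> np.ndarray:
    """Per-cell differential box counts of one local window at one scale.

    The box height is s * G / M (G = 256 gray levels, M = window side), so
    counts depend only on intensity spans and are shift-invariant.
    """
    win = np.asarray(window, dtype=float)
    m = win.shape[0]
    n = m // scale
    cells = win[:n * scale, :n * scale].reshape(n, scale, n, scale)
    span = cells.max(axis=(1, 3)) - cells.min(axis=(1, 3))
    box_h = scale * _GRAY_LEVELS / m
    return np.floor(span / box_h).astype(int) + 1


def local_fractal_dimension(window: np.ndarray,
                            scales: tuple[int, ...] = DBC_SCALES) -> float:
    """Least-squares slope of log N(s) against log(1/s) for one window."""
    logs, logN = [], []
    for s in scales:
        n = dbc_box_counts(window, s).sum()
        logs.append(np.log(1.0 / s))
        logN.append(np.log(n))
    slope, _ = np.polyfit(logs, logN, 1)
    return float(slope)


def extract_fd(block: np.ndarray) -> np.ndarray:
    """3 fractal features: mean and sd of the local DBC dimension map, and
    lacunarity (var/mean^2) of the finest-scale box-count distribution."""
    block = np.asarray(block, dtype=float)
    h, w = block.shape
    window = DBC_WINDOW if min(h, w) >= DBC_WINDOW else 8
    if min(h, w) < window:
        raise ValueError("block must be at least 8x8 for fractal features")
    stride = max(1, window // 2)
    dims, masses = [], []
    for r in range(0, h - window + 1, stride):
        for c in range(0, w - window + 1, stride):
            win = block[r:r + window, c:c + window]
            dims.append(local_fractal_dimension(win))
            masses.append(dbc_box_counts(win, DBC_SCALES[0]).ravel())
    dims = np.array(dims)
    masses = np.concatenate(masses).astype(float)
    mmean = masses.mean()
    lac = float(masses.var() / mmean**2) if mmean > 0 else 0.0
    return np.array([dims.mean(), dims.std(), lac])


# ---------------------------------------------------------------------------
# Gray-level run-length statistics

GLRL_LEVELS = 51


def _quantize_glrl(block: np.ndarray, levels: int = GLRL_LEVELS) -> np.ndarray:
    return np.clip(np.asarray(block), 0, 255).astype(int) * levels // 256


def _accumulate_line(mat: np.ndarray, line: np.ndarray) -> None:
    if line.size == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [line.size]])
    for s, e in zip(starts, ends):
        mat[line[s], e - s - 1] += 1


def glrl_matrix(block: np.ndarray, orientation: int,
                levels: int = GLRL_LEVELS) -> np.ndarray:
    """Run-length matrix (levels x max_run_length) for one orientation.

    Orientations are 0 (rows, left-right), 45 (up-right diagonals), 90
    (columns, top-down), 135 (down-right diagonals), in degrees.
    """
    q = _quantize_glrl(block, levels)
    h, w = q.shape
    mat = np.zeros((levels, max(h, w)), dtype=float)
    if orientation == 0:
        lines = [q[r, :] for r in range(h)]
    elif orientation == 90:
        lines = [q[:, c] for c in range(w)]
    elif orientation == 135:
        lines = [np.diagonal(q, offset=k) for k in range(-(h - 1), w)]
    elif orientation == 45:
        flipped = q[::-1]
        lines = [np.diagonal(flipped, offset=k) for k in range(-(h - 1), w)]
    else:
        raise ValueError("orientation must be one of 0, 45, 90, 135")
    for line in lines:
        _accumulate_line(mat, np.ascontiguousarray(line))
    return mat


def glrl_stats(mat: np.ndarray, n_pixels: int) -> np.ndarray:
    """The 7 run-length statistics (SRE, LRE, GLN, RP, RLN, LGRE, HGRE).

    Gray-level weights use 1-based level indices; RP divides the number of
    runs by the number of scanned pixels.
    """
    nr = mat.sum()
    if nr == 0:
        return np.zeros(7)
    j = np.arange(1, mat.shape[1] + 1, dtype=float)
    g = np.arange(1, mat.shape[0] + 1, dtype=float)
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    sre = (col / j**2).sum() / nr
    lre = (col * j**2).sum() / nr
    gln = (row**2).sum() / nr
    rp = nr / n_pixels
    rln = (col**2).sum() / nr
    lgre = (row / g**2).sum() / nr
    hgre = (row * g**2).sum() / nr
    return np.array([sre, lre, gln, rp, rln, lgre, hgre])


def extract_glrl(block: np.ndarray) -> np.ndarray:
    """7 run-length statistics of the matrix summed over the 4 orientations."""
    block = np.asarray(block)
    h, w = block.shape
    summed = sum(glrl_matrix(block, o) for o in (0, 45, 90, 135))
    return glrl_stats(summed, n_pixels=4 * h * w)
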
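"""Intensity-statistics descriptors: global statistics, axis moments, spectrum.

All statistics use the population (n) convention for variance-type moments
unless noted; the normal-fit slots follow the usual maximum-likelihood fit
with 95% confidence bounds (Student-t for the mean, chi-square for the
standard deviation, which uses the unbiased n-1 estimate as the usual fit
output does).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from ..sampling import max_inscribed_rect


def extract_gibs(block: np.ndarray) -> np.ndarray:
    """15 global intensity statistics of the block.

    Order: max, min, mean, median, sd, variance, entropy (bits, 256-bin
    histogram), p25, p75, then the normal-fit values mu, sigma, and 95%
    confidence bounds (mu_lo, mu_hi, sigma_lo, sigma_hi).
    """
    flat = np.asarray(block, dtype=float).ravel()
    n = flat.size
    counts = np.bincount(np.clip(flat, 0, 255).astype(int), minlength=256)
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())

    mu = flat.mean()
    sd_pop = flat.std()
    s = flat.std(ddof=1) if n > 1 else 0.0
    if s > 0:
        tcrit = sps.t.ppf(0.975, n - 1)
        mu_lo = mu - tcrit * s / np.sqrt(n)
        mu_hi = mu + tcrit * s / np.sqrt(n)
        sigma_lo = s * np.sqrt((n - 1) / sps.chi2.ppf(0.975, n - 1))
        sigma_hi = s * np.sqrt((n - 1) / sps.chi2.ppf(0.025, n - 1))
    else:
        mu_lo = mu_hi = mu
        sigma_lo = sigma_hi = 0.0
    return np.array([
        flat.max(), flat.min(), mu, np.median(flat), sd_pop, flat.var(),
        entropy, np.percentile(flat, 25), np.percentile(flat, 75),
        mu, s, mu_lo, mu_hi, sigma_lo, sigma_hi,
    ])


def _axis_skew_kurt(arr: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Population skewness and (Pearson) kurtosis of each 1-D slice.

    Zero-variance slices contribute 0 to both (degenerate-moment convention).
    """
    arr = np.asarray(arr, dtype=float)
    m = arr.mean(axis=axis, keepdims=True)
    d = arr - m
    m2 = (d**2).mean(axis=axis)
    m3 = (d**3).mean(axis=axis)
    m4 = (d**4).mean(axis=axis)
    safe_m2 = np.where(m2 > 0, m2, 1.0)
    skew = np.where(m2 > 0, m3 / safe_m2**1.5, 0.0)
    kurt = np.where(m2 > 0, m4 / safe_m2**2, 0.0)
    return skew, kurt


def extract_ais(block: np.ndarray) -> np.ndarray:
    """12 axis intensity statistics.

    Skewness and kurtosis are computed along each row ("horizontal") and each
    column ("vertical"); the min, mean and max of each series are emitted in
    groups of four: (skew.h, skew.v, kurt.h, kurt.v).
    """
    block = np.asarray(block, dtype=float)
    skew_h, kurt_h = _axis_skew_kurt(block, axis=1)
    skew_v, kurt_v = _axis_skew_kurt(block, axis=0)
    out = []
    for agg in (np.min, np.mean, np.max):
        out += [agg(skew_h), agg(skew_v), agg(kurt_h), agg(kurt_v)]
    return np.array(out)


def _spectrum(rect: np.ndarray) -> np.ndarray:
    """Descending singular values of the column-mean-centered rectangle."""
    centered = rect - rect.mean(axis=0, keepdims=True)
    return np.linalg.svd(centered, compute_uv=False)


def _safe_ratio(a: float, b: float) -> float:
    return a / b if b != 0 else 0.0


def extract_eigen(block: np.ndarray, roi_sub: np.ndarray | None = None) -> np.ndarray:
    """28 spectral features of the maximum ROI rectangle inside the window.

    The spectral magnitudes are the singular values of the column-centered
    pixel rectangle.  For a non-square rectangle a square window of side
    min(h, w) slides inside it (stride side/2) and the per-window sorted
    spectra are averaged element-wise.  Output: 4 largest magnitudes, 4
    smallest (ascending), 25th/75th percentiles of the spectrum, the 16
    ratios max_i/min_j, and max1/max4, min1/min4 (x/0 and 0/0 map to 0).
    """
    block = np.asarray(block, dtype=float)
    if roi_sub is None:
        roi_sub = np.ones(block.shape, dtype=bool)
    rect = max_inscribed_rect(roi_sub)
    sub = block[rect.top:rect.top + rect.height, rect.left:rect.left + rect.width]
    h, w = sub.shape
    side = min(h, w)
    if side == h == w:
        spectrum = _spectrum(sub)
    else:
        stride = max(1, side // 2)
        spectra = []
        for r in range(0, h - side + 1, stride):
            for c in range(0, w - side + 1, stride):
                spectra.append(np.sort(_spectrum(sub[r:r + side, c:c + side]))[::-1])
        spectrum = np.mean(spectra, axis=0)
    if spectrum.size < 4:
        warnings.warn("ROI rectangle smaller than 4x4: spectrum padded with zeros")
        spectrum = np.pad(spectrum, (0, 4 - spectrum.size))
    # numerically-null magnitudes are true zeros (e.g. the rank deficiency
    # introduced by centering); snap them so the x/0 -> 0 convention applies
    if spectrum.max() > 0:
        spectrum = np.where(spectrum < 1e-10 * spectrum.max(), 0.0, spectrum)
    desc = np.sort(spectrum)[::-1]
    asc = np.sort(spectrum)
    lmax = desc[:4]
    lmin = asc[:4]
    ratios = [_safe_ratio(lmax[i], lmin[j]) for i in range(4) for j in range(4)]
    ratios += [_safe_ratio(lmax[0], lmax[3]), _safe_ratio(lmin[0], lmin[3])]
    return np.concatenate([
        lmax, lmin,
        [np.percentile(spectrum, 25), np.percentile(spectrum, 75)],
        ratios,
    ])
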
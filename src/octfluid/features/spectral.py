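"""Gradient- and frequency-domain descriptors: HOG, a Gabor bank, and LESH.

The LESH descriptor is built on a log-Gabor phase-congruency measure (Kovesi
style): phase congruency is contrast-invariant, so the descriptor is robust
to the global intensity scaling differences between OCT devices.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Histogram of oriented gradients

HOG_CELLS = 3
HOG_BINS = 9
_HOG_EPS = 1e-6


def extract_hog(block: np.ndarray) -> np.ndarray:
    """81 HOG values: a 3x3 cell grid, 9 unsigned-orientation bins per cell.

    Gradients are central differences; orientation is unsigned in [0, 180);
    magnitude is linearly interpolated between the two nearest bin centers
    (centers at 10, 30, ..., 170 degrees).  Each cell histogram is
    L2-normalized (zero vectors stay zero); cells are concatenated row-major,
    bins within cells.
    """
    img = np.asarray(block, dtype=float)
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx)) % 180.0

    pos = theta / (180.0 / HOG_BINS) - 0.5
    b0 = np.floor(pos).astype(int) % HOG_BINS
    frac = pos - np.floor(pos)
    b1 = (b0 + 1) % HOG_BINS

    row_edges = np.linspace(0, img.shape[0], HOG_CELLS + 1).astype(int)
    col_edges = np.linspace(0, img.shape[1], HOG_CELLS + 1).astype(int)
    out = []
    for i in range(HOG_CELLS):
        for j in range(HOG_CELLS):
            rs = slice(row_edges[i], row_edges[i + 1])
            cs = slice(col_edges[j], col_edges[j + 1])
            hist = (np.bincount(b0[rs, cs].ravel(),
                                weights=(mag[rs, cs] * (1 - frac[rs, cs])).ravel(),
                                minlength=HOG_BINS)
                    + np.bincount(b1[rs, cs].ravel(),
                                  weights=(mag[rs, cs] * frac[rs, cs]).ravel(),
                                  minlength=HOG_BINS))
            norm = np.sqrt((hist**2).sum() + _HOG_EPS**2)
            out.append(hist / norm if hist.any() else hist)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Gabor filter bank

GABOR_F_MAX = 0.25
GABOR_N_FREQS = 8
GABOR_N_ORIENTS = 8
_GABOR_GAMMA = np.sqrt(2.0)
_GABOR_ETA = np.sqrt(2.0)

_gabor_cache: dict[tuple, tuple] = {}


def gabor_kernel(frequency: float, theta: float) -> np.ndarray:
    """Complex 2-D Gabor kernel: Gaussian envelope times a complex sinusoid.

    sigma is tied to the frequency (sigma = 0.56 / f); support is truncated
    at 3 sigma.
    """
    sigma = 0.56 / frequency
    r = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    xp = x * np.cos(theta) + y * np.sin(theta)
    yp = -x * np.sin(theta) + y * np.cos(theta)
    amp = (frequency**2 / (np.pi * _GABOR_GAMMA * _GABOR_ETA)) * np.exp(
        -(xp**2 + _GABOR_GAMMA**2 * yp**2) / (2 * sigma**2))
    return amp * np.exp(1j * 2 * np.pi * frequency * xp)


def gabor_bank() -> list[tuple[int, int, float, float]]:
    """(freq index, orient index, frequency, theta) for the 8x8 bank."""
    bank = []
    for k in range(GABOR_N_FREQS):
        f = GABOR_F_MAX / (np.sqrt(2.0) ** k)
        for j in range(GABOR_N_ORIENTS):
            bank.append((k, j, f, j * np.pi / GABOR_N_ORIENTS))
    return bank


def _gabor_filters_for_shape(shape: tuple[int, int]):
    """Pre-FFT'd bank for a block shape (cached): reflect-pad + frequency mult."""
    key = shape
    if key in _gabor_cache:
        return _gabor_cache[key]
    kernels = [(k, j, gabor_kernel(f, th)) for k, j, f, th in gabor_bank()]
    rmax = max(kern.shape[0] // 2 for _, _, kern in kernels)
    padded_shape = (shape[0] + 2 * rmax, shape[1] + 2 * rmax)
    ffts = []
    for k, j, kern in kernels:
        kf = np.fft.fft2(kern, s=padded_shape)
        ffts.append((k, j, kern.shape[0] // 2, kf))
    _gabor_cache[key] = (rmax, padded_shape, ffts)
    return _gabor_cache[key]


def gabor_responses(block: np.ndarray) -> np.ndarray:
    """Magnitudes of the 64 complex filter responses, shape (64, H, W).

    Filtering uses reflective boundary handling; frequency-major order.
    """
    img = np.asarray(block, dtype=float)
    h, w = img.shape
    rmax, padded_shape, ffts = _gabor_filters_for_shape((h, w))
    padded = np.pad(img, rmax, mode="reflect")
    imf = np.fft.fft2(padded, s=padded_shape)
    out = np.empty((len(ffts), h, w))
    for idx, (_, _, r, kf) in enumerate(ffts):
        resp = np.fft.ifft2(imf * kf)
        out[idx] = np.abs(resp[rmax + r:rmax + r + h, rmax + r:rmax + r + w])
    return out


def extract_gabor(block: np.ndarray) -> np.ndarray:
    """128 Gabor features: 64 response-magnitude means then 64 sds."""
    mags = gabor_responses(block)
    means = mags.mean(axis=(1, 2))
    sds = mags.std(axis=(1, 2))
    return np.concatenate([means, sds])


# ---------------------------------------------------------------------------
# Phase congruency and LESH

PC_N_SCALES = 5
PC_N_ORIENTS = 8
PC_MIN_WAVELENGTH = 3.0
PC_MULT = 2.1
PC_SIGMA_ONF = 0.55
PC_K = 2.0
PC_EPS = 1e-4
LESH_PARTITIONS = 4


def _pc_filters(shape: tuple[int, int]):
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0
    theta = np.arctan2(-fy, fx)  # image y-axis points down
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)
    radials = []
    for s in range(PC_N_SCALES):
        f0 = 1.0 / (PC_MIN_WAVELENGTH * PC_MULT**s)
        lg = np.exp(-(np.log(radius / f0) ** 2)
                    / (2 * np.log(PC_SIGMA_ONF) ** 2)) * lowpass
        lg[0, 0] = 0.0
        radials.append(lg)
    sigma_theta = 1.2 * (np.pi / PC_N_ORIENTS)
    spreads = []
    for o in range(PC_N_ORIENTS):
        angl = o * np.pi / PC_N_ORIENTS
        d = np.abs(np.arctan2(np.sin(theta - angl), np.cos(theta - angl)))
        d = np.minimum(d, np.pi - d)  # orientation is axial (180-degree period)
        spreads.append(np.exp(-(d**2) / (2 * sigma_theta**2)))
    return radials, spreads


def phase_congruency(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-orientation phase congruency of an image.

    Returns ``(pc, amplitude)`` with shape (n_orients, H, W): the Kovesi-style
    noise-compensated phase congruency and the summed filter amplitude per
    orientation.  A constant image gives all zeros.
    """
    img = np.asarray(img, dtype=float)
    imf = np.fft.fft2(img)
    radials, spreads = _pc_filters(img.shape)
    pc = np.empty((PC_N_ORIENTS,) + img.shape)
    amp = np.empty_like(pc)
    for o, spread in enumerate(spreads):
        sum_e = np.zeros(img.shape)
        sum_o = np.zeros(img.shape)
        sum_an = np.zeros(img.shape)
        eo_list = []
        for s, radial in enumerate(radials):
            eo = np.fft.ifft2(imf * radial * spread)
            eo_list.append(eo)
            sum_e += eo.real
            sum_o += eo.imag
            sum_an += np.abs(eo)
        x_energy = np.hypot(sum_e, sum_o) + PC_EPS
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros(img.shape)
        for eo in eo_list:
            energy += (eo.real * mean_e + eo.imag * mean_o
                       - np.abs(eo.real * mean_o - eo.imag * mean_e))
        # Rayleigh noise estimate from the smallest-scale response
        tau = np.median(np.abs(eo_list[0])) / np.sqrt(np.log(4.0))
        inv_mult = 1.0 / PC_MULT
        total_tau = tau * (1 - inv_mult**PC_N_SCALES) / (1 - inv_mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2)
        t = noise_mean + PC_K * noise_sigma
        pc[o] = np.maximum(energy - t, 0.0) / (sum_an + PC_EPS)
        amp[o] = sum_an
    return pc, amp


def extract_lesh(block: np.ndarray) -> np.ndarray:
    """128 LESH values: 16 spatial partitions x 8 orientation bins.

    Each pixel contributes its total phase congruency to the orientation bin
    of its dominant-energy orientation, accumulated per partition of a 4x4
    grid; the concatenated histogram is globally L2-normalized.
    """
    img = np.asarray(block, dtype=float)
    pc, amp = phase_congruency(img)
    pc_total = pc.sum(axis=0)
    label = np.argmax(amp, axis=0)
    h, w = img.shape
    row_edges = np.linspace(0, h, LESH_PARTITIONS + 1).astype(int)
    col_edges = np.linspace(0, w, LESH_PARTITIONS + 1).astype(int)
    out = []
    for i in range(LESH_PARTITIONS):
        for j in range(LESH_PARTITIONS):
            rs = slice(row_edges[i], row_edges[i + 1])
            cs = slice(col_edges[j], col_edges[j + 1])
            hist = np.bincount(label[rs, cs].ravel(),
                               weights=pc_total[rs, cs].ravel(),
                               minlength=PC_N_ORIENTS)
            out.append(hist)
    vec = np.concatenate(out)
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec
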
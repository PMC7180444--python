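"""Synthetic OCT-like B-scan generator with known layer boundaries and cyst masks.

The generator emulates the image properties the analysis pipeline assumes:
bright, layered retinal bands on a dark vitreous/choroid background, a foveal
dip, multiplicative speckle noise, dark (hyporeflective) elliptical cystoid
regions strictly between the inner limiting membrane (ILM) and the retinal
pigment epithelium (RPE), vertical hyporeflective shadow columns, and
hyperreflective drusen-like bumps of the RPE.

Images are 8-bit grayscale.  Every output is a pure function of the
``PhantomSpec`` (which includes the seed), so datasets are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic B-scan.

    Gray levels are in [0, 255]; distances in pixels.  ``speckle_shape`` is the
    gamma shape parameter of the multiplicative speckle factor (unit mean);
    ``math.inf`` disables noise.
    """

    width: int = 360
    height: int = 220
    n_layers: int = 4
    ilm_baseline: int = 60
    rpe_baseline: int = 160
    curvature_amplitude: float = 12.0
    speckle_shape: float = 6.0
    tissue_mean: float = 170.0
    fluid_mean: float = 50.0
    background_mean: float = 25.0
    n_cysts: int = 5
    cyst_axes_range: tuple[float, float] = (10.0, 30.0)
    blurred_border_fraction: float = 0.3
    n_shadows: int = 1
    shadow_attenuation: float = 0.5
    n_drusen: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not (self.fluid_mean < self.tissue_mean):
            raise ValueError("invalid PhantomSpec: fluid_mean must be < tissue_mean "
                             "(cystoid fluid is hyporeflective)")
        if not (0 < self.ilm_baseline < self.rpe_baseline < self.height):
            raise ValueError("invalid PhantomSpec: requires 0 < ilm_baseline < "
                             "rpe_baseline < height")
        if self.width < 61 or self.height < 61:
            raise ValueError("invalid PhantomSpec: width and height must be >= 61 "
                             "so at least one 61x61 window fits")
        if not self.speckle_shape > 0:
            raise ValueError("invalid PhantomSpec: speckle_shape must be positive")
        if not (0 < self.shadow_attenuation < 1):
            raise ValueError("invalid PhantomSpec: shadow_attenuation must lie in (0,1)")
        lo, hi = self.cyst_axes_range
        if not (0 < lo <= hi):
            raise ValueError("invalid PhantomSpec: cyst_axes_range must satisfy 0 < min <= max")
        for name in ("n_layers", "n_cysts", "n_shadows", "n_drusen"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid PhantomSpec: {name} must be non-negative")
        if self.n_layers < 1:
            raise ValueError("invalid PhantomSpec: n_layers must be >= 1")


@dataclass
class GroundTruth:
    """Reference annotation of one phantom: cyst mask and true layer rows."""

    cyst_mask: np.ndarray          # bool, image shape
    ilm_true: np.ndarray           # int, per column
    rpe_true: np.ndarray           # int, per column


@dataclass
class BScan:
    """One grayscale cross-sectional retinal image."""

    pixels: np.ndarray             # uint8, (height, width)
    id: str = "bscan"

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _layer_profile(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-column ILM and RPE rows with a central foveal dip and gentle tilt."""
    cols = np.arange(spec.width)
    center = spec.width / 2.0 + rng.uniform(-spec.width / 8, spec.width / 8)
    sigma = spec.width / 5.0
    dip = spec.curvature_amplitude * np.exp(-((cols - center) ** 2) / (2 * sigma**2))
    tilt = rng.uniform(-0.02, 0.02) * (cols - spec.width / 2.0)
    ilm = spec.ilm_baseline + dip + tilt
    rpe = spec.rpe_baseline + 0.35 * dip + tilt
    ilm = np.clip(np.round(ilm), 1, spec.height - 3).astype(int)
    rpe = np.clip(np.round(rpe), 2, spec.height - 2).astype(int)
    rpe = np.maximum(rpe, ilm + 40)  # keep the retina thick enough for windows
    return ilm, rpe


def _reflectance_template(spec: PhantomSpec, ilm: np.ndarray, rpe: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Noise-free reflectance image: dark background, banded retina, bright RPE."""
    h, w = spec.height, spec.width
    rows = np.arange(h)[:, None]
    img = np.full((h, w), spec.background_mean, dtype=float)

    inner = (rows >= ilm[None, :]) & (rows <= rpe[None, :])
    # depth in [0,1] inside the retina, per column
    thickness = (rpe - ilm).astype(float)
    depth = np.where(inner, (rows - ilm[None, :]) / np.maximum(thickness, 1), 0.0)

    # n_layers bright bands separated by slightly darker interband tissue; the
    # band just above the RPE is hyporeflective so the RPE edge stays the
    # second-strongest dark-to-light transition in every column.
    band_levels = spec.tissue_mean * (0.95 + 0.1 * np.cos(np.arange(spec.n_layers)))
    base = spec.tissue_mean * 0.75
    tissue = np.full((h, w), base, dtype=float)
    for k in range(spec.n_layers):
        lo = k / spec.n_layers
        hi = (k + 0.6) / spec.n_layers
        band = (depth >= lo) & (depth < hi)
        tissue[band] = band_levels[k]
    # hyporeflective pre-RPE gap and bright RPE band
    gap = depth >= 0.82
    tissue[gap] = spec.tissue_mean * 0.55
    rpe_band_px = 8
    rpe_band = (rows >= rpe[None, :]) & (rows < (rpe + rpe_band_px)[None, :])
    img[inner] = tissue[inner]
    img[rpe_band] = min(spec.tissue_mean * 1.25, 240.0)
    return img


def _add_cysts(spec: PhantomSpec, img: np.ndarray, ilm: np.ndarray, rpe: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Draw filled rotated ellipses of fluid with Gaussian-feathered borders."""
    h, w = img.shape
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    lo, hi = spec.cyst_axes_range
    for _ in range(spec.n_cysts):
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        theta = rng.uniform(0, np.pi)
        cx = rng.uniform(0.1 * w, 0.9 * w)
        margin_top = 6
        margin_bot = 10
        c = int(round(cx))
        top = ilm[c] + margin_top + a
        bot = rpe[c] - margin_bot - a
        if bot <= top:
            continue
        cy = rng.uniform(top, bot)
        x = cc - cx
        y = rr - cy
        xr = x * np.cos(theta) + y * np.sin(theta)
        yr = -x * np.sin(theta) + y * np.cos(theta)
        d = (xr / a) ** 2 + (yr / b) ** 2
        inside = d <= 1.0
        # keep cysts strictly between the layers
        inside &= (rr > ilm[None, :]) & (rr < rpe[None, :])
        if not inside.any():
            continue
        feather = 0.35 if rng.uniform() < spec.blurred_border_fraction else 0.12
        alpha = np.clip((1.0 - d) / feather, 0.0, 1.0)
        alpha[~((rr > ilm[None, :]) & (rr < rpe[None, :]))] = 0.0
        img = img * (1 - alpha) + spec.fluid_mean * alpha
        mask |= inside
    return img, mask


def _add_drusen(spec: PhantomSpec, img: np.ndarray, rpe: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Local upward bumps of the RPE band with hyperreflective fill."""
    h, w = img.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)
    for _ in range(spec.n_drusen):
        cx = rng.uniform(0.1 * w, 0.9 * w)
        width = rng.uniform(10, 25)
        height_px = rng.uniform(6, 14)
        bump = height_px * np.exp(-((cols - cx) ** 2) / (2 * (width / 2.355) ** 2))
        top = np.round(rpe - bump).astype(int)
        region = (rows >= top[None, :]) & (rows < rpe[None, :]) & (bump[None, :] > 1.0)
        img[region] = min(spec.tissue_mean * 1.25, 240.0)
    return img


def _add_shadows(spec: PhantomSpec, img: np.ndarray, ilm: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Columnar multiplicative attenuation below a chosen origin row."""
    h, w = img.shape
    rows = np.arange(h)[:, None]
    for _ in range(spec.n_shadows):
        cx = rng.uniform(0.08 * w, 0.92 * w)
        half = rng.uniform(3, 8)
        c0 = max(0, int(cx - half))
        c1 = min(w, int(cx + half) + 1)
        origin = int(np.min(ilm[c0:c1])) + int(rng.integers(4, 18))
        factor = np.ones((h, 1))
        factor[origin:, 0] = spec.shadow_attenuation
        img[:, c0:c1] = img[:, c0:c1] * factor
    return img


def generate_bscan(spec: PhantomSpec) -> tuple[BScan, GroundTruth]:
    """Generate one synthetic B-scan and its ground truth.

    Deterministic: identical ``spec`` (including ``spec.seed``) gives
    bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ilm, rpe = _layer_profile(spec, rng)
    img = _reflectance_template(spec, ilm, rpe, rng)
    img, cyst_mask = _add_cysts(spec, img, ilm, rpe, rng)
    img = _add_drusen(spec, img, rpe, rng)
    img = _add_shadows(spec, img, ilm, rng)
    if math.isfinite(spec.speckle_shape):
        k = spec.speckle_shape
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=img.shape)
        img = img * speckle
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    gt = GroundTruth(cyst_mask=cyst_mask, ilm_true=ilm, rpe_true=rpe)
    return BScan(pixels=pixels, id=f"phantom-{spec.seed}"), gt


def generate_dataset(spec_template: PhantomSpec, n_images: int,
                     seed: int) -> list[tuple[BScan, GroundTruth]]:
    """Generate ``n_images`` phantoms with per-image seeds derived from ``seed``.

    Image sizes are jittered around the template, and roughly half the images
    are cyst-free so that labeled window sets can be balanced downstream.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    spec_template.validate()
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_images)
    out = []
    for i in range(n_images):
        rng_i = np.random.default_rng(child_seeds[i])
        dw = int(rng_i.integers(-20, 21))
        dh = int(rng_i.integers(-10, 11))
        has_cysts = i % 2 == 0  # deterministic near-half split
        spec_i = dataclasses.replace(
            spec_template,
            width=max(61, spec_template.width + dw),
            height=max(61, spec_template.height + dh),
            n_cysts=spec_template.n_cysts if has_cysts else 0,
            seed=int(child_seeds[i]),
        )
        scan, gt = generate_bscan(spec_i)
        scan.id = f"phantom-{seed}-{i:03d}"
        out.append((scan, gt))
    return out


def planted_feature_table(n_samples: int = 500, n_informative: int = 5,
                          n_noise: int = 100, effect: float = 1.0,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic labeled table with a few informative columns among noise.

    The informative columns differ in mean between the two balanced classes by
    ``effect`` standard deviations; all other columns are pure standard-normal
    noise.  Returns ``(X, y, informative_idx)``; informative columns are
    scattered at deterministic positions.
    """
    rng = np.random.default_rng(seed)
    y = np.arange(n_samples) % 2
    rng.shuffle(y)
    d = n_informative + n_noise
    X = rng.standard_normal((n_samples, d))
    idx = np.linspace(0, d - 1, n_informative).astype(int)
    X[:, idx] += effect * y[:, None]
    return X, y, idx


def write_phantom(directory: str | Path, scan: BScan, gt: GroundTruth,
                  spec: PhantomSpec | None = None) -> dict:
    """Write one phantom to disk: image PNG, mask PNG, boundary CSV, spec JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / f"{scan.id}.png",
        "mask": directory / f"{scan.id}_mask.png",
        "boundaries": directory / f"{scan.id}_layers.csv",
    }
    iio.imwrite(paths["image"], scan.pixels)
    iio.imwrite(paths["mask"], (gt.cyst_mask.astype(np.uint8) * 255))
    with open(paths["boundaries"], "w") as fh:
        fh.write("column,ilm_row,rpe_row\n")
        for c in range(scan.width):
            fh.write(f"{c},{gt.ilm_true[c]},{gt.rpe_true[c]}\n")
    if spec is not None:
        paths["spec"] = directory / f"{scan.id}_spec.json"
        with open(paths["spec"], "w") as fh:
            json.dump(dataclasses.asdict(spec), fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
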
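"""Window sampling inside the retinal region of interest.

Overlapping square windows are placed on a raster grid; a window is kept when
its center lies between the ILM and RPE and its full block fits inside the
image (no padding is fabricated).  Against a reference cyst mask, a window is
labeled cystoid when the cyst fraction of its in-ROI pixels reaches a small
threshold ``tau``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import BScan, GroundTruth

CYSTOID = "cystoid"
NON_CYSTOID = "non_cystoid"


@dataclass
class Sample:
    """One W x W window: pixel block, ROI sub-mask and (optional) label."""

    center: tuple[int, int]
    size: int
    block: np.ndarray
    roi_sub: np.ndarray
    label: str | None = None
    source_id: str = ""


@dataclass(frozen=True)
class Rect:
    top: int
    left: int
    height: int
    width: int

    @property
    def area(self) -> int:
        return self.height * self.width


def extract_windows(image, roi: np.ndarray, w: int = 61,
                    stride: int | None = None, source_id: str = "") -> list[Sample]:
    """All windows on the raster grid with ROI-interior centers and full support.

    ``stride`` defaults to round(W/2).  Deterministic raster (row-major) order.
    """
    pixels = image.pixels if isinstance(image, BScan) else np.asarray(image)
    if w % 2 == 0:
        raise ValueError("window size W must be odd")
    stride = int(round(w / 2)) if stride is None else stride
    if not (1 <= stride <= w):
        raise ValueError("stride must satisfy 1 <= stride <= W")
    h, wid = pixels.shape
    half = w // 2
    if w > h or w > wid:
        warnings.warn("window larger than image; no samples extracted")
        return []
    samples = []
    for r in range(half, h - half, stride):
        for c in range(half, wid - half, stride):
            if not roi[r, c]:
                continue
            block = pixels[r - half:r + half + 1, c - half:c + half + 1]
            roi_sub = roi[r - half:r + half + 1, c - half:c + half + 1]
            samples.append(Sample(center=(r, c), size=w, block=block,
                                  roi_sub=roi_sub, source_id=source_id))
    return samples


def label_window(sample: Sample, cyst_mask: np.ndarray, tau: float = 0.05) -> str:
    """Label a window by the cyst fraction of its in-ROI pixels."""
    r, c = sample.center
    half = sample.size // 2
    sub = cyst_mask[r - half:r + half + 1, c - half:c + half + 1]
    roi_area = int(sample.roi_sub.sum())
    if roi_area == 0:
        raise ValueError("cannot label a window with an empty ROI sub-mask")
    frac = (sub & sample.roi_sub).sum() / roi_area
    return CYSTOID if frac >= tau else NON_CYSTOID


def max_inscribed_rect(roi_sub: np.ndarray) -> Rect:
    """Axis-aligned all-true rectangle of maximum area (histogram-stack method).

    Ties are broken by smallest (top, left).
    """
    mask = np.asarray(roi_sub, dtype=bool)
    if not mask.any():
        raise ValueError("max_inscribed_rect requires at least one true pixel")
    h, w = mask.shape
    heights = np.zeros(w + 1, dtype=int)  # sentinel zero column at the end
    best_area, best_rect = 0, None
    for r in range(h):
        heights[:w] = np.where(mask[r], heights[:w] + 1, 0)
        stack: list[int] = []
        for c in range(w + 1):
            while stack and heights[stack[-1]] > heights[c]:
                hh = heights[stack.pop()]
                left = stack[-1] + 1 if stack else 0
                area = hh * (c - left)
                top = r - hh + 1
                if area > best_area or (
                        area == best_area
                        and (top, left) < (best_rect.top, best_rect.left)):
                    best_area = area
                    best_rect = Rect(top=top, left=left, height=hh, width=c - left)
            stack.append(c)
    assert best_rect is not None
    return best_rect


def build_dataset(images_truth: list[tuple[BScan, GroundTruth]] | list,
                  rois: list[np.ndarray] | None = None, w: int = 61,
                  stride: int | None = None, tau: float = 0.05,
                  balance: bool = True, seed: int = 0) -> pd.DataFrame:
    """Labeled sample table over a set of images with ground truth.

    ``rois`` optionally supplies per-image ROI masks (e.g. from segmented
    boundaries); by default the true boundaries define the ROI.  With
    ``balance``, the majority class is randomly down-sampled (seeded) to the
    minority count.  Columns: source_id, row, col, W, label.
    """
    from .layers import LayerBoundaries, roi_mask  # local import to avoid cycle

    rows = []
    for i, (scan, gt) in enumerate(images_truth):
        if rois is not None:
            roi = rois[i]
        else:
            roi = roi_mask(LayerBoundaries(gt.ilm_true, gt.rpe_true),
                           scan.pixels.shape)
        for s in extract_windows(scan, roi, w=w, stride=stride,
                                 source_id=scan.id):
            label = label_window(s, gt.cyst_mask, tau=tau)
            rows.append((s.source_id, s.center[0], s.center[1], w, label))
    table = pd.DataFrame(rows, columns=["source_id", "row", "col", "W", "label"])
    counts = table["label"].value_counts()
    for cls in (CYSTOID, NON_CYSTOID):
        if counts.get(cls, 0) == 0:
            raise ValueError(f"class {cls!r} is absent; cannot build a labeled dataset")
    if balance:
        rng = np.random.default_rng(seed)
        n_min = counts.min()
        kept = []
        for cls, group in table.groupby("label", sort=True):
            idx = np.sort(rng.choice(group.index.to_numpy(), size=n_min,
                                     replace=False))
            kept.append(table.loc[idx])
        table = pd.concat(kept).sort_index().reset_index(drop=True)
    return table


def reextract_blocks(table: pd.DataFrame,
                     images: dict[str, np.ndarray],
                     rois: dict[str, np.ndarray]) -> list[Sample]:
    """Rebuild Sample objects from a sample table and the source images."""
    out = []
    for rec in table.itertuples(index=False):
        pixels = images[rec.source_id]
        roi = rois[rec.source_id]
        half = rec.W // 2
        r, c = rec.row, rec.col
        out.append(Sample(center=(r, c), size=rec.W,
                          block=pixels[r - half:r + half + 1, c - half:c + half + 1],
                          roi_sub=roi[r - half:r + half + 1, c - half:c + half + 1],
                          label=rec.label, source_id=rec.source_id))
    return out
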
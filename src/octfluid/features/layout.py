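"""Canonical registry of the 510-value window descriptor.

The descriptor concatenates eleven categories in a fixed order; the 1-based
index ranges are part of the contract and are relied on by the selection and
evaluation analytics::

    GIBS   1-15    global intensity statistics
    AIS    16-27   per-axis skewness/kurtosis summaries
    EIGEN  28-55   spectral magnitudes of the ROI rectangle and their ratios
    LESH   56-183  local energy shape histogram (5 scales, 8 orients, 16 parts)
    GLCM   184-199 co-occurrence statistics (distance 2; 0/45/90/135 deg)
    HOG    200-280 3x3 cells x 9 orientation bins
    GABOR  281-408 8 frequencies x 8 orientations, mean then sd
    LBP    409-472 neighbors {4,8,12,16} x radii 1..8, mean then sd
    LAWS   473-500 14 texture-energy maps, mean then sd
    FD     501-503 local box-counting dimension: mean, sd, lacunarity
    GLRL   504-510 run-length statistics on the orientation-summed matrix
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

_LAWS_MAPS = ["e3e3", "s3s3", "l3e3", "l3s3", "e3s3",
              "e5e5", "s5s5", "r5r5", "l5e5", "l5s5", "l5r5",
              "e5s5", "e5r5", "s5r5"]

_GLCM_ANGLES = ["0", "45", "90", "135"]


def _build_names() -> tuple[list[str], dict[str, tuple[int, int]]]:
    names: list[str] = []
    ranges: dict[str, tuple[int, int]] = {}

    def start_category(cat):
        return len(names)

    def end_category(cat, start):
        ranges[cat] = (start, len(names))

    s = start_category("GIBS")
    names += ["gibs.max", "gibs.min", "gibs.mean", "gibs.median", "gibs.sd",
              "gibs.var", "gibs.entropy", "gibs.p25", "gibs.p75",
              "gibs.mle.mu", "gibs.mle.sigma", "gibs.mle.mu_lo",
              "gibs.mle.mu_hi", "gibs.mle.sigma_lo", "gibs.mle.sigma_hi"]
    end_category("GIBS", s)

    s = start_category("AIS")
    for agg in ("min", "mean", "max"):
        for stat in ("skew.h", "skew.v", "kurt.h", "kurt.v"):
            names.append(f"ais.{agg}.{stat}")
    end_category("AIS", s)

    s = start_category("EIGEN")
    names += [f"eigen.max{i}" for i in range(1, 5)]
    names += [f"eigen.min{i}" for i in range(1, 5)]
    names += ["eigen.p25", "eigen.p75"]
    for i in range(1, 5):
        for j in range(1, 5):
            names.append(f"eigen.ratio.max{i}.min{j}")
    names += ["eigen.ratio.max1.max4", "eigen.ratio.min1.min4"]
    end_category("EIGEN", s)

    s = start_category("LESH")
    for p in range(16):
        for o in range(8):
            names.append(f"lesh.p{p}.o{o}")
    end_category("LESH", s)

    s = start_category("GLCM")
    for stat in ("contrast", "correlation", "energy", "homogeneity"):
        for ang in _GLCM_ANGLES:
            names.append(f"glcm.{stat}.{ang}")
    end_category("GLCM", s)

    s = start_category("HOG")
    for c in range(9):
        for b in range(9):
            names.append(f"hog.c{c}.b{b}")
    end_category("HOG", s)

    s = start_category("GABOR")
    for stat in ("mean", "sd"):
        for f in range(8):
            for o in range(8):
                names.append(f"gabor.{stat}.f{f}.o{o}")
    end_category("GABOR", s)

    s = start_category("LBP")
    for stat in ("mean", "sd"):
        for p in (4, 8, 12, 16):
            for r in range(1, 9):
                names.append(f"lbp.{stat}.p{p}.r{r}")
    end_category("LBP", s)

    s = start_category("LAWS")
    for stat in ("mean", "sd"):
        for m in _LAWS_MAPS:
            names.append(f"laws.{stat}.{m}")
    end_category("LAWS", s)

    s = start_category("FD")
    names += ["fd.mean", "fd.sd", "fd.lacunarity"]
    end_category("FD", s)

    s = start_category("GLRL")
    names += ["glrl.sre", "glrl.lre", "glrl.gln", "glrl.rp", "glrl.rln",
              "glrl.lgre", "glrl.hgre"]
    end_category("GLRL", s)
    return names, ranges


@dataclass(frozen=True)
class FeatureLayout:
    """Ordered feature names and 0-based half-open category index ranges."""

    names: tuple[str, ...]
    ranges: dict[str, tuple[int, int]]

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def categories(self) -> list[str]:
        return list(self.ranges)

    def category_size(self, category: str) -> int:
        a, b = self.ranges[category]
        return b - a

    def category_of(self, index: int) -> str:
        for cat, (a, b) in self.ranges.items():
            if a <= index < b:
                return cat
        raise IndexError(index)

    def indices(self, category: str):
        a, b = self.ranges[category]
        return range(a, b)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"names": list(self.names),
                       "ranges": {k: list(v) for k, v in self.ranges.items()}},
                      fh, indent=2)


def default_layout() -> FeatureLayout:
    names, ranges = _build_names()
    return FeatureLayout(names=tuple(names), ranges=ranges)


LAYOUT = default_layout()
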
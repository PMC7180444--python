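"""Assembly of the full 510-value window descriptor."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..sampling import Sample
from .intensity import extract_ais, extract_eigen, extract_gibs
from .layout import LAYOUT, FeatureLayout
from .spectral import extract_gabor, extract_hog, extract_lesh
from .texture import extract_fd, extract_glcm, extract_glrl, extract_laws, extract_lbp


class FeatureExtractionError(RuntimeError):
    """A category extractor failed; carries the category name."""

    def __init__(self, category: str, cause: Exception):
        super().__init__(f"feature extraction failed in category {category}: {cause}")
        self.category = category


def extract_all(sample: Sample | np.ndarray,
                roi_sub: np.ndarray | None = None) -> np.ndarray:
    """The full descriptor of one window, in canonical layout order.

    Accepts a ``Sample`` or a raw pixel block (with an optional ROI sub-mask
    for the spectral-rectangle category; all other categories operate on the
    full block).  Pure function of (block, roi_sub).
    """
    if isinstance(sample, Sample):
        block = sample.block
        roi_sub = sample.roi_sub if roi_sub is None else roi_sub
    else:
        block = np.asarray(sample)
    parts = []
    categories = [
        ("GIBS", lambda: extract_gibs(block)),
        ("AIS", lambda: extract_ais(block)),
        ("EIGEN", lambda: extract_eigen(block, roi_sub)),
        ("LESH", lambda: extract_lesh(block)),
        ("GLCM", lambda: extract_glcm(block)),
        ("HOG", lambda: extract_hog(block)),
        ("GABOR", lambda: extract_gabor(block)),
        ("LBP", lambda: extract_lbp(block)),
        ("LAWS", lambda: extract_laws(block)),
        ("FD", lambda: extract_fd(block)),
        ("GLRL", lambda: extract_glrl(block)),
    ]
    for cat, fn in categories:
        try:
            values = np.asarray(fn(), dtype=float)
        except Exception as exc:  # attach the category to the failure
            raise FeatureExtractionError(cat, exc) from exc
        expected = LAYOUT.category_size(cat)
        if values.shape != (expected,):
            raise FeatureExtractionError(
                cat, ValueError(f"expected {expected} values, got {values.shape}"))
        parts.append(values)
    vec = np.concatenate(parts)
    if not np.all(np.isfinite(vec)):
        bad = int(np.flatnonzero(~np.isfinite(vec))[0])
        raise FeatureExtractionError(LAYOUT.category_of(bad),
                                     ValueError(f"non-finite value at index {bad}"))
    return vec


class WindowFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: windows -> 510-column feature matrix.

    ``transform`` accepts a list of ``Sample`` objects or an array of pixel
    blocks of shape (n, W, W).  ``fit`` only validates and records the layout.
    """

    def fit(self, X, y=None):
        self.layout_ = LAYOUT
        self.n_features_out_ = LAYOUT.n_features
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "layout_"):
            self.fit(X)
        return np.vstack([extract_all(x) for x in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(LAYOUT.names, dtype=object)


def features_table(samples: list[Sample]):
    """Feature DataFrame with canonical column names plus provenance columns."""
    import pandas as pd

    mat = WindowFeatureExtractor().fit(samples).transform(samples)
    df = pd.DataFrame(mat, columns=list(LAYOUT.names))
    df.insert(0, "source_id", [s.source_id for s in samples])
    df.insert(1, "row", [s.center[0] for s in samples])
    df.insert(2, "col", [s.center[1] for s in samples])
    df.insert(3, "label", [s.label for s in samples])
    return df
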
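"""ILM/RPE delimitation by shortest paths through a gradient-weighted pixel graph.

Each pixel is a graph node; edges connect a pixel to its three neighbors in
the next column (up-diagonal, straight, down-diagonal), so any source-to-sink
path is a monotone left-to-right boundary.  Edge weights are low where the
vertical dark-to-light gradient is strong, so minimum-cost paths trace the
strongest retinal interfaces: the vitreous/ILM transition and the top of the
bright RPE band.  Two zero-ish-weight virtual columns are appended at both
sides (with free vertical movement) so a path may enter and leave at any row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .phantom import BScan

W_MIN_DEFAULT = 1e-5


class SegmentationError(RuntimeError):
    """Raised when the two recovered boundary paths collide or cross.

    Carries both raw paths for inspection.
    """

    def __init__(self, message: str, path_a: np.ndarray, path_b: np.ndarray):
        super().__init__(message)
        self.path_a = path_a
        self.path_b = path_b


@dataclass
class LayerBoundaries:
    """Per-column row indices of the ILM (upper) and RPE (lower) boundaries."""

    ilm_row: np.ndarray
    rpe_row: np.ndarray

    def validate(self) -> None:
        if np.any(self.ilm_row >= self.rpe_row):
            raise ValueError("ILM must lie strictly above the RPE in every column")


def _as_array(image) -> np.ndarray:
    pixels = image.pixels if isinstance(image, BScan) else np.asarray(image)
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[0] < 3 or pixels.shape[1] < 2:
        raise ValueError("image must be a 2-D grid with height >= 3 and width >= 2")
    return pixels


def vertical_gradient(image, polarity: str = "dark_to_light",
                      sigma: float = 1.0) -> np.ndarray:
    """Normalized one-sided vertical derivative of the image.

    ``dark_to_light`` keeps positive downward derivatives (intensity increases
    with row index), ``light_to_dark`` the negative ones.  The image is
    smoothed with a Gaussian (sigma 1, ~5 px support) before the central
    difference; the result is min-max scaled to [0, 1] per image (all zeros
    for a constant image).
    """
    pixels = _as_array(image)
    if polarity not in ("dark_to_light", "light_to_dark"):
        raise ValueError(f"unknown polarity: {polarity!r}")
    # difference first: integer-valued global shifts cancel exactly, making
    # the gradient (and thus the recovered boundaries) shift-invariant
    grad = np.gradient(pixels, axis=0)
    grad = gaussian_filter(grad, sigma=sigma, mode="nearest", truncate=2.0)
    if polarity == "light_to_dark":
        grad = -grad
    grad = np.clip(grad, 0.0, None)
    peak = grad.max()
    if peak > 0:
        grad = grad / peak
    return grad


def edge_weights(gradient_a, gradient_b, w_min: float = W_MIN_DEFAULT):
    """Edge weight between two nodes: ``2 - (g_a + g_b) + w_min``.

    Strictly positive and decreasing in both normalized gradients.
    """
    return 2.0 - (np.asarray(gradient_a) + np.asarray(gradient_b)) + w_min


def _build_graph(grad: np.ndarray, w_min: float) -> tuple[csr_matrix, int, int]:
    """Sparse directed graph over the gradient grid padded with virtual columns."""
    h, w = grad.shape
    g = np.ones((h, w + 2))
    g[:, 1:-1] = grad
    wp = w + 2

    def node(r, c):
        return r * wp + c

    rows_idx, cols_idx, data = [], [], []
    rr = np.arange(h)
    for c in range(wp - 1):
        for dr in (-1, 0, 1):
            r2 = rr + dr
            ok = (r2 >= 0) & (r2 < h)
            src = node(rr[ok], c)
            dst = node(r2[ok], c + 1)
            data.append(edge_weights(g[rr[ok], c], g[r2[ok], c + 1], w_min))
            rows_idx.append(src)
            cols_idx.append(dst)
    # free vertical movement in the two virtual columns only
    for c in (0, wp - 1):
        for dr in (-1, 1):
            r2 = rr + dr
            ok = (r2 >= 0) & (r2 < h)
            rows_idx.append(node(rr[ok], c))
            cols_idx.append(node(r2[ok], c))
            data.append(edge_weights(g[rr[ok], c], g[r2[ok], c], w_min))
    graph = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
        shape=(h * wp, h * wp),
    )
    return graph, h, wp


def shortest_path(grad: np.ndarray, w_min: float = W_MIN_DEFAULT,
                  return_cost: bool = False):
    """Minimum-cost left-to-right path through the gradient grid.

    Returns the per-column row index of the optimal boundary (and its total
    cost, including the virtual-column entry/exit edges, if ``return_cost``).
    """
    grad = np.asarray(grad, dtype=float)
    if grad.ndim != 2 or grad.shape[1] < 2:
        raise ValueError("gradient grid must be 2-D with width >= 2")
    graph, h, wp = _build_graph(grad, w_min)
    source = 0  # top-left virtual node; virtual columns are freely traversable
    dist, pred = dijkstra(graph, directed=True, indices=source,
                          return_predecessors=True)
    sinks = np.arange(h) * wp + (wp - 1)
    best_sink = sinks[np.argmin(dist[sinks])]
    # backtrack
    path_nodes = []
    node = best_sink
    while node != -9999 and node != source:
        path_nodes.append(node)
        node = pred[node]
    path_nodes.append(source)
    path_nodes.reverse()
    rows = np.array([n // wp for n in path_nodes])
    cols = np.array([n % wp for n in path_nodes])
    real = (cols >= 1) & (cols <= wp - 2)
    boundary = np.empty(wp - 2, dtype=int)
    boundary[cols[real] - 1] = rows[real]
    if return_cost:
        return boundary, float(dist[best_sink])
    return boundary


def segment_ilm_rpe(image, exclusion_margin: int = 10,
                    w_min: float = W_MIN_DEFAULT) -> LayerBoundaries:
    """Recover the ILM and RPE boundaries of a B-scan.

    Both interfaces are dark-to-light transitions: the first shortest path
    follows the strongest one; a band of ``exclusion_margin`` rows around it
    is then suppressed and the search repeated for the second.  The upper of
    the two paths is assigned to the ILM, the lower to the RPE.
    """
    grad = vertical_gradient(image, "dark_to_light")
    first = shortest_path(grad, w_min)
    grad2 = grad.copy()
    h = grad.shape[0]
    rows = np.arange(h)[:, None]
    band = np.abs(rows - first[None, :]) <= exclusion_margin
    grad2[band] = 0.0
    second = shortest_path(grad2, w_min)

    if first.mean() <= second.mean():
        ilm, rpe = first, second
    else:
        ilm, rpe = second, first
    if np.any(ilm >= rpe):
        raise SegmentationError(
            "ILM and RPE paths collide or cross", first, second)
    return LayerBoundaries(ilm_row=ilm, rpe_row=rpe)


def roi_mask(boundaries: LayerBoundaries, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the region of interest: rows between ILM and RPE inclusive."""
    h, w = shape
    if boundaries.ilm_row.shape[0] != w or boundaries.rpe_row.shape[0] != w:
        raise ValueError("boundaries do not match the requested shape")
    rows = np.arange(h)[:, None]
    return (rows >= boundaries.ilm_row[None, :]) & (rows <= boundaries.rpe_row[None, :])


def boundary_mae(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute per-column row error between two boundaries."""
    return float(np.mean(np.abs(np.asarray(estimated, float) - np.asarray(truth, float))))
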
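"""Superpixel region graphs and spectral graph machinery.

An image is partitioned into superpixels (SLIC clustering on intensity and
position); each region becomes a graph node carrying its mean pixel
intensity, and edges connect regions that touch under 8-connectivity. The
combinatorial Laplacian L = D - W of that region-adjacency graph supports
the graph Fourier transform q_hat = U^T q and exact spectral filtering
y = U g(Lambda) U^T x, which serves as the correctness oracle for the
Chebyshev convolution layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import json
import numpy as np
from skimage.segmentation import slic as _slic


@dataclass
class SuperpixelSegmentation:
    """A partition of an image into contiguous labeled regions."""

    label_map: np.ndarray  # integer raster, labels in [0, n_regions)
    n_regions: int
    region_sizes: np.ndarray
    region_centroids: np.ndarray  # (n_regions, 2) mean (row, col)


@dataclass
class RegionGraph:
    """Region-adjacency graph of one image.

    ``X`` holds one feature row per node (mean region intensity by default);
    ``W`` is the symmetric, zero-diagonal adjacency; Laplacian and spectrum
    are computed on construction. ``mask`` flags real (non-padding) nodes.
    """

    X: np.ndarray
    W: np.ndarray
    label: str | None = None
    source_id: str = ""
    L: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    lambda_max: float = 0.0
    mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.L is None:
            self.L = laplacian(self.W)
            # largest Laplacian eigenvalue, for Chebyshev rescaling
            self.lambda_max = float(np.linalg.eigvalsh(self.L)[-1])
        if self.mask is None:
            self.mask = np.ones(self.W.shape[0], dtype=bool)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


# ---------------------------------------------------------------------------
# segmentation and graph assembly


def segment_superpixels(
    image: np.ndarray,
    n_regions_target: int,
    compactness: float = 1.0,
    seed: int | None = None,
) -> SuperpixelSegmentation:
    """SLIC superpixel clustering on (intensity, x, y).

    The achieved region count is approximate (SLIC merges/splits clusters to
    keep regions contiguous) but stays near the target on typical images.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale raster")
    if n_regions_target < 2:
        raise ValueError("n_regions_target must be >= 2")
    if n_regions_target > img.size:
        raise ValueError("more regions requested than pixels")
    labels = _slic(
        img,
        n_segments=n_regions_target,
        compactness=compactness,
        channel_axis=None,
        start_label=0,
        enforce_connectivity=True,
    )
    # relabel to a dense 0..n-1 range
    uniq, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(img.shape)
    n = len(uniq)
    sizes = np.bincount(labels.ravel(), minlength=n)
    rows, cols = np.indices(img.shape)
    cent = np.stack(
        [
            np.bincount(labels.ravel(), weights=rows.ravel(), minlength=n) / sizes,
            np.bincount(labels.ravel(), weights=cols.ravel(), minlength=n) / sizes,
        ],
        axis=1,
    )
    return SuperpixelSegmentation(
        label_map=labels, n_regions=n, region_sizes=sizes, region_centroids=cent
    )


def region_features(image: np.ndarray, seg: SuperpixelSegmentation) -> np.ndarray:
    """Mean pixel intensity per region, as an (n_regions, 1) feature matrix."""
    img = np.asarray(image, dtype=float)
    if img.shape != seg.label_map.shape:
        raise ValueError("image and label map shapes differ")
    sums = np.bincount(
        seg.label_map.ravel(), weights=img.ravel(), minlength=seg.n_regions
    )
    counts = np.bincount(seg.label_map.ravel(), minlength=seg.n_regions)
    if np.any(counts == 0):
        raise RuntimeError("segmentation contains an empty region")
    return (sums / counts)[:, None]


def region_adjacency(
    seg: SuperpixelSegmentation,
    gaussian_sigma: float | None = None,
) -> np.ndarray:
    """Binary adjacency: W_ij = 1 iff regions i, j share a boundary under
    8-connectivity.

    With ``gaussian_sigma`` set, contiguous pairs instead get the weight
    exp(-d_ij^2 / (2 sigma^2)) of their centroid distance d_ij.
    """
    lm = seg.label_map
    n = seg.n_regions
    pairs = []
    # the four forward offsets cover all 8-connected neighbor pairs
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = lm[max(0, -dr) or None : lm.shape[0] - dr if dr > 0 else None,
               max(0, -dc) or None : lm.shape[1] - dc if dc > 0 else None]
        b = lm[dr if dr > 0 else None : lm.shape[0] + dr if dr < 0 else None,
               dc if dc > 0 else None : lm.shape[1] + dc if dc < 0 else None]
        diff = a != b
        pairs.append(np.stack([a[diff], b[diff]], axis=1))
    W = np.zeros((n, n))
    if pairs:
        ij = np.concatenate(pairs, axis=0)
        if len(ij):
            W[ij[:, 0], ij[:, 1]] = 1.0
            W[ij[:, 1], ij[:, 0]] = 1.0
    np.fill_diagonal(W, 0.0)
    if gaussian_sigma is not None:
        d = np.linalg.norm(
            seg.region_centroids[:, None, :] - seg.region_centroids[None, :, :],
            axis=2,
        )
        W *= np.exp(-(d**2) / (2.0 * gaussian_sigma**2))
    return W


def build_region_graph(
    image: np.ndarray,
    n_regions_target: int = 100,
    compactness: float = 1.0,
    gaussian_sigma: float | None = None,
    label: str | None = None,
    source_id: str = "",
    seed: int | None = None,
) -> RegionGraph:
    """Segment an image and assemble its region-adjacency graph."""
    seg = segment_superpixels(image, n_regions_target, compactness, seed)
    X = region_features(image, seg)
    W = region_adjacency(seg, gaussian_sigma)
    return RegionGraph(X=X, W=W, label=label, source_id=source_id)


# ---------------------------------------------------------------------------
# spectral machinery


def degree_matrix(W: np.ndarray) -> np.ndarray:
    """Diagonal matrix of row sums, D_ii = sum_j W_ij."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    return np.diag(W.sum(axis=1))


def laplacian(W: np.ndarray) -> np.ndarray:
    """Combinatorial graph Laplacian L = D - W."""
    return degree_matrix(W) - np.asarray(W, dtype=float)


def eigendecompose(L: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Orthonormal eigenbasis of a symmetric Laplacian.

    Returns (U, eigenvalues ascending, lambda_max) with L = U diag(lam) U^T.
    """
    L = np.asarray(L, dtype=float)
    if not np.allclose(L, L.T, atol=1e-8):
        raise ValueError("Laplacian must be symmetric")
    lam, U = np.linalg.eigh(L)
    return U, lam, float(lam[-1])


def graph_fourier(q: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Graph Fourier transform q_hat = U^T q."""
    q = np.asarray(q, dtype=float)
    if q.shape[0] != U.shape[0]:
        raise ValueError("signal length does not match node count")
    return U.T @ q


def inverse_graph_fourier(q_hat: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Inverse transform q = U q_hat."""
    q_hat = np.asarray(q_hat, dtype=float)
    if q_hat.shape[0] != U.shape[1]:
        raise ValueError("spectrum length does not match node count")
    return U @ q_hat


def spectral_filter(
    x: np.ndarray,
    g: Callable[[np.ndarray], np.ndarray],
    U: np.ndarray,
    lam: np.ndarray,
) -> np.ndarray:
    """Exact spectral filtering y = U g(Lambda) U^T x.

    ``x`` may be a vector or an (n_nodes, n_features) matrix; ``g`` is applied
    element-wise to the eigenvalues.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != U.shape[0]:
        raise ValueError("signal/feature matrix does not match node count")
    glam = np.asarray(g(np.asarray(lam, dtype=float)), dtype=float)
    if not np.all(np.isfinite(glam)):
        raise ValueError("filter function not finite on the spectrum")
    if x.ndim == 1:
        return U @ (glam * (U.T @ x))
    return U @ (glam[:, None] * (U.T @ x))


def scale_laplacian(L: np.ndarray, lambda_max: float) -> np.ndarray:
    """Rescale L so its spectrum lies in [-1, 1]: L_tilde = 2 L / lambda_max - I.

    Required for a numerically stable Chebyshev polynomial basis.
    """
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive (graph has no edges?)")
    L = np.asarray(L, dtype=float)
    return 2.0 * L / lambda_max - np.eye(L.shape[0])


def pad_graph(graph: RegionGraph, n_max: int) -> RegionGraph:
    """Append zero-feature isolated nodes so every graph has n_max nodes.

    Padding nodes have degree 0 and are excluded via the returned mask; the
    Laplacian gains an all-zero block, so spectral operators act on the real
    subgraph unchanged.
    """
    n = graph.n_nodes
    if n > n_max:
        raise ValueError(f"graph has {n} nodes, exceeds budget {n_max}")
    if n == n_max:
        return RegionGraph(
            X=graph.X,
            W=graph.W,
            label=graph.label,
            source_id=graph.source_id,
            L=graph.L,
            lambda_max=graph.lambda_max,
            mask=np.ones(n, dtype=bool),
        )
    pad = n_max - n
    X = np.vstack([graph.X, np.zeros((pad, graph.X.shape[1]))])
    W = np.zeros((n_max, n_max))
    W[:n, :n] = graph.W
    L = np.zeros((n_max, n_max))
    L[:n, :n] = graph.L
    mask = np.zeros(n_max, dtype=bool)
    mask[:n] = True
    return RegionGraph(
        X=X,
        W=W,
        label=graph.label,
        source_id=graph.source_id,
        L=L,
        lambda_max=graph.lambda_max,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# cached graph archives


def save_graph(graph: RegionGraph, path: str | Path, params: dict | None = None):
    """Write one graph as an .npz archive (sparse adjacency triplets) plus a
    JSON sidecar recording the segmentation parameters used."""
    path = Path(path)
    i, j = np.nonzero(graph.W)
    keep = i < j
    np.savez(
        path,
        X=graph.X,
        adj_i=i[keep],
        adj_j=j[keep],
        adj_w=graph.W[i[keep], j[keep]],
        n_nodes=graph.n_nodes,
        label=graph.label or "",
        source_id=graph.source_id,
    )
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(params or {}, fh, indent=2)


def load_graph(path: str | Path) -> RegionGraph:
    with np.load(Path(path), allow_pickle=False) as z:
        n = int(z["n_nodes"])
        W = np.zeros((n, n))
        W[z["adj_i"], z["adj_j"]] = z["adj_w"]
        W[z["adj_j"], z["adj_i"]] = z["adj_w"]
        label = str(z["label"]) or None
        return RegionGraph(
            X=z["X"], W=W, label=label, source_id=str(z["source_id"])
        )
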
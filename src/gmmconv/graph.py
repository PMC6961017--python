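"""Superpixel region graphs for graph convolutional networks.

An image is partitioned into SLIC superpixels; each superpixel becomes a
graph node carrying its mean intensity, and directed edges connect every
ordered pair of superpixels whose hop distance on the region-adjacency
graph is at most ``D`` (loops included).  Each edge carries a 2-D
pseudo-coordinate ``u(s, t)``: the offset of t's centroid relative to s's,
expressed with x rightward and y *upward* (image rows increase downward,
so the row axis is negated) and divided by ``coord_scale`` so that typical
1-hop offsets have magnitude about one.  Continuous filters are evaluated
at these pseudo-coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.segmentation import slic
from skimage.transform import rescale


@dataclass
class GraphBuildConfig:
    """Parameters controlling image-to-graph conversion.

    Attributes
    ----------
    area : float
        Expected average superpixel area A in pixels^2; the requested SLIC
        segment count is ``round(H*W / A)``.
    hops : int
        Maximum hop distance D on the region-adjacency graph; all ordered
        pairs within D hops are connected (plus loops).
    target_scale : float
        Scaling constant W applied to mask-derived node targets; values
        well above 1 steer training away from the all-zero local minimum.
    downscale : float
        Linear scale factor applied to image and mask before segmentation
        (bilinear for images, nearest for masks).
    compactness : float
        SLIC compactness.
    coord_scale : float or None
        Pseudo-coordinate normaliser in pixels; ``None`` means
        ``hops * sqrt(area)``.
    """

    area: float = 256.0
    hops: int = 2
    target_scale: float = 100.0
    downscale: float = 1.0
    compactness: float = 10.0
    coord_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.area < 4:
            raise ValueError(f"expected superpixel area must be >= 4, got {self.area}")
        if int(self.hops) != self.hops or self.hops < 1:
            raise ValueError(f"hop distance must be an integer >= 1, got {self.hops}")
        if self.target_scale <= 0:
            raise ValueError("target_scale must be positive")
        if not (0 < self.downscale <= 1):
            raise ValueError("downscale must lie in (0, 1]")

    @property
    def effective_coord_scale(self) -> float:
        if self.coord_scale is not None:
            return float(self.coord_scale)
        return float(self.hops) * float(np.sqrt(self.area))


@dataclass
class LabelMap:
    """Superpixel segmentation: one contiguous label in 0..K-1 per pixel."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def node_count(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class SuperpixelGraph:
    """Directed graph over superpixels.

    ``edge_src[e] -> edge_dst[e]`` with pseudo-coordinate ``pseudo[e]``;
    the edge list is sorted lexicographically by (src, dst) and contains a
    loop (k, k) with u = (0, 0) for every node.
    """

    node_count: int
    features: np.ndarray            # (K, N) in [0, 1]
    edge_src: np.ndarray            # (E,) int
    edge_dst: np.ndarray            # (E,) int
    pseudo: np.ndarray              # (E, 2) float, (x, y) convention
    centroids: np.ndarray           # (K, 2) float, (row, col) pixel coords
    targets: Optional[np.ndarray] = None   # (K,) in [0, W]
    labels: Optional[np.ndarray] = None    # (H, W) int, if built from an image
    coord_scale: float = 1.0

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        K = self.node_count
        if self.features.shape[0] != K or self.centroids.shape[0] != K:
            raise ValueError("feature/centroid table size mismatch")
        pairs = set(zip(self.edge_src.tolist(), self.edge_dst.tolist()))
        if len(pairs) != self.n_edges:
            raise ValueError("duplicate edges")
        for k in range(K):
            if (k, k) not in pairs:
                raise ValueError(f"missing loop edge at node {k}")
        loops = self.edge_src == self.edge_dst
        if not np.all(self.pseudo[loops] == 0.0):
            raise ValueError("loop pseudo-coordinates must be (0, 0)")
        index = {(s, t): e for e, (s, t) in enumerate(zip(self.edge_src, self.edge_dst))}
        for (s, t), e in index.items():
            rev = index.get((t, s))
            if rev is not None and not np.array_equal(self.pseudo[rev], -self.pseudo[e]):
                raise ValueError("pseudo-coordinates are not antisymmetric")
        if self.features.min() < 0 or self.features.max() > 1:
            raise ValueError("features outside [0, 1]")


def compute_superpixels(image: np.ndarray, config: GraphBuildConfig) -> LabelMap:
    """Segment a grayscale image into SLIC superpixels of expected area A.

    The requested segment count is ``round(H*W / A)``; SLIC may deliver a
    slightly different number.  Labels are relabelled to a contiguous
    0..K-1 range.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D grayscale array")
    h, w = image.shape
    if config.area > h * w:
        raise ValueError(f"superpixel area {config.area} exceeds image area {h * w}")
    n_segments = max(1, int(round(h * w / config.area)))
    if n_segments == 1:
        return LabelMap(np.zeros((h, w), dtype=np.int64))
    labels = slic(
        image,
        n_segments=n_segments,
        compactness=config.compactness,
        channel_axis=None,
        start_label=0,
        enforce_connectivity=True,
    )
    _, contiguous = np.unique(labels, return_inverse=True)
    return LabelMap(contiguous.reshape(h, w).astype(np.int64))


def mean_node_features(label_map: LabelMap, image: np.ndarray) -> np.ndarray:
    """Per-node mean intensity, shape (K, 1), values in [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != label_map.shape:
        raise ValueError("image and label map shapes differ")
    flat = label_map.labels.ravel()
    counts = np.bincount(flat)
    sums = np.bincount(flat, weights=image.ravel())
    return (sums / counts)[:, None]


def _adjacency_pairs(labels: np.ndarray) -> np.ndarray:
    """1-hop adjacency: superpixels sharing a 4-connected pixel boundary."""
    pairs = []
    a, b = labels[:, :-1], labels[:, 1:]
    m = a != b
    pairs.append(np.stack([a[m], b[m]], axis=1))
    a, b = labels[:-1, :], labels[1:, :]
    m = a != b
    pairs.append(np.stack([a[m], b[m]], axis=1))
    p = np.concatenate(pairs, axis=0)
    both = np.concatenate([p, p[:, ::-1]], axis=0)
    return np.unique(both, axis=0)


def node_centroids(label_map: LabelMap) -> np.ndarray:
    """Per-node mean pixel coordinate (row, col), shape (K, 2)."""
    labels = label_map.labels
    flat = labels.ravel()
    counts = np.bincount(flat).astype(np.float64)
    rr, cc = np.indices(labels.shape)
    rows = np.bincount(flat, weights=rr.ravel()) / counts
    cols = np.bincount(flat, weights=cc.ravel()) / counts
    return np.stack([rows, cols], axis=1)


def build_edges(label_map: LabelMap, hops: int, coord_scale: float = 1.0):
    """Directed edge list within ``hops`` of the adjacency graph, plus loops.

    Returns ``(edge_src, edge_dst, pseudo, centroids)``.  Pseudo-coordinates
    use x = dcol / coord_scale, y = -drow / coord_scale (y points upward so
    that angles follow the counterclockwise convention).
    """
    if hops < 1:
        raise ValueError("hop distance must be >= 1")
    labels = label_map.labels
    K = label_map.node_count
    adj = np.zeros((K, K), dtype=bool)
    pairs = _adjacency_pairs(labels)
    if len(pairs):
        adj[pairs[:, 0], pairs[:, 1]] = True
    reach = adj.copy()
    frontier = adj
    for _ in range(hops - 1):
        frontier = (frontier.astype(np.uint8) @ adj.astype(np.uint8)) > 0
        reach |= frontier
    np.fill_diagonal(reach, True)  # loops always present
    src, dst = np.nonzero(reach)
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    centroids = node_centroids(label_map)
    drow = centroids[dst, 0] - centroids[src, 0]
    dcol = centroids[dst, 1] - centroids[src, 1]
    pseudo = np.stack([dcol, -drow], axis=1) / float(coord_scale)
    pseudo[src == dst] = 0.0
    return src.astype(np.int64), dst.astype(np.int64), pseudo, centroids


def mask_to_targets(label_map: LabelMap, mask: np.ndarray, target_scale: float) -> np.ndarray:
    """Node targets: W times the mask coverage fraction of each superpixel.

    Superpixels straddling the mask border get fractional values in
    (0, W); fully covered superpixels get exactly W.
    """
    mask = np.asarray(mask)
    if mask.shape != label_map.shape:
        raise ValueError("mask and label map shapes differ")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary {0, 1}")
    flat = label_map.labels.ravel()
    counts = np.bincount(flat)
    covered = np.bincount(flat, weights=mask.ravel().astype(np.float64))
    return float(target_scale) * covered / counts


def build_graph(
    image: np.ndarray,
    mask: Optional[np.ndarray] = None,
    config: Optional[GraphBuildConfig] = None,
) -> SuperpixelGraph:
    """Full image-to-graph pipeline: downscale, SLIC, features, edges, targets.

    Deterministic given identical inputs and configuration.
    """
    if config is None:
        config = GraphBuildConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:  # colour input: luminance average
        image = image.mean(axis=2)
    if config.downscale < 1.0:
        image = rescale(image, config.downscale, order=1, anti_aliasing=True)
        image = np.clip(image, 0.0, 1.0)
        if mask is not None:
            mask = rescale(
                np.asarray(mask).astype(np.float64), config.downscale, order=0
            ).astype(np.int64)
    label_map = compute_superpixels(image, config)
    features = mean_node_features(label_map, image)
    scale = config.effective_coord_scale
    src, dst, pseudo, centroids = build_edges(label_map, config.hops, scale)
    targets = None
    if mask is not None:
        targets = mask_to_targets(label_map, np.asarray(mask), config.target_scale)
    return SuperpixelGraph(
        node_count=label_map.node_count,
        features=features,
        edge_src=src,
        edge_dst=dst,
        pseudo=pseudo,
        centroids=centroids,
        targets=targets,
        labels=label_map.labels,
        coord_scale=scale,
    )
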
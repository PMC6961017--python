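"""Soft node labels marking outer edges at a chosen orientation.

These targets drive the verification experiment: a network is trained to
highlight superpixels lying on a blob boundary whose outward direction
matches an orientation theta.  For each node s the label is an
orientation-weighted average of intensity differences to its neighbours,

    h_theta(s) = max( sum_t w^2 (f(t) - f(s)) / sum_t w^2 , 0 ),
    w = sin(alpha(s, t) - theta),

summing only neighbours with w > 0, where alpha(s, t) is the angle of
the edge (s, t) against the horizontal axis (counterclockwise, y up).
With theta = 0 the label is positive where intensity increases upward
across a horizontal boundary, i.e. for superpixels sitting on or just
below (in image rows) a blob's lower horizontal edge.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .graph import GraphBuildConfig, SuperpixelGraph, build_graph


def edge_angle(graph: SuperpixelGraph, s: int, t: int) -> float:
    """Angle alpha(s, t) of the edge pseudo-coordinate, in (-pi, pi].

    Undefined (and rejected) for loop edges.
    """
    if s == t:
        raise ValueError("edge angle is undefined for loop edges")
    match = (graph.edge_src == s) & (graph.edge_dst == t)
    idx = np.nonzero(match)[0]
    if len(idx) == 0:
        raise ValueError(f"no edge ({s}, {t}) in graph")
    ux, uy = graph.pseudo[idx[0]]
    return float(np.arctan2(uy, ux))


def orientation_weight(alpha, theta: float):
    """Edge orientation weight sin(alpha - theta)."""
    return np.sin(np.asarray(alpha) - theta)


def oriented_targets(graph: SuperpixelGraph, f: np.ndarray, theta: float) -> np.ndarray:
    """Per-node soft label h_theta; nodes with no positively weighted neighbour get 0."""
    f = np.asarray(f, dtype=np.float64).reshape(-1)
    src, dst = graph.edge_src, graph.edge_dst
    nonloop = src != dst
    s, t = src[nonloop], dst[nonloop]
    u = graph.pseudo[nonloop]
    alpha = np.arctan2(u[:, 1], u[:, 0])
    w = np.sin(alpha - theta)
    keep = w > 0
    s, t, w = s[keep], t[keep], w[keep]
    w2 = w * w
    num = np.zeros(graph.node_count)
    den = np.zeros(graph.node_count)
    np.add.at(num, s, w2 * (f[t] - f[s]))
    np.add.at(den, s, w2)
    h = np.zeros(graph.node_count)
    ok = den > 0
    h[ok] = np.maximum(num[ok] / den[ok], 0.0)
    return h


def make_verification_dataset(
    masks: Sequence[np.ndarray],
    theta: float,
    config: GraphBuildConfig = None,
) -> dict:
    """Graphs and oriented targets for the edge-orientation experiment.

    Each binary blob mask is converted to an A=400, D=1 superpixel graph
    whose node features are the mask coverage in [0, 1]; targets are
    ``oriented_targets`` at ``theta``.  The first 100 masks are split
    60/20/20 into train/validation/test.

    Returns ``{"train": [...], "val": [...], "test": [...]}`` where each
    element is a SuperpixelGraph with ``targets`` set.
    """
    if config is None:
        config = GraphBuildConfig(area=400.0, hops=1, target_scale=1.0, downscale=1.0)
    if len(masks) < 100:
        raise ValueError(f"need at least 100 masks, got {len(masks)}")
    graphs: List[SuperpixelGraph] = []
    for mask in masks[:100]:
        mask = np.asarray(mask)
        g = build_graph(mask.astype(np.float64), mask=None, config=config)
        g.targets = oriented_targets(g, g.features[:, 0], theta)
        graphs.append(g)
    return {"train": graphs[:60], "val": graphs[60:80], "test": graphs[80:100]}


def retarget(graphs: Sequence[SuperpixelGraph], theta: float) -> List[SuperpixelGraph]:
    """The same graphs with targets recomputed for a different orientation."""
    out = []
    for g in graphs:
        g2 = SuperpixelGraph(
            node_count=g.node_count, features=g.features, edge_src=g.edge_src,
            edge_dst=g.edge_dst, pseudo=g.pseudo, centroids=g.centroids,
            targets=oriented_targets(g, g.features[:, 0], theta),
            labels=g.labels, coord_scale=g.coord_scale)
        out.append(g2)
    return out
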
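"""Shared fixtures: random graphs and an independent brute-force oracle.

The oracle evaluates the layer equation directly — an explicit Python
loop over edges, channel pairs and Gaussian components — and is kept
deliberately separate from the package's vectorised kernels.
"""

import numpy as np
import pytest

from gmmconv.graph import SuperpixelGraph


def random_graph(rng, n_nodes, n_channels=1, edge_prob=0.35, with_targets=False):
    """A random directed graph with loops and antisymmetric pseudo-coordinates."""
    pairs = [(s, t) for s in range(n_nodes) for t in range(s + 1, n_nodes)
             if rng.random() < edge_prob]
    edges = {(k, k): np.zeros(2) for k in range(n_nodes)}
    for s, t in pairs:
        v = rng.normal(scale=1.0, size=2)
        edges[(s, t)] = v
        edges[(t, s)] = -v
    keys = sorted(edges)
    src = np.array([k[0] for k in keys], dtype=np.int64)
    dst = np.array([k[1] for k in keys], dtype=np.int64)
    pseudo = np.array([edges[k] for k in keys])
    return SuperpixelGraph(
        node_count=n_nodes,
        features=rng.random((n_nodes, n_channels)),
        edge_src=src, edge_dst=dst, pseudo=pseudo,
        centroids=rng.random((n_nodes, 2)) * 50,
        targets=rng.random(n_nodes) if with_targets else None,
    )


def gaussian_mixture_value(g, mu, var, u):
    """Direct term-by-term evaluation of the mixture at point u."""
    total = 0.0
    for j in range(len(g)):
        quad = sum((u[d] - mu[j, d]) ** 2 / var[j, d] for d in range(2))
        total += g[j] * np.exp(-0.5 * quad)
    return total


def layer_forward_oracle(graph, f, layer, coord_transform=None):
    """Naive per-edge, per-channel-pair evaluation of one conv layer."""
    Q = np.eye(2) if coord_transform is None else coord_transform
    K = graph.node_count
    M, N = layer.n_out, layer.n_in
    var = layer.var
    pre = np.zeros((K, M))
    for m in range(M):
        pre[:, m] = float(np.sum(layer.b[m]))  # effective channel bias
    for e in range(graph.n_edges):
        s, t = int(graph.edge_src[e]), int(graph.edge_dst[e])
        u = Q @ graph.pseudo[e]
        for m in range(M):
            for n in range(N):
                phi = gaussian_mixture_value(layer.g[m, n], layer.mu[m, n],
                                             var[m, n], u)
                pre[s, m] += phi * f[t, n]
    return np.maximum(pre, 0.0) if layer.activation == "relu" else pre


def network_forward_oracle(net, graph, f):
    h = np.atleast_2d(np.asarray(f, dtype=float))
    if h.shape[0] == 1 and graph.node_count != 1:
        h = h.T
    for layer in net.layers:
        h = layer_forward_oracle(graph, h, layer, net.coord_transform)
    return h


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
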
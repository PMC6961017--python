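"""GMM-filter convolution layers and sequential networks.

A layer owns an independent Gaussian-mixture filter for every pair of
input channel n and output channel m, a bias per output channel and an
element-wise activation:

    h_m(s) = act( b_m + sum_n sum_{t in N(s)} phi_{n,m}(u(s, t)) f_n(t) )

Loop edges make a node its own neighbour, contributing phi(0, 0) f(s).
With J Gaussians per filter and d=2 pseudo-coordinates the trainable
parameter count is J(2d+1) per filter and M N (J(2d+1)+1) per layer.

A network is the left-to-right composition of layers whose channel
counts chain.  Each network additionally carries a 2x2 coordinate map Q
(identity after construction) applied to every pseudo-coordinate before
filter evaluation; analytic rotation and mirroring of a trained network
only update Q (see :mod:`gmmconv.transforms`).
"""

from __future__ import annotations

import json
from typing import List, Optional

import numpy as np

from . import _kernels
from .filters import D_COORD, GMMFilter
from .graph import SuperpixelGraph

ACTIVATIONS = ("relu", "identity")


class GMMConvLayer:
    """M output x N input channels of GMM filters, bias and activation.

    Parameters are stored as dense arrays: ``g`` (M, N, J), ``mu``
    (M, N, J, 2), ``log_var`` (M, N, J, 2) and ``b`` (M, N).  Variances
    are kept in log space so gradient steps can never drive them
    non-positive.  The bias is carried per filter pair — the effective
    per-channel bias of the layer equation is the row sum
    ``b.sum(axis=1)`` — so the trainable scalar count per layer is
    exactly M N (J(2d+1)+1).
    """

    def __init__(self, n_in: int, n_out: int, n_gaussians: int = 4,
                 activation: str = "relu"):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}; use one of {ACTIVATIONS}")
        self.n_in = int(n_in)
        self.n_out = int(n_out)
        self.n_gaussians = int(n_gaussians)
        self.activation = activation
        self.g = np.zeros((n_out, n_in, n_gaussians))
        self.mu = np.zeros((n_out, n_in, n_gaussians, D_COORD))
        self.log_var = np.zeros((n_out, n_in, n_gaussians, D_COORD))
        self.b = np.zeros((n_out, n_in))

    @property
    def var(self) -> np.ndarray:
        return np.exp(self.log_var)

    @property
    def effective_bias(self) -> np.ndarray:
        """Per-output-channel bias b_m = sum_n b[m, n]."""
        return self.b.sum(axis=1)

    def filter(self, n: int, m: int) -> GMMFilter:
        """The filter connecting input channel n to output channel m (a copy)."""
        return GMMFilter(self.g[m, n].copy(), self.mu[m, n].copy(), self.var[m, n].copy())

    @property
    def param_count(self) -> int:
        return self.n_out * self.n_in * (self.n_gaussians * (2 * D_COORD + 1) + 1)

    def param_arrays(self):
        return [self.g, self.mu, self.log_var, self.b]

    def copy(self) -> "GMMConvLayer":
        out = GMMConvLayer(self.n_in, self.n_out, self.n_gaussians, self.activation)
        out.g = self.g.copy()
        out.mu = self.mu.copy()
        out.log_var = self.log_var.copy()
        out.b = self.b.copy()
        return out

    def forward(self, src, dst, v, f):
        h, _, _ = _kernels.layer_forward(
            src, dst, v, np.ascontiguousarray(f, dtype=np.float64),
            self.g, self.mu, self.var, self.effective_bias,
            self.activation == "relu")
        return h


class GMMNetwork:
    """Sequential composition of GMM convolution layers."""

    def __init__(self, layers: List[GMMConvLayer],
                 coord_transform: Optional[np.ndarray] = None):
        for a, bl in zip(layers[:-1], layers[1:]):
            if a.n_out != bl.n_in:
                raise ValueError(
                    f"channel mismatch between layers: {a.n_out} -> {bl.n_in}")
        self.layers = layers
        if coord_transform is None:
            coord_transform = np.eye(D_COORD)
        self.coord_transform = np.asarray(coord_transform, dtype=np.float64)

    @property
    def n_in(self) -> int:
        return self.layers[0].n_in

    @property
    def n_out(self) -> int:
        return self.layers[-1].n_out

    @property
    def param_count(self) -> int:
        return sum(layer.param_count for layer in self.layers)

    def copy(self) -> "GMMNetwork":
        return GMMNetwork([l.copy() for l in self.layers], self.coord_transform.copy())

    def _edge_coords(self, graph: SuperpixelGraph) -> np.ndarray:
        v = graph.pseudo @ self.coord_transform.T
        return np.ascontiguousarray(v, dtype=np.float64)

    def forward(self, graph: SuperpixelGraph, f: Optional[np.ndarray] = None) -> np.ndarray:
        """Node outputs, shape (K, M_last).  ``f`` defaults to graph.features."""
        if f is None:
            f = graph.features
        f = np.asarray(f, dtype=np.float64)
        if f.ndim == 1:
            f = f[:, None]
        if f.shape[1] != self.n_in:
            raise ValueError(
                f"input has {f.shape[1]} channels, network expects {self.n_in}")
        v = self._edge_coords(graph)
        src, dst = graph.edge_src, graph.edge_dst
        h = f
        for layer in self.layers:
            h = layer.forward(src, dst, v, h)
        return h

    # -- training support -------------------------------------------------

    def forward_cached(self, graph: SuperpixelGraph, f: Optional[np.ndarray] = None):
        """Forward pass keeping per-layer caches for ``backward``."""
        if f is None:
            f = graph.features
        f = np.asarray(f, dtype=np.float64)
        if f.ndim == 1:
            f = f[:, None]
        v = self._edge_coords(graph)
        src, dst = graph.edge_src, graph.edge_dst
        caches = []
        h = np.ascontiguousarray(f)
        for layer in self.layers:
            h_out, pre, ecache = _kernels.layer_forward(
                src, dst, v, h, layer.g, layer.mu, layer.var,
                layer.effective_bias, layer.activation == "relu")
            caches.append((h, pre, ecache))
            h = h_out
        return h, (v, src, dst, caches)

    def backward(self, grad_out: np.ndarray, state):
        """Gradients of a scalar loss w.r.t. every trainable array.

        Returns a list per layer of ``[grad_g, grad_mu, grad_log_var,
        grad_b]`` matching :meth:`GMMConvLayer.param_arrays` order.
        """
        v, src, dst, caches = state
        grads: list = [None] * len(self.layers)
        grad_h = np.ascontiguousarray(grad_out, dtype=np.float64)
        for idx in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[idx]
            f_in, pre, ecache = caches[idx]
            var = layer.var
            gg, gmu, gvar, gb, gf = _kernels.layer_backward(
                src, dst, v, f_in, layer.g, layer.mu, var, pre, ecache,
                grad_h, layer.activation == "relu")
            # d/d log_var = d/d var * var; bias gradient broadcasts over n
            grads[idx] = [gg, gmu, gvar * var,
                          np.repeat(gb[:, None], layer.n_in, axis=1)]
            grad_h = gf
        return grads

    def param_arrays(self):
        out = []
        for layer in self.layers:
            out.extend(layer.param_arrays())
        return out

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "coord_transform": self.coord_transform.tolist(),
            "layers": [
                {
                    "n_in": l.n_in,
                    "n_out": l.n_out,
                    "n_gaussians": l.n_gaussians,
                    "activation": l.activation,
                    "g": l.g.tolist(),
                    "mu": l.mu.tolist(),
                    "log_var": l.log_var.tolist(),
                    "b": l.b.tolist(),
                }
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GMMNetwork":
        layers = []
        for spec in data["layers"]:
            layer = GMMConvLayer(spec["n_in"], spec["n_out"], spec["n_gaussians"],
                                 spec["activation"])
            layer.g = np.asarray(spec["g"], dtype=np.float64)
            layer.mu = np.asarray(spec["mu"], dtype=np.float64)
            layer.log_var = np.asarray(spec["log_var"], dtype=np.float64)
            layer.b = np.asarray(spec["b"], dtype=np.float64)
            layers.append(layer)
        return cls(layers, np.asarray(data["coord_transform"], dtype=np.float64))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GMMNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def param_count(net: GMMNetwork) -> int:
    """Total trainable scalars, sum over layers of M N (J(2d+1)+1)."""
    return net.param_count


def init_glorot(net: GMMNetwork, seed: Optional[int] = None) -> GMMNetwork:
    """Initialise a network in place and return it.

    Mixture weights g are Glorot-uniform with fan_in = N*J and
    fan_out = M*J; means are uniform on [-1, 1]^2 (the unit-scaled
    pseudo-coordinate range); variances start at 1; biases at 0.
    """
    rng = np.random.default_rng(seed)
    for layer in net.layers:
        fan_in = layer.n_in * layer.n_gaussians
        fan_out = layer.n_out * layer.n_gaussians
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        layer.g = rng.uniform(-limit, limit, size=layer.g.shape)
        layer.mu = rng.uniform(-1.0, 1.0, size=layer.mu.shape)
        layer.log_var = np.zeros_like(layer.log_var)
        layer.b = np.zeros_like(layer.b)
    return net
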
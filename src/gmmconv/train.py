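"""Training loop, argmax-node detection and rotation-ensemble decision rules.

Training minimises the mean squared error between network node outputs
and node targets with Adam, cycling over the training graphs one graph
per optimisation step (an "epoch" is one pass over all training graphs).
Every ``eval_interval`` epochs the mean MSE over the training and
validation sets is recorded, and the returned model is the snapshot with
the smallest recorded validation MSE.

Detection picks the node with the highest network response; a detection
counts as a hit when that node's centroid falls inside the ground-truth
bounding box enlarged by a superpixel-sized margin on every side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import SuperpixelGraph
from .network import GMMConvLayer, GMMNetwork, init_glorot
from .transforms import RotationBank


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 2000
    eval_interval: int = 50
    seed: int = 0
    # loss is mean squared error and the optimizer is Adam throughout

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0 or self.eval_interval < 1:
            raise ValueError("epochs must be >= 0 and eval_interval >= 1")


@dataclass
class DetectionResult:
    node: int
    centroid: np.ndarray
    score: float
    hit: Optional[bool] = None
    angle: float = 0.0


class Adam:
    """Adam over a list of parameter arrays (updates in place)."""

    def __init__(self, params: List[np.ndarray], lr: float,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _graph_mse(net: GMMNetwork, graph: SuperpixelGraph) -> float:
    out = net.forward(graph)[:, 0]
    return float(np.mean((out - graph.targets) ** 2))


def mean_mse(net: GMMNetwork, graphs: Sequence[SuperpixelGraph]) -> float:
    """Mean over graphs of the per-graph node MSE."""
    return float(np.mean([_graph_mse(net, g) for g in graphs]))


def train(
    net: GMMNetwork,
    train_graphs: Sequence[SuperpixelGraph],
    val_graphs: Sequence[SuperpixelGraph],
    config: TrainConfig,
) -> Tuple[GMMNetwork, List[dict]]:
    """Train in place; return (best network copy, history).

    History holds one record per evaluation epoch (eval_interval,
    2*eval_interval, ...) with train and validation MSE; the returned
    network is the snapshot at the record with minimal validation MSE
    (the initial network if no evaluation ever ran).
    """
    for g in list(train_graphs) + list(val_graphs):
        if g.targets is None:
            raise ValueError("all graphs must carry targets for training")
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.param_arrays(), lr=config.learning_rate)
    history: List[dict] = []
    best = net.copy()
    best_val = np.inf
    best_epoch = 0
    n = len(train_graphs)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for gi in order:
            graph = train_graphs[gi]
            out, state = net.forward_cached(graph)
            target = graph.targets[:, None]
            grad_out = 2.0 * (out - target) / out.size
            grads_nested = net.backward(grad_out, state)
            flat = [a for layer in grads_nested for a in layer]
            opt.step(flat)
        if epoch % config.eval_interval == 0:
            tr = mean_mse(net, train_graphs)
            va = mean_mse(net, val_graphs) if len(val_graphs) else np.nan
            history.append({"epoch": epoch, "train_mse": tr, "val_mse": va})
            if len(val_graphs) and va < best_val:
                best_val = va
                best = net.copy()
                best_epoch = epoch
    if not history or not len(val_graphs):
        best = net.copy()
    best_epoch_attr = best_epoch if history else 0
    for rec in history:
        rec["selected"] = rec["epoch"] == best_epoch_attr
    return best, history


def detect(output: np.ndarray, centroids: np.ndarray) -> DetectionResult:
    """Argmax-node detection; ties broken by the lowest node id."""
    output = np.asarray(output).reshape(-1)
    if output.size == 0:
        raise ValueError("cannot detect on an empty graph")
    node = int(np.argmax(output))  # argmax returns the first (lowest-id) maximum
    return DetectionResult(node=node, centroid=np.asarray(centroids[node]),
                           score=float(output[node]))


def evaluate_hit(result: DetectionResult, bbox, enlargement: float) -> bool:
    """True iff the detected centroid lies inside the enlarged bounding box.

    ``bbox`` is (rmin, cmin, rmax, cmax) inclusive; the box grows by
    ``enlargement`` pixels on every side and the boundary counts as
    inside.
    """
    rmin, cmin, rmax, cmax = bbox
    r, c = result.centroid
    hit = (rmin - enlargement <= r <= rmax + enlargement
           and cmin - enlargement <= c <= cmax + enlargement)
    result.hit = bool(hit)
    return result.hit


def ensemble_detect_max(bank: RotationBank, graph: SuperpixelGraph) -> DetectionResult:
    """Run every rotated network; keep the globally maximal node response.

    Ties are broken by smaller |theta|, then smaller theta, then lower
    node id.
    """
    best: Optional[DetectionResult] = None
    for theta, net in bank:
        out = net.forward(graph)[:, 0]
        res = detect(out, graph.centroids)
        res.angle = float(theta)
        if best is None:
            best = res
            continue
        key = (-res.score, abs(res.angle), res.angle, res.node)
        best_key = (-best.score, abs(best.angle), best.angle, best.node)
        if key < best_key:
            best = res
    return best


def ensemble_detect_any(bank: RotationBank, graph: SuperpixelGraph, bbox,
                        enlargement: float) -> bool:
    """True iff at least one rotated network's argmax node scores a hit."""
    for theta, net in bank:
        out = net.forward(graph)[:, 0]
        res = detect(out, graph.centroids)
        res.angle = float(theta)
        if evaluate_hit(res, bbox, enlargement):
            return True
    return False


def accuracy(results: Sequence[bool]) -> float:
    """Fraction of hits."""
    if len(results) == 0:
        raise ValueError("accuracy of an empty result list is undefined")
    return float(np.count_nonzero(results)) / len(results)


ARCHITECTURES = {
    # (channels per layer boundary, activations)
    "verification": ([1, 10, 1], ["relu", "identity"]),
    "main": ([1, 20, 10, 5, 1], ["relu", "relu", "relu", "identity"]),
    "main_plus": ([1, 20, 20, 10, 5, 1], ["relu", "relu", "relu", "relu", "identity"]),
}


def build_architecture(name: str, n_gaussians: int = 4,
                       seed: Optional[int] = None) -> GMMNetwork:
    """One of the named architectures; Glorot-initialised when a seed is given.

    ``verification``: 1 -> 10 -> 1 channels (two layers, 420 parameters).
    ``main``: 1 -> 20 -> 10 -> 5 -> 1 (four layers, 5775 parameters).
    ``main_plus``: ``main`` with one extra 20-group layer at the input.
    """
    if name not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {name!r}; choose from {sorted(ARCHITECTURES)}")
    channels, acts = ARCHITECTURES[name]
    layers = [GMMConvLayer(channels[i], channels[i + 1], n_gaussians, acts[i])
              for i in range(len(acts))]
    net = GMMNetwork(layers)
    if seed is not None:
        init_glorot(net, seed)
    return net
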
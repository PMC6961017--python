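"""Scikit-learn-style estimators wrapping the graph pipeline and the network.

`SuperpixelGraphBuilder` is a stateless transformer turning images (or
image/mask pairs, or Scenes) into superpixel graphs; `GMMGraphRegressor`
fits a GMM-filter graph network to node targets and predicts per-node
responses.  Both follow the scikit-learn parameter protocol
(``get_params`` / ``set_params`` / ``clone``), so they compose with
sklearn model-selection utilities even though their samples are graphs
rather than feature rows.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .graph import GraphBuildConfig, SuperpixelGraph, build_graph
from .synth import Scene
from .train import TrainConfig, build_architecture, train, mean_mse


class SuperpixelGraphBuilder(BaseEstimator, TransformerMixin):
    """Transform images into superpixel graphs.

    Parameters mirror :class:`gmmconv.graph.GraphBuildConfig`.  Input
    samples may be plain grayscale arrays, ``(image, mask)`` pairs or
    :class:`gmmconv.synth.Scene` objects; masks yield node targets
    scaled by ``target_scale``.
    """

    def __init__(self, area: float = 256.0, hops: int = 2,
                 target_scale: float = 100.0, downscale: float = 1.0,
                 compactness: float = 10.0, coord_scale: Optional[float] = None):
        self.area = area
        self.hops = hops
        self.target_scale = target_scale
        self.downscale = downscale
        self.compactness = compactness
        self.coord_scale = coord_scale

    def _config(self) -> GraphBuildConfig:
        return GraphBuildConfig(
            area=self.area, hops=self.hops, target_scale=self.target_scale,
            downscale=self.downscale, compactness=self.compactness,
            coord_scale=self.coord_scale)

    def fit(self, X=None, y=None):
        self.config_ = self._config()  # validates parameters
        return self

    def transform(self, X: Sequence) -> List[SuperpixelGraph]:
        config = self._config()
        out = []
        for item in X:
            if isinstance(item, Scene):
                image, mask = item.image, item.mask
            elif isinstance(item, tuple):
                image, mask = item
            else:
                image, mask = item, None
            out.append(build_graph(image, mask=mask, config=config))
        return out


class GMMGraphRegressor(BaseEstimator):
    """Node-level regressor: a trained GMM-filter graph convolution network.

    Parameters
    ----------
    architecture : str
        One of ``"verification"``, ``"main"``, ``"main_plus"``.
    learning_rate, epochs, eval_interval : float, int, int
        Adam learning rate, training epochs (one per-graph step for each
        training graph per epoch) and validation cadence in epochs.
    validation_fraction : float
        Trailing fraction of the training graphs held out for model
        selection when no explicit validation set is passed to ``fit``.
    random_state : int
        Seed for Glorot initialisation and graph ordering.

    Attributes
    ----------
    network_ : GMMNetwork
        The selected (minimum validation MSE) network.
    history_ : list of dict
        Per-evaluation train/validation MSE records.
    """

    def __init__(self, architecture: str = "main", learning_rate: float = 1e-4,
                 epochs: int = 2000, eval_interval: int = 50,
                 n_gaussians: int = 4, validation_fraction: float = 0.25,
                 random_state: int = 0):
        self.architecture = architecture
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.eval_interval = eval_interval
        self.n_gaussians = n_gaussians
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X: Sequence[SuperpixelGraph], y=None,
            X_val: Optional[Sequence[SuperpixelGraph]] = None):
        """Fit on graphs carrying targets (or targets passed as ``y``)."""
        graphs = [self._with_targets(g, t) for g, t in
                  zip(X, y if y is not None else [None] * len(X))]
        if X_val is None:
            n_val = max(1, int(round(len(graphs) * self.validation_fraction)))
            train_graphs, val_graphs = graphs[:-n_val], graphs[-n_val:]
        else:
            train_graphs, val_graphs = graphs, list(X_val)
        net = build_architecture(self.architecture, n_gaussians=self.n_gaussians,
                                 seed=self.random_state)
        cfg = TrainConfig(learning_rate=self.learning_rate, epochs=self.epochs,
                          eval_interval=self.eval_interval, seed=self.random_state)
        self.network_, self.history_ = train(net, train_graphs, val_graphs, cfg)
        return self

    @staticmethod
    def _with_targets(graph: SuperpixelGraph, targets) -> SuperpixelGraph:
        if targets is None:
            return graph
        g = SuperpixelGraph(
            node_count=graph.node_count, features=graph.features,
            edge_src=graph.edge_src, edge_dst=graph.edge_dst,
            pseudo=graph.pseudo, centroids=graph.centroids,
            targets=np.asarray(targets, dtype=np.float64),
            labels=graph.labels, coord_scale=graph.coord_scale)
        return g

    def predict(self, X: Sequence[SuperpixelGraph]) -> List[np.ndarray]:
        """Per-node outputs (last channel) for each graph."""
        if not hasattr(self, "network_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        return [self.network_.forward(g)[:, 0] for g in X]

    def score(self, X: Sequence[SuperpixelGraph], y=None) -> float:
        """Negative mean MSE over graphs (higher is better)."""
        graphs = [self._with_targets(g, t) for g, t in
                  zip(X, y if y is not None else [None] * len(X))]
        return -mean_mse(self.network_, graphs)
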
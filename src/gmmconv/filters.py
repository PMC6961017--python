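"""Continuous convolutional filters defined by Gaussian mixtures.

A filter is a function of a 2-D pseudo-coordinate u:

    phi(u) = sum_j g_j * exp(-1/2 (u - mu_j)^T K_j^{-1} (u - mu_j))

with J scalar weights g_j (any sign), 2-D means mu_j and diagonal 2x2
covariances K_j (stored as two positive variances each).  The trainable
parameter count is J(2d+1) with d=2.

Because the filter lives in continuous coordinate space it can be rotated
or mirrored *exactly* after training by composing the evaluation point
with a linear map — no raster resampling, no interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

D_COORD = 2  # pseudo-coordinate dimensionality


@dataclass
class GMMFilter:
    """One Gaussian-mixture filter: weights (J,), means (J, 2), variances (J, 2)."""

    g: np.ndarray
    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.atleast_1d(np.asarray(self.g, dtype=np.float64))
        self.mu = np.asarray(self.mu, dtype=np.float64).reshape(len(self.g), D_COORD)
        self.var = np.asarray(self.var, dtype=np.float64).reshape(len(self.g), D_COORD)
        if np.any(self.var <= 0):
            raise ValueError("all variances must be positive")

    @property
    def n_gaussians(self) -> int:
        return len(self.g)

    @property
    def param_count(self) -> int:
        return self.n_gaussians * (2 * D_COORD + 1)

    def response(self, u) -> np.ndarray:
        """Evaluate phi at one or many pseudo-coordinates.

        ``u`` may be shape (2,) or (..., 2); the result drops the last axis.
        """
        u = np.asarray(u, dtype=np.float64)
        single = u.ndim == 1
        pts = np.atleast_2d(u)
        diff = pts[:, None, :] - self.mu[None, :, :]          # (P, J, 2)
        quad = np.sum(diff * diff / self.var[None, :, :], axis=2)
        vals = np.sum(self.g[None, :] * np.exp(-0.5 * quad), axis=1)
        return float(vals[0]) if single else vals.reshape(u.shape[:-1])


@dataclass
class TransformedFilter:
    """A base filter composed with a linear coordinate map Q: phi'(u) = phi(Q u).

    Rotation by theta uses Q = R(-theta); mirroring across the vertical
    axis uses Q = diag(-1, 1).  The base filter is never modified.
    """

    base: GMMFilter
    transform: np.ndarray

    def __post_init__(self) -> None:
        self.transform = np.asarray(self.transform, dtype=np.float64).reshape(2, 2)

    @property
    def n_gaussians(self) -> int:
        return self.base.n_gaussians

    @property
    def param_count(self) -> int:
        return self.base.param_count

    def response(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=np.float64)
        return self.base.response(u @ self.transform.T)


def rotation_matrix(theta: float) -> np.ndarray:
    """Counterclockwise 2-D rotation matrix R(theta)."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]], dtype=np.float64)


MIRROR_MATRIX = np.array([[-1.0, 0.0], [0.0, 1.0]])  # reflect across vertical axis
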
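"""Analytic rotation and mirroring of trained filters and networks.

Because GMM filters live in continuous pseudo-coordinate space, a trained
filter can be rotated exactly: the rotated filter is

    phi_theta(u) = phi(R(-theta) u)

(equivalently mu -> R(theta) mu with covariance R K R^T).  We never
materialise rotated parameters — a network carries a 2x2 coordinate map
Q, and rotating it right-multiplies Q by R(-theta).  This keeps the
diagonal-covariance storage intact and makes the equivariance identity

    forward(Phi_theta, graph with u -> R(theta) u) == forward(Phi, graph)

hold to machine precision: if a trained network detects a structure, its
rotated copy detects the identically rotated structure.  Mirroring
(reflection across the vertical axis, u_x -> -u_x) works the same way
and lets a network trained on left ears score right ears.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np

from .filters import GMMFilter, MIRROR_MATRIX, TransformedFilter, rotation_matrix
from .network import GMMNetwork


def rotate_filter(filt: Union[GMMFilter, TransformedFilter], theta: float) -> TransformedFilter:
    """The rotated filter phi_theta with phi_theta(u) = phi(R(-theta) u)."""
    if isinstance(filt, TransformedFilter):
        return TransformedFilter(filt.base, filt.transform @ rotation_matrix(-theta))
    return TransformedFilter(filt, rotation_matrix(-theta))


def mirror_filter(filt: Union[GMMFilter, TransformedFilter]) -> TransformedFilter:
    """The mirrored filter phi^m with phi^m(u) = phi((-u_x, u_y))."""
    if isinstance(filt, TransformedFilter):
        return TransformedFilter(filt.base, filt.transform @ MIRROR_MATRIX)
    return TransformedFilter(filt, MIRROR_MATRIX.copy())


def rotate_network(net: GMMNetwork, theta: float) -> GMMNetwork:
    """A copy of ``net`` with every filter in every layer rotated by theta.

    Biases, activations and all stored parameters are unchanged; only the
    evaluation-coordinate map is composed with R(-theta).
    """
    out = net.copy()
    out.coord_transform = net.coord_transform @ rotation_matrix(-theta)
    return out


def mirror_network(net: GMMNetwork) -> GMMNetwork:
    """A copy of ``net`` with every filter reflected across the vertical axis."""
    out = net.copy()
    out.coord_transform = net.coord_transform @ MIRROR_MATRIX
    return out


def bank_angles(count: int) -> np.ndarray:
    """Rotation angles equally spaced over [-pi, pi].

    ``count`` nominal orientations give spacing 2*pi/(count-1); since
    -pi and +pi coincide modulo 2*pi only the -pi endpoint is stored, so
    ``count`` = 11 yields ten distinct networks at spacing pi/5 covering
    eleven nominal panels, with theta = 0 always present for odd counts.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if count == 1:
        return np.array([0.0])
    return np.linspace(-np.pi, np.pi, count)[:-1]


@dataclass
class RotationBank:
    """A base network plus its rotated copies at a grid of angles."""

    base: GMMNetwork
    angles: np.ndarray
    networks: List[GMMNetwork]

    def __iter__(self):
        return iter(zip(self.angles, self.networks))

    def __len__(self) -> int:
        return len(self.networks)


def rotation_bank(net: GMMNetwork, count: int = 11,
                  angles: Sequence[float] = None) -> RotationBank:
    """Build the rotated-network bank Phi_theta.

    The default 11 nominal orientations reproduce a pi/5 angular step;
    the network at angle 0 is numerically identical to the base network.
    """
    th = np.asarray(angles, dtype=np.float64) if angles is not None else bank_angles(count)
    nets = [rotate_network(net, float(t)) for t in th]
    return RotationBank(base=net, angles=th, networks=nets)
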
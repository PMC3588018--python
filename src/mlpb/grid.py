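"""Spatial discretization of the half-space [0, L].

The potential varies on two very different scales: steeply inside and just
beyond the headgroup region ``[0, 2D]`` (a fraction of a nanometre) and on
the Debye scale further out.  The grid therefore concentrates half of its
intervals on ``[0, 2D]``, built from three uniform segments ``[0, D]``,
``[D, 2D]`` and ``[2D, L]`` so that the headgroup boundary ``x = D`` is a
node *exactly* (the headgroup source term is discontinuous there).
Doubling the node budget doubles each segment count, so coarser node sets
are subsets of finer ones (dyadic refinement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .parameters import ModelParameters

#: Smallest accepted node budget; below this the headgroup region would be
#: unresolved.
MIN_NODES = 100


@dataclass(frozen=True)
class Grid:
    """1-D node set on [0, L] with the headgroup boundary resolved exactly.

    Attributes
    ----------
    x : ordered node positions, x[0] = 0, x[-1] = L (m)
    d_index : index with ``x[d_index] == D`` exactly
    spacing_policy : human-readable description of the segment layout
    """

    x: NDArray[np.float64]
    d_index: int
    spacing_policy: str

    @property
    def n_nodes(self) -> int:
        return self.x.size

    def __post_init__(self) -> None:
        x = self.x
        if x.ndim != 1 or x.size < 2:
            raise ValueError("grid needs at least two ordered nodes")
        if np.any(np.diff(x) <= 0):
            raise ValueError("grid nodes must be strictly increasing")
        if not (0 <= self.d_index < x.size):
            raise ValueError("d_index out of range")


def build_grid(params: ModelParameters, n_nodes: int = 4000) -> Grid:
    """Build the non-uniform grid for the given parameter set.

    ``n_nodes`` is the interval budget (the grid has ``n_nodes + 1`` nodes);
    it must be a multiple of 4 and at least :data:`MIN_NODES` so that each of
    the three uniform segments receives its share.  Deterministic for fixed
    inputs.
    """
    if n_nodes < MIN_NODES:
        raise ValueError(f"n_nodes must be >= {MIN_NODES}, got {n_nodes}")
    if n_nodes % 4 != 0:
        raise ValueError("n_nodes must be a multiple of 4 (dyadic segment split)")
    D, L = params.D, params.L
    if not (0 < 2 * D < L):
        raise ValueError("grid construction requires 2*D < L")
    n_quarter = n_nodes // 4
    seg1 = np.linspace(0.0, D, n_quarter + 1)
    seg2 = np.linspace(D, 2 * D, n_quarter + 1)
    seg3 = np.linspace(2 * D, L, n_nodes - 2 * n_quarter + 1)
    x = np.concatenate([seg1, seg2[1:], seg3[1:]])
    policy = (
        f"uniform segments [0,D]/{n_quarter}, [D,2D]/{n_quarter}, "
        f"[2D,L]/{n_nodes - 2 * n_quarter}"
    )
    return Grid(x=x, d_index=n_quarter, spacing_policy=policy)
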
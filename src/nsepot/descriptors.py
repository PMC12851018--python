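"""Neighbor lists and smooth, rotation-invariant atomic environment features.

Geometric features are radial only: Gaussian radial basis functions
modulated by a cosine cutoff, contracted against learned per-element
embedding vectors of the neighbors.  Angular correlations enter the model
through message passing over the evolving per-atom charges rather than
through explicit angular symmetry functions.  Every feature and its radial
derivative vanish identically at the cutoff, so predictions are smooth under
neighbor-list rebuilds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, segment_sum, tensor
from .systems import AtomicSystem

__all__ = ["NeighborList", "RadialBasis", "build_neighbor_list", "featurize"]


@dataclass
class NeighborList:
    """Directed pair list: (i, j) with i != j and r_ij <= cutoff."""

    pairs: np.ndarray          # (P, 2) int
    distances: np.ndarray      # (P,) Angstrom
    unit_vectors: np.ndarray   # (P, 3), points from j to i
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])


@dataclass
class RadialBasis:
    """Gaussian radial shells under a cosine cutoff envelope."""

    n_basis: int = 16
    cutoff: float = 5.0
    r_min: float = 0.5
    width: float = field(default=None)  # type: ignore[assignment]
    centers: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.centers is None:
            self.centers = np.linspace(self.r_min, self.cutoff, self.n_basis)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.width is None:
            self.width = float(self.centers[1] - self.centers[0]) if self.n_basis > 1 else 0.5

    def evaluate(self, r):
        """Basis values for pair distances `r` (array or Tensor) -> (P, n_basis).

        g_k(r) = exp(-(r - c_k)^2 / (2 w^2)) * fc(r) with the squared-cosine
        cutoff fc(r) = [0.5 (1 + cos(pi r / Rc))]^2 for r < Rc, 0 beyond.
        Squaring makes fc vanish quadratically and fc' cubically at Rc, so
        every basis function approaches the cutoff with a derivative that is
        itself going to zero.
        """
        r = tensor(r)
        rv = r.value
        inside = (rv < self.cutoff).astype(np.float64)
        # the mask is constant w.r.t. differentiation: fc and fc' vanish at Rc
        half = 0.5 * ((r * (np.pi / self.cutoff)).cos() + 1.0)
        fc = (half * half) * inside
        rcol = r.reshape(-1, 1)
        diff = rcol - self.centers[np.newaxis, :]
        gauss = ((diff * diff) * (-0.5 / self.width**2)).exp()
        return gauss * fc.reshape(-1, 1)


def build_neighbor_list(system: AtomicSystem, cutoff: float) -> NeighborList:
    """All directed pairs within `cutoff` (brute-force O(N^2), exact)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = system.coordinates
    delta = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((delta**2).sum(axis=-1))
    n = system.n_atoms
    mask = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    ii, jj = np.nonzero(mask)
    pairs = np.stack([ii, jj], axis=1)
    d = dist[ii, jj]
    with np.errstate(invalid="ignore", divide="ignore"):
        uv = delta[ii, jj] / d[:, None] if len(d) else np.zeros((0, 3))
    return NeighborList(pairs=pairs, distances=d, unit_vectors=uv, cutoff=float(cutoff))


def featurize(
    system: AtomicSystem,
    neighbor_list: NeighborList,
    basis: RadialBasis,
    embeddings: np.ndarray,
    coordinates=None,
):
    """Per-atom environment vectors, shape (N, n_basis * embedding_dim).

    env_i = sum_{j in N(i)} g(r_ij) (x) e_{Z_j}, an outer product of the
    radial basis expansion of each neighbor distance with the neighbor's
    element embedding, summed over neighbors.  Exactly invariant to global
    rotation/translation (depends only on distances) and equivariant under
    atom permutation.  `embeddings` maps Z -> embedding row; `coordinates`
    may be a Tensor to keep the graph differentiable.
    """
    coords = tensor(system.coordinates if coordinates is None else coordinates)
    n = system.n_atoms
    emb_dim = embeddings.shape[1] if hasattr(embeddings, "shape") else np.asarray(embeddings).shape[1]
    n_feat = basis.n_basis * emb_dim
    if neighbor_list.n_pairs == 0:
        return Tensor(np.zeros((n, n_feat)))
    ii = neighbor_list.pairs[:, 0]
    jj = neighbor_list.pairs[:, 1]
    delta = coords[ii] - coords[jj]
    r = ((delta * delta).sum(axis=1) + 1e-300).sqrt()
    g = basis.evaluate(r)                                   # (P, B)
    emb = tensor(embeddings)
    neigh_emb = emb[np.asarray(system.atomic_numbers)[jj]]  # (P, E)
    outer = g.reshape(-1, basis.n_basis, 1) * neigh_emb.reshape(-1, 1, emb_dim)
    env = segment_sum(outer.reshape(-1, n_feat), ii, n)
    return env
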
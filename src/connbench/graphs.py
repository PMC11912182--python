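"""Population graphs and their spectral preprocessing.

Graph-convolutional classifiers here operate transductively on a *population
graph*: one node per participant, edges encoding non-imaging similarity.  Two
constructions are supported:

* a binary site graph — weight 1 between participants scanned at the same
  collection site, 0 otherwise;
* trainable pairwise-association-encoder (PAE) weights computed from sex and
  site one-hot encodings, used by the edge-variational GCN (see
  :mod:`connbench.models`).

Chebyshev graph convolutions need the rescaled symmetric-normalized Laplacian
``L~ = 2 L / lambda_max - I`` whose spectrum lies in [-1, 1]; isolated nodes
contribute zero Laplacian rows, and a graph with no edges at all falls back to
the generic bound ``lambda_max = 2`` (hence ``L~ = -I``).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "build_site_graph",
    "scaled_laplacian",
    "PAE",
    "pae_edge_weights",
    "edge_dropout",
    "write_edge_list",
]


def build_site_graph(sites) -> np.ndarray:
    """Binary same-site adjacency (zero diagonal)."""
    sites = np.asarray(sites)
    if sites.size == 0:
        raise ValueError("site list must be non-empty")
    w = (sites[:, None] == sites[None, :]).astype(float)
    np.fill_diagonal(w, 0.0)
    return w


def scaled_laplacian(weights: np.ndarray, lam_tol: float = 1e-9) -> np.ndarray:
    """Rescaled normalized Laplacian with spectrum in [-1, 1].

    ``L = I - D^-1/2 W D^-1/2`` on nodes with positive degree (isolated nodes
    get zero rows/columns), then ``L~ = 2 L / lambda_max - I``.  ``lambda_max``
    is computed exactly by dense eigendecomposition; if the graph has no edges
    the generic upper bound 2 is used, which forces ``L~ = -I``.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be square")
    if (w < 0).any():
        raise ValueError("negative edge weights are not allowed")
    if np.abs(w - w.T).max() > 1e-10:
        raise ValueError("weights must be symmetric")
    n = w.shape[0]
    deg = w.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    lap = -w * inv_sqrt[:, None] * inv_sqrt[None, :]
    diag = np.where(deg > 0, 1.0, 0.0)
    lap[np.diag_indices(n)] += diag
    lam_max = float(np.linalg.eigvalsh(lap).max())
    if lam_max < lam_tol:
        lam_max = 2.0
    return 2.0 * lap / lam_max - np.eye(n)


class PAE:
    """Pairwise association encoder: phenotypes -> edge weights in (0, 1).

    Each participant's sex and site one-hots are mapped through a shared linear
    embedding ``h = tanh(E P + b)``; a pair's weight is a logistic function of
    an affine map of the order-invariant pair encoding ``[|h_i - h_j| , h_i*h_j]``.
    Parameters are plain autodiff tensors so the graph can be trained jointly
    with a classifier's loss.
    """

    def __init__(self, n_pheno: int, embed_dim: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        s = 1.0 / np.sqrt(n_pheno)
        self.P = Tensor(rng.uniform(-s, s, size=(n_pheno, embed_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(embed_dim), requires_grad=True)
        self.a = Tensor(
            rng.uniform(-0.5, 0.5, size=(2 * embed_dim,)), requires_grad=True
        )
        self.a0 = Tensor(np.zeros(()), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.P, self.b, self.a, self.a0]

    def weights(self, pheno: np.ndarray) -> Tensor:
        """Dense n x n symmetric weight tensor with zero diagonal."""
        E = Tensor(np.asarray(pheno, dtype=float))
        h = (E @ self.P + self.b).tanh()  # n x d
        n, d = h.shape
        hi = h.reshape(n, 1, d)
        hj = h.reshape(1, n, d)
        pair = concat([(hi - hj).abs(), hi * hj], axis=2)  # n x n x 2d
        logit = (pair * self.a.reshape(1, 1, 2 * d)).sum(axis=2) + self.a0
        w = logit.sigmoid()
        off = 1.0 - np.eye(n)
        return w * Tensor(off)


def pae_edge_weights(pheno: np.ndarray, pae: PAE | None = None, seed: int = 0) -> np.ndarray:
    """Convenience evaluation of PAE edge weights as a plain array."""
    pheno = np.asarray(pheno, dtype=float)
    if pheno.ndim != 2 or pheno.shape[0] < 2:
        raise ValueError("pheno must be an n x p matrix with n >= 2")
    if np.isnan(pheno).any():
        raise ValueError("missing phenotype values")
    if pae is None:
        pae = PAE(pheno.shape[1], seed=seed)
    return pae.weights(pheno).data


def write_edge_list(weights: np.ndarray, path) -> None:
    """Export a graph as a three-column TSV edge list (i, j, weight), i < j."""
    w = np.asarray(weights, dtype=float)
    i, j = np.triu_indices(w.shape[0], k=1)
    keep = w[i, j] != 0
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for a, b, v in zip(i[keep], j[keep], w[i, j][keep]):
            fh.write(f"{a}\t{b}\t{v:.17g}\n")


def edge_dropout(weights: np.ndarray, rate: float, seed: int, training: bool = True):
    """Randomly zero undirected edges with probability ``rate`` (training only).

    Surviving weights are rescaled by 1/(1-rate) so the expected graph is
    unchanged; at evaluation time the graph passes through untouched.
    Returns the dropout *mask* so it can also be applied to weight tensors.
    """
    w = np.asarray(weights, dtype=float)
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if not training or rate == 0:
        return w.copy(), np.ones_like(w)
    rng = np.random.default_rng(seed)
    n = w.shape[0]
    keep = rng.random((n, n)) >= rate
    keep = np.triu(keep, k=1)
    keep = keep + keep.T  # symmetric undirected mask
    mask = keep / (1.0 - rate)
    np.fill_diagonal(mask, 1.0)  # self-weights (if any) are never dropped
    return w * mask, mask
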
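"""Diffusion maps with an adaptive Gaussian kernel.

The feature space is embedded by the spectrum of a row-stochastic diffusion
operator built from a locally adaptive Gaussian affinity: the bandwidth of
each state is the distance to its ``ka``-th nearest neighbour, so dense and
sparse regions are put on a comparable footing. The multiscale embedding
rescales each non-trivial eigenvector by lambda/(1-lambda), aggregating
diffusion distances over all diffusion times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg

from .pseudobulk import exact_knn

logger = logging.getLogger(__name__)


class DisconnectedGraphError(ValueError):
    """The kernel graph has more than one connected component."""


@dataclass
class DiffusionMap:
    """Eigenpairs of the diffusion operator over the feature space."""

    eigenvalues: np.ndarray  # descending; lambda_1 ~ 1 for a connected graph
    eigenvectors: np.ndarray  # states x m right eigenvectors of P
    state_ids: np.ndarray
    k_dm: int
    ka: int
    n_components_at_one: int = 1

    @property
    def n_states(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class MultiscaleSpace:
    """States x n_eigs multiscale coordinates (eigvec_i * lambda_i/(1-lambda_i))."""

    coords: np.ndarray
    state_ids: np.ndarray
    n_eigs: int
    eigenvalues_used: np.ndarray = field(default=None)

    @property
    def n_states(self) -> int:
        return self.coords.shape[0]


def adaptive_kernel(features: np.ndarray, k_dm: int = 30, ka: int = 10) -> np.ndarray:
    """Adaptive Gaussian affinity over the union of KNN relations.

    sigma_i is the distance from state i to its ``ka``-th nearest neighbour;
    the affinity w_ij = exp(-d_ij^2 / (sigma_i sigma_j)) is kept wherever
    j is among i's ``k_dm`` neighbours or vice versa, symmetrised by the
    elementwise maximum, with zero diagonal. Duplicate states (sigma=0)
    fall back to their smallest positive neighbour distance.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if not 1 <= ka <= k_dm:
        raise ValueError(f"need 1 <= ka <= k_dm, got ka={ka}, k_dm={k_dm}")
    if k_dm >= n:
        raise ValueError(f"k_dm={k_dm} must be < n={n}")
    dist, idx = exact_knn(features, k_dm)
    sigma = dist[:, ka - 1].copy()
    if np.any(sigma == 0):
        logger.warning(
            "adaptive_kernel: %d duplicate state(s); widening zero bandwidths",
            int((sigma == 0).sum()),
        )
        for i in np.flatnonzero(sigma == 0):
            positive = dist[i][dist[i] > 0]
            sigma[i] = positive.min() if len(positive) else 1.0
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k_dm)
    cols = idx.ravel()
    d2 = (dist.ravel()) ** 2
    W[rows, cols] = np.exp(-d2 / (sigma[rows] * sigma[cols]))
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    return W


def diffusion_operator(affinity: np.ndarray) -> np.ndarray:
    """Row-normalise a symmetric non-negative affinity into a stochastic P."""
    affinity = np.asarray(affinity, dtype=float)
    if (affinity < 0).any():
        raise ValueError("affinity must be non-negative")
    row_sums = affinity.sum(axis=1)
    isolated = np.flatnonzero(row_sums == 0)
    if len(isolated):
        raise ValueError(f"isolated state(s) with zero affinity: {isolated.tolist()}")
    return affinity / row_sums[:, None]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each eigenvector positive."""
    flips = np.sign(vectors[np.argmax(np.abs(vectors), axis=0), np.arange(vectors.shape[1])])
    flips[flips == 0] = 1.0
    return vectors * flips


def diffusion_map(
    features: np.ndarray | pd.DataFrame,
    n_comps: int = 10,
    k_dm: int = 30,
    ka: int = 10,
    seed: int = 0,
) -> DiffusionMap:
    """Top eigenpairs of the diffusion operator of the feature space.

    The eigenproblem is solved on the symmetric conjugate
    ``D^{-1/2} W D^{-1/2}`` for numerical stability; right eigenvectors of
    P are recovered as ``D^{-1/2} v`` and sign-fixed for determinism.
    """
    if isinstance(features, pd.DataFrame):
        state_ids = features.index.to_numpy(dtype=object)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        state_ids = np.arange(X.shape[0])
    n = X.shape[0]
    if n_comps >= n:
        raise ValueError(f"n_comps={n_comps} must be < n_states={n}")
    k_dm = min(k_dm, n - 1)
    ka = max(1, min(ka, k_dm))
    W = adaptive_kernel(X, k_dm=k_dm, ka=ka)
    row_sums = W.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("kernel produced isolated states; increase k_dm")
    d_inv_sqrt = 1.0 / np.sqrt(row_sums)
    A = W * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    A = (A + A.T) / 2.0
    if n <= 200 or n_comps >= n - 1:
        vals, vecs = scipy.linalg.eigh(A)
        order = np.argsort(vals)[::-1][:n_comps]
        vals, vecs = vals[order], vecs[:, order]
    else:
        v0 = np.random.default_rng(seed).standard_normal(n)
        try:
            vals, vecs = scipy.sparse.linalg.eigsh(A, k=n_comps, which="LA", v0=v0)
        except scipy.sparse.linalg.ArpackNoConvergence as err:
            raise RuntimeError(
                "diffusion eigensolver failed to converge; try a larger k_dm"
            ) from err
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    phi = _fix_signs(vecs * d_inv_sqrt[:, None])
    n_at_one = int(np.sum(vals > 1 - 1e-8))
    if n_at_one > 1:
        logger.warning(
            "diffusion_map: %d eigenvalue(s) at 1 — kernel graph is disconnected",
            n_at_one,
        )
    return DiffusionMap(
        eigenvalues=vals,
        eigenvectors=phi,
        state_ids=state_ids,
        k_dm=k_dm,
        ka=ka,
        n_components_at_one=n_at_one,
    )


def multiscale_space(dm: DiffusionMap, n_eigs: int | str = "auto") -> MultiscaleSpace:
    """Multiscale embedding from the non-trivial diffusion eigenvectors.

    With ``n_eigs="auto"`` the number of components is set by the largest
    gap in the non-trivial spectrum (argmax of lambda_i - lambda_{i+1}),
    floored at 2. Component j is eigenvector j+1 scaled by
    lambda/(1-lambda); a used eigenvalue >= 1 means the input graph is
    disconnected and is an error.
    """
    lam = dm.eigenvalues
    m = len(lam)
    if n_eigs == "auto":
        if m < 3:
            n_eigs = 2
        else:
            # gaps[g] = lambda_{g+2} - lambda_{g+3}; keeping eigenvectors up to
            # the left edge of the largest gap retains g+1 non-trivial ones
            gaps = lam[1:-1] - lam[2:]
            n_eigs = max(2, int(np.argmax(gaps)) + 1)
    n_eigs = int(n_eigs)
    if n_eigs + 1 > m:
        raise ValueError(f"n_eigs={n_eigs} exceeds available eigenpairs ({m - 1})")
    use = slice(1, n_eigs + 1)
    lam_used = lam[use]
    if np.any(lam_used >= 1 - 1e-12):
        raise DisconnectedGraphError(
            "a non-trivial eigenvalue is at 1: the kernel graph is disconnected"
        )
    scale = lam_used / (1 - lam_used)
    coords = dm.eigenvectors[:, use] * scale[None, :]
    return MultiscaleSpace(
        coords=coords,
        state_ids=dm.state_ids,
        n_eigs=n_eigs,
        eigenvalues_used=lam_used,
    )
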
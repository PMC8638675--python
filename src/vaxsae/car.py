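"""Leroux conditional autoregressive (CAR) prior structure.

The three discrete district-level models share a Gaussian spatial random
effect phi ~ N(0, sigma_phi^2 Q(W)^-1) with precision structure

    Q(W) = rho * (diag(W 1) - W) + (1 - rho) * I,

where W is the binary district adjacency matrix, rho in [0, 1] the spatial
autocorrelation (rho = 0: iid effects; rho = 1: intrinsic CAR, improper),
and sigma_phi^2 a marginal variance parameter.

Because Q(W) is a convex combination of the graph Laplacian L = diag(W1) - W
and the identity, a single eigendecomposition L = V diag(lam) V' gives
Q = V diag(rho*lam + 1 - rho) V' for every rho, which this module exploits
for log-determinants, sampling and whitening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AdjacencyGraph",
    "LerouxParams",
    "leroux_precision",
    "leroux_logdet",
    "sample_leroux",
    "LerouxEigen",
]


@dataclass(frozen=True)
class LerouxParams:
    """Hyperparameters of the Leroux CAR prior."""

    rho: float
    sigma2_phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")
        if self.sigma2_phi <= 0:
            raise ValueError(f"sigma2_phi must be positive, got {self.sigma2_phi}")


class AdjacencyGraph:
    """Symmetric binary district adjacency with zero diagonal.

    Parameters
    ----------
    W : (n, n) array-like of {0, 1}
        Binary neighbourhood matrix; W[i, j] = 1 iff districts i and j share
        a border of positive length.
    ids : sequence, optional
        District identifiers; defaults to 0..n-1.
    """

    def __init__(self, W, ids=None):
        W = np.asarray(W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be a square matrix")
        if not np.array_equal(W, W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have zero diagonal")
        if not np.all(np.isin(W, (0.0, 1.0))):
            raise ValueError("W entries must be 0 or 1")
        self.W = W
        n = W.shape[0]
        self.ids = list(range(n)) if ids is None else list(ids)
        if len(self.ids) != n:
            raise ValueError("ids length must match W")
        if self.n_components > 1:
            warnings.warn(
                f"adjacency graph has {self.n_components} connected components; "
                "islands decouple as rho -> 1",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.W.sum(axis=1)) - self.W

    @property
    def n_components(self) -> int:
        return sp.csgraph.connected_components(sp.csr_matrix(self.W), directed=False)[0]


def leroux_precision(graph: AdjacencyGraph, params: LerouxParams, scaled: bool = True):
    """Sparse joint precision of phi under the Leroux prior.

    Returns sigma_phi^-2 * Q(W) with Q(W) = rho*(diag(W1) - W) + (1-rho)*I
    when ``scaled`` (the full precision of phi), otherwise the structure
    matrix Q(W) alone.  Positive definite for rho < 1; singular at rho = 1
    on a connected graph (intrinsic model).
    """
    rho = params.rho
    L = sp.csr_matrix(graph.laplacian)
    Q = rho * L + (1.0 - rho) * sp.identity(graph.n, format="csr")
    if scaled:
        Q = Q / params.sigma2_phi
    return Q


class LerouxEigen:
    """Eigendecomposition of the graph Laplacian, reused across rho values.

    Q(rho) = V diag(rho*lam + 1 - rho) V', so log-determinants, inverses and
    whitening transforms for any rho are O(n^2) after one O(n^3) setup.
    """

    def __init__(self, graph: AdjacencyGraph):
        self.graph = graph
        lam, V = np.linalg.eigh(graph.laplacian)
        self.lam = np.clip(lam, 0.0, None)  # Laplacian is PSD; clip fp noise
        self.V = V

    def spectrum(self, rho: float) -> np.ndarray:
        return rho * self.lam + (1.0 - rho)

    _SING_TOL = 1e-10  # spectrum below this is numerically singular

    def logdet(self, rho: float) -> float:
        s = self.spectrum(rho)
        if np.any(s <= self._SING_TOL):
            raise np.linalg.LinAlgError("Q singular: rho = 1 on a connected graph")
        return float(np.sum(np.log(s)))

    def whitener(self, rho: float, sigma_phi: float) -> np.ndarray:
        """Matrix A with phi = A z, z ~ N(0, I)  =>  phi ~ N(0, sigma^2 Q^-1)."""
        s = self.spectrum(rho)
        if np.any(s <= self._SING_TOL):
            raise np.linalg.LinAlgError(
                "cannot whiten an intrinsic (rho = 1) Leroux prior; use rho < 1"
            )
        return sigma_phi * self.V / np.sqrt(s)


def leroux_logdet(graph: AdjacencyGraph, rho: float) -> float:
    """log det Q(W) for rho in [0, 1); raises for the singular rho = 1 case."""
    return LerouxEigen(graph).logdet(rho)


def sample_leroux(
    graph: AdjacencyGraph,
    params: LerouxParams,
    n_samples: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw phi ~ N(0, sigma_phi^2 Q(W)^-1); requires rho < 1.

    Returns an (n_samples, n) array. Deterministic given the seed.
    """
    if params.rho >= 1.0:
        raise ValueError("sampling requires a proper prior: rho < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = LerouxEigen(graph).whitener(params.rho, np.sqrt(params.sigma2_phi))
    z = rng.standard_normal((n_samples, graph.n))
    return z @ A.T
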
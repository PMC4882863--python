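"""Gauss-Hermite quadrature grids for integrating over latent traits.

The marginal likelihood of the MNRM integrates the conditional response
probability over a multivariate normal latent density.  We use
probabilists' Gauss-Hermite rules (weight function exp(-z^2/2)), whose
normalised weights integrate the standard normal density exactly, taken
to a tensor product over dimensions and rotated by the Cholesky factor
of the latent correlation matrix.

An adaptive variant recentres the standardised rule at a person's
posterior mode with the Laplace covariance, which concentrates the nodes
where the integrand actually lives; it is exposed for likelihood
evaluation and used by tests to validate the fixed-grid results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, LinAlgError
from scipy.special import roots_hermitenorm

from .errors import ModelError


def _check_correlation(corr: np.ndarray, n_dims: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (n_dims, n_dims):
        raise ModelError(f"correlation matrix must be {n_dims}x{n_dims}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ModelError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ModelError("correlation matrix must have unit diagonal")
    try:
        cholesky(corr, lower=True)
    except LinAlgError:
        raise ModelError("correlation matrix is not positive definite") from None
    return corr


@dataclass
class QuadratureGrid:
    """Tensor-product Gauss-Hermite grid over ``n_dims`` latent dimensions.

    Attributes
    ----------
    nodes_per_dim : int
        Nodes of the underlying one-dimensional rule (default 10).
    n_dims : int
        Number of latent dimensions.
    z : ndarray (Q, n_dims)
        Standardised abscissae (nodes of N(0, I)).
    log_weights : ndarray (Q,)
        Log of the normalised weights; ``sum(exp(log_weights)) == 1``.
    adaptation : dict
        Optional per-person recentring information (location ``mu`` and
        Cholesky scale ``L`` arrays) recorded by adaptive evaluations.
    """

    nodes_per_dim: int = 10
    n_dims: int = 1
    z: np.ndarray = field(init=False, repr=False)
    log_weights: np.ndarray = field(init=False, repr=False)
    adaptation: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        x, w = roots_hermitenorm(self.nodes_per_dim)
        w = w / w.sum()  # normalise: integrates N(0,1) to exactly 1
        grids = list(itertools.product(range(self.nodes_per_dim), repeat=self.n_dims))
        idx = np.asarray(grids, dtype=int)
        self.z = x[idx]
        self.log_weights = np.log(w)[idx].sum(axis=1)
        self._x1d = x

    @property
    def n_points(self) -> int:
        return self.z.shape[0]

    def rotate(self, corr: np.ndarray) -> np.ndarray:
        """Abscissae for N(0, corr): ``theta = z @ chol(corr).T``."""
        corr = _check_correlation(corr, self.n_dims)
        L = cholesky(corr, lower=True)
        return self.z @ L.T

    def cell_half_widths(self) -> np.ndarray:
        """Per-node half-widths of the 1-d Voronoi cells in z-space.

        Used to jitter plausible-value draws uniformly within the cell of
        the sampled node.  Shape (Q, n_dims, 2): distances to the lower
        and upper cell boundary.
        """
        x = self._x1d
        mids = (x[:-1] + x[1:]) / 2.0
        lo = np.empty_like(x)
        hi = np.empty_like(x)
        lo[1:] = x[1:] - mids
        hi[:-1] = mids - x[:-1]
        # unbounded outer cells: mirror the inner half-width
        lo[0] = hi[0]
        hi[-1] = lo[-1]
        idx = np.searchsorted(x, self.z.reshape(-1))
        idx = np.clip(idx, 0, len(x) - 1).reshape(self.z.shape)
        return np.stack([lo[idx], hi[idx]], axis=-1)
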
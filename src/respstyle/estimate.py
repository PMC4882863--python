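"""Penalised marginal maximum likelihood estimation of the MNRM.

The free parameters are the effect-coded category intercepts (K-1 per
item) and, optionally, the correlations between the latent dimensions;
all category slopes are fixed by the constraint structure and all latent
variances are fixed to 1 for identification.  The marginal likelihood
integrates over a multivariate normal latent density with Gauss-Hermite
quadrature, and a normal prior on the intercepts keeps estimates away
from the boundary when categories are sparse, so the objective maximised
is the log-posterior = log-likelihood + log-prior.

Estimation is an EM algorithm.  Because the slopes are fixed, the E-step
reduces to posterior weights of each person over the quadrature grid and
the M-step separates into one small concave multinomial-logit problem
per item (solved by Newton iterations with step halving) plus a moment
update of the latent correlation matrix rescaled to unit diagonal.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve, LinAlgError
from scipy.special import logsumexp

from .errors import DataError, ModelError, NumericError
from .model import (
    ItemParameters,
    ModelSpec,
    ResponseMatrix,
    grid_log_probs,
)
from .quadrature import QuadratureGrid, _check_correlation

DEFAULT_PRIOR_SD = 3.0


# ---------------------------------------------------------------------------
# E-step machinery (shared with scoring)
# ---------------------------------------------------------------------------

def _person_grid_loglik(resp0: np.ndarray, logp: np.ndarray) -> np.ndarray:
    """Log-likelihood of each person at each grid point.

    ``resp0`` is 0-based with -1 for missing; ``logp`` is the
    (items, Q, K) log-probability tensor.  Missing items contribute no
    factor.  Returns shape (n_persons, Q).
    """
    n, n_items = resp0.shape
    L = np.zeros((n, logp.shape[1]))
    for j in range(n_items):
        u = resp0[:, j]
        obs = u >= 0
        if obs.any():
            L[obs] += logp[j][:, u[obs]].T
    return L


def posterior_weights(
    data: ResponseMatrix,
    params: ItemParameters,
    spec: ModelSpec,
    corr: np.ndarray,
    grid: QuadratureGrid,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior weights of every person over the quadrature grid.

    Returns ``(W, ll, theta)`` where ``W`` (n, Q) are normalised posterior
    weights, ``ll`` (n,) the per-person marginal log-likelihoods and
    ``theta`` (Q, n_dims) the grid abscissae under ``corr``.
    """
    data.validate(spec.n_categories)
    theta = grid.rotate(corr)
    logp = grid_log_probs(theta, params)
    L = _person_grid_loglik(data.responses - 1, logp)
    A = L + grid.log_weights
    ll = logsumexp(A, axis=1)
    W = np.exp(A - ll[:, None])
    return W, ll, theta


def marginal_log_likelihood(
    data: ResponseMatrix,
    params: ItemParameters,
    spec: ModelSpec,
    corr: np.ndarray | None = None,
    grid: QuadratureGrid | None = None,
    adaptive: bool = False,
) -> float:
    """Quadrature approximation of the marginal log-likelihood.

    With ``adaptive=True`` the standardised rule is recentred at each
    person's posterior mode with the Laplace covariance before summing,
    which is markedly more accurate at few nodes per dimension; the
    recentring locations are recorded in ``grid.adaptation``.
    """
    if corr is None:
        corr = np.eye(spec.n_dims)
    if grid is None:
        grid = QuadratureGrid(nodes_per_dim=10, n_dims=spec.n_dims)
    corr = _check_correlation(corr, spec.n_dims)
    if not adaptive:
        _, ll, _ = posterior_weights(data, params, spec, corr, grid)
        return float(ll.sum())
    return _adaptive_log_likelihood(data, params, spec, corr, grid)


def _adaptive_log_likelihood(data, params, spec, corr, grid) -> float:
    data.validate(spec.n_categories)
    resp0 = data.responses - 1
    d = spec.n_dims
    corr_inv = np.linalg.inv(corr)
    _, logdet_corr = np.linalg.slogdet(corr)
    z, logw = grid.z, grid.log_weights
    zz_half = 0.5 * np.einsum("qd,qd->q", z, z)
    total = 0.0
    mus, Ls = [], []
    for i in range(data.n_persons):
        mu, H = _posterior_mode(resp0[i], params, corr_inv, d)
        try:
            C = cholesky(np.linalg.inv(-H), lower=True)
        except LinAlgError:
            # non-finite / non-PD curvature: fall back to the prior scale
            C = cholesky(corr, lower=True)
        theta_q = mu + z @ C.T
        L_i = _person_grid_loglik(resp0[i : i + 1], grid_log_probs(theta_q, params))[0]
        quad = np.einsum("qd,de,qe->q", theta_q, corr_inv, theta_q)
        log_phi = -0.5 * (quad + d * np.log(2 * np.pi) + logdet_corr)
        logdet_C = np.log(np.abs(np.diag(C))).sum()
        total += logsumexp(
            logw + zz_half + 0.5 * d * np.log(2 * np.pi) + logdet_C + L_i + log_phi
        )
        mus.append(mu)
        Ls.append(C)
    grid.adaptation = {"mu": np.array(mus), "scale": np.array(Ls)}
    return float(total)


def _posterior_mode(resp0_i: np.ndarray, params: ItemParameters,
                    corr_inv: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Newton ascent to a person's posterior mode; returns (mode, Hessian)."""
    theta = np.zeros(d)
    obs = np.where(resp0_i >= 0)[0]
    H = -corr_inv
    for _ in range(100):
        g = -corr_inv @ theta
        H = -corr_inv.copy()
        for j in obs:
            A = params.slopes[j]  # (K, d)
            logits = A @ theta + params.intercepts[j]
            logits -= logits.max()
            p = np.exp(logits)
            p /= p.sum()
            pa = p @ A
            g += A[resp0_i[j]] - pa
            H -= A.T @ (A * p[:, None]) - np.outer(pa, pa)
        step = solve(H, g)
        theta = theta - step
        if np.abs(step).max() < 1e-10:
            break
    return theta, H


# ---------------------------------------------------------------------------
# fitted-model container and information criteria
# ---------------------------------------------------------------------------

def information_criteria(log_likelihood: float, n_parameters: int,
                         n_persons: int) -> dict[str, float]:
    """Penalised-likelihood criteria; lower values indicate better fit.

    AIC = -2LL + 2p, AIC3 = -2LL + 3p, BIC = -2LL + p ln(n),
    CAIC = -2LL + p (ln(n) + 1).
    """
    if n_persons < 1:
        raise DataError("n_persons must be >= 1")
    m2ll = -2.0 * log_likelihood
    p = float(n_parameters)
    logn = np.log(n_persons)
    return {
        "AIC": m2ll + 2.0 * p,
        "AIC3": m2ll + 3.0 * p,
        "BIC": m2ll + p * logn,
        "CAIC": m2ll + p * (logn + 1.0),
    }


@dataclass
class FittedModel:
    """Result of :func:`fit_mnrm`."""

    spec: ModelSpec
    params: ItemParameters
    latent_correlations: np.ndarray
    log_likelihood: float
    log_prior: float
    log_posterior: float
    n_parameters: int
    criteria: dict[str, float]
    converged: bool
    iteration_trace: list[float]
    n_persons: int
    prior_sd: float
    nodes_per_dim: int
    data_fingerprint: str = ""
    flagged_items: tuple[int, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "dim_labels": list(self.spec.dim_labels),
            "intercepts": self.params.intercepts.tolist(),
            "latent_correlations": self.latent_correlations.tolist(),
            "log_likelihood": self.log_likelihood,
            "log_prior": self.log_prior,
            "log_posterior": self.log_posterior,
            "n_parameters": self.n_parameters,
            "criteria": self.criteria,
            "converged": self.converged,
            "iteration_trace": self.iteration_trace,
            "n_persons": self.n_persons,
            "prior_sd": self.prior_sd,
            "nodes_per_dim": self.nodes_per_dim,
            "data_fingerprint": self.data_fingerprint,
            "flagged_items": list(self.flagged_items),
        }


def _fingerprint(data: ResponseMatrix) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(data.responses).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# M-steps
# ---------------------------------------------------------------------------

def _mstep_intercepts(
    counts_j: np.ndarray,
    slope_logits_j: np.ndarray,
    c_j: np.ndarray,
    prior_sd: float,
) -> np.ndarray:
    """Maximise one item's expected complete-data log-posterior.

    ``counts_j`` (Q, K) are expected response counts on the grid,
    ``slope_logits_j`` (Q, K) the fixed slope contribution to the logits.
    The K intercepts are optimised in the (K-1)-dimensional sum-to-zero
    basis by damped Newton; the problem is strictly concave.
    """
    K = c_j.shape[0]
    B = np.vstack([np.eye(K - 1), -np.ones(K - 1)])  # sum-to-zero basis
    n_q = counts_j.sum(axis=1)
    count_k = counts_j.sum(axis=0)
    inv_var = 1.0 / prior_sd**2

    def objective(c):
        logits = slope_logits_j + c
        lse = logsumexp(logits, axis=1)
        return float((counts_j * logits).sum() - n_q @ lse - 0.5 * inv_var * (c @ c))

    b = solve(B.T @ B, B.T @ c_j)  # current coordinates
    f = objective(B @ b)
    for _ in range(60):
        c = B @ b
        logits = slope_logits_j + c
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        g = count_k - n_q @ p - inv_var * c
        gb = B.T @ g
        if np.abs(gb).max() < 1e-11:
            break
        np_ = p * n_q[:, None]
        H = -(np.diag(np_.sum(axis=0)) - p.T @ np_) - inv_var * np.eye(K)
        try:
            step = solve(B.T @ H @ B, gb, assume_a="sym")
        except LinAlgError:
            raise NumericError("singular Hessian in intercept update") from None
        # Newton direction with step halving on the concave objective
        t = 1.0
        for _ in range(30):
            f_new = objective(B @ (b - t * step))
            if f_new >= f - 1e-12:
                break
            t /= 2.0
        b = b - t * step
        f = f_new
    return B @ b


def _mstep_correlation(W: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Moment update of the latent correlation matrix.

    The expected second-moment matrix of theta under the person
    posteriors is rescaled to unit diagonal (variances are fixed for
    identification).
    """
    wq = W.sum(axis=0)
    S = (theta * wq[:, None]).T @ theta / W.shape[0]
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


# ---------------------------------------------------------------------------
# the EM driver
# ---------------------------------------------------------------------------

def fit_mnrm(
    data: ResponseMatrix,
    spec: ModelSpec,
    prior_sd: float = DEFAULT_PRIOR_SD,
    nodes_per_dim: int = 10,
    tol: float = 1e-7,
    param_tol: float = 1e-5,
    max_iter: int = 500,
    start: ItemParameters | None = None,
    verbose: bool = False,
) -> FittedModel:
    """Fit the constrained MNRM by EM with Gauss-Hermite quadrature.

    Parameters
    ----------
    data : ResponseMatrix
    spec : ModelSpec
    prior_sd : float
        SD of the normal(0, prior_sd^2) prior on the effect-coded
        intercepts; keeps sparse categories off the boundary.
    nodes_per_dim : int
        Gauss-Hermite nodes per latent dimension (default 10).
    tol, param_tol : float
        Convergence: relative change of the log-posterior below ``tol``
        and maximum absolute parameter change below ``param_tol``.
    max_iter : int
        Iteration cap; exceeding it returns ``converged=False`` with a
        warning rather than raising.
    start : ItemParameters, optional
        Starting intercepts (defaults to all zero).

    Returns
    -------
    FittedModel
        Parameters at a local maximum of the penalised marginal
        likelihood, with an iteration trace of the log-posterior that is
        non-decreasing up to numerical tolerance.
    """
    data.validate(spec.n_categories)
    resp0 = data.responses - 1
    n, J = resp0.shape
    if J != spec.n_items:
        raise DataError(f"data has {J} items, spec expects {spec.n_items}")
    K, D = spec.n_categories, spec.n_dims
    n_free_corr = D * (D - 1) // 2 if spec.correlation_structure == "free" and D > 1 else 0

    params = start if start is not None else ItemParameters.from_spec(spec)
    params = ItemParameters(params.slopes.copy(), params.intercepts.copy())
    params.validate_against(spec)
    corr = np.eye(D)
    free_corr = spec.correlation_structure == "free" and D > 1

    grid = QuadratureGrid(nodes_per_dim=nodes_per_dim, n_dims=D)
    Q = grid.n_points

    # one-hot indicator (n, J*K) for expected-count accumulation
    ind = np.zeros((n, J * K))
    rows = np.repeat(np.arange(n), J)
    cols = (np.arange(J)[None, :] * K + np.clip(resp0, 0, K - 1)).ravel()
    mask = (resp0 >= 0).ravel()
    ind[rows[mask], cols[mask]] = 1.0

    # flag items with never-observed categories (prior-driven intercepts)
    seen = ind.sum(axis=0).reshape(J, K) > 0
    flagged = tuple(int(j) for j in range(J) if not seen[j].all())
    if flagged:
        warnings.warn(
            f"items {[j + 1 for j in flagged]} have categories never observed; "
            "their intercepts are driven by the prior",
            stacklevel=2,
        )

    slope_logits = None  # (J, Q, K) fixed part of the logits, per grid
    prev_obj = -np.inf
    prev_corr = corr.copy()
    corr_updated = False
    last_delta = np.inf  # max parameter change in the previous M-step
    rel = np.inf
    trace: list[float] = []
    converged = False
    ll_total = np.nan

    def log_prior_of(c: np.ndarray) -> float:
        return float(
            -0.5 * (c**2).sum() / prior_sd**2
            - c.size * np.log(prior_sd * np.sqrt(2 * np.pi))
        )

    for iteration in range(max_iter):
        theta = grid.rotate(corr)
        slope_logits = np.einsum("qd,jkd->jqk", theta, params.slopes)
        logp = slope_logits + params.intercepts[:, None, :]
        logp -= logsumexp(logp, axis=2, keepdims=True)
        L = _person_grid_loglik(resp0, logp)
        A = L + grid.log_weights
        ll_person = logsumexp(A, axis=1)
        W = np.exp(A - ll_person[:, None])
        ll_total = float(ll_person.sum())
        obj = ll_total + log_prior_of(params.intercepts)

        if corr_updated and obj < prev_obj - 1e-9:
            # The rescaled correlation update is a moment approximation,
            # not an exact ascent step; once it stops improving the
            # objective it has reached its resolution.  Revert and keep
            # the correlations frozen (the intercept M-steps are exact
            # ascent, so monotonicity is preserved from here on).
            corr = prev_corr
            corr_updated = False
            free_corr = False
            continue
        trace.append(obj)
        if verbose:
            print(f"iter {iteration:4d}  log-posterior {obj:.6f}")

        rel = abs(obj - prev_obj) / (abs(prev_obj) + 1.0)
        if iteration > 0 and rel < tol and last_delta < param_tol:
            converged = True
            break
        prev_obj = obj

        # --- M-step: intercepts, one concave problem per item ----------
        counts = (W.T @ ind).reshape(Q, J, K)
        new_intercepts = np.empty_like(params.intercepts)
        for j in range(J):
            new_intercepts[j] = _mstep_intercepts(
                counts[:, j, :], slope_logits[j], params.intercepts[j], prior_sd
            )
        delta = np.abs(new_intercepts - params.intercepts).max()
        params.intercepts = new_intercepts

        # --- M-step: latent correlations -------------------------------
        if free_corr:
            prev_corr = corr.copy()
            corr_new = _mstep_correlation(W, theta)
            delta = max(delta, np.abs(corr_new - corr).max())
            corr = corr_new
            corr_updated = True
        last_delta = delta

    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations "
            f"(last relative change {rel:.3g})",
            stacklevel=2,
        )

    n_free = (K - 1) * J + n_free_corr
    log_prior = log_prior_of(params.intercepts)
    return FittedModel(
        spec=spec,
        params=params,
        latent_correlations=corr,
        log_likelihood=ll_total,
        log_prior=log_prior,
        log_posterior=ll_total + log_prior,
        n_parameters=n_free,
        criteria=information_criteria(ll_total, n_free, n),
        converged=converged,
        iteration_trace=trace,
        n_persons=n,
        prior_sd=prior_sd,
        nodes_per_dim=nodes_per_dim,
        data_fingerprint=_fingerprint(data),
        flagged_items=flagged,
    )


def compare_models(fits: Sequence[FittedModel]) -> pd.DataFrame:
    """Side-by-side comparison of fits to the same data.

    Returns one row per model with log-likelihood, log-prior,
    log-posterior, parameter count, the four information criteria and,
    per criterion, the rank (1 = best, i.e. lowest).
    """
    if len(fits) < 2:
        raise DataError("need at least two fitted models to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise DataError("fitted models were not estimated on the same data")
    rows = []
    for f in fits:
        label = f"{len(f.spec.substantive_dims)}dim" + (
            "+ERS" if f.spec.ers_included else ""
        )
        row = {
            "model": label,
            "n_dimensions": f.spec.n_dims,
            "log_likelihood": f.log_likelihood,
            "log_prior": f.log_prior,
            "log_posterior": f.log_posterior,
            "n_parameters": f.n_parameters,
        }
        row.update(f.criteria)
        rows.append(row)
    table = pd.DataFrame(rows)
    for crit in ("AIC", "AIC3", "BIC", "CAIC"):
        table[f"rank_{crit}"] = table[crit].rank(method="min").astype(int)
    return table
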
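"""Person scoring: EAP estimates, posterior SDs and plausible values.

EAP (expected a posteriori) scores are posterior means of the latent
trait vector given a person's responses under the fitted model,
approximated on the same Gauss-Hermite grid used for estimation (the
grid resolution can be refined independently via ``nodes_per_dim``).
Plausible values are random draws from the grid-approximated posterior:
a grid node is sampled with its posterior weight and jittered uniformly
within the node's cell so draws do not collapse onto the abscissae.
Five draws per person is the default, the number conventionally carried
into downstream multiply-imputed analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .errors import DataError
from .estimate import FittedModel, posterior_weights
from .model import ModelSpec, ResponseMatrix
from .quadrature import QuadratureGrid


@dataclass
class PersonScores:
    """Per-person latent-trait summaries.

    ``eap`` and ``posterior_sd`` have shape (n_persons, n_dims);
    ``plausible_values`` has shape (n_persons, n_draws, n_dims) or is
    None when no draws were requested.  ``seed`` records the root seed
    used for the draws.
    """

    person_ids: tuple
    dim_labels: tuple[str, ...]
    eap: np.ndarray
    posterior_sd: np.ndarray
    plausible_values: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return 0 if self.plausible_values is None else self.plausible_values.shape[1]


def _scoring_grid(fit: FittedModel, grid: QuadratureGrid | None,
                  nodes_per_dim: int | None) -> QuadratureGrid:
    if grid is not None:
        return grid
    return QuadratureGrid(
        nodes_per_dim=nodes_per_dim or fit.nodes_per_dim,
        n_dims=fit.spec.n_dims,
    )


def eap_scores(
    data: ResponseMatrix,
    fit: FittedModel,
    grid: QuadratureGrid | None = None,
    nodes_per_dim: int | None = None,
) -> PersonScores:
    """EAP point estimates and posterior SDs for every person.

    Persons with no observed responses get the prior mean 0 and the
    prior SD 1 on every dimension; since data validation requires at
    least one observed response this only arises for deliberately
    constructed inputs.
    """
    spec = fit.spec
    if data.n_items != spec.n_items:
        raise DataError(
            f"data has {data.n_items} items, model expects {spec.n_items}"
        )
    grid = _scoring_grid(fit, grid, nodes_per_dim)
    W, _, theta = posterior_weights(
        data, fit.params, spec, fit.latent_correlations, grid
    )
    eap = W @ theta
    second = W @ theta**2
    sd = np.sqrt(np.maximum(second - eap**2, 0.0))
    return PersonScores(
        person_ids=data.person_ids,
        dim_labels=spec.dim_labels,
        eap=eap,
        posterior_sd=sd,
    )


def draw_plausible_values(
    data: ResponseMatrix,
    fit: FittedModel,
    n_draws: int = 5,
    seed: int = 0,
    grid: QuadratureGrid | None = None,
    nodes_per_dim: int | None = None,
) -> PersonScores:
    """Draw plausible values from each person's latent posterior.

    A grid node is sampled per draw with probability equal to its
    posterior weight, then jittered uniformly within the node's
    one-dimensional quadrature cells (in the standardised space, mapped
    through the correlation Cholesky factor).  Randomness uses one root
    seed with an independent spawned substream per person, so results
    are reproducible and invariant to scoring order.
    """
    if n_draws < 1:
        raise DataError("n_draws must be >= 1")
    spec = fit.spec
    grid = _scoring_grid(fit, grid, nodes_per_dim)
    W, _, _ = posterior_weights(data, fit.params, spec, fit.latent_correlations, grid)
    L = cholesky(np.asarray(fit.latent_correlations), lower=True)
    half = grid.cell_half_widths()  # (Q, D, 2)
    eap_part = eap_scores(data, fit, grid=grid)
    n = data.n_persons
    pv = np.empty((n, n_draws, spec.n_dims))
    streams = np.random.SeedSequence(seed).spawn(n)
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        q = rng.choice(W.shape[1], size=n_draws, p=W[i] / W[i].sum())
        u = rng.uniform(-1.0, 1.0, size=(n_draws, spec.n_dims))
        width = np.where(u < 0, half[q, :, 0], half[q, :, 1])
        z = grid.z[q] + u * width
        pv[i] = z @ L.T
    return PersonScores(
        person_ids=data.person_ids,
        dim_labels=spec.dim_labels,
        eap=eap_part.eap,
        posterior_sd=eap_part.posterior_sd,
        plausible_values=pv,
        seed=seed,
    )


def score_table(scores: PersonScores, data: ResponseMatrix,
                spec: ModelSpec) -> pd.DataFrame:
    """Export table: response strings per scale, EAPs, SDs, draws.

    Missing responses appear as ``.`` in the response strings.
    """
    rows = []
    for i, pid in enumerate(scores.person_ids):
        row: dict = {"person_id": pid}
        for scale in spec.substantive_dims:
            items = spec.items_for(scale)
            chars = [
                str(v) if v >= 1 else "." for v in data.responses[i, items]
            ]
            row[f"responses_{scale}"] = "".join(chars)
        for d, lab in enumerate(scores.dim_labels):
            row[f"eap_{lab}"] = scores.eap[i, d]
        for d, lab in enumerate(scores.dim_labels):
            row[f"sd_{lab}"] = scores.posterior_sd[i, d]
        if scores.plausible_values is not None:
            for d, lab in enumerate(scores.dim_labels):
                for m in range(scores.n_draws):
                    row[f"{lab}_pv{m + 1}"] = scores.plausible_values[i, m, d]
        rows.append(row)
    if not rows:  # header-only table for empty input
        cols = ["person_id"]
        cols += [f"responses_{s}" for s in spec.substantive_dims]
        cols += [f"eap_{lab}" for lab in spec.dim_labels]
        cols += [f"sd_{lab}" for lab in spec.dim_labels]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)
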
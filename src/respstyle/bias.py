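"""ERS-induced bias in sum scores.

For a subscale the model-implied ("purified") expected sum score at a
substantive trait level ``theta`` and style level ``theta_ers`` is

    ES(theta, theta_ers) = sum_j sum_k k * P(U_j = k | theta, theta_ers),

with all non-targeted substantive dimensions held at 0.  The bias a
style level induces at a given trait level is

    BIAS(theta, theta_ers) = ES(theta, theta_ers) - ES(theta, 0),

which is identically zero at theta_ers = 0.  The bias curves for
different style levels share an approximately common zero: above it
extreme responding inflates sum scores (endpoint choices shift mass to
category K), below it the same behaviour deflates them.  Two related
trait levels are computed and reported side by side: the *crossing
point* (:func:`find_crossing`), the root of mean expected item score =
scale midpoint (K+1)/2, and the *intersection point*
(:func:`find_intersection`), the trait level minimising the largest
|bias| across the style levels, i.e. the family's common zero.  On the
packaged NEO-FFI Neuroticism estimates the two are close but not equal
(about 1.9 and 1.6); published descriptions treat them as coinciding
at roughly the same level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError, DataError
from .model import ItemParameters, ModelSpec, expected_item_score

DEFAULT_ERS_LEVELS: tuple[float, ...] = (2.0, 1.0, 0.0, -1.0, -2.0)


def _theta_grid_vectors(spec: ModelSpec, scale: str,
                        theta_sub: np.ndarray, theta_ers: float) -> np.ndarray:
    theta_sub = np.atleast_1d(np.asarray(theta_sub, dtype=float))
    full = np.zeros((theta_sub.size, spec.n_dims))
    full[:, spec.dim_index(scale)] = theta_sub
    if spec.ers_included:
        full[:, -1] = theta_ers
    elif theta_ers != 0.0:
        raise ConfigError("model has no ERS dimension; theta_ers must be 0")
    return full


def expected_sum_score(
    theta_sub: float | np.ndarray,
    theta_ers: float,
    params: ItemParameters,
    spec: ModelSpec,
    scale: str,
) -> float | np.ndarray:
    """Expected sum score of one subscale at given trait and ERS levels.

    All substantive dimensions other than ``scale`` are held at 0.
    The result lies in [n_items, K * n_items] for the subscale's items.
    """
    items = spec.items_for(scale)
    if items.size == 0:
        raise DataError(f"scale {scale!r} has no items")
    theta = _theta_grid_vectors(spec, scale, theta_sub, theta_ers)
    es = expected_item_score(theta, params, items).sum(axis=0)
    return float(es[0]) if np.isscalar(theta_sub) else es


def bias(
    theta_sub: float | np.ndarray,
    theta_ers: float,
    params: ItemParameters,
    spec: ModelSpec,
    scale: str,
) -> float | np.ndarray:
    """Sum-score bias induced by ERS level ``theta_ers`` at ``theta_sub``."""
    return expected_sum_score(theta_sub, theta_ers, params, spec, scale) - \
        expected_sum_score(theta_sub, 0.0, params, spec, scale)


def find_crossing(
    params: ItemParameters,
    spec: ModelSpec,
    scale: str,
    interval: tuple[float, float] = (-4.0, 4.0),
) -> float:
    """Trait level at which the mean expected item score hits the midpoint.

    Solves ``mean_j E[score_j | theta, theta_ers=0] = (K+1)/2`` by
    bracketed root finding to 1e-6.  This is the point at which the bias
    curves for all ERS levels pass (close to) zero together.
    """
    items = spec.items_for(scale)
    n_items = items.size
    midpoint = (spec.n_categories + 1) / 2.0

    def gap(th: float) -> float:
        return expected_sum_score(th, 0.0, params, spec, scale) / n_items - midpoint

    lo, hi = interval
    if gap(lo) * gap(hi) > 0:
        raise DataError(
            f"mean expected score does not cross {midpoint} on [{lo}, {hi}]"
        )
    return float(brentq(gap, lo, hi, xtol=1e-6))


def find_intersection(
    params: ItemParameters,
    spec: ModelSpec,
    scale: str,
    ers_levels: Sequence[float] = DEFAULT_ERS_LEVELS,
    interval: tuple[float, float] = (-4.0, 4.0),
) -> float:
    """Common zero of the bias-curve family (minimax point).

    Returns the trait level minimising ``max over levels |bias|`` — the
    point at which the curves for all ERS levels jointly pass closest
    to zero.  Located by a coarse scan followed by bounded scalar
    minimisation.
    """
    from scipy.optimize import minimize_scalar

    levels = [lev for lev in ers_levels if lev != 0.0]
    if not levels:
        raise ConfigError("need at least one non-zero ERS level")

    def worst(th: float) -> float:
        return max(abs(float(bias(th, lev, params, spec, scale))) for lev in levels)

    grid = np.linspace(interval[0], interval[1], 161)
    best = grid[int(np.argmin([worst(t) for t in grid]))]
    span = (grid[1] - grid[0]) * 2
    res = minimize_scalar(
        worst, bounds=(best - span, best + span), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


@dataclass
class BiasCurve:
    """Bias as a function of the substantive trait at several ERS levels.

    ``crossing_point`` is the midpoint root of the mean expected score;
    ``intersection_point`` is the family's common zero (see module
    docstring); the ``max_abs_bias_at_*`` fields report how far the
    curves are from zero at each of the two anchors.
    """

    scale: str
    theta_grid: np.ndarray
    ers_levels: tuple[float, ...]
    bias_values: np.ndarray  # (len(theta_grid), len(ers_levels))
    crossing_point: float
    max_abs_bias_at_crossing: float
    intersection_point: float
    max_abs_bias_at_intersection: float

    def to_frame(self) -> pd.DataFrame:
        table = pd.DataFrame(
            self.bias_values,
            columns=[f"ers_{lev:g}" for lev in self.ers_levels],
        )
        table.insert(0, "theta", self.theta_grid)
        return table

    def plot(self, ax=None):
        """Bias curves versus the substantive trait, one line per ERS level."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for col, lev in enumerate(self.ers_levels):
            ax.plot(self.theta_grid, self.bias_values[:, col],
                    label=f"$\\theta_{{ERS}}$ = {lev:g}")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.axvline(self.crossing_point, color="grey", ls=":", lw=0.8)
        ax.set_xlabel(f"$\\theta_{{{self.scale}}}$")
        ax.set_ylabel("bias in sum score")
        ax.legend(fontsize=8)
        return ax


def bias_curves(
    params: ItemParameters,
    spec: ModelSpec,
    scale: str,
    ers_levels: Sequence[float] = DEFAULT_ERS_LEVELS,
    theta_grid: np.ndarray | None = None,
) -> BiasCurve:
    """Full bias matrix over a trait grid plus the crossing point."""
    if theta_grid is None:
        theta_grid = np.arange(-4.0, 4.0 + 1e-9, 0.05)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size > 1 and np.any(np.diff(theta_grid) <= 0):
        raise DataError("theta_grid must be strictly increasing")
    base = expected_sum_score(theta_grid, 0.0, params, spec, scale)
    values = np.column_stack([
        expected_sum_score(theta_grid, lev, params, spec, scale) - base
        for lev in ers_levels
    ])
    span = (float(theta_grid[0]), float(theta_grid[-1]))
    crossing = find_crossing(params, spec, scale, span)
    at_cross = max(
        abs(float(bias(crossing, lev, params, spec, scale))) for lev in ers_levels
    )
    inter = find_intersection(params, spec, scale, ers_levels, span)
    at_inter = max(
        abs(float(bias(inter, lev, params, spec, scale))) for lev in ers_levels
    )
    return BiasCurve(
        scale=scale,
        theta_grid=theta_grid,
        ers_levels=tuple(float(v) for v in ers_levels),
        bias_values=values,
        crossing_point=crossing,
        max_abs_bias_at_crossing=at_cross,
        intersection_point=inter,
        max_abs_bias_at_intersection=at_inter,
    )
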
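"""Constrained multidimensional nominal response model (MNRM).

Each Likert item j with K ordered categories is modelled with a
multinomial logit whose category logits are linear in the latent traits:

    P(U_j = k | theta) = exp(eta_jk) / sum_h exp(eta_jh),
    eta_jk = sum_d a_jkd * theta_d + c_jk,

where ``a_jkd`` is the slope of category k of item j on latent dimension d
and ``c_jk`` is a category intercept.  The parameterisation used here is
the constrained one in which the substantive category slopes are fixed to
the equally spaced vector (-1, -0.5, 0, 0.5, 1) — making each subscale a
multidimensional partial-credit-style model — and an optional extreme
response style (ERS) dimension loads on *every* item with the fixed slope
vector (0.75, -0.5, -0.5, -0.5, 0.75): positive on both endpoint
categories, negative on the intermediate ones.  A person high on the ERS
trait is therefore more likely to choose category 1 or K regardless of
item content.

Intercepts are identified by effect coding: for each item the K category
intercepts sum to zero.

A set of published category-intercept estimates for the NEO Five-Factor
Inventory Neuroticism, Agreeableness and Conscientiousness subscales
(36 items, fitted with this exact constraint structure on a cohort of
1188 older adults) is packaged as a fixture and doubles as the default
generating truth for the synthetic-data module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, NumericError

#: Fixed substantive category slopes (equal-interval, partial-credit style).
SUBSTANTIVE_SLOPES: tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)

#: Fixed ERS category slopes: positive on the two endpoint categories.
ERS_SLOPES: tuple[float, ...] = (0.75, -0.5, -0.5, -0.5, 0.75)

#: Label used for the ERS dimension everywhere in the package.
ERS_LABEL = "ERS"

MISSING = -1  # internal missing-response marker


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a constrained MNRM.

    Parameters
    ----------
    n_items : int
        Number of items.
    n_categories : int
        Number of response categories K (5 for a 5-point Likert scale).
    substantive_dims : tuple of str
        Ordered labels of the substantive trait dimensions.
    item_to_dim : tuple of str
        For each item, the label of the substantive dimension it measures.
    ers_included : bool
        Whether an ERS dimension (appended last) is part of the model.
    slope_structure : mapping
        Per dimension label, the fixed length-K category slope vector.
        Must contain an entry for :data:`ERS_LABEL` when ``ers_included``.
    correlation_structure : str
        ``"free"`` (latent correlations estimated) or ``"identity"``.
    """

    n_items: int
    n_categories: int
    substantive_dims: tuple[str, ...]
    item_to_dim: tuple[str, ...]
    ers_included: bool = False
    slope_structure: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    correlation_structure: str = "free"

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_categories < 2:
            raise ConfigError("need at least one item and two categories")
        if len(set(self.substantive_dims)) != len(self.substantive_dims):
            raise ConfigError(f"duplicate dimension labels: {self.substantive_dims}")
        if ERS_LABEL in self.substantive_dims:
            raise ConfigError(f"{ERS_LABEL!r} is reserved for the style dimension")
        if len(self.item_to_dim) != self.n_items:
            raise ConfigError("item_to_dim must assign every item to a dimension")
        unknown = set(self.item_to_dim) - set(self.substantive_dims)
        if unknown:
            raise ConfigError(f"items mapped to unknown dimensions: {sorted(unknown)}")
        labels = list(self.substantive_dims) + ([ERS_LABEL] if self.ers_included else [])
        for lab in labels:
            vec = self.slope_structure.get(lab)
            if vec is None:
                raise ConfigError(f"no slope vector for dimension {lab!r}")
            if len(vec) != self.n_categories:
                raise ConfigError(
                    f"slope vector for {lab!r} has length {len(vec)}, "
                    f"expected K={self.n_categories}"
                )
        if self.correlation_structure not in ("free", "identity"):
            raise ConfigError(
                f"correlation_structure must be 'free' or 'identity', "
                f"got {self.correlation_structure!r}"
            )

    # -- derived geometry ------------------------------------------------
    @property
    def n_dims(self) -> int:
        return len(self.substantive_dims) + int(self.ers_included)

    @property
    def dim_labels(self) -> tuple[str, ...]:
        if self.ers_included:
            return self.substantive_dims + (ERS_LABEL,)
        return self.substantive_dims

    def dim_index(self, label: str) -> int:
        try:
            return self.dim_labels.index(label)
        except ValueError:
            raise ConfigError(
                f"unknown dimension {label!r}; valid labels: {self.dim_labels}"
            ) from None

    def items_for(self, label: str) -> np.ndarray:
        """Indices of the items mapped to substantive dimension ``label``."""
        if label not in self.substantive_dims:
            raise ConfigError(
                f"unknown scale {label!r}; valid scales: {self.substantive_dims}"
            )
        return np.array([j for j, d in enumerate(self.item_to_dim) if d == label])

    def slope_array(self) -> np.ndarray:
        """Full (n_items, K, n_dims) slope tensor implied by the constraints."""
        a = np.zeros((self.n_items, self.n_categories, self.n_dims))
        for j, lab in enumerate(self.item_to_dim):
            a[j, :, self.dim_index(lab)] = self.slope_structure[lab]
        if self.ers_included:
            a[:, :, -1] = np.asarray(self.slope_structure[ERS_LABEL])
        return a


@dataclass
class ItemParameters:
    """Per-item category slopes and intercepts of an MNRM.

    ``slopes`` has shape (n_items, K, n_dims); ``intercepts`` has shape
    (n_items, K) and is effect-coded (each row sums to zero).
    """

    slopes: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.slopes.ndim != 3 or self.intercepts.ndim != 2:
            raise ConfigError("slopes must be (items, K, dims); intercepts (items, K)")
        if self.slopes.shape[:2] != self.intercepts.shape:
            raise ConfigError(
                f"shape mismatch: slopes {self.slopes.shape}, "
                f"intercepts {self.intercepts.shape}"
            )

    @property
    def n_items(self) -> int:
        return self.intercepts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.intercepts.shape[1]

    @property
    def n_dims(self) -> int:
        return self.slopes.shape[2]

    @classmethod
    def from_spec(cls, spec: ModelSpec, intercepts: np.ndarray | None = None) -> "ItemParameters":
        """Build a parameter container with the spec's fixed slopes.

        Intercepts default to zero (the neutral starting point for
        estimation); if given they are validated against effect coding.
        """
        if intercepts is None:
            intercepts = np.zeros((spec.n_items, spec.n_categories))
        intercepts = np.asarray(intercepts, dtype=float)
        params = cls(slopes=spec.slope_array(), intercepts=intercepts)
        params.validate_against(spec)
        return params

    def validate_against(self, spec: ModelSpec, atol: float = 0.011) -> None:
        """Check effect coding and the constraint structure.

        The sum-to-zero tolerance is loose enough to accept parameter
        tables printed to three decimals.
        """
        if self.n_items != spec.n_items or self.n_categories != spec.n_categories:
            raise ConfigError("parameter shapes do not match the model spec")
        if self.n_dims != spec.n_dims:
            raise ConfigError("slope tensor has the wrong number of dimensions")
        rowsums = self.intercepts.sum(axis=1)
        if np.any(np.abs(rowsums) > atol):
            bad = int(np.argmax(np.abs(rowsums)))
            raise ConfigError(
                f"intercepts of item {bad + 1} are not effect-coded "
                f"(sum = {rowsums[bad]:.4f})"
            )
        # off-dimension substantive slopes must be exactly zero
        for j, lab in enumerate(spec.item_to_dim):
            for d, other in enumerate(spec.substantive_dims):
                if other != lab and np.any(self.slopes[j, :, d] != 0.0):
                    raise ConfigError(
                        f"item {j + 1} has non-zero slopes on {other!r}"
                    )

    def to_frame(self, spec: ModelSpec) -> pd.DataFrame:
        """Long-format table: item, category, intercept, slope per dimension."""
        rows = []
        for j in range(self.n_items):
            for k in range(self.n_categories):
                row = {"item": j + 1, "category": k + 1,
                       "intercept": self.intercepts[j, k]}
                for d, lab in enumerate(spec.dim_labels):
                    row[f"slope_{lab}"] = self.slopes[j, k, d]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ResponseMatrix:
    """Persons x items integer responses in 1..K, with missing allowed.

    Missing responses are stored as :data:`MISSING` (-1).
    """

    responses: np.ndarray
    person_ids: tuple = ()

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=int)
        if self.responses.ndim != 2:
            raise DataError("responses must be a 2-d persons x items array")
        if not self.person_ids:
            self.person_ids = tuple(range(1, self.responses.shape[0] + 1))
        if len(self.person_ids) != self.responses.shape[0]:
            raise DataError("person_ids length does not match responses")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def observed(self) -> np.ndarray:
        return self.responses != MISSING

    def validate(self, n_categories: int) -> None:
        obs = self.responses[self.observed]
        if obs.size and (obs.min() < 1 or obs.max() > n_categories):
            bad = np.argwhere(
                self.observed & ((self.responses < 1) | (self.responses > n_categories))
            )[0]
            raise DataError(
                f"response out of range 1..{n_categories} at person "
                f"{self.person_ids[bad[0]]}, item {bad[1] + 1}: "
                f"{self.responses[tuple(bad)]}"
            )
        if not self.observed.any(axis=1).all():
            i = int(np.argmin(self.observed.any(axis=1)))
            raise DataError(f"person {self.person_ids[i]} has no observed responses")


# ---------------------------------------------------------------------------
# probability computations
# ---------------------------------------------------------------------------

def _stable_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = logits - logits.max(axis=axis, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=axis, keepdims=True)


def category_probabilities(
    theta: Sequence[float],
    item: int,
    params: ItemParameters,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Category-response probabilities of one item at one trait vector.

    Computes ``softmax_k(sum_d a_jkd theta_d + c_jk)`` with a max-shifted
    exponential for numerical stability.

    Parameters
    ----------
    theta : sequence of float
        Latent trait vector, one coordinate per model dimension.
    item : int
        Zero-based item index.
    params : ItemParameters
    spec : ModelSpec, optional
        When given, used to cross-check the dimension count.

    Returns
    -------
    ndarray of shape (K,)
        Probabilities in (0, 1) summing to 1.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or theta.shape[0] != params.n_dims:
        raise DataError(
            f"theta has length {theta.size}, model has {params.n_dims} dimensions"
        )
    if spec is not None and spec.n_dims != params.n_dims:
        raise DataError("spec and params disagree on the number of dimensions")
    if not (0 <= item < params.n_items):
        raise DataError(f"item index {item} outside 0..{params.n_items - 1}")
    logits = params.slopes[item] @ theta + params.intercepts[item]
    if not np.all(np.isfinite(logits)):
        raise NumericError(f"non-finite category logits for item {item + 1}")
    return _stable_softmax(logits)


def grid_log_probs(theta_grid: np.ndarray, params: ItemParameters) -> np.ndarray:
    """Log category probabilities of every item on a grid of trait vectors.

    Returns an array of shape (n_items, n_points, K); the vectorised core
    used by estimation, scoring and bias computations.
    """
    theta_grid = np.atleast_2d(np.asarray(theta_grid, dtype=float))
    logits = np.einsum("qd,jkd->jqk", theta_grid, params.slopes)
    logits += params.intercepts[:, None, :]
    logits -= logits.max(axis=2, keepdims=True)
    return logits - np.log(np.exp(logits).sum(axis=2, keepdims=True))


def expected_item_score(theta_grid: np.ndarray, params: ItemParameters,
                        items: Sequence[int]) -> np.ndarray:
    """Model-implied expected score ``sum_k k P(k)`` per item on a grid.

    Category codes are 1-based, so scores live in [1, K].
    Returns shape (len(items), n_points).
    """
    items = np.asarray(items, dtype=int)
    logp = grid_log_probs(theta_grid, params)[items]
    k = np.arange(1, params.n_categories + 1, dtype=float)
    return np.exp(logp) @ k


# ---------------------------------------------------------------------------
# model builders and the packaged NEO-FFI fixture
# ---------------------------------------------------------------------------

def effect_coded_from_baseline(intercepts: np.ndarray) -> np.ndarray:
    """Convert baseline-category-coded intercepts to effect coding.

    Subtracting the per-item mean maps any identified coding (e.g.
    ``c_j1 = 0``) onto the sum-to-zero coding without changing the implied
    probabilities, because the softmax is invariant to adding a constant
    to all category logits of an item.
    """
    intercepts = np.asarray(intercepts, dtype=float)
    return intercepts - intercepts.mean(axis=1, keepdims=True)


def build_constrained_model(
    scales: Sequence[str] = ("N", "A", "C"),
    items_per_scale: int = 12,
    ers: bool = True,
    n_categories: int = 5,
    correlation_structure: str = "free",
) -> tuple[ModelSpec, ItemParameters]:
    """Build the standard constrained model and a zero-intercept template.

    One substantive dimension per scale with fixed slopes
    (-1, -0.5, 0, 0.5, 1); when ``ers`` is true an ERS dimension with
    fixed slopes (0.75, -0.5, -0.5, -0.5, 0.75) on every item is appended.
    """
    scales = tuple(scales)
    if len(set(scales)) != len(scales):
        raise ConfigError(f"duplicate scale labels: {scales}")
    if items_per_scale < 1:
        raise ConfigError("items_per_scale must be >= 1")
    if n_categories != len(SUBSTANTIVE_SLOPES):
        raise ConfigError(
            "the fixed slope vectors are defined for K=5 categories"
        )
    structure: dict[str, tuple[float, ...]] = {s: SUBSTANTIVE_SLOPES for s in scales}
    if ers:
        structure[ERS_LABEL] = ERS_SLOPES
    spec = ModelSpec(
        n_items=items_per_scale * len(scales),
        n_categories=n_categories,
        substantive_dims=scales,
        item_to_dim=tuple(s for s in scales for _ in range(items_per_scale)),
        ers_included=ers,
        slope_structure=structure,
        correlation_structure=correlation_structure,
    )
    return spec, ItemParameters.from_spec(spec)


def load_neoffi_params(ers: bool = True) -> tuple[ModelSpec, ItemParameters]:
    """Load the packaged NEO-FFI category-intercept estimates.

    Published estimates for the 36 Neuroticism (items 1-12),
    Agreeableness (13-24) and Conscientiousness (25-36) items of the
    NEO-FFI short form, fitted with the fixed-slope four-dimensional
    model on 1188 older adults.  Values are stored verbatim as printed
    (three decimals); rows sum to ~0, consistent with effect coding.
    Items 20 and 22 print 0.000 for category 5 and are kept verbatim.

    Returns the matching :class:`ModelSpec` (with or without the ERS
    dimension) and the :class:`ItemParameters`.
    """
    with resources.files("respstyle.data").joinpath("neoffi_intercepts.csv").open() as fh:
        table = pd.read_csv(fh)
    table = table.sort_values("item")
    intercepts = table[[f"c{k}" for k in range(1, 6)]].to_numpy(dtype=float)
    spec, params = build_constrained_model(("N", "A", "C"), 12, ers=ers)
    params = ItemParameters(slopes=spec.slope_array(), intercepts=intercepts)
    params.validate_against(spec)
    return spec, params


def neoffi_params_json() -> dict:
    """The packaged fixture in its structured-JSON form."""
    with resources.files("respstyle.data").joinpath("neoffi_intercepts.json").open() as fh:
        return json.load(fh)
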
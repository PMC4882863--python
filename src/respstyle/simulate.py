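"""Synthetic cohorts with the structure the analysis assumes.

The generator emulates a Likert-type personality battery administered
to an ageing cohort followed for competing events: correlated
substantive traits plus a content-independent ERS trait, item responses
drawn from the constrained MNRM (by default using the packaged NEO-FFI
intercept estimates as generating truth, so the synthetic items behave
like the published ones), and exponential cause-specific event times
for disease and death whose disease hazard depends on one trait.
Covariate distributions default to the source cohort's description:
age ~ N(73.81, 6.71), 30% male, education ~ N(18.42, 3.36) truncated
to [3, 30].

Every dataset is exactly reproducible from (config, seed): a single
root seed is split into independent substreams for traits, responses,
covariates and event times.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import (
    ERS_LABEL,
    ItemParameters,
    ModelSpec,
    ResponseMatrix,
    build_constrained_model,
    grid_log_probs,
    load_neoffi_params,
)

DEFAULT_LATENT_CORR = (
    (1.0, -0.25, -0.30),
    (-0.25, 1.0, 0.30),
    (-0.30, 0.30, 1.0),
)


@dataclass
class SurvivalSimConfig:
    """Competing-risks generating mechanism.

    Baseline hazards are per-year exponential rates; log-hazard-ratio
    vectors apply to (centred age, male, centred education, trait).
    """

    baseline_disease: float = 0.03
    baseline_death: float = 0.05
    horizon: float = 20.0
    trait_dim: str = "N"
    disease_loghr: tuple[float, float, float, float] = (0.134, 0.05, 0.04, 0.2)
    death_loghr: tuple[float, float, float, float] = (0.09, 0.40, -0.02, 0.0)
    age_mean: float = 73.81
    age_sd: float = 6.71
    male_prob: float = 0.30
    education_mean: float = 18.42
    education_sd: float = 3.36
    education_range: tuple[float, float] = (3.0, 30.0)

    def __post_init__(self) -> None:
        if self.baseline_disease <= 0 or self.baseline_death <= 0:
            raise ConfigError("baseline hazards must be positive")
        if self.horizon < 0:
            raise ConfigError("censoring horizon must be non-negative")


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort."""

    n_persons: int = 1188
    scales: tuple[str, ...] = ("N", "A", "C")
    items_per_scale: int = 12
    n_categories: int = 5
    latent_corr: tuple = DEFAULT_LATENT_CORR
    ers_sd: float = 1.0
    ers_corr: tuple = (0.0, 0.0, 0.0)
    item_source: str = "neoffi"  # "neoffi" | "random"
    random_intercept_sd: float = 1.5
    survival: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        if self.item_source not in ("neoffi", "random"):
            raise ConfigError("item_source must be 'neoffi' or 'random'")
        if self.item_source == "neoffi" and (
            self.scales != ("N", "A", "C") or self.items_per_scale != 12
            or self.n_categories != 5
        ):
            raise ConfigError(
                "the packaged intercepts require 3 scales (N, A, C) x 12 items, K=5"
            )
        if isinstance(self.survival, dict):
            self.survival = SurvivalSimConfig(**self.survival)
        if self.survival.trait_dim not in self.dim_labels:
            raise ConfigError(
                f"survival trait_dim {self.survival.trait_dim!r} is not one "
                f"of the model dimensions {self.dim_labels}"
            )

    @property
    def dim_labels(self) -> tuple[str, ...]:
        return self.scales + (ERS_LABEL,)

    def full_corr(self) -> np.ndarray:
        """Correlation matrix over substantive traits + ERS (unit scale)."""
        m = len(self.scales)
        R = np.eye(m + 1)
        R[:m, :m] = np.asarray(self.latent_corr, dtype=float)
        R[:m, m] = R[m, :m] = np.asarray(self.ers_corr, dtype=float)
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise ConfigError("latent correlation matrix is not PSD")
        return R

    def model(self) -> tuple[ModelSpec, ItemParameters]:
        """The generating model spec and parameters."""
        if self.item_source == "neoffi":
            return load_neoffi_params(ers=True)
        spec, params = build_constrained_model(
            self.scales, self.items_per_scale, ers=True,
            n_categories=self.n_categories,
        )
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 4]))
        c = rng.normal(0.0, self.random_intercept_sd,
                       size=(spec.n_items, spec.n_categories))
        params.intercepts = c - c.mean(axis=1, keepdims=True)
        return spec, params


def generate_thetas(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the (n_persons, n_scales + 1) latent trait matrix.

    Multivariate normal with zero mean, unit variances and the
    configured correlations; the last column (ERS) is then scaled by
    ``ers_sd`` so a multiplier of 0 yields an inert style dimension.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    R = config.full_corr()
    thetas = rng.multivariate_normal(
        np.zeros(R.shape[0]), R, size=config.n_persons, method="cholesky"
    )
    thetas[:, -1] *= config.ers_sd
    return thetas


def generate_responses(
    thetas: np.ndarray,
    params: ItemParameters,
    spec: ModelSpec,
    seed: int | np.random.Generator = 0,
) -> ResponseMatrix:
    """Draw item responses categorically from the MNRM probabilities."""
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(np.random.SeedSequence([seed, 1]))
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape[1] != spec.n_dims:
        raise ConfigError(
            f"thetas have {thetas.shape[1]} columns, model has {spec.n_dims} dims"
        )
    n = thetas.shape[0]
    logp = grid_log_probs(thetas, params)  # (J, n, K)
    cum = np.cumsum(np.exp(logp), axis=2)
    u = rng.random(size=(spec.n_items, n, 1))
    resp = (u > cum).sum(axis=2) + 1  # categorical inverse-CDF draw
    return ResponseMatrix(responses=resp.T)


def generate_survival(
    thetas: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Competing-risks follow-up records for each person.

    Latent disease and death times are exponential with cause-specific
    hazards ``lambda * exp(linear predictor)``; the observed time is the
    minimum of the two and the administrative censoring horizon, and
    the event code records which came first (0 censored, 1 disease,
    2 death).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sc = config.survival
    n = thetas.shape[0]
    age = rng.normal(sc.age_mean, sc.age_sd, size=n)
    male = (rng.random(n) < sc.male_prob).astype(int)
    education = np.clip(
        rng.normal(sc.education_mean, sc.education_sd, size=n),
        *sc.education_range,
    )
    trait = thetas[:, list(config.dim_labels).index(sc.trait_dim)]
    X = np.column_stack([age - sc.age_mean, male, education - sc.education_mean,
                         trait])
    lp_disease = X @ np.asarray(sc.disease_loghr)
    lp_death = X @ np.asarray(sc.death_loghr)
    t_disease = rng.exponential(1.0, size=n) / (sc.baseline_disease * np.exp(lp_disease))
    t_death = rng.exponential(1.0, size=n) / (sc.baseline_death * np.exp(lp_death))
    time = np.minimum(np.minimum(t_disease, t_death), sc.horizon)
    event = np.where(
        time >= sc.horizon, 0, np.where(t_disease <= t_death, 1, 2)
    )
    return pd.DataFrame({
        "person_id": np.arange(1, n + 1),
        "time": time,
        "event": event,
        "age": age,
        "male": male,
        "education": education,
    })


@dataclass
class BenchmarkBundle:
    """Self-describing synthetic dataset: data, generating truth, config."""

    config: SimulationConfig
    spec: ModelSpec
    params: ItemParameters
    thetas: np.ndarray
    responses: ResponseMatrix
    survival: pd.DataFrame
    paths: dict = field(default_factory=dict)


def make_benchmark_dataset(
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
) -> BenchmarkBundle:
    """Generate a full cohort and optionally write it as a CSV bundle.

    The bundle contains ``responses.csv`` (person_id + one column per
    item), ``truth.csv`` (the generating trait matrix), ``survival.csv``
    and ``config.json`` (with the seed), so regeneration from the stored
    config is byte-identical.
    """
    if config is None:
        config = SimulationConfig()
    spec, params = config.model()
    thetas = generate_thetas(config)
    responses = generate_responses(thetas, params, spec, seed=config.seed)
    survival = generate_survival(thetas, config)
    bundle = BenchmarkBundle(
        config=config, spec=spec, params=params, thetas=thetas,
        responses=responses, survival=survival,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        resp_df = pd.DataFrame(
            responses.responses,
            columns=[f"item{j + 1}" for j in range(spec.n_items)],
        )
        resp_df.insert(0, "person_id", list(responses.person_ids))
        truth_df = pd.DataFrame(thetas, columns=[f"theta_{d}" for d in config.dim_labels])
        truth_df.insert(0, "person_id", list(responses.person_ids))
        files = {
            "responses": outdir / "responses.csv",
            "truth": outdir / "truth.csv",
            "survival": outdir / "survival.csv",
            "config": outdir / "config.json",
        }
        resp_df.to_csv(files["responses"], index=False)
        truth_df.to_csv(files["truth"], index=False, float_format="%.10g")
        survival.to_csv(files["survival"], index=False, float_format="%.10g")
        with open(files["config"], "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
        bundle.paths = {k: str(v) for k, v in files.items()}
    return bundle
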
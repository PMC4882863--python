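"""Cause-specific proportional hazards with multiply-drawn trait scores.

Follow-up ends at the first of: the disease event of interest (coded 1),
a competing event such as death (coded 2), or administrative censoring
(coded 0).  Cause-specific hazards are estimated by Cox partial
likelihood treating competing events as censoring, which is the correct
construction when censoring by the competing event is informative.
Fitting itself is delegated to lifelines (Efron tie handling); this
module owns the cause-specific censoring construction, the pooling of
estimates across plausible-value draws by Rubin's rules, and Cox-Snell
residual diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, NelsonAalenFitter
from scipy import stats

from .errors import DataError

EVENT_CENSORED, EVENT_DISEASE, EVENT_DEATH = 0, 1, 2


@dataclass
class SurvivalRecord:
    """One person's follow-up: time in years, event code, covariates."""

    person_id: object
    time: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataError(f"negative follow-up time for {self.person_id}")
        if self.event not in (EVENT_CENSORED, EVENT_DISEASE, EVENT_DEATH):
            raise DataError(f"event code must be 0, 1 or 2, got {self.event}")


def records_to_frame(records: Sequence[SurvivalRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        row = {"person_id": r.person_id, "time": r.time, "event": r.event}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CauseSpecificFit:
    """Cox fit for one cause; competing events treated as censoring."""

    cause: int
    covariates: tuple[str, ...]
    coef: pd.Series
    cov: pd.DataFrame
    n_events: int
    aic: float
    model: CoxPHFitter

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.coef.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coef)


def fit_cause_specific(
    records: Sequence[SurvivalRecord] | pd.DataFrame,
    cause: int = EVENT_DISEASE,
    covariates: Sequence[str] = ("age", "male", "education"),
) -> CauseSpecificFit:
    """Cause-specific Cox model for one event type.

    Persons experiencing any other event type are censored at their
    event time; ties are handled by Efron's approximation (the lifelines
    default).
    """
    df = records_to_frame(records)
    covariates = tuple(covariates)
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise DataError(f"missing covariate columns: {missing}")
    sub = df[["time", *covariates]].copy()
    if not np.isfinite(sub[list(covariates)].to_numpy(dtype=float)).all():
        raise DataError("non-finite covariate values")
    sub["observed"] = (df["event"] == cause).astype(int)
    n_events = int(sub["observed"].sum())
    if n_events < 1:
        raise DataError(f"no events of cause {cause} in the data")
    cph = CoxPHFitter()
    cph.fit(sub, duration_col="time", event_col="observed")
    return CauseSpecificFit(
        cause=cause,
        covariates=covariates,
        coef=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        n_events=n_events,
        aic=float(cph.AIC_partial_),
        model=cph,
    )


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    """A log-hazard coefficient pooled across imputation draws."""

    coefficient: float
    se: float
    hazard_ratio: float
    ci95: tuple[float, float]
    df: float
    p_value: float
    within_var: float
    between_var: float
    n_imputations: int
    pooled: bool = True


def pool_rubin(
    per_draw_coefs: Sequence[float],
    per_draw_vars: Sequence[float],
) -> PooledEstimate:
    """Combine per-draw estimates by Rubin's rules.

    The pooled coefficient is the mean across draws; the total variance
    is ``W + (1 + 1/m) B`` with ``W`` the mean within-draw variance and
    ``B`` the between-draw variance.  Confidence intervals and the
    two-sided p-value use a t reference with the Rubin degrees of
    freedom ``(m - 1)(1 + W / ((1 + 1/m) B))^2``.
    """
    coefs = np.asarray(per_draw_coefs, dtype=float)
    vars_ = np.asarray(per_draw_vars, dtype=float)
    if coefs.shape != vars_.shape or coefs.ndim != 1:
        raise DataError("per-draw coefficients and variances must match in length")
    m = coefs.size
    if m < 1:
        raise DataError("need at least one draw")
    qbar = float(coefs.mean())
    w = float(vars_.mean())
    if m == 1:
        warnings.warn("single draw: returning the unpooled fit", stacklevel=2)
        se = float(np.sqrt(w))
        z = qbar / se if se > 0 else np.inf
        return PooledEstimate(
            coefficient=qbar, se=se, hazard_ratio=float(np.exp(qbar)),
            ci95=(qbar - 1.959964 * se, qbar + 1.959964 * se),
            df=np.inf, p_value=float(2 * stats.norm.sf(abs(z))),
            within_var=w, between_var=0.0, n_imputations=1, pooled=False,
        )
    b = float(coefs.var(ddof=1))
    total = w + (1.0 + 1.0 / m) * b
    se = float(np.sqrt(total))
    if b > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        tcrit = float(stats.t.ppf(0.975, df))
        p = float(2 * stats.t.sf(abs(qbar / se), df)) if se > 0 else 0.0
    else:
        df = np.inf
        tcrit = 1.959964
        p = float(2 * stats.norm.sf(abs(qbar / se))) if se > 0 else 0.0
    return PooledEstimate(
        coefficient=qbar,
        se=se,
        hazard_ratio=float(np.exp(qbar)),
        ci95=(qbar - tcrit * se, qbar + tcrit * se),
        df=df,
        p_value=p,
        within_var=w,
        between_var=b,
        n_imputations=m,
    )


# ---------------------------------------------------------------------------
# Cox-Snell diagnostics
# ---------------------------------------------------------------------------

@dataclass
class CoxSnellSummary:
    """Slope of the Nelson-Aalen curve of the residuals against the
    45-degree line; ~1 under correct specification (Exp(1) residuals)."""

    slope: float
    residuals: np.ndarray
    events: np.ndarray


def _baseline_cumhaz_at(model: CoxPHFitter, times: np.ndarray) -> np.ndarray:
    bch = model.baseline_cumulative_hazard_
    grid = bch.index.to_numpy(dtype=float)
    vals = bch.iloc[:, 0].to_numpy(dtype=float)
    idx = np.searchsorted(grid, times, side="right") - 1
    out = np.where(idx >= 0, vals[np.clip(idx, 0, len(vals) - 1)], 0.0)
    return out


def cox_snell_check(
    records: Sequence[SurvivalRecord] | pd.DataFrame,
    fit: CauseSpecificFit | None,
    cause: int = EVENT_DISEASE,
    trim_quantile: float = 0.9,
) -> CoxSnellSummary:
    """Cox-Snell residual diagnostic for a cause-specific fit.

    Residuals are each subject's estimated cumulative cause-specific
    hazard at their follow-up time; under a correctly specified model
    the residuals behave as a censored Exp(1) sample, so the
    Nelson-Aalen cumulative hazard of the residuals should track the
    45-degree line.  The summary slope is a through-the-origin least
    squares fit over residuals below ``trim_quantile`` (the upper tail
    of a Nelson-Aalen curve is noisy by construction).

    Passing ``fit=None`` checks the covariate-free null model.
    """
    df = records_to_frame(records)
    events = (df["event"] == cause).to_numpy(dtype=int)
    times = df["time"].to_numpy(dtype=float)
    if fit is None:
        naf = NelsonAalenFitter()
        naf.fit(times, event_observed=events)
        grid = naf.cumulative_hazard_.index.to_numpy(dtype=float)
        vals = naf.cumulative_hazard_.iloc[:, 0].to_numpy(dtype=float)
        idx = np.searchsorted(grid, times, side="right") - 1
        resid = np.where(idx >= 0, vals[np.clip(idx, 0, len(vals) - 1)], 0.0)
    else:
        X = df[list(fit.covariates)]
        partial = fit.model.predict_partial_hazard(X).to_numpy(dtype=float).ravel()
        resid = _baseline_cumhaz_at(fit.model, times) * partial
    naf = NelsonAalenFitter()
    naf.fit(resid, event_observed=events)
    r = naf.cumulative_hazard_.index.to_numpy(dtype=float)
    h = naf.cumulative_hazard_.iloc[:, 0].to_numpy(dtype=float)
    cut = np.quantile(resid[events == 1], trim_quantile) if events.any() else np.inf
    keep = (r > 0) & (r <= cut)
    if not keep.any():
        raise DataError("no usable residuals for the diagnostic")
    slope = float(np.sum(r[keep] * h[keep]) / np.sum(r[keep] ** 2))
    return CoxSnellSummary(slope=slope, residuals=resid, events=events)


# ---------------------------------------------------------------------------
# the three-way predictor comparison
# ---------------------------------------------------------------------------

def fit_pooled_over_draws(
    records: Sequence[SurvivalRecord] | pd.DataFrame,
    draws: np.ndarray,
    trait_name: str = "trait",
    cause: int = EVENT_DISEASE,
    covariates: Sequence[str] = ("age", "male", "education"),
) -> tuple[dict[str, PooledEstimate], float]:
    """One cause-specific Cox fit per plausible-value draw, Rubin-pooled.

    ``draws`` has shape (n_persons, n_draws).  Returns pooled estimates
    per covariate (including the trait) and the mean partial AIC.
    """
    df = records_to_frame(records)
    draws = np.asarray(draws, dtype=float)
    if draws.shape[0] != len(df):
        raise DataError("draws and survival records cover different persons")
    all_covs = list(covariates) + [trait_name]
    per_cov_coefs: dict[str, list[float]] = {c: [] for c in all_covs}
    per_cov_vars: dict[str, list[float]] = {c: [] for c in all_covs}
    aics = []
    for m in range(draws.shape[1]):
        df[trait_name] = draws[:, m]
        f = fit_cause_specific(df, cause=cause, covariates=all_covs)
        for c in all_covs:
            per_cov_coefs[c].append(float(f.coef[c]))
            per_cov_vars[c].append(float(f.cov.loc[c, c]))
        aics.append(f.aic)
    pooled = {c: pool_rubin(per_cov_coefs[c], per_cov_vars[c]) for c in all_covs}
    return pooled, float(np.mean(aics))


def compare_predictor_variants(
    records: Sequence[SurvivalRecord] | pd.DataFrame,
    raw_sums: np.ndarray,
    eap_uncorrected: np.ndarray,
    pv_corrected: np.ndarray,
    cause: int = EVENT_DISEASE,
    covariates: Sequence[str] = ("age", "male", "education"),
    standardize_raw: bool = False,
) -> pd.DataFrame:
    """Cause-specific hazard models under three trait-predictor variants.

    Variants: raw subscale sum scores; EAP estimates from the model
    without the ERS dimension (a fixed covariate, which understates
    uncertainty); plausible values from the ERS-corrected model, fitted
    per draw and pooled by Rubin's rules.  All variants adjust for the
    same covariates (by default age, sex, education).

    Returns a long table with one row per (variant, predictor) holding
    the hazard ratio, SE of the log-hazard, p-value, 95% CI and the
    variant's (mean) partial AIC.
    """
    df = records_to_frame(records)
    n = len(df)
    for name, arr in (("raw_sums", raw_sums), ("eap_uncorrected", eap_uncorrected)):
        if np.asarray(arr).shape[0] != n:
            raise DataError(f"{name} does not cover the same persons as records")
    raw = np.asarray(raw_sums, dtype=float)
    if standardize_raw:
        raw = (raw - raw.mean()) / raw.std(ddof=0)
    rows = []
    for variant, predictor in (
        ("raw_scores", raw),
        ("eap_uncorrected", np.asarray(eap_uncorrected, dtype=float)),
    ):
        df["trait"] = predictor
        f = fit_cause_specific(df, cause=cause,
                               covariates=list(covariates) + ["trait"])
        for c in list(covariates) + ["trait"]:
            se = float(np.sqrt(f.cov.loc[c, c]))
            z = float(f.coef[c]) / se
            rows.append({
                "variant": variant, "predictor": c,
                "hazard_ratio": float(np.exp(f.coef[c])), "se": se,
                "p_value": float(2 * stats.norm.sf(abs(z))),
                "ci_low": float(np.exp(f.coef[c] - 1.959964 * se)),
                "ci_high": float(np.exp(f.coef[c] + 1.959964 * se)),
                "aic": f.aic,
            })
    pooled, aic = fit_pooled_over_draws(
        df, np.asarray(pv_corrected, dtype=float), cause=cause,
        covariates=covariates,
    )
    for c in list(covariates) + ["trait"]:
        est = pooled[c]
        rows.append({
            "variant": "pv_corrected", "predictor": c,
            "hazard_ratio": est.hazard_ratio, "se": est.se,
            "p_value": est.p_value,
            "ci_low": float(np.exp(est.ci95[0])),
            "ci_high": float(np.exp(est.ci95[1])),
            "aic": aic,
        })
    return pd.DataFrame(rows)
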
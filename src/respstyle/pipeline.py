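"""End-to-end orchestration: fit, compare, score, bias, survival.

The pipeline mirrors the intended analysis flow: fit the model without
and with the ERS dimension, compare them by information criteria, score
persons with the preferred (ERS-corrected) model, trace the sum-score
bias curves for one subscale, and — when survival records are provided —
compare the three trait-predictor variants in cause-specific Cox
models.  Every artifact carries the seed and a hash of the
configuration, so a rerun with identical inputs is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bias import DEFAULT_ERS_LEVELS, bias_curves
from .errors import RespstyleError
from .estimate import compare_models, fit_mnrm
from .io import read_responses, read_survival, write_fitted_model
from .model import build_constrained_model
from .score import draw_plausible_values, score_table
from .surv import compare_predictor_variants


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run (YAML-loadable)."""

    responses_path: str = ""
    survival_path: str | None = None
    output_dir: str = "respstyle_output"
    scales: tuple[str, ...] = ("N", "A", "C")
    n_categories: int = 5
    nodes_per_dim: int = 10
    prior_sd: float = 3.0
    tol: float = 1e-7
    max_iter: int = 500
    n_draws: int = 5
    seed: int = 0
    bias_scale: str = "N"
    ers_levels: tuple[float, ...] = DEFAULT_ERS_LEVELS
    covariates: tuple[str, ...] = ("age", "male", "education")
    cause: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise RespstyleError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.scales = tuple(cfg.scales)
        cfg.ers_levels = tuple(cfg.ers_levels)
        cfg.covariates = tuple(cfg.covariates)
        return cfg

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; later stages are skipped after a failure.

    Returns the machine-readable report (also written to
    ``report.json`` in the output directory).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def fail(stage: str, exc: Exception) -> dict:
        kind = exc.category if isinstance(exc, RespstyleError) else "unexpected"
        report["stages"][stage] = {
            "status": "failed", "error_class": kind, "error": str(exc),
            "traceback": traceback.format_exc(limit=3),
        }
        _write_report(report, out)
        return report

    # ---- load ----------------------------------------------------------
    try:
        data = read_responses(config.responses_path, config.n_categories)
        n_scales = len(config.scales)
        if data.n_items % n_scales:
            raise RespstyleError(
                f"{data.n_items} items do not split evenly over "
                f"{n_scales} scales"
            )
        items_per_scale = data.n_items // n_scales
        report["stages"]["load"] = {
            "status": "ok", "n_persons": data.n_persons, "n_items": data.n_items,
        }
    except Exception as exc:  # noqa: BLE001
        return fail("load", exc)

    # ---- fit both models ----------------------------------------------
    fits = {}
    try:
        for ers in (False, True):
            spec, _ = build_constrained_model(
                config.scales, items_per_scale, ers=ers,
                n_categories=config.n_categories,
            )
            fit = fit_mnrm(
                data, spec, prior_sd=config.prior_sd,
                nodes_per_dim=config.nodes_per_dim, tol=config.tol,
                max_iter=config.max_iter,
            )
            name = "with_ers" if ers else "without_ers"
            fits[name] = fit
            write_fitted_model(fit, out / f"fit_{name}.json")
        report["stages"]["fit"] = {
            "status": "ok",
            "log_likelihoods": {k: f.log_likelihood for k, f in fits.items()},
            "converged": {k: f.converged for k, f in fits.items()},
        }
    except Exception as exc:  # noqa: BLE001
        return fail("fit", exc)

    # ---- compare -------------------------------------------------------
    try:
        table = compare_models([fits["without_ers"], fits["with_ers"]])
        table.to_csv(out / "model_comparison.csv", index=False)
        preferred = {
            crit: str(table.loc[table[crit].idxmin(), "model"])
            for crit in ("AIC", "AIC3", "BIC", "CAIC")
        }
        report["stages"]["compare"] = {
            "status": "ok",
            "criteria": table.set_index("model")[
                ["AIC", "AIC3", "BIC", "CAIC"]
            ].to_dict(),
            "preferred_by": preferred,
        }
    except Exception as exc:  # noqa: BLE001
        return fail("compare", exc)

    # ---- score with the ERS-corrected model ---------------------------
    try:
        scores = draw_plausible_values(
            data, fits["with_ers"], n_draws=config.n_draws, seed=config.seed,
        )
        score_table(scores, data, fits["with_ers"].spec).to_csv(
            out / "scores.csv", index=False, float_format="%.6g"
        )
        report["stages"]["score"] = {
            "status": "ok", "n_draws": config.n_draws,
            "eap_means": dict(zip(scores.dim_labels,
                                  scores.eap.mean(axis=0).round(6))),
        }
    except Exception as exc:  # noqa: BLE001
        return fail("score", exc)

    # ---- bias curves ---------------------------------------------------
    try:
        curve = bias_curves(
            fits["with_ers"].params, fits["with_ers"].spec,
            config.bias_scale, ers_levels=config.ers_levels,
        )
        curve.to_frame().to_csv(
            out / f"bias_{config.bias_scale}.csv", index=False,
            float_format="%.6g",
        )
        report["stages"]["bias"] = {
            "status": "ok",
            "crossing_point": curve.crossing_point,
            "max_abs_bias_at_crossing": curve.max_abs_bias_at_crossing,
            "intersection_point": curve.intersection_point,
            "max_abs_bias_at_intersection": curve.max_abs_bias_at_intersection,
        }
    except Exception as exc:  # noqa: BLE001
        return fail("bias", exc)

    # ---- survival ------------------------------------------------------
    if config.survival_path is None:
        report["stages"]["survival"] = {"status": "skipped"}
    else:
        try:
            surv = read_survival(config.survival_path)
            scale_items = fits["with_ers"].spec.items_for(config.bias_scale)
            raw = np.where(
                data.responses[:, scale_items] > 0,
                data.responses[:, scale_items], 0,
            ).sum(axis=1)
            trait_idx = fits["with_ers"].spec.dim_index(config.bias_scale)
            eap3 = _eap_for(data, fits["without_ers"], config.bias_scale)
            pv = scores.plausible_values[:, :, trait_idx]
            table = compare_predictor_variants(
                surv, raw, eap3, pv, cause=config.cause,
                covariates=config.covariates,
            )
            table.to_csv(out / "survival_comparison.csv", index=False,
                         float_format="%.6g")
            trait_rows = table[table["predictor"] == "trait"]
            report["stages"]["survival"] = {
                "status": "ok",
                "trait_hazard_ratios": dict(
                    zip(trait_rows["variant"], trait_rows["hazard_ratio"].round(6))
                ),
            }
        except Exception as exc:  # noqa: BLE001
            return fail("survival", exc)

    _write_report(report, out)
    return report


def _eap_for(data, fit, scale: str) -> np.ndarray:
    from .score import eap_scores

    s = eap_scores(data, fit)
    return s.eap[:, fit.spec.dim_index(scale)]


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
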
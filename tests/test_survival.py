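import numpy as np
import pandas as pd
import pytest

from respstyle import (
    DataError,
    SimulationConfig,
    SurvivalSimConfig,
    SurvivalRecord,
    fit_cause_specific,
    generate_survival,
    generate_thetas,
    pool_rubin,
)
from respstyle.surv import (
    compare_predictor_variants,
    cox_snell_check,
    fit_pooled_over_draws,
)


def simulated_records(n=2000, seed=11, trait_loghr=0.2, **kw):
    config = SimulationConfig(
        n_persons=n, seed=seed,
        survival=SurvivalSimConfig(
            disease_loghr=(0.134, 0.05, 0.04, trait_loghr), **kw
        ),
    )
    thetas = generate_thetas(config)
    df = generate_survival(thetas, config)
    df["trait"] = thetas[:, 0]
    return df


class TestPoolRubin:
    def test_hand_computed_toy_case(self):
        est = pool_rubin([0.1, 0.2, 0.3], [0.01, 0.01, 0.01])
        assert est.coefficient == pytest.approx(0.2)
        assert est.within_var == pytest.approx(0.01)
        assert est.between_var == pytest.approx(0.01)
        assert est.se**2 == pytest.approx(0.01 + (4 / 3) * 0.01)
        assert est.hazard_ratio == pytest.approx(np.exp(0.2))
        assert est.n_imputations == 3

    def test_identical_draws_collapse_to_within_variance(self):
        est = pool_rubin([0.4, 0.4, 0.4, 0.4, 0.4], [0.02] * 5)
        assert est.between_var == 0.0
        assert est.se == pytest.approx(np.sqrt(0.02))

    def test_total_variance_dominates_within(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            coefs = rng.normal(0, 0.3, 5)
            var = rng.uniform(0.001, 0.05, 5)
            est = pool_rubin(coefs, var)
            assert est.se**2 >= est.within_var - 1e-15

    def test_single_draw_flagged(self):
        with pytest.warns(UserWarning):
            est = pool_rubin([0.3], [0.01])
        assert not est.pooled
        assert est.se == pytest.approx(0.1)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DataError):
            pool_rubin([0.1, 0.2], [0.01])


class TestFitCauseSpecific:
    def test_recovers_known_log_hazard_ratio(self):
        df = simulated_records(n=2000, seed=21)
        fit = fit_cause_specific(
            df, cause=1, covariates=("age", "male", "education", "trait")
        )
        se = fit.se["trait"]
        assert abs(fit.coef["trait"] - 0.2) < 2 * se

    def test_null_covariate_coverage(self):
        """Permuted trait: the 95% CI should cover zero at ~95%."""
        rng = np.random.default_rng(5)
        covered = 0
        reps = 60
        for rep in range(reps):
            df = simulated_records(n=400, seed=300 + rep, trait_loghr=0.0)
            df["trait"] = rng.permutation(df["trait"].to_numpy())
            fit = fit_cause_specific(df, cause=1, covariates=("trait",))
            se = fit.se["trait"]
            c = fit.coef["trait"]
            covered += (c - 1.96 * se) <= 0.0 <= (c + 1.96 * se)
        assert 0.85 <= covered / reps <= 1.0

    def test_no_competing_events_equals_single_event_fit(self):
        df = simulated_records(n=800, seed=31)
        df.loc[df["event"] == 2, "event"] = 0  # censor all deaths
        cs = fit_cause_specific(df, cause=1, covariates=("trait",))
        plain = df.copy()
        plain["observed"] = (plain["event"] > 0).astype(int)
        from lifelines import CoxPHFitter

        ref = CoxPHFitter().fit(plain[["time", "trait", "observed"]],
                                duration_col="time", event_col="observed")
        assert cs.coef["trait"] == pytest.approx(ref.params_["trait"], abs=1e-10)

    def test_no_events_of_cause_rejected(self):
        df = simulated_records(n=50, seed=41)
        df["event"] = 0
        with pytest.raises(DataError):
            fit_cause_specific(df, cause=1, covariates=("trait",))

    def test_record_objects_accepted(self):
        df = simulated_records(n=300, seed=51)
        records = [
            SurvivalRecord(r.person_id, r.time, int(r.event),
                           {"trait": r.trait})
            for r in df.itertuples()
        ]
        fit = fit_cause_specific(records, cause=1, covariates=("trait",))
        assert np.isfinite(fit.coef["trait"])

    def test_invalid_event_code_rejected(self):
        with pytest.raises(DataError):
            SurvivalRecord(1, 2.0, 5)


class TestCoxSnell:
    def test_correct_specification_slope_near_one(self):
        df = simulated_records(n=2000, seed=11, trait_loghr=0.8)
        fit = fit_cause_specific(
            df, cause=1, covariates=("age", "male", "education", "trait")
        )
        assert 0.9 <= cox_snell_check(df, fit).slope <= 1.1

    def test_sign_flipped_model_detected(self):
        df = simulated_records(n=2000, seed=11, trait_loghr=0.8)
        flipped = df.copy()
        flipped["trait"] = -flipped["trait"]
        bad = fit_cause_specific(
            flipped, cause=1, covariates=("age", "male", "education", "trait")
        )
        slope = cox_snell_check(df, bad).slope
        assert slope > 1.1 or slope < 0.9

    def test_null_model_on_exponential_data(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1.0, 3000)
        df = pd.DataFrame({
            "person_id": np.arange(3000),
            "time": np.minimum(t, 2.5),
            "event": (t <= 2.5).astype(int),
        })
        assert cox_snell_check(df, None).slope == pytest.approx(1.0, abs=0.1)


@pytest.fixture(scope="module")
def null_setup():
    """Zero trait effect: noisy proxies of the trait as predictors."""
    df = simulated_records(n=1500, seed=61, trait_loghr=0.0)
    rng = np.random.default_rng(3)
    truth = df["trait"].to_numpy()
    raw = truth + rng.normal(0, 0.6, len(df))
    eap = 0.8 * truth + rng.normal(0, 0.3, len(df))
    pv = (0.8 * truth)[:, None] + rng.normal(0, 0.5, (len(df), 5))
    return df, raw, eap, pv


class TestPredictorVariants:
    def test_null_effect_gives_unit_hazard_ratios(self, null_setup):
        df, raw, eap, pv = null_setup
        table = compare_predictor_variants(df, raw, eap, pv)
        trait = table[table["predictor"] == "trait"]
        assert (np.abs(np.log(trait["hazard_ratio"])) < 0.15).all()

    def test_table_layout(self, null_setup):
        df, raw, eap, pv = null_setup
        table = compare_predictor_variants(df, raw, eap, pv)
        assert set(table["variant"]) == {"raw_scores", "eap_uncorrected",
                                         "pv_corrected"}
        for variant, sub in table.groupby("variant"):
            assert list(sub["predictor"]) == ["age", "male", "education",
                                              "trait"]
        assert {"hazard_ratio", "se", "p_value", "ci_low", "ci_high",
                "aic"} <= set(table.columns)

    def test_person_mismatch_rejected(self, null_setup):
        df, raw, eap, pv = null_setup
        with pytest.raises(DataError):
            compare_predictor_variants(df, raw[:-1], eap, pv)

    def test_pooled_se_exceeds_any_single_draw_when_draws_disagree(
        self, null_setup
    ):
        df, raw, eap, pv = null_setup
        pooled, _ = fit_pooled_over_draws(df, pv, covariates=())
        est = pooled["trait"]
        assert est.between_var > 0
        assert est.se**2 > est.within_var


class TestAttenuationStructure:
    def test_corrected_scores_less_attenuated_than_uncorrected(self, neoffi):
        """Scored under the generating parameters, plausible values from
        the ERS-aware model transfer more of the true trait signal per
        unit of predictor variance than ERS-blind scoring: the slope
        factor cov(PV, theta)/var(PV) is larger with the correction."""
        from respstyle import (
            build_constrained_model,
            draw_plausible_values,
            generate_responses,
            load_neoffi_params,
        )
        from conftest import truth_fit

        spec4, params4 = neoffi
        spec3, params3 = load_neoffi_params(ers=False)
        config = SimulationConfig(n_persons=2000, seed=5)
        thetas = generate_thetas(config)
        data = generate_responses(thetas, params4, spec4, seed=config.seed)
        thN = thetas[:, 0]
        factors = {}
        for name, spec, params, corr in (
            ("ers", spec4, params4, config.full_corr()),
            ("no_ers", spec3, params3, config.full_corr()[:3, :3]),
        ):
            fit = truth_fit(spec, params, corr, nodes_per_dim=7)
            pv = draw_plausible_values(data, fit, n_draws=2, seed=1)
            x = pv.plausible_values[:, 0, 0]
            factors[name] = np.cov(x, thN)[0, 1] / x.var()
        assert factors["ers"] > factors["no_ers"]
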
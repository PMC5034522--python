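"""Tests for design encoding, model application and weighted fitting."""

import numpy as np
import pandas as pd
import pytest

from bmicorrect import (
    CorrectionModel,
    DataError,
    DomainError,
    MissingDataError,
    SingularDesignError,
    Term,
    UnitError,
    WeightStatus,
    aic_select,
    apply_model,
    build_design,
    correct_record,
    derive_sr_weight_status,
    design_vector,
    fit_wls,
    published_models,
    screen_interactions,
)
from bmicorrect.correction import default_candidate_blocks, record_values
from bmicorrect.records import CM_PER_INCH, KG_PER_POUND

from conftest import make_record

REFERENCE_VALUES = {
    "sr_weight": 0.0,
    "sr_height": 0.0,
    "age_months": 0.0,
    "puberty": 0.0,
    "cesd": 0.0,
    "self_rated_health": 0.0,
    "self_esteem": 0.0,
    "dieting": 0.0,
    "sr_weight_status": "HW",
    "body_size_estimation": "AboutRight",
    "race_ethnicity": "White",
    "sex": "male",
    "parent_education": "College_plus",
}


class TestPublishedModels:
    def test_key_coefficients(self, models):
        wm, hm = models
        coefs_w = {t.column: t.coefficient for t in wm.terms}
        coefs_h = {t.column: t.coefficient for t in hm.terms}
        assert wm.intercept == 8.20 and hm.intercept == 9.53
        assert coefs_w["sr_weight"] == 0.95
        assert coefs_h["sr_height"] == 0.85
        assert coefs_h["sex[female]"] == 0.65
        assert hm.reference_levels["sex"] == "male"

    def test_weight_model_excludes_race_sex_parent_education(self, models):
        wm, _ = models
        preds = {t.predictor for t in wm.terms}
        assert preds.isdisjoint({"race_ethnicity", "sex", "parent_education"})

    def test_json_round_trip_is_bit_exact(self, models, tmp_path):
        for m in models:
            path = tmp_path / f"{m.outcome}.json"
            m.to_json(path)
            back = CorrectionModel.from_json(path)
            assert back.intercept == m.intercept
            assert [(t.predictor, t.level, t.coefficient) for t in back.terms] == [
                (t.predictor, t.level, t.coefficient) for t in m.terms
            ]
            assert back.reference_levels == m.reference_levels

    def test_reference_level_terms_rejected(self):
        with pytest.raises(DomainError, match="reference level"):
            CorrectionModel(
                outcome="weight",
                unit_system="metric",
                intercept=0.0,
                terms=(Term("sr_weight_status", "HW", 1.0),),
                reference_levels={"sr_weight_status": "HW"},
            )


class TestDesignVector:
    def test_reference_record_is_all_zero(self, models):
        wm, hm = models
        assert np.all(design_vector(REFERENCE_VALUES, wm) == 0)
        assert np.all(design_vector(REFERENCE_VALUES, hm) == 0)

    def test_categorical_indicator(self, models):
        wm, _ = models
        vals = dict(REFERENCE_VALUES, body_size_estimation="OW")
        x = dict(zip([t.column for t in wm.terms], design_vector(vals, wm)))
        assert x["body_size_estimation[OW]"] == 1.0
        assert x["body_size_estimation[UW]"] == 0.0

    def test_missing_covariate_names_field(self, models, growth_table):
        wm, _ = models
        rec = make_record(cesd=None)
        with pytest.raises(MissingDataError, match="cesd"):
            design_vector(rec, wm, growth_table)

    def test_grouped_parent_education_level(self, models):
        _, hm = models
        for lvl, expect in (("HS_or_less", 1.0), ("Some_college", 1.0),
                            ("College_plus", 0.0)):
            vals = dict(REFERENCE_VALUES, parent_education=lvl)
            x = dict(zip([t.column for t in hm.terms], design_vector(vals, hm)))
            assert x["parent_education[Less_than_college]"] == expect


class TestApplyModel:
    def test_reference_record_recovers_intercepts(self, models):
        wm, hm = models
        assert apply_model(wm, REFERENCE_VALUES) == pytest.approx(8.20)
        assert apply_model(hm, REFERENCE_VALUES) == pytest.approx(9.53)

    def test_single_covariate_dot_products(self, models):
        wm, hm = models
        vals = dict(REFERENCE_VALUES, sr_weight=100.0)
        assert apply_model(wm, vals) == pytest.approx(8.20 + 0.95 * 100.0)
        vals = dict(REFERENCE_VALUES, sr_height=60.0)
        assert apply_model(hm, vals) == pytest.approx(9.53 + 0.85 * 60.0)

    def test_affine_in_continuous_covariates(self, models):
        wm, _ = models
        v1 = dict(REFERENCE_VALUES, sr_weight=120.0, cesd=5.0, puberty=2.0)
        v2 = dict(REFERENCE_VALUES, sr_weight=160.0, cesd=25.0, puberty=4.0)
        for alpha in (0.0, 0.25, 0.5, 1.0):
            mix = dict(
                REFERENCE_VALUES,
                **{
                    k: alpha * v1[k] + (1 - alpha) * v2[k]
                    for k in ("sr_weight", "cesd", "puberty")
                },
            )
            expected = alpha * apply_model(wm, v1) + (1 - alpha) * apply_model(wm, v2)
            assert apply_model(wm, mix) == pytest.approx(expected, abs=1e-9)

    def test_record_units_are_converted_to_model_units(self, models, growth_table):
        wm, _ = models
        rec = make_record(sr_weight_kg=100.0 * KG_PER_POUND)
        vals = record_values(rec, "imperial", growth_table)
        assert vals["sr_weight"] == pytest.approx(100.0)
        assert vals["sr_height"] == pytest.approx(175.0 / CM_PER_INCH)


class TestDeriveSrStatus:
    def test_adult_obese_self_report(self, growth_table):
        rec = make_record(sr_height_cm=170.0, sr_weight_kg=31.0 * 1.70**2)
        assert derive_sr_weight_status(rec, growth_table) is WeightStatus.OB

    def test_median_self_report_is_healthy(self, growth_table):
        L, M, S = growth_table.lookup("female", 180.0)
        rec = make_record(sex="female", age_months=180.0, sr_height_cm=160.0,
                          sr_weight_kg=M * 1.60**2)
        assert derive_sr_weight_status(rec, growth_table) is WeightStatus.HW

    def test_invalid_sr_height_rejected_at_construction(self):
        with pytest.raises(DomainError):
            make_record(sr_height_cm=0.0)


class TestCorrectRecord:
    def _identity_models(self):
        wm = CorrectionModel("weight", "metric", 0.0,
                             (Term("sr_weight", None, 1.0),))
        hm = CorrectionModel("height", "metric", 0.0,
                             (Term("sr_height", None, 1.0),))
        return wm, hm

    def test_identity_models_return_self_report(self, growth_table):
        rec = make_record()
        wm, hm = self._identity_models()
        out = correct_record(rec, wm, hm, growth_table)
        assert out.weight_kg == pytest.approx(rec.sr_weight_kg)
        assert out.height_cm == pytest.approx(rec.sr_height_cm)
        assert out.bmi == pytest.approx(70.0 / 1.75**2)

    def test_published_models_match_brute_force(self, models, growth_table):
        wm, hm = models
        rec = make_record(sex="female", race_ethnicity="Black",
                          parent_education="HS_or_less", dieting=True,
                          body_size_estimation="OW", puberty=4, cesd=17.0,
                          self_rated_health=3.0, self_esteem=4.5)
        vals = record_values(rec, "imperial", growth_table)

        def brute(model):
            total = model.intercept
            for t in model.terms:
                parts = t.predictor.split("*")
                levels = (
                    [None] * len(parts)
                    if t.level is None
                    else [l or None for l in t.level.split("*")]
                )
                prod = 1.0
                for p, l in zip(parts, levels):
                    v = vals[p]
                    if l is None:
                        prod *= float(v)
                    elif l == "Less_than_college":
                        prod *= float(v in ("HS_or_less", "Some_college"))
                    else:
                        prod *= float(v == l)
                total += t.coefficient * prod
            return total

        out = correct_record(rec, wm, hm, growth_table)
        assert out.weight_kg == pytest.approx(brute(wm) * KG_PER_POUND, abs=1e-9)
        assert out.height_cm == pytest.approx(brute(hm) * CM_PER_INCH, abs=1e-9)

    def test_mixed_unit_models_rejected(self, models, growth_table):
        wm, _ = models
        _, hm_metric = self._identity_models(), None
        hm = CorrectionModel("height", "metric", 0.0,
                             (Term("sr_height", None, 1.0),))
        with pytest.raises(UnitError):
            correct_record(make_record(), wm, hm, growth_table)

    def test_incomplete_record_raises_missing_data(self, models, growth_table):
        wm, hm = models
        with pytest.raises(MissingDataError):
            correct_record(make_record(puberty=None), wm, hm, growth_table)


class TestFitWls:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(0, 10, 30)
        X = pd.DataFrame({"sr_weight": x})
        res = fit_wls(2.0 + 3.0 * x, X, outcome="weight")
        assert res.model.intercept == pytest.approx(2.0, abs=1e-10)
        assert res.model.terms[0].coefficient == pytest.approx(3.0, abs=1e-10)
        assert res.r2 == pytest.approx(1.0)

    def test_weights_concentrated_on_subset(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = 1.0 + 2.0 * x + rng.normal(size=60)
        X = pd.DataFrame({"sr_weight": x})
        w = np.where(np.arange(60) < 40, 1.0, 1e-12)
        heavy = fit_wls(y, X, w)
        sub = fit_wls(y[:40], X.iloc[:40])
        assert heavy.model.intercept == pytest.approx(sub.model.intercept, abs=1e-5)
        assert heavy.model.terms[0].coefficient == pytest.approx(
            sub.model.terms[0].coefficient, abs=1e-5
        )

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(11)
        n = 10_000
        X = pd.DataFrame({"sr_weight": rng.normal(70, 10, n),
                          "cesd": rng.normal(11, 7, n)})
        beta = {"sr_weight": 0.9, "cesd": -0.05}
        y = 5.0 + X @ pd.Series(beta) + rng.normal(0, 2, n)
        res = fit_wls(np.asarray(y), X, rng.uniform(0.5, 1.5, n))
        for t in res.model.terms:
            assert abs(t.coefficient - beta[t.column]) <= 3 * res.coefficient_ses[t.column]

    def test_rank_deficiency_lists_columns(self):
        x = np.linspace(0, 1, 20)
        X = pd.DataFrame({"sr_weight": x, "cesd": 2 * x})
        with pytest.raises(SingularDesignError) as exc:
            fit_wls(x, X)
        assert exc.value.columns

    def test_too_few_observations(self):
        X = pd.DataFrame({"sr_weight": [1.0, 2.0, 3.0]})
        with pytest.raises(DataError):
            fit_wls(np.ones(3), X)

    def test_fitted_values_reproduced_by_apply_model(self, small_cohort,
                                                     growth_table):
        dd = build_design(small_cohort, default_candidate_blocks("weight"),
                          "weight", "metric", growth_table)
        res = fit_wls(dd.y, dd.X, dd.w, outcome="weight",
                      reference_levels=dd.reference_levels)
        coefs = np.array([t.coefficient for t in res.model.terms])
        fitted = res.model.intercept + dd.X[
            [t.column for t in res.model.terms]
        ].to_numpy() @ coefs
        # spot-check through the record pathway as well
        preds = [apply_model(res.model, r, growth_table) for r in small_cohort[:25]]
        assert np.allclose(preds, fitted[:25], atol=1e-9)


class TestAicSelect:
    def test_single_mandatory_block_returned_unchanged(self, small_cohort,
                                                       growth_table):
        res = aic_select(["sr_weight"], small_cohort, "weight",
                         unit_system="metric", growth_ref=growth_table)
        assert res.model.provenance["blocks_retained"] == ["sr_weight"]
        assert res.model.provenance["blocks_removed"] == []

    def test_selection_never_increases_aic(self, small_cohort, growth_table):
        blocks = default_candidate_blocks("weight")
        full = build_design(small_cohort, blocks, "weight", "metric", growth_table)
        full_fit = fit_wls(full.y, full.X, full.w)
        res = aic_select(blocks, small_cohort, "weight", unit_system="metric",
                         growth_ref=growth_table)
        assert res.aic <= full_fit.aic + 1e-9
        assert res.model.provenance["full_model_aic"] == pytest.approx(full_fit.aic)

    def test_strong_signal_blocks_all_retained(self):
        rng = np.random.default_rng(5)
        n = 1500
        recs = [
            make_record(
                id=f"r{i}",
                sr_weight_kg=float(w),
                dieting=bool(d),
                cesd=float(c),
                measured_weight_kg=float(2.0 + 1.0 * w + 4.0 * d + 0.3 * c + e),
                sr_weight_status=WeightStatus.HW,
            )
            for i, (w, d, c, e) in enumerate(
                zip(
                    rng.uniform(45, 95, n),
                    rng.integers(0, 2, n),
                    rng.uniform(0, 40, n),
                    rng.normal(0, 1.0, n),
                )
            )
        ]
        res = aic_select(["sr_weight", "dieting", "cesd"], recs, "weight")
        assert set(res.model.provenance["blocks_retained"]) == {
            "sr_weight", "dieting", "cesd",
        }

    def test_pure_noise_block_removed(self):
        rng = np.random.default_rng(10)
        n = 1200
        recs = [
            make_record(
                id=f"r{i}",
                sr_weight_kg=float(w),
                cesd=float(c),
                measured_weight_kg=float(1.0 + 1.0 * w + e),
                sr_weight_status=WeightStatus.HW,
            )
            for i, (w, c, e) in enumerate(
                zip(
                    rng.uniform(45, 95, n),
                    rng.uniform(0, 40, n),  # no effect on the outcome
                    rng.normal(0, 1.5, n),
                )
            )
        ]
        res = aic_select(["sr_weight", "cesd"], recs, "weight")
        assert res.model.provenance["blocks_retained"] == ["sr_weight"]
        assert res.model.provenance["blocks_removed"] == ["cesd"]


def _interaction_records(n=1600, interaction=2.5, seed=21, with_bse=True):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        w = float(rng.uniform(45, 95))
        d = bool(rng.integers(0, 2))
        bse = str(rng.choice(["UW", "AboutRight", "OW"])) if with_bse else "AboutRight"
        y = (
            3.0 + 1.0 * w + 1.2 * d + 0.8 * (bse == "OW")
            + interaction * d * (bse == "OW") + float(rng.normal(0, 1.0))
        )
        recs.append(
            make_record(
                id=f"r{i}", sr_weight_kg=w, dieting=d, body_size_estimation=bse,
                measured_weight_kg=y, sr_weight_status=WeightStatus.HW,
            )
        )
    return recs


class TestScreenInteractions:
    def test_no_interaction_generative_model_rarely_keeps_any(self):
        """Without a generative interaction, the AIC rule admits a spurious
        product term only at roughly the chi-square(1) > 2 rate (~16%), so
        across fixed seeds the kept count stays small."""
        kept = 0
        for seed in range(8):
            recs = _interaction_records(n=1200, interaction=0.0, seed=40 + seed,
                                        with_bse=False)
            sel = aic_select(["sr_weight", "dieting"], recs, "weight")
            res = screen_interactions(sel, recs)
            kept += bool(res.model.provenance["interactions_kept"])
        assert kept <= 3

    def test_strong_interaction_retained(self):
        recs = _interaction_records(interaction=2.5, seed=21)
        sel = aic_select(["sr_weight", "dieting", "body_size_estimation"],
                         recs, "weight")
        res = screen_interactions(sel, recs)
        kept = res.model.provenance["interactions_kept"]
        assert ["dieting", "body_size_estimation"] in kept or [
            "body_size_estimation", "dieting",
        ] in kept
        # the fitted interaction model can still be applied to records
        pred = apply_model(res.model, recs[0])
        assert np.isfinite(pred)
        assert res.aic < sel.aic

    def test_single_predictor_returns_input(self, small_cohort, growth_table):
        sel = aic_select(["sr_weight"], small_cohort, "weight",
                         unit_system="metric", growth_ref=growth_table)
        assert screen_interactions(sel, small_cohort,
                                   growth_ref=growth_table) is sel
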
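"""Normative model estimation: translations, density law, stepwise, LOOCV."""

import numpy as np
import pandas as pd
import pytest

from lungsms import errors
from lungsms.normative import (
    NormativeDensityModel,
    explore_covariates,
    fit_density_regression,
    fit_volume_translation,
    loocv_sms,
)
from lungsms.reference_equations import predicted_tlc
from lungsms.sms import score_record
from lungsms.synthetic import CohortSpec, generate_normative_cohort

TRUTH = dict(alpha=2.50, beta=-0.70, sigma=0.025, gamma=0.40, delta=0.95)


def _translation_cohort(n_per_gender=50, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for gender, mean_h, sd_h in (("male", 1.76, 0.07), ("female", 1.63, 0.06)):
        for i in range(n_per_gender):
            h = float(rng.normal(mean_h, sd_h))
            tlc = predicted_tlc(gender, h)
            v = 0.4 + 0.95 * tlc + (rng.normal(0, noise) if noise else 0.0)
            rows.append({"subject_id": f"{gender}{i}", "gender": gender,
                         "height": h, "v_ct": v, "pd15": 90.0})
    return pd.DataFrame(rows)


class TestVolumeTranslation:
    def test_parameter_recovery_within_three_se(self):
        tr = fit_volume_translation(_translation_cohort())
        for gender in ("male", "female"):
            t = tr[gender]
            assert abs(t.gamma - 0.4) <= 3 * t.se_gamma
            assert abs(t.delta - 0.95) <= 3 * t.se_delta

    def test_noise_free_recovery_is_exact(self):
        tr = fit_volume_translation(_translation_cohort(noise=0.0))
        for t in tr.values():
            assert t.gamma == pytest.approx(0.4, abs=1e-9)
            assert t.delta == pytest.approx(0.95, abs=1e-9)

    def test_two_per_gender_is_fit_error(self):
        df = _translation_cohort(n_per_gender=2)
        with pytest.raises(errors.FitError):
            fit_volume_translation(df)

    def test_single_gender_cohort_fits_that_gender_only(self, fitted_model):
        df = _translation_cohort()
        males = df[df.gender == "male"]
        tr = fit_volume_translation(males)
        assert "male" in tr and "female" not in tr
        # scoring the absent gender later fails loudly
        model = NormativeDensityModel(
            pd.concat([males], ignore_index=True).assign(
                pd15=lambda d: 90.0 + np.arange(len(d)))).fit(regional=False)
        with pytest.raises(errors.ScopeError):
            score_record("x", "female", 1.6, 5.0, 90.0, model)


class TestDensityRegression:
    def test_generator_truth_recovered_within_three_se(self, normative_cohort):
        law = fit_density_regression(normative_cohort, log_base="10")
        assert abs(law.alpha - TRUTH["alpha"]) <= 3 * law.se_alpha
        assert abs(law.beta - TRUTH["beta"]) <= 3 * law.se_beta
        assert abs(law.sigma - TRUTH["sigma"]) <= 3 * law.se_sigma

    def test_exact_loglog_line_gives_sigma_zero_with_warning(self):
        spec = CohortSpec(seed=5, sigma=0.0, volume_noise_sd=0.0,
                          inspiration_sd=0.0)
        df = generate_normative_cohort(spec)
        with pytest.warns(errors.DegenerateModelWarning):
            law = fit_density_regression(df, log_base="10")
        assert law.sigma == pytest.approx(0.0, abs=1e-10)
        assert law.alpha == pytest.approx(TRUTH["alpha"], abs=1e-8)
        assert law.beta == pytest.approx(TRUTH["beta"], abs=1e-8)

    def test_regional_scope_requires_regional_columns(self, normative_cohort):
        df = normative_cohort.drop(columns=["v_ct_apical", "pd15_apical"])
        with pytest.raises(errors.ScopeError):
            fit_density_regression(df, scope="apical", log_base="10")

    def test_nonpositive_density_names_subject(self, normative_cohort):
        df = normative_cohort.copy()
        df.loc[3, "pd15"] = -1.0
        with pytest.raises(errors.DomainError, match=str(df.loc[3, "subject_id"])):
            fit_density_regression(df, log_base="10")

    def test_too_few_subjects(self, normative_cohort):
        with pytest.raises(errors.FitError):
            fit_density_regression(normative_cohort.head(5), log_base="10")


class TestModelObject:
    def test_fit_is_invariant_to_subject_ordering(self, normative_cohort,
                                                  fitted_model):
        shuffled = normative_cohort.sample(frac=1.0, random_state=9)
        other = NormativeDensityModel(shuffled, log_base="10").fit()
        assert other.global_law.alpha == pytest.approx(
            fitted_model.global_law.alpha, abs=1e-10)
        assert other.global_law.sigma == pytest.approx(
            fitted_model.global_law.sigma, abs=1e-12)
        for region in ("apical", "central", "basal"):
            assert other.regional_laws[region].beta == pytest.approx(
                fitted_model.regional_laws[region].beta, abs=1e-10)

    def test_sms_invariant_to_log_base(self, normative_cohort):
        m_e = NormativeDensityModel(normative_cohort, log_base="e").fit(
            regional=False)
        m_10 = NormativeDensityModel(normative_cohort, log_base="10").fit(
            regional=False)
        assert m_e.global_law.alpha != pytest.approx(m_10.global_law.alpha)
        row = normative_cohort.iloc[5]
        s_e = score_record("x", row.gender, row.height, row.v_ct, row.pd15, m_e)
        s_10 = score_record("x", row.gender, row.height, row.v_ct, row.pd15, m_10)
        assert s_e.sms_global == pytest.approx(s_10.sms_global, abs=1e-9)

    def test_insample_sms_mean_zero_sd_near_one(self, normative_cohort,
                                                fitted_model):
        scores = [
            score_record(r.subject_id, r.gender, r.height, r.v_ct, r.pd15,
                         fitted_model).sms_global
            for r in normative_cohort.itertuples()
        ]
        assert abs(np.mean(scores)) < 1e-8
        assert 0.9 < np.std(scores, ddof=1) < 1.1

    def test_summary_lists_all_scopes(self, fitted_model):
        text = fitted_model.summary()
        for token in ("global", "apical", "central", "basal", "alpha", "gamma"):
            assert token in text

    def test_regional_fit_requires_columns_when_forced(self, normative_cohort):
        df = normative_cohort[["subject_id", "gender", "height", "v_ct", "pd15"]]
        with pytest.raises(errors.ScopeError):
            NormativeDensityModel(df).fit(regional=True)


def test_density_law_plot_renders(normative_cohort, fitted_model):
    import matplotlib

    matplotlib.use("Agg")
    ax = fitted_model.plot_density_law(normative_cohort)
    assert ax.get_legend() is not None


class TestCovariateExploration:
    def test_volume_and_inspiration_detected(self, normative_cohort):
        report = explore_covariates(normative_cohort)
        assert {"log_v_ct", "inspiration_level"} <= set(report.selected_terms)
        assert report.r_squared_final > 0.5
        assert set(report.selected_terms) <= set(report.candidate_terms)

    def test_null_cohort_explains_nothing(self, normative_cohort):
        df = normative_cohort.copy()
        rng = np.random.default_rng(12)
        df["pd15"] = 90.0 * np.exp(rng.normal(0, 0.05, len(df)))
        report = explore_covariates(df)
        assert report.r_squared_final < 0.15

    def test_constant_covariate_dropped_with_warning(self, normative_cohort):
        df = normative_cohort.copy()
        df["age"] = 50.0
        with pytest.warns(errors.DegenerateModelWarning):
            report = explore_covariates(df)
        assert "age" not in report.candidate_terms


class TestLoocv:
    def test_heldout_scores_are_calibrated(self, normative_cohort):
        res = loocv_sms(normative_cohort)
        assert abs(res.mean_sms) <= 0.15
        assert 0.85 <= res.sd_sms <= 1.20
        assert len(res.scores) == len(normative_cohort)

    def test_small_cohort_rejected(self, normative_cohort):
        with pytest.raises(errors.FitError):
            loocv_sms(normative_cohort.head(8))

    def test_duplicated_subjects_fail_as_degenerate_fold(self):
        row = {"subject_id": "dup", "gender": "male", "height": 1.75,
               "v_ct": 6.0, "pd15": 92.0}
        df = pd.DataFrame([row] * 12)
        with pytest.raises(errors.FitError, match="fold 0"):
            loocv_sms(df)
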
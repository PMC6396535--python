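"""Volume correction, the Standard Mass Score and the scoring pipeline."""

import math

import numpy as np
import pytest

from lungsms import errors
from lungsms.io import CTVolume, SubjectRecord
from lungsms.normative import DensityLaw, NormativeModel, VolumeTranslation
from lungsms.sms import (
    classify,
    classify_pattern,
    score_record,
    score_subject,
    standard_mass_score,
    volume_correct,
)
from lungsms.synthetic import generate_patient_cohort, generate_phantom, \
    phantom_for_subject


def _toy_model(alpha=2.6, beta=-1.0, sigma=0.03, log_base="10"):
    nan = float("nan")
    law = DensityLaw(alpha, beta, sigma, nan, nan, nan, 0)
    tr = {"male": VolumeTranslation(0.4, 0.95, nan, nan, 0),
          "female": VolumeTranslation(0.4, 0.95, nan, nan, 0)}
    return NormativeModel(global_law=law, translations={"global": tr},
                          slope_s=-1.1, log_base=log_base)


class TestVolumeCorrect:
    def test_identity_at_predicted_volume(self):
        assert volume_correct(80.0, 6.0, 6.0, -1.1) == pytest.approx(80.0)

    def test_hand_arithmetic(self):
        # 80 · (7/6)^(−1.1) computed independently
        expected = 80.0 * math.exp(-1.1 * math.log(7.0 / 6.0))
        got = volume_correct(80.0, 6.0, 7.0, -1.1)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(67.52, abs=0.01)

    def test_strict_sponge_model_conserves_mass(self):
        rho_cor = volume_correct(80.0, 6.0, 7.0, -1.0)
        assert rho_cor * 7.0 == pytest.approx(80.0 * 6.0)

    @pytest.mark.parametrize("args", [(-1, 6, 7, -1.1), (80, 0, 7, -1.1),
                                      (80, 6, -7, -1.1), (80, 6, 7, 0.5)])
    def test_domain_guards(self, args):
        with pytest.raises(errors.DomainError):
            volume_correct(*args)


class TestStandardMassScore:
    def test_zero_at_normative_mean(self):
        model = _toy_model()
        v = 6.0
        rho = 10 ** (2.6 - math.log10(v))
        assert standard_mass_score(rho, v, model) == pytest.approx(0.0, abs=1e-12)

    def test_minus_two_at_two_sigma_below(self):
        model = _toy_model()
        v = 6.0
        rho = 10 ** (2.6 - math.log10(v) - 2 * 0.03)
        sms = standard_mass_score(rho, v, model)
        assert sms == pytest.approx(-2.0, abs=1e-10)
        assert classify(-2.0) == "normal"       # the band is inclusive at ±2
        assert classify(2.0) == "normal"
        assert classify(-2.0 - 1e-9) == "abnormal_low"
        assert classify(2.0 + 1e-9) == "abnormal_high"

    def test_emphysema_magnitude_example(self):
        """40 g/L at 6 L predicted under (2.6, −1.0, 0.03) in log10.

        Cross-checked through the natural-log formulation of the same model:
        both routes give ≈ −7.33 standard deviations.
        """
        model10 = _toy_model()
        sms10 = standard_mass_score(40.0, 6.0, model10)
        ln10 = math.log(10.0)
        model_e = _toy_model(alpha=2.6 * ln10, beta=-1.0, sigma=0.03 * ln10,
                             log_base="e")
        sms_e = standard_mass_score(40.0, 6.0, model_e)
        assert sms10 == pytest.approx(sms_e, abs=1e-9)
        assert sms10 == pytest.approx(-7.326, abs=0.001)

    def test_sigma_zero_rejected(self):
        model = _toy_model(sigma=0.0)
        with pytest.raises(errors.DegenerateInputError):
            standard_mass_score(40.0, 6.0, model)

    @pytest.mark.parametrize("rho_pair", [(80.0, 60.0), (50.0, 49.0)])
    def test_lower_density_gives_lower_score(self, rho_pair):
        model = _toy_model()
        hi, lo = rho_pair
        s_hi = standard_mass_score(
            volume_correct(hi, 6.0, 6.5, -1.1), 6.5, model)
        s_lo = standard_mass_score(
            volume_correct(lo, 6.0, 6.5, -1.1), 6.5, model)
        assert s_lo < s_hi


class TestScoreRecord:
    def test_tabular_path_recovers_generated_truth_exactly(self, patient_cohort,
                                                           truth_model):
        df, truth = patient_cohort
        regional_cols = ("apical", "central", "basal")
        for row, t in zip(df.itertuples(), truth.itertuples()):
            res = score_record(
                row.subject_id, row.gender, row.height, row.v_ct, row.pd15,
                truth_model,
                regional={r: (getattr(row, f"v_ct_{r}"),
                              getattr(row, f"pd15_{r}")) for r in regional_cols})
            assert res.sms_global == pytest.approx(t.sms_global, abs=1e-9)
            for r in regional_cols:
                assert res.sms_regional[r] == pytest.approx(
                    getattr(t, f"sms_{r}"), abs=1e-9)

    def test_audit_trail_is_complete(self, fitted_model, normative_cohort):
        row = normative_cohort.iloc[0]
        res = score_record(row.subject_id, row.gender, row.height, row.v_ct,
                           row.pd15, fitted_model)
        d = res.to_dict()
        for key in ("rho_cal_gl", "v_ct_l", "tlc_pred_l", "v_ct_pred_l",
                    "rho_cor_gl", "sms_global", "classification"):
            assert key in d
        assert res.classification["global"] in ("normal", "abnormal_low",
                                                "abnormal_high")


class TestScoreSubjectPipeline:
    def test_normative_mean_phantom_scores_near_zero(self, normal_phantom,
                                                     truth_model):
        volume, _ = normal_phantom
        subject = SubjectRecord("ph", "male", 1.76)
        res = score_subject(volume, subject, truth_model)
        assert abs(res.sms_global) < 0.5
        for region in ("apical", "central", "basal"):
            assert abs(res.sms_regional[region]) < 0.5
        assert res.audit["path"] == "imaging"
        assert res.audit["references"]["air_n"] >= 100

    def test_inspiration_change_is_volume_corrected(self, normal_phantom,
                                                    truth_model):
        """A sponge-consistent 85% inhale shifts the SMS by < 0.2."""
        volume, _ = normal_phantom
        subject = SubjectRecord("ph", "male", 1.76)
        base = score_subject(volume, subject, truth_model)
        spec = phantom_for_subject(truth_model, "male", 1.76, seed=11,
                                   inspiration_fraction=0.85)
        shallow, _ = generate_phantom(spec)
        res = score_subject(shallow, subject, truth_model)
        assert abs(res.sms_global - base.sms_global) < 0.2

    def test_global_affine_hu_distortion_is_neutralized(self, normal_phantom,
                                                        truth_model):
        volume, _ = normal_phantom
        subject = SubjectRecord("ph", "male", 1.76)
        base = score_subject(volume, subject, truth_model)
        distorted = CTVolume(1.07 * volume.voxels.astype(np.float64) - 40.0,
                             volume.spacing)
        res = score_subject(distorted, subject, truth_model)
        assert res.sms_global == pytest.approx(base.sms_global, abs=1e-6)

    def test_basal_deficit_phantom_flags_basal_only(self, truth_model):
        spec = phantom_for_subject(
            truth_model, "male", 1.76, seed=12,
            sms_regional={"apical": 0.0, "central": 0.0, "basal": -4.0})
        volume, _ = generate_phantom(spec)
        res = score_subject(volume, SubjectRecord("ph", "male", 1.76),
                            truth_model)
        assert res.sms_regional["basal"] < -2
        assert res.sms_regional["apical"] > -2
        assert res.sms_regional["central"] > -2
        assert classify_pattern(res).name == "basal"

    def test_failures_carry_the_stage_name(self, truth_model):
        uniform = CTVolume(np.full((24, 24, 24), 40.0, np.float32), (3, 3, 3))
        with pytest.raises(errors.SegmentationError) as exc_info:
            score_subject(uniform, SubjectRecord("x", "male", 1.76),
                          truth_model)
        assert any("segmentation" in note
                   for note in getattr(exc_info.value, "__notes__", []))


class TestClassifyPattern:
    @pytest.mark.parametrize("scores,name,canonical", [
        ((-1.0, -1.0, -1.0), "none", True),
        ((-1.0, -1.0, -3.0), "basal", True),
        ((-1.0, -3.0, -3.0), "central+basal", True),
        ((-3.0, -3.0, -3.0), "apical+central+basal", True),
        ((-3.0, -1.0, -1.0), "apical", False),
        ((-3.0, -1.0, -3.0), "apical+basal", False),
    ])
    def test_patterns_and_canonical_flags(self, scores, name, canonical):
        pat = classify_pattern(scores)
        assert pat.name == name
        assert pat.canonical is canonical

    def test_boundary_is_strict(self):
        assert classify_pattern((-2.0, -2.0, -2.0)).name == "none"

    def test_missing_regional_score_rejected(self):
        with pytest.raises(errors.DegenerateInputError):
            classify_pattern({"apical": -1.0, "central": -1.0})
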
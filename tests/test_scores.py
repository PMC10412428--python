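import dataclasses
import math

import numpy as np
import pytest
from scipy.special import expit

from nashtriage.cohort import MissingFieldError
from nashtriage.scores import (
    AnalyteDomainError,
    CutoffPolicy,
    LogisticCompositeCoefficients,
    UnitSanityError,
    default_registry,
    load_default_coefficients,
    score_all,
    score_alt,
    score_elf,
    score_fib4,
    score_frame_vectorized,
    score_nfs,
    score_nis2plus,
    score_nis4,
)


def coeffs(*betas, variant="nis4"):
    b = list(betas) + [0.0] * (5 - len(betas))
    return LogisticCompositeCoefficients(*b, variant=variant, provenance="test")


class TestNis4:
    def test_zero_betas_give_half(self, complete_record):
        assert score_nis4(complete_record, coeffs(0)) == 0.5

    def test_intercept_only(self, complete_record):
        assert score_nis4(complete_record, coeffs(1)) == pytest.approx(expit(1), abs=1e-10)

    def test_log10_mir34a_unit(self, complete_record):
        rec = dataclasses.replace(complete_record, mir34a=10.0)
        assert score_nis4(rec, coeffs(0, 1)) == pytest.approx(expit(1), abs=1e-10)

    def test_variant_mismatch_rejected(self, complete_record):
        with pytest.raises(ValueError, match="variant"):
            score_nis4(complete_record, coeffs(0, variant="nis2plus"))

    def test_nonpositive_analyte_named(self, complete_record):
        rec = dataclasses.replace(complete_record, ykl40=None)
        with pytest.raises(MissingFieldError, match="ykl40"):
            score_nis4(rec, coeffs(0))

    def test_monotone_in_positive_coefficient_covariate(self, complete_record):
        c = coeffs(0, 2.0, 0.5, 1.0, 0.3)
        lo = score_nis4(complete_record, c)
        hi = score_nis4(dataclasses.replace(complete_record, mir34a=3.0), c)
        assert 0 < lo < hi < 1


class TestNis2Plus:
    def test_zero_betas_sex_invariant(self, complete_record):
        male = dataclasses.replace(complete_record, sex="male")
        c = coeffs(0, variant="nis2plus")
        assert score_nis2plus(complete_record, c) == score_nis2plus(male, c) == 0.5

    def test_female_sex_terms_inert(self, complete_record):
        # sex coded 0 for females: beta3/beta4 cannot move the score
        c1 = coeffs(0.4, 1.2, 0.8, 0.0, 0.0, variant="nis2plus")
        c2 = coeffs(0.4, 1.2, 0.8, 9.9, -7.7, variant="nis2plus")
        assert score_nis2plus(complete_record, c1) == pytest.approx(
            score_nis2plus(complete_record, c2), abs=1e-12
        )

    def test_interaction_cancels_main_effect(self, complete_record):
        rec = dataclasses.replace(complete_record, sex="male", mir34a=10.0)
        c = coeffs(0, 1, 0, 0, -1, variant="nis2plus")
        assert score_nis2plus(rec, c) == pytest.approx(0.5, abs=1e-12)

    def test_invariant_to_removed_covariates(self, complete_record):
        c = load_default_coefficients()["nis2plus"]
        other = dataclasses.replace(complete_record, a2m=9.0, hba1c=12.0)
        assert score_nis2plus(complete_record, c) == score_nis2plus(other, c)


class TestFib4:
    def test_hand_computed(self, complete_record):
        rec = dataclasses.replace(complete_record, age=60, ast=40.0,
                                  platelets=200.0, alt=40.0)
        expected = 2400 / (200 * math.sqrt(40))
        assert score_fib4(rec) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.8974, abs=5e-5)

    def test_alt_one_simplifies(self, complete_record):
        rec = dataclasses.replace(complete_record, alt=1.0)
        assert score_fib4(rec) == pytest.approx(
            rec.age * rec.ast / rec.platelets, abs=1e-12
        )

    def test_homogeneity(self, complete_record):
        base = score_fib4(complete_record)
        double_ast = dataclasses.replace(complete_record, ast=2 * complete_record.ast)
        double_plt = dataclasses.replace(
            complete_record, platelets=2 * complete_record.platelets
        )
        assert score_fib4(double_ast) == pytest.approx(2 * base, rel=1e-12)
        assert score_fib4(double_plt) == pytest.approx(base / 2, rel=1e-12)

    def test_domain_error(self, complete_record):
        rec = dataclasses.replace(complete_record, platelets=None)
        with pytest.raises(MissingFieldError, match="platelets"):
            score_fib4(rec)


class TestNfs:
    def test_hand_computed(self, complete_record):
        rec = dataclasses.replace(
            complete_record, age=50, bmi=30.0, diabetes=True, ast=40.0,
            alt=40.0, platelets=250.0, albumin=4.0,
        )
        # -1.675 + 1.85 + 2.82 + 1.13 + 0.99 - 3.25 - 2.64
        assert score_nfs(rec) == pytest.approx(-0.775, abs=1e-12)

    def test_platelet_linearity(self, complete_record):
        base = score_nfs(complete_record)
        more = dataclasses.replace(
            complete_record, platelets=complete_record.platelets + 100
        )
        assert score_nfs(more) == pytest.approx(base - 1.3, abs=1e-10)

    def test_ifg_via_fasting_glucose(self, complete_record):
        rec = dataclasses.replace(complete_record, diabetes=False, fpg=6.0)
        low = dataclasses.replace(complete_record, diabetes=False, fpg=5.0)
        assert score_nfs(rec) - score_nfs(low) == pytest.approx(1.13, abs=1e-10)

    def test_albumin_unit_sanity(self, complete_record):
        rec = dataclasses.replace(complete_record, albumin=None)
        rec = dataclasses.replace(rec, albumin=40.0)  # looks like g/L
        with pytest.raises(UnitSanityError):
            score_nfs(rec)
        assert np.isfinite(score_nfs(rec, allow_g_per_L_albumin=True))


class TestElf:
    def test_unit_analytes_give_intercept(self, complete_record):
        rec = dataclasses.replace(complete_record, ha=1.0, piiinp=1.0, timp1=1.0)
        assert score_elf(rec) == pytest.approx(2.494, abs=1e-12)

    def test_single_e_fold(self, complete_record):
        rec = dataclasses.replace(
            complete_record, ha=math.e, piiinp=1.0, timp1=1.0
        )
        assert score_elf(rec) == pytest.approx(2.494 + 0.846, abs=1e-12)

    def test_log_additivity(self, complete_record):
        base = score_elf(complete_record)
        scaled = dataclasses.replace(
            complete_record,
            ha=complete_record.ha * math.e,
            piiinp=complete_record.piiinp * math.e,
            timp1=complete_record.timp1 * math.e,
        )
        assert score_elf(scaled) - base == pytest.approx(1.972, abs=1e-10)

    def test_domain_error(self, complete_record):
        rec = dataclasses.replace(complete_record, ha=None)
        with pytest.raises(MissingFieldError, match="ha"):
            score_elf(rec)


class TestAltUln:
    @pytest.mark.parametrize(
        "sex,alt,positive",
        [
            ("female", 33.0, True),
            ("female", 32.9, False),
            ("male", 40.0, False),
            ("male", 41.0, True),
        ],
    )
    def test_sex_specific_boundaries(self, complete_record, sex, alt, positive):
        rec = dataclasses.replace(complete_record, sex=sex, alt=alt)
        value, uln = score_alt(rec)
        assert (value >= uln) is positive


class TestCutoffPolicy:
    def test_exactly_one_mode(self):
        with pytest.raises(ValueError):
            CutoffPolicy()
        with pytest.raises(ValueError):
            CutoffPolicy(low=0.4, high=0.6, single=0.5)
        with pytest.raises(ValueError):
            CutoffPolicy(low=0.7, high=0.6)
        assert CutoffPolicy(low=0.4, high=0.6).is_dual
        assert not CutoffPolicy(single=1.0).is_dual


class TestScoreAll:
    def test_complete_cohort_fully_scored(self, default_cohort):
        sub = default_cohort.head(10)
        scores, reasons = score_all(sub, default_registry())
        assert scores.shape == (10, 6)
        assert not scores.isna().any().any()
        assert reasons == {}

    def test_missing_input_propagates_reason(self, default_cohort):
        sub = default_cohort.head(3).copy()
        sub.loc[sub.index[1], "timp1"] = np.nan
        registry = {"elf": default_registry()["elf"]}
        scores, reasons = score_all(sub, registry)
        pid = sub.iloc[1]["patient_id"]
        assert np.isnan(scores["elf"].iloc[1])
        assert reasons[(pid, "elf")] == "missing:timp1"

    def test_vectorized_scorer_matches_per_record_path(self, default_cohort):
        sub = default_cohort.head(40)
        slow, _ = score_all(sub, default_registry())
        fast = score_frame_vectorized(sub)
        for col in slow.columns:
            np.testing.assert_allclose(slow[col], fast[col], rtol=1e-12)


def test_frozen_coefficients_have_provenance():
    sets = load_default_coefficients()
    assert set(sets) == {"nis4", "nis2plus"}
    for c in sets.values():
        assert "synthetic-calibration" in c.provenance
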
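"""Classification rules: guideline cut-offs, boundaries, missingness ternary logic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

from multimorb import (
    ConditionClassifier,
    ConditionThresholds,
    build_panel,
    classify_anaemia,
    classify_anthropometry,
    classify_ckd,
    classify_diabetes,
    classify_hypertension,
    classify_screen,
    classify_self_report_only,
    egfr_ckd_epi_2021,
)
from multimorb.conditions import InvalidMeasurementError, creatinine_from_egfr

NAN = float("nan")


def same_state(got, want):
    return (math.isnan(got) and math.isnan(want)) or got == want


@pytest.mark.parametrize(
    "sbp,dbp,sr,want",
    [
        (150, 85, False, 1.0),  # above SBP cut
        (139.9, 89.9, False, 0.0),  # boundary exclusive below
        (140.0, 60, False, 1.0),  # SBP cut inclusive
        (120, 90.0, False, 1.0),  # DBP cut inclusive
        (NAN, NAN, True, 1.0),  # self-reported treatment history counts
        (NAN, NAN, False, NAN),  # no information
        (120, NAN, False, 0.0),  # measured below available cut
    ],
)
def test_hypertension_rule(sbp, dbp, sr, want):
    assert same_state(classify_hypertension(sbp, dbp, sr), want)


@pytest.mark.parametrize(
    "fbs,sr,want",
    [(126, False, 1.0), (125.9, False, 0.0), (NAN, False, NAN), (NAN, True, 1.0)],
)
def test_diabetes_rule(fbs, sr, want):
    assert same_state(classify_diabetes(fbs, sr), want)


@pytest.mark.parametrize(
    "hb,sex,want",
    [
        (12.9, "male", 1.0),
        (13.0, "male", 0.0),
        (12.0, "female", 0.0),  # "below" is strict
        (11.9, "female", 1.0),
        (NAN, "female", NAN),
    ],
)
def test_anaemia_rule(hb, sex, want):
    assert same_state(classify_anaemia(hb, sex), want)


class TestCKD:
    def test_egfr_matches_hand_computation(self):
        # worked triple: Scr 1.0 mg/dL, age 50, male
        want = 142.0 * (1.0 / 0.9) ** -1.200 * 0.9938**50
        assert egfr_ckd_epi_2021(1.0, 50, "male") == pytest.approx(want, rel=1e-12)
        # female branch with Scr below kappa uses the alpha exponent
        want_f = 142.0 * (0.6 / 0.7) ** -0.241 * 0.9938**40 * 1.012
        assert egfr_ckd_epi_2021(0.6, 40, "female") == pytest.approx(want_f, rel=1e-12)

    def test_inverse_round_trips(self):
        for egfr in (25.0, 59.0, 61.0, 95.0):
            scr = creatinine_from_egfr(egfr, 55, "female")
            assert egfr_ckd_epi_2021(scr, 55, "female") == pytest.approx(egfr, rel=1e-10)

    def test_low_egfr_is_present(self):
        scr = creatinine_from_egfr(45.0, 60, "male")
        assert classify_ckd(scr, 60, "male", 5.0) == 1.0

    def test_albuminuria_branch(self):
        scr = creatinine_from_egfr(90.0, 50, "male")
        assert classify_ckd(scr, 50, "male", 10.0) == 0.0
        assert classify_ckd(scr, 50, "male", 35.0) == 1.0
        assert classify_ckd(scr, 50, "male", 30.0) == 1.0  # cut inclusive

    def test_missing_needs_both_axes(self):
        assert math.isnan(classify_ckd(NAN, 50, "male", NAN))
        assert classify_ckd(NAN, 50, "male", 40.0) == 1.0

    def test_invalid_creatinine(self):
        with pytest.raises(InvalidMeasurementError):
            classify_ckd(-0.5, 50, "male", 10.0)


@pytest.mark.parametrize(
    "score,cut,rng,want",
    [
        (10, 10, (0, 27), 1.0),  # PHQ-9 "10 or higher"
        (9, 10, (0, 27), 0.0),
        (10, 10, (0, 21), 1.0),  # GAD-7 cut
        (NAN, 10, (0, 27), NAN),
    ],
)
def test_screen_rule(score, cut, rng, want):
    assert same_state(classify_screen(score, cut, False, rng), want)


def test_screen_range_validated():
    with pytest.raises(InvalidMeasurementError):
        classify_screen(28, 10, False, (0, 27))


def test_resp_disease_self_report_or_screen():
    assert classify_screen(2, 5, True, (0, 10)) == 1.0
    assert classify_screen(5, 5, False, (0, 10)) == 1.0
    assert classify_screen(4, 5, False, (0, 10)) == 0.0


@pytest.mark.parametrize(
    "label,reported,want",
    [
        ("arthritis", {"arthritis"}, 1.0),
        ("cancer", set(), 0.0),
        ("epilepsy", {"epilepsy", "cancer"}, 1.0),
        ("cancer", None, NAN),  # whole self-report block absent
    ],
)
def test_self_report_only(label, reported, want):
    assert same_state(classify_self_report_only(label, reported), want)


@pytest.mark.parametrize(
    "bmi,waist,sex,want",
    [
        (22.9, 80.0, "female", ("normal", False)),  # both boundaries, ">" strict
        (23.0, 80.1, "female", ("overweight_obese", True)),  # ">=23" inclusive
        (18.4, 91, "male", ("underweight", True)),
        (18.5, 90.0, "male", ("normal", False)),
    ],
)
def test_anthropometry(bmi, waist, sex, want):
    assert classify_anthropometry(bmi, waist, sex) == want


class TestBuildPanel:
    def _record(self, **kw):
        base = dict(
            id="x", age=45.0, sex="male", sbp=120.0, dbp=75.0, fbs=100.0, hb=14.0,
            serum_creatinine=0.9, uacr=10.0, phq9=2.0, gad7=1.0, copd_ps=1.0,
            sr_hypertension=0.0, sr_diabetes=0.0, sr_resp_disease=0.0,
            sr_heart_disease=0.0, sr_arthritis=0.0, sr_epilepsy=0.0,
            sr_cancer=0.0, sr_sickle_cell=0.0, sr_mental_disorder=0.0,
        )
        base.update(kw)
        return base

    def test_single_condition_not_multimorbid(self):
        p = build_panel(self._record(sbp=150.0))
        assert p.condition_count == 1 and not p.multimorbid

    def test_two_conditions_multimorbid(self):
        p = build_panel(self._record(sbp=150.0, fbs=130.0))
        assert p.condition_count == 2 and p.multimorbid

    def test_missing_states_count_as_absent(self):
        p = build_panel(self._record(sbp=150.0, fbs=130.0, phq9=15.0, hb=NAN,
                                     sr_cancer=NAN))
        assert p.condition_count == 3 and p.multimorbid
        assert math.isnan(p.states["anaemia"]) and math.isnan(p.states["cancer"])

    def test_strict_variant_rejects_missing(self):
        with pytest.raises(ValueError):
            build_panel(self._record(hb=NAN), count_missing_as_absent=False)

    def test_idempotent_reclassification(self):
        rec = self._record(sbp=145.0, uacr=50.0, phq9=11.0)
        assert build_panel(rec) == build_panel(rec)


@given(
    sbp=hst.floats(90, 200),
    dbp=hst.floats(55, 120),
    bump=hst.floats(0, 60),
)
def test_hypertension_monotone_in_bp(sbp, dbp, bump):
    """Raising a measured risk value never flips present -> absent."""
    before = classify_hypertension(sbp, dbp, False)
    after = classify_hypertension(sbp + bump, dbp, False)
    assert not (before == 1.0 and after == 0.0)
    assert after >= before


@given(fbs=hst.floats(60, 300), bump=hst.floats(0, 100))
def test_diabetes_monotone_in_fbs(fbs, bump):
    assert classify_diabetes(fbs + bump, False) >= classify_diabetes(fbs, False)


def test_vectorized_matches_per_record(default_cohort, default_panel):
    sub = default_cohort.head(40)
    for i, row in sub.iterrows():
        panel = build_panel(row.to_dict())
        for cond, state in panel.states.items():
            assert same_state(state, default_panel.loc[i, cond])
        assert panel.condition_count == default_panel.loc[i, "condition_count"]


def test_exact_recovery_of_planted_status(default_cohort, default_panel):
    """Classified status equals planted latent status wherever observed."""
    for cond in [c for c in default_panel.columns if f"true_{c}" in default_cohort]:
        got = default_panel[cond]
        truth = default_cohort[f"true_{cond}"]
        obs = got.notna()
        assert (got[obs] == truth[obs]).all()


def test_thresholds_validated():
    with pytest.raises(ValueError):
        ConditionThresholds(hb_male=11.0)  # must exceed hb_female
    with pytest.raises(ValueError):
        ConditionThresholds(dm_fbs=-1)
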
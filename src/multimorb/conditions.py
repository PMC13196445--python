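"""Rule-based chronic-condition classification.

Thirteen chronic conditions are operationalized from raw survey
measurements and self-reported prior diagnoses:

* hypertension — JNC-7 cut-offs on the mean of repeated BP readings
  (SBP >= 140 or DBP >= 90 mmHg) or self-reported treatment history;
* diabetes — fasting blood sugar >= 126 mg/dL or self-reported treatment;
* anaemia — WHO haemoglobin criteria (< 13.0 g/dL men, < 12.0 g/dL women);
* chronic kidney disease — KDIGO single-visit call: eGFR < 60 mL/min/1.73m²
  (2021 race-free creatinine equation) or uACR >= 30 mg/g;
* depression / anxiety — PHQ-9 >= 10 / GAD-7 >= 10;
* chronic respiratory disease — self-reported asthma/COPD or COPD-PS >= 5;
* heart disease, arthritis, epilepsy, cancer, sickle-cell anaemia, other
  mental disorder — self-report of a provider diagnosis only.

Condition states are ternary and encoded as floats: ``1.0`` present,
``0.0`` absent, ``nan`` missing.  Multimorbidity is two or more conditions
present; by default missing states contribute nothing to the count
(pairwise-available convention), with a strict complete-case variant
behind a flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: Condition labels in canonical order.
CONDITIONS = (
    "hypertension",
    "diabetes",
    "anaemia",
    "ckd",
    "heart_disease",
    "resp_disease",
    "arthritis",
    "epilepsy",
    "cancer",
    "sickle_cell",
    "depression",
    "anxiety",
    "mental_disorder",
)

#: Conditions classified purely from self-reported provider diagnoses.
SELF_REPORT_ONLY = (
    "heart_disease",
    "arthritis",
    "epilepsy",
    "cancer",
    "sickle_cell",
    "mental_disorder",
)

PRESENT = 1.0
ABSENT = 0.0
MISSING = float("nan")


class InvalidMeasurementError(ValueError):
    """A raw measurement is outside its physically/instrumentally valid range."""


@dataclass(frozen=True)
class ConditionThresholds:
    """Diagnostic cut-offs used by the classification rules.

    Defaults follow the cited guidelines: JNC-7 (140/90 mmHg), ADA fasting
    glucose (126 mg/dL), PHQ-9/GAD-7 screening cut (10), WHO anaemia
    (13.0/12.0 g/dL), KDIGO (eGFR 60, uACR 30), South Asian waist cut-offs
    (90/80 cm), Asian BMI categories (18.5, 23), COPD-PS screening cut (5),
    and the two-condition multimorbidity definition.
    """

    htn_sbp: float = 140.0
    htn_dbp: float = 90.0
    dm_fbs: float = 126.0
    phq9_cut: int = 10
    gad7_cut: int = 10
    hb_male: float = 13.0
    hb_female: float = 12.0
    egfr_cut: float = 60.0
    uacr_cut: float = 30.0
    waist_male: float = 90.0
    waist_female: float = 80.0
    bmi_under: float = 18.5
    bmi_over: float = 23.0
    copd_ps_cut: int = 5
    mm_cut: int = 2

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be > 0")
        if self.hb_male <= self.hb_female:
            raise ValueError("hb_male threshold must exceed hb_female")


@dataclass
class ConditionPanel:
    """Ternary condition states for one participant plus the multimorbidity call."""

    states: dict[str, float]
    condition_count: int
    multimorbid: bool

    def __post_init__(self) -> None:
        n_present = sum(1 for v in self.states.values() if v == PRESENT)
        if n_present != self.condition_count:
            raise ValueError("condition_count inconsistent with states")


def _asfloat(x) -> np.ndarray:
    out = np.asarray(x, dtype=float)
    return out


def _asbool(x) -> np.ndarray:
    # self-report flags: nan (missing report) -> False at the rule level
    arr = np.asarray(x, dtype=float)
    return np.nan_to_num(arr, nan=0.0) > 0


def _state(present: np.ndarray, missing: np.ndarray, scalar: bool):
    out = np.where(missing, np.nan, np.asarray(present, dtype=float))
    return float(np.ravel(out)[0]) if scalar else out


def classify_hypertension(sbp, dbp, self_report=False, thresholds: ConditionThresholds | None = None):
    """JNC-7 call on mean BP readings, rescued by self-reported treatment.

    Present if SBP >= 140 or DBP >= 90 or a self-reported history of
    treatment; missing only when both measurements are unavailable and
    there is no self-report.
    """
    t = thresholds or ConditionThresholds()
    scalar = np.isscalar(sbp) or sbp is None
    sbp, dbp = _asfloat(_none_to_nan(sbp)), _asfloat(_none_to_nan(dbp))
    sr = _asbool(_none_to_nan(self_report))
    present = (sbp >= t.htn_sbp) | (dbp >= t.htn_dbp) | sr
    missing = np.isnan(sbp) & np.isnan(dbp) & ~sr
    return _state(present, missing, scalar)


def classify_diabetes(fbs, self_report=False, thresholds: ConditionThresholds | None = None):
    """Fasting blood sugar >= 126 mg/dL (inclusive) or self-reported treatment."""
    t = thresholds or ConditionThresholds()
    scalar = np.isscalar(fbs) or fbs is None
    fbs = _asfloat(_none_to_nan(fbs))
    sr = _asbool(_none_to_nan(self_report))
    present = (fbs >= t.dm_fbs) | sr
    missing = np.isnan(fbs) & ~sr
    return _state(present, missing, scalar)


def classify_anaemia(hb, sex, thresholds: ConditionThresholds | None = None):
    """WHO criteria: haemoglobin strictly below 13.0 (men) / 12.0 (women) g/dL."""
    t = thresholds or ConditionThresholds()
    scalar = np.isscalar(hb) or hb is None
    hb = _asfloat(_none_to_nan(hb))
    cut = np.where(np.asarray(sex, dtype=object) == "female", t.hb_female, t.hb_male)
    present = hb < cut
    missing = np.isnan(hb)
    return _state(present, missing, scalar)


def egfr_ckd_epi_2021(serum_creatinine, age, sex):
    """Estimated GFR by the 2021 race-free CKD-EPI creatinine equation.

    eGFR = 142 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.200 * 0.9938^age
    * 1.012 (if female), with k = 0.7/0.9 and a = -0.241/-0.302 for
    females/males.  Units: mL/min/1.73 m².
    """
    scalar = np.isscalar(serum_creatinine) or serum_creatinine is None
    scr = _asfloat(_none_to_nan(serum_creatinine))
    if np.any(scr <= 0):
        raise InvalidMeasurementError("serum creatinine must be positive")
    age = _asfloat(age)
    female = np.asarray(sex, dtype=object) == "female"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    ratio = scr / kappa
    egfr = (
        142.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.200
        * 0.9938**age
        * np.where(female, 1.012, 1.0)
    )
    return float(egfr) if scalar else egfr


def creatinine_from_egfr(egfr, age, sex):
    """Invert the 2021 CKD-EPI equation (monotone in creatinine).

    Used by the synthetic generator to plant a target eGFR; the equation is
    piecewise log-linear in Scr so the inverse is closed-form.
    """
    scalar = np.isscalar(egfr)
    egfr = _asfloat(egfr)
    age = _asfloat(age)
    female = np.asarray(sex, dtype=object) == "female"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    base = 142.0 * 0.9938**age * np.where(female, 1.012, 1.0)
    # ratio = Scr/kappa; egfr = base * ratio^alpha for ratio<=1, base * ratio^-1.2 for ratio>=1
    r = egfr / base
    ratio = np.where(r >= 1.0, r ** (1.0 / alpha), r ** (-1.0 / 1.2))
    out = ratio * kappa
    return float(out) if scalar else out


def classify_ckd(serum_creatinine, age, sex, uacr, thresholds: ConditionThresholds | None = None):
    """KDIGO single-visit call: eGFR < 60 or uACR >= 30 mg/g.

    Missing only when neither an eGFR (creatinine) nor a uACR is available.
    The chronicity criterion (>= 3 months) cannot be established from a
    single survey visit and is not applied.
    """
    t = thresholds or ConditionThresholds()
    scalar = np.isscalar(serum_creatinine) or serum_creatinine is None
    scr, age_a, sex_a, uacr_a = np.broadcast_arrays(
        np.atleast_1d(_asfloat(_none_to_nan(serum_creatinine))),
        np.atleast_1d(_asfloat(age)),
        np.atleast_1d(np.asarray(sex, dtype=object)),
        np.atleast_1d(_asfloat(_none_to_nan(uacr))),
    )
    valid = ~np.isnan(scr)
    egfr = np.full(scr.shape, np.nan)
    if valid.any():
        egfr[valid] = egfr_ckd_epi_2021(scr[valid], age_a[valid], sex_a[valid])
    present = (egfr < t.egfr_cut) | (uacr_a >= t.uacr_cut)
    missing = np.isnan(egfr) & np.isnan(uacr_a)
    return _state(present, missing, scalar)


def classify_screen(score, cut, self_report=False, score_range=(0, 27)):
    """Screening-scale call: present iff score >= cut (or self-report).

    Covers PHQ-9 depression (cut 10), GAD-7 anxiety (cut 10) and the
    COPD-PS branch of chronic respiratory disease (cut 5, combined with
    self-reported asthma/COPD).
    """
    scalar = np.isscalar(score) or score is None
    s = _asfloat(_none_to_nan(score))
    lo, hi = score_range
    bad = ~np.isnan(s) & ((s < lo) | (s > hi))
    if np.any(bad):
        raise InvalidMeasurementError(
            f"score outside instrument range [{lo}, {hi}]"
        )
    sr = _asbool(_none_to_nan(self_report))
    present = (s >= cut) | sr
    missing = np.isnan(s) & ~sr
    return _state(present, missing, scalar)


def classify_self_report_only(label: str, self_reported: Iterable[str] | None):
    """Self-report-only conditions: present iff the label was reported.

    ``self_reported=None`` means the whole self-report block is absent for
    the participant, yielding a missing state.
    """
    if self_reported is None:
        return MISSING
    return PRESENT if label in set(self_reported) else ABSENT


def classify_anthropometry(bmi, waist, sex, thresholds: ConditionThresholds | None = None):
    """Asian BMI category and South Asian abdominal-obesity call.

    BMI: underweight < 18.5, normal 18.5–22.9, overweight/obese >= 23
    (inclusive).  Abdominal obesity: waist strictly above 90 cm (men) /
    80 cm (women).
    """
    t = thresholds or ConditionThresholds()
    if bmi is None or (np.isscalar(bmi) and np.isnan(bmi)):
        category = None
    elif bmi < t.bmi_under:
        category = "underweight"
    elif bmi < t.bmi_over:
        category = "normal"
    else:
        category = "overweight_obese"
    cut = t.waist_female if sex == "female" else t.waist_male
    if waist is None or (np.isscalar(waist) and np.isnan(waist)):
        abdominal = None
    else:
        abdominal = bool(waist > cut)
    return category, abdominal


def _none_to_nan(x):
    if x is None:
        return np.nan
    if isinstance(x, (list, tuple)):
        return [np.nan if v is None else v for v in x]
    return x


def _get(record: Mapping, key: str):
    v = record.get(key, np.nan)
    if v is None:
        return np.nan
    return v


def _classify_record(record: Mapping, t: ConditionThresholds) -> dict[str, float]:
    """All 13 ternary states for one participant record (mapping access)."""
    sr_set = record.get("self_reported", None)

    def sr(label: str):
        # prefer an explicit sr_<label> column; fall back to the set form
        col = f"sr_{label}"
        if col in record:
            return _get(record, col)
        if sr_set is None:
            return np.nan
        return float(label in sr_set)

    states: dict[str, float] = {}
    states["hypertension"] = classify_hypertension(
        _get(record, "sbp"), _get(record, "dbp"), sr("hypertension"), t
    )
    states["diabetes"] = classify_diabetes(_get(record, "fbs"), sr("diabetes"), t)
    states["anaemia"] = classify_anaemia(_get(record, "hb"), record.get("sex"), t)
    states["ckd"] = classify_ckd(
        _get(record, "serum_creatinine"), record.get("age"), record.get("sex"), _get(record, "uacr"), t
    )
    states["depression"] = classify_screen(_get(record, "phq9"), t.phq9_cut, False, (0, 27))
    states["anxiety"] = classify_screen(_get(record, "gad7"), t.gad7_cut, False, (0, 21))
    states["resp_disease"] = classify_screen(
        _get(record, "copd_ps"), t.copd_ps_cut, sr("resp_disease"), (0, 10)
    )
    for label in SELF_REPORT_ONLY:
        v = sr(label)
        states[label] = float(v > 0) if not np.isnan(v) else np.nan
    return {c: states[c] for c in CONDITIONS}


def build_panel(
    record: Mapping,
    thresholds: ConditionThresholds | None = None,
    count_missing_as_absent: bool = True,
) -> ConditionPanel:
    """Classify one participant into a :class:`ConditionPanel`.

    ``count_missing_as_absent=True`` (default) keeps participants with
    partially missing condition information in the multimorbidity count —
    missing states contribute zero.  The strict variant requires a fully
    observed panel and raises otherwise.
    """
    t = thresholds or ConditionThresholds()
    states = _classify_record(record, t)
    n_missing = sum(1 for v in states.values() if np.isnan(v))
    if n_missing and not count_missing_as_absent:
        raise ValueError(
            f"{n_missing} condition state(s) missing under strict complete-case counting"
        )
    count = int(sum(1 for v in states.values() if v == PRESENT))
    return ConditionPanel(states=states, condition_count=count, multimorbid=count >= t.mm_cut)


class ConditionClassifier(BaseEstimator, TransformerMixin):
    """Transform a cohort table into a ternary condition-panel table.

    A stateless scikit-learn transformer: ``transform`` maps a participant
    DataFrame (one row each, raw measurements + ``sr_*`` self-report
    columns) to a DataFrame with one 1/0/NaN column per condition plus
    ``condition_count`` and ``multimorbid``.

    Parameters
    ----------
    thresholds :
        Diagnostic cut-offs; defaults to the guideline values.
    count_missing_as_absent :
        If False (strict complete-case), ``condition_count`` and
        ``multimorbid`` are set to NaN for participants with any missing
        condition state instead of treating missing as absent.
    """

    def __init__(
        self,
        thresholds: ConditionThresholds | None = None,
        count_missing_as_absent: bool = True,
    ):
        self.thresholds = thresholds
        self.count_missing_as_absent = count_missing_as_absent

    def fit(self, X: pd.DataFrame, y=None):
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        t = self.thresholds or ConditionThresholds()
        n = len(X)
        sex = X["sex"].to_numpy(dtype=object)
        col = lambda name: (
            X[name].to_numpy(dtype=float) if name in X else np.full(n, np.nan)
        )
        out = pd.DataFrame(index=X.index)
        out["hypertension"] = classify_hypertension(col("sbp"), col("dbp"), col("sr_hypertension"), t)
        out["diabetes"] = classify_diabetes(col("fbs"), col("sr_diabetes"), t)
        out["anaemia"] = classify_anaemia(col("hb"), sex, t)
        out["ckd"] = classify_ckd(col("serum_creatinine"), col("age"), sex, col("uacr"), t)
        out["depression"] = classify_screen(col("phq9"), t.phq9_cut, False, (0, 27))
        out["anxiety"] = classify_screen(col("gad7"), t.gad7_cut, False, (0, 21))
        out["resp_disease"] = classify_screen(col("copd_ps"), t.copd_ps_cut, col("sr_resp_disease"), (0, 10))
        for label in SELF_REPORT_ONLY:
            out[label] = col(f"sr_{label}")
        out = out[list(CONDITIONS)]
        states = out.to_numpy(dtype=float)
        count = np.nansum(states == PRESENT, axis=1).astype(float)
        multimorbid = (count >= t.mm_cut).astype(float)
        if not self.count_missing_as_absent:
            any_missing = np.isnan(states).any(axis=1)
            count[any_missing] = np.nan
            multimorbid[any_missing] = np.nan
        out["condition_count"] = count
        out["multimorbid"] = multimorbid
        if "id" in X:
            out.insert(0, "id", X["id"].to_numpy())
        return out


def classify_cohort(
    cohort: pd.DataFrame,
    thresholds: ConditionThresholds | None = None,
    count_missing_as_absent: bool = True,
) -> pd.DataFrame:
    """Functional wrapper over :class:`ConditionClassifier`."""
    clf = ConditionClassifier(thresholds, count_missing_as_absent)
    return clf.fit(cohort).transform(cohort)
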
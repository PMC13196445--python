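"""Synthetic cross-sectional cohort generator with planted co-occurrence.

Emulates a community survey of adults aged >= 30 years in which thirteen
chronic conditions are ascertained by measurement and self-report.  The
generator plants a known statistical structure so that every downstream
stage (classification, prevalence, regression, network clustering) can be
validated against ground truth:

* marginal condition prevalences calibrated to configurable targets;
* an age gradient per condition (log-odds per decade of age);
* a two-block latent-factor co-occurrence structure — each participant
  carries two independent standard-normal factors, one loading the
  cardio-metabolic conditions (hypertension, diabetes, anaemia, heart
  disease, CKD) and one loading the respiratory/arthritis/psychological
  conditions; the remaining rare conditions load neither;
* completely-at-random missingness per measurement block.

Raw measurements (BP, fasting glucose, haemoglobin, creatinine/uACR,
screening scores, self-report flags) are drawn from truncated normals
conditional on the planted latent condition status, so that applying the
rule-based classifiers recovers the planted status exactly wherever the
relevant measurements are observed.

Condition intercepts are calibrated by deterministic bisection so that the
*expected* classified prevalence over the cohort's age/factor mixture
equals the target; realised prevalences fluctuate with binomial noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .conditions import CONDITIONS, SELF_REPORT_ONLY, creatinine_from_egfr

__all__ = [
    "CohortSpec",
    "ParticipantRecord",
    "CalibrationError",
    "generate_cohort",
    "generate_cohort_frame",
    "write_cohort",
    "read_cohort",
]


class CalibrationError(RuntimeError):
    """Raised when no intercept can reach the target prevalence for a condition."""


# Study-condition defaults: overall condition prevalences of the surveyed
# cohort (N = 2333 adults >= 30 y).
DEFAULT_TARGET_PREVALENCE: dict[str, float] = {
    "hypertension": 0.508,
    "diabetes": 0.322,
    "anaemia": 0.429,
    "ckd": 0.226,
    "heart_disease": 0.070,
    "resp_disease": 0.106,
    "arthritis": 0.114,
    "epilepsy": 0.018,
    "cancer": 0.012,
    "sickle_cell": 0.009,
    "depression": 0.095,
    "anxiety": 0.045,
    "mental_disorder": 0.017,
}

#: Two-block latent structure: a cardio-metabolic cluster and a
#: respiratory/arthritis/psychological cluster; rare conditions independent.
DEFAULT_BLOCK_ASSIGNMENT: dict[str, str] = {
    "hypertension": "cardiometabolic",
    "diabetes": "cardiometabolic",
    "anaemia": "cardiometabolic",
    "heart_disease": "cardiometabolic",
    "ckd": "cardiometabolic",
    "resp_disease": "other",
    "arthritis": "other",
    "depression": "other",
    "anxiety": "other",
    "epilepsy": "independent",
    "cancer": "independent",
    "sickle_cell": "independent",
    "mental_disorder": "independent",
}

#: Log-odds per latent-factor SD.  1.2 plants a strong but realistic
#: within-block association (pairwise ORs of roughly 2-3).
DEFAULT_FACTOR_LOADING: dict[str, float] = {
    c: (0.0 if DEFAULT_BLOCK_ASSIGNMENT[c] == "independent" else 1.2) for c in CONDITIONS
}

#: Log-odds per decade of age, back-derived from the <=50 vs >50 prevalence
#: contrast of the surveyed cohort.
DEFAULT_AGE_SLOPE: dict[str, float] = {
    "hypertension": 0.74,
    "diabetes": 0.43,
    "anaemia": 0.05,
    "ckd": 0.53,
    "heart_disease": 0.76,
    "resp_disease": 0.66,
    "arthritis": 0.65,
    "epilepsy": 0.0,
    "cancer": 0.0,
    "sickle_cell": -0.5,
    "depression": 0.43,
    "anxiety": 0.20,
    "mental_disorder": 0.0,
}

#: MCAR missingness per measurement block.  ``renal`` covers serum
#: creatinine and uACR jointly (one blood/urine collection event), matching
#: the per-condition missing counts of the emulated survey.
DEFAULT_MISSING_FRACTION: dict[str, float] = {
    "bp": 0.0,
    "fbs": 0.075,
    "hb": 0.098,
    "renal": 0.130,
    "phq9": 0.0,
    "gad7": 0.0,
    "copd_ps": 0.0,
    "sr_heart_disease": 0.008,
    "sr_cancer": 0.020,
    "sr_sickle_cell": 0.075,
    "sr_arthritis": 0.02,
    "sr_epilepsy": 0.01,
    "sr_mental_disorder": 0.01,
}

# Table-1 style demographic margins by age group (<=50 / >50).
_EDU_PROBS = {
    "le50": (0.160, 0.504, 0.336),  # none, upto_secondary, secondary_plus
    "gt50": (0.484, 0.330, 0.186),
}
_TOBACCO = {"le50": 0.450, "gt50": 0.586}
_ALCOHOL = {"le50": 0.244, "gt50": 0.235}
_BMI_PROBS = {
    "le50": (0.134, 0.418, 0.448),  # under, normal, over (normalized margins)
    "gt50": (0.184, 0.407, 0.409),
}
_WAIST_HIGH = {"le50": 0.230, "gt50": 0.263}

#: Probability that a true hypertension/diabetes case also carries a
#: self-reported treatment history (rescues classification when the
#: measurement is missing).
SELF_REPORT_RESCUE = 0.30


@dataclass
class CohortSpec:
    """Parameters of the simulated survey cohort.

    Defaults reproduce the emulated study's conditions: 2,333 adults
    >= 30 years, age ~ N(50.0, 13.2²) truncated at 30, 58.1% women, the
    surveyed marginal prevalences, a two-block latent co-occurrence
    structure, and the survey's per-measurement missingness.
    """

    n_participants: int = 2333
    seed: int = 20240701
    age_mean: float = 50.0
    age_sd: float = 13.2
    age_min: float = 30.0
    prop_female: float = 0.581
    target_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_PREVALENCE)
    )
    block_assignment: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_ASSIGNMENT)
    )
    factor_loading: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_LOADING)
    )
    age_slope: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_SLOPE))
    missing_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_FRACTION)
    )

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be > 0")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError("prop_female must be in [0, 1]")
        for c, p in self.target_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"target prevalence for {c} outside [0, 1]")
            if c not in self.block_assignment:
                raise ValueError(f"condition {c} lacks a block assignment")
        for b in self.block_assignment.values():
            if b not in ("cardiometabolic", "other", "independent"):
                raise ValueError(f"unknown block {b!r}")
        for m, f in self.missing_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"missing fraction for {m} outside [0, 1]")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.target_prevalence)


@dataclass
class ParticipantRecord:
    """One simulated participant; any measurement may be NaN (missing)."""

    id: str
    age: float
    sex: str
    education: str
    tobacco_use: bool
    alcohol_use: bool
    sbp: float
    dbp: float
    fbs: float
    hb: float
    serum_creatinine: float
    uacr: float
    phq9: float
    gad7: float
    bmi: float
    waist: float
    copd_ps: float
    self_reported: set = field(default_factory=set)
    self_report_missing: set = field(default_factory=set)


def _sigmoid(x):
    return st.logistic.cdf(x)


def _covariate_draws(spec: CohortSpec, m: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (age, factor) sample of the covariate mixture for calibration.

    Uses a fixed internal stream (independent of the cohort seed) so the
    calibrated intercepts depend only on the spec's distributional
    parameters, never on the realised cohort.
    """
    rng = np.random.default_rng(987654321)
    a = (spec.age_min - spec.age_mean) / spec.age_sd
    age = st.truncnorm.rvs(a, np.inf, loc=spec.age_mean, scale=spec.age_sd, size=m, random_state=rng)
    factor = rng.standard_normal(m)
    return age, factor


def calibrate_intercept(
    target: float,
    age_slope: float,
    loading: float,
    age: np.ndarray,
    factor: np.ndarray,
    age_center: float = 50.0,
    rel_tol: float = 1e-6,
    name: str = "condition",
) -> float:
    """Bisection for the logistic intercept hitting a target marginal prevalence.

    Solves  E[sigmoid(b0 + slope*(age-50)/10 + loading*F)] = target  over
    the supplied covariate sample; the expectation is monotone increasing
    in b0, so plain bisection on [-30, 30] converges deterministically.
    """
    eta = age_slope * (age - age_center) / 10.0 + loading * factor

    def mean_p(b0: float) -> float:
        return float(_sigmoid(b0 + eta).mean())

    lo, hi = -30.0, 30.0
    if not (mean_p(lo) <= target <= mean_p(hi)):
        raise CalibrationError(
            f"target prevalence {target} unreachable for {name!r} given loadings"
        )
    while hi - lo > rel_tol * max(1.0, abs(lo), abs(hi)):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_intercepts(spec: CohortSpec) -> dict[str, float]:
    """Calibrated intercept for every condition in the spec."""
    age, factor = _covariate_draws(spec)
    out = {}
    for c, target in spec.target_prevalence.items():
        out[c] = calibrate_intercept(
            target,
            spec.age_slope.get(c, 0.0),
            spec.factor_loading.get(c, 0.0),
            age,
            factor,
            name=c,
        )
    return out


def _tnorm(rng, mean, sd, lo, hi, size=None):
    """Truncated-normal draw; accepts array bounds."""
    mean, sd = np.broadcast_arrays(np.asarray(mean, float), np.asarray(sd, float))
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return st.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size or mean.shape or None, random_state=rng)


def _draw_measurements(
    rng: np.random.Generator,
    status: dict[str, np.ndarray],
    age: np.ndarray,
    sex: np.ndarray,
    n: int,
) -> dict[str, np.ndarray]:
    """Raw measurements conditional on planted status (threshold-consistent)."""
    female = sex == "female"
    out: dict[str, np.ndarray] = {}

    def g(c: str) -> np.ndarray:
        # conditions omitted from a custom spec are simply never present
        return status.get(c, np.zeros(n, dtype=int))

    # Blood pressure: cases sit above the SBP cut, non-cases below both cuts.
    htn = g("hypertension").astype(bool)
    sbp = np.where(
        htn,
        _tnorm(rng, np.full(n, 152.0), 12.0, 140.5, 220.0),
        _tnorm(rng, np.full(n, 122.0), 10.0, 92.0, 139.4),
    )
    dbp_hi = np.minimum(sbp - 8.0, np.where(htn, 115.0, 89.4))
    dbp = _tnorm(rng, np.where(htn, 88.0, 76.0), 8.0, 55.0, dbp_hi)
    out["sbp"], out["dbp"] = np.round(sbp, 1), np.round(dbp, 1)

    dm = g("diabetes").astype(bool)
    out["fbs"] = np.round(
        np.where(
            dm,
            _tnorm(rng, np.full(n, 160.0), 30.0, 126.0, 350.0),
            _tnorm(rng, np.full(n, 100.0), 12.0, 70.0, 125.4),
        ),
        1,
    )

    cut = np.where(female, 12.0, 13.0)
    an = g("anaemia").astype(bool)
    out["hb"] = np.round(
        np.where(
            an,
            _tnorm(rng, cut - 2.0, 1.2, 6.0, cut - 0.1),
            _tnorm(rng, cut + 1.5, 1.0, cut, 18.5),
        ),
        1,
    )

    # Renal: cases present via low eGFR or high uACR (50/50); controls normal
    # on both axes.  Creatinine is back-computed from the target eGFR.
    ck = g("ckd").astype(bool)
    via_uacr = rng.random(n) < 0.5
    egfr = np.where(
        ck & ~via_uacr,
        _tnorm(rng, np.full(n, 45.0), 8.0, 20.0, 59.4),
        _tnorm(rng, np.full(n, 92.0), 12.0, 60.5, 130.0),
    )
    uacr = np.where(
        ck & via_uacr,
        _tnorm(rng, np.full(n, 80.0), 50.0, 30.0, 900.0),
        _tnorm(rng, np.full(n, 12.0), 7.0, 0.5, 29.4),
    )
    out["serum_creatinine"] = np.round(creatinine_from_egfr(egfr, age, sex), 3)
    out["uacr"] = np.round(uacr, 1)

    dep = g("depression").astype(bool)
    phq = np.where(
        dep,
        _tnorm(rng, np.full(n, 13.0), 3.0, 10.0, 27.0),
        _tnorm(rng, np.full(n, 4.0), 2.5, 0.0, 9.4),
    )
    out["phq9"] = np.clip(np.rint(phq), 0, 27)
    anx = g("anxiety").astype(bool)
    gad = np.where(
        anx,
        _tnorm(rng, np.full(n, 12.5), 2.5, 10.0, 21.0),
        _tnorm(rng, np.full(n, 3.5), 2.2, 0.0, 9.4),
    )
    out["gad7"] = np.clip(np.rint(gad), 0, 21)

    # Respiratory disease: 70% of cases self-report asthma/COPD; the rest are
    # picked up by the COPD-PS screen.
    resp = g("resp_disease").astype(bool)
    sr_resp = resp & (rng.random(n) < 0.70)
    cps = np.where(
        resp & ~sr_resp,
        _tnorm(rng, np.full(n, 7.0), 1.5, 5.0, 10.0),
        _tnorm(rng, np.full(n, 2.0), 1.5, 0.0, 4.4),
    )
    out["copd_ps"] = np.clip(np.rint(cps), 0, 10)
    out["sr_resp_disease"] = sr_resp.astype(float)

    # Treated cases may self-report even when the measurement goes missing.
    out["sr_hypertension"] = (htn & (rng.random(n) < SELF_REPORT_RESCUE)).astype(float)
    out["sr_diabetes"] = (dm & (rng.random(n) < SELF_REPORT_RESCUE)).astype(float)

    for label in SELF_REPORT_ONLY:
        out[f"sr_{label}"] = g(label).astype(float)
    return out


_MISSING_TARGETS = {
    "bp": ("sbp", "dbp"),
    "fbs": ("fbs",),
    "hb": ("hb",),
    "renal": ("serum_creatinine", "uacr"),
    "phq9": ("phq9",),
    "gad7": ("gad7",),
    "copd_ps": ("copd_ps",),
}


def _apply_missingness(
    rng: np.random.Generator, cols: dict[str, np.ndarray], fractions: Mapping[str, float], n: int
) -> None:
    for key, frac in fractions.items():
        if frac <= 0:
            continue
        mask = rng.random(n) < frac
        targets = _MISSING_TARGETS.get(key, (key,) if key in cols else ())
        for t in targets:
            cols[t] = np.where(mask, np.nan, cols[t])


def generate_cohort_frame(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort as a DataFrame (one participant per row).

    Byte-identical output for identical (spec, seed).  Columns: id,
    demographics, raw measurements, anthropometry, ``sr_*`` self-report
    flags (1/0/NaN), plus ``true_<condition>`` ground-truth columns for
    validation (dropped by :func:`write_cohort` unless requested).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    a = (spec.age_min - spec.age_mean) / spec.age_sd
    age = st.truncnorm.rvs(a, np.inf, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng)
    age = np.round(age, 1)
    sex = np.where(rng.random(n) < spec.prop_female, "female", "male").astype(object)
    gt50 = age > 50.0

    def by_age(d):
        return np.where(gt50, d["gt50"], d["le50"])

    u = rng.random(n)
    p_none = by_age({k: v[0] for k, v in _EDU_PROBS.items()})
    p_upto = by_age({k: v[1] for k, v in _EDU_PROBS.items()})
    education = np.where(
        u < p_none, "none", np.where(u < p_none + p_upto, "upto_secondary", "secondary_plus")
    ).astype(object)
    tobacco = rng.random(n) < by_age(_TOBACCO)
    alcohol = rng.random(n) < by_age(_ALCOHOL)

    # Anthropometry drawn from the survey's categorical margins.
    u = rng.random(n)
    p_under = by_age({k: v[0] for k, v in _BMI_PROBS.items()})
    p_norm = by_age({k: v[1] for k, v in _BMI_PROBS.items()})
    bmi = np.where(
        u < p_under,
        _tnorm(rng, np.full(n, 17.2), 0.9, 14.0, 18.4),
        np.where(
            u < p_under + p_norm,
            _tnorm(rng, np.full(n, 20.8), 1.2, 18.5, 22.9),
            _tnorm(rng, np.full(n, 26.0), 2.5, 23.0, 40.0),
        ),
    )
    wcut = np.where(sex == "female", 80.0, 90.0)
    high_waist = rng.random(n) < by_age(_WAIST_HIGH)
    waist = np.where(
        high_waist,
        _tnorm(rng, wcut + 8.0, 5.0, wcut + 0.5, wcut + 40.0),
        _tnorm(rng, wcut - 8.0, 6.0, 55.0, wcut - 0.1),
    )

    intercepts = calibrate_intercepts(spec)
    factors = {
        "cardiometabolic": rng.standard_normal(n),
        "other": rng.standard_normal(n),
        "independent": np.zeros(n),
    }
    status: dict[str, np.ndarray] = {}
    for c in spec.conditions:
        eta = (
            intercepts[c]
            + spec.age_slope.get(c, 0.0) * (age - 50.0) / 10.0
            + spec.factor_loading.get(c, 0.0) * factors[spec.block_assignment[c]]
        )
        status[c] = (rng.random(n) < _sigmoid(eta)).astype(int)

    cols = _draw_measurements(rng, status, age, sex, n)
    _apply_missingness(rng, cols, spec.missing_fraction, n)

    df = pd.DataFrame(
        {
            "id": [f"P{i + 1:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education": education,
            "tobacco_use": tobacco.astype(int),
            "alcohol_use": alcohol.astype(int),
            "bmi": np.round(bmi, 1),
            "waist": np.round(waist, 1),
        }
    )
    for k, v in cols.items():
        df[k] = v
    for c in spec.conditions:
        df[f"true_{c}"] = status[c]
    return df


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Simulate a cohort as :class:`ParticipantRecord` objects."""
    df = generate_cohort_frame(spec)
    records = []
    sr_labels = [c for c in spec.conditions if f"sr_{c}" in df.columns]
    for row in df.itertuples(index=False):
        d = row._asdict()
        reported = {c for c in sr_labels if d.get(f"sr_{c}") == 1.0}
        missing = {c for c in sr_labels if np.isnan(d.get(f"sr_{c}", np.nan))}
        records.append(
            ParticipantRecord(
                id=d["id"],
                age=d["age"],
                sex=d["sex"],
                education=d["education"],
                tobacco_use=bool(d["tobacco_use"]),
                alcohol_use=bool(d["alcohol_use"]),
                sbp=d["sbp"],
                dbp=d["dbp"],
                fbs=d["fbs"],
                hb=d["hb"],
                serum_creatinine=d["serum_creatinine"],
                uacr=d["uacr"],
                phq9=d["phq9"],
                gad7=d["gad7"],
                bmi=d["bmi"],
                waist=d["waist"],
                copd_ps=d["copd_ps"],
                self_reported=reported,
                self_report_missing=missing,
            )
        )
    return records


def write_cohort(df: pd.DataFrame, path, include_truth: bool = False, sep: str = ",") -> None:
    """Write a cohort table as UTF-8 delimited text with ``NA`` for missing."""
    out = df if include_truth else df[[c for c in df.columns if not c.startswith("true_")]]
    out.to_csv(path, sep=sep, index=False, na_rep="NA", encoding="utf-8")


def read_cohort(path, sep: str = ",") -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort`."""
    return pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=True)
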
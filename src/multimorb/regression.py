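"""Logistic association models fitted by iteratively reweighted least squares.

:class:`LogisticIRLS` is a scikit-learn-compatible binary classifier whose
purpose is statistical reporting: maximum-likelihood coefficients, Wald
standard errors from the inverse observed information, odds ratios and
confidence intervals.  Covariate coding follows the survey convention:
age binned to 30-49 (reference) / 50-59 / 60-69 / >=70, reference levels
male sex, highest education, no tobacco, no alcohol, normal BMI
(18.5-22.9) and normal waist circumference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats as st
from sklearn.base import BaseEstimator, ClassifierMixin

from .conditions import ConditionThresholds

__all__ = [
    "LogisticIRLS",
    "RankDeficientDesignError",
    "SeparationWarning",
    "fit_logistic",
    "code_covariates",
    "forest_table",
]


class RankDeficientDesignError(np.linalg.LinAlgError):
    """The design matrix is not full rank after reference coding."""


class SeparationWarning(UserWarning):
    """(Quasi-)complete separation: ML estimates diverge; fit flagged."""


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the collinear ones
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise RankDeficientDesignError(f"collinear design columns: {', '.join(bad)}")


class LogisticIRLS(BaseEstimator, ClassifierMixin):
    """Binary logistic regression by Newton-Raphson / IRLS.

    Parameters
    ----------
    max_iter : maximum IRLS iterations (default 100).
    tol : convergence tolerance on the maximum absolute score (gradient)
        component (default 1e-8).
    ridge : jitter added to the information-matrix diagonal to stabilise
        near-singular steps (default 1e-8).
    add_intercept : prepend an intercept column (default True).
    confidence : level of the Wald odds-ratio intervals (default 0.95).

    Attributes (after ``fit``)
    --------------------------
    coef_ : (n_terms,) coefficients on the log-odds scale (intercept first
        when ``add_intercept``).
    se_ : Wald standard errors from the inverse information at the optimum.
    term_names_ : column labels, ``intercept`` first.
    converged_, n_iter_ : convergence state.
    n_used_ : rows actually fitted.
    """

    def __init__(self, max_iter=100, tol=1e-8, ridge=1e-8, add_intercept=True, confidence=0.95):
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge
        self.add_intercept = add_intercept
        self.confidence = confidence

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"x{j}" for j in range(np.asarray(X).shape[1])
        ]
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or len(y) != len(X):
            raise ValueError("X must be 2-D and aligned with 1-D y")
        uniq = np.unique(y)
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError("outcome must be binary 0/1")
        self.classes_ = np.array([0.0, 1.0])
        if self.add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
            names = ["intercept"] + names
        _check_rank(X, names)

        beta = np.zeros(X.shape[1])
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = X @ beta
            p = st.logistic.cdf(eta)
            score = X.T @ (y - p)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            w = p * (1.0 - p)
            info = (X * w[:, None]).T @ X
            info[np.diag_indices_from(info)] += self.ridge
            beta = beta + np.linalg.solve(info, score)

        if not converged or np.max(np.abs(beta)) > 20.0:
            warnings.warn(
                "possible separation: coefficients diverging or IRLS did not converge",
                SeparationWarning,
            )
            converged = converged and np.max(np.abs(beta)) <= 20.0

        p = st.logistic.cdf(X @ beta)
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        info[np.diag_indices_from(info)] += self.ridge
        cov = np.linalg.inv(info)

        self.term_names_ = names
        self.coef_ = beta
        self.se_ = np.sqrt(np.diag(cov))
        self.cov_ = cov
        self.converged_ = bool(converged)
        self.n_iter_ = it
        self.n_used_ = len(y)
        self.n_features_in_ = X.shape[1] - int(self.add_intercept)
        return self

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        if self.add_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def predict_proba(self, X):
        p = st.logistic.cdf(self._design(X) @ self.coef_)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)

    # -- statistical reporting ------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Per-term OR, Wald CI and p-value (intercept reported on log-odds only)."""
        z = st.norm.ppf(0.5 + self.confidence / 2.0)
        coef, se = self.coef_, self.se_
        wald = coef / se
        return pd.DataFrame(
            {
                "term": self.term_names_,
                "coef": coef,
                "se": se,
                "odds_ratio": np.exp(coef),
                "ci_low": np.exp(coef - z * se),
                "ci_high": np.exp(coef + z * se),
                "p_value": 2.0 * st.norm.sf(np.abs(wald)),
            }
        )


def fit_logistic(outcome, covariates, max_iter: int = 100, tol: float = 1e-8) -> LogisticIRLS:
    """Fit a logistic model and return the fitted estimator."""
    return LogisticIRLS(max_iter=max_iter, tol=tol).fit(covariates, outcome)


AGE_BINS = ((30.0, 50.0, "30-49"), (50.0, 60.0, "50-59"), (60.0, 70.0, "60-69"), (70.0, np.inf, ">=70"))

#: covariate -> (dummy column, reference level) bookkeeping for reports
COVARIATE_GROUPS = {
    "age_group": ["age_50_59", "age_60_69", "age_70p"],
    "sex": ["sex_female"],
    "education": ["edu_upto_secondary", "edu_none"],
    "tobacco": ["tobacco_use"],
    "alcohol": ["alcohol_use"],
    "bmi": ["bmi_underweight", "bmi_overweight_obese"],
    "waist": ["waist_high"],
}


def code_covariates(
    cohort: pd.DataFrame,
    thresholds: ConditionThresholds | None = None,
    dropna: bool = True,
) -> pd.DataFrame:
    """Reference-coded design frame for the multimorbidity models.

    Age is binned to 30-49 (reference), 50-59, 60-69, >=70; sex, education,
    BMI category, waist category, tobacco and alcohol are coded as 0/1
    indicators against the reference levels male / highest education /
    normal BMI / normal waist / non-use.  Participants younger than 30 are
    excluded with a warning; with ``dropna`` (default) rows with any
    missing covariate are dropped (complete-case), and the result carries
    the surviving index for alignment with the outcome.
    """
    t = thresholds or ConditionThresholds()
    df = cohort
    under_age = df["age"] < 30.0
    if under_age.any():
        warnings.warn(f"excluding {int(under_age.sum())} participant(s) younger than 30")
        df = df.loc[~under_age]

    age = df["age"].to_numpy(dtype=float)
    X = pd.DataFrame(index=df.index)
    X["age_50_59"] = ((age >= 50.0) & (age < 60.0)).astype(float)
    X["age_60_69"] = ((age >= 60.0) & (age < 70.0)).astype(float)
    X["age_70p"] = (age >= 70.0).astype(float)
    X["sex_female"] = (df["sex"] == "female").astype(float)

    edu = df["education"]
    X["edu_upto_secondary"] = (edu == "upto_secondary").astype(float)
    X["edu_none"] = (edu == "none").astype(float)
    X.loc[edu.isna(), ["edu_upto_secondary", "edu_none"]] = np.nan

    X["tobacco_use"] = df["tobacco_use"].astype(float)
    X["alcohol_use"] = df["alcohol_use"].astype(float)

    bmi = df["bmi"].to_numpy(dtype=float)
    X["bmi_underweight"] = (bmi < t.bmi_under).astype(float)
    X["bmi_overweight_obese"] = (bmi >= t.bmi_over).astype(float)
    X.loc[np.isnan(bmi), ["bmi_underweight", "bmi_overweight_obese"]] = np.nan

    waist = df["waist"].to_numpy(dtype=float)
    wcut = np.where(df["sex"] == "female", t.waist_female, t.waist_male)
    X["waist_high"] = (waist > wcut).astype(float)
    X.loc[np.isnan(waist), "waist_high"] = np.nan

    if dropna:
        X = X.dropna()
    return X


def forest_table(
    cohort: pd.DataFrame,
    panel: pd.DataFrame,
    thresholds: ConditionThresholds | None = None,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Crude and adjusted odds ratios for multimorbidity.

    Crude ORs come from single-covariate-group fits; adjusted ORs from the
    full multivariable model.  Rows are the non-reference dummy terms.
    """
    X = code_covariates(cohort, thresholds)
    y = panel.loc[X.index, "multimorbid"].astype(float)
    keep = ~y.isna()
    X, y = X.loc[keep], y.loc[keep]

    adjusted = LogisticIRLS(confidence=confidence).fit(X, y).summary().set_index("term")
    rows = []
    for group, cols in COVARIATE_GROUPS.items():
        crude = LogisticIRLS(confidence=confidence).fit(X[cols], y).summary().set_index("term")
        for col in cols:
            rows.append(
                {
                    "covariate": group,
                    "term": col,
                    "crude_or": crude.loc[col, "odds_ratio"],
                    "crude_ci_low": crude.loc[col, "ci_low"],
                    "crude_ci_high": crude.loc[col, "ci_high"],
                    "adj_or": adjusted.loc[col, "odds_ratio"],
                    "adj_ci_low": adjusted.loc[col, "ci_low"],
                    "adj_ci_high": adjusted.loc[col, "ci_high"],
                    "adj_p": adjusted.loc[col, "p_value"],
                    "n_used": len(y),
                }
            )
    return pd.DataFrame(rows)
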
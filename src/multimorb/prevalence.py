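"""Prevalence estimation for clustered cross-sectional surveys.

Crude prevalence uses complete-case denominators (participants with a
non-missing state for the condition).  Confidence intervals are Wald
intervals whose half-width is inflated by sqrt(DEFF) to account for
cluster sampling; with DEFF = 1 they reduce to the textbook Wald interval.
Direct age standardization weights stratum-specific prevalences by a fixed
standard population.  The module also implements the survey sample-size
calculation n = DEFF * z^2 * p(1-p) / d^2 with non-response inflation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .conditions import CONDITIONS

__all__ = [
    "PrevalenceEstimate",
    "SampleSizeSpec",
    "StandardPopulation",
    "DegenerateProportionError",
    "UndefinedEstimateError",
    "crude_prevalence",
    "deff_ci",
    "sample_size",
    "age_standardize",
    "prevalence_table",
]


class UndefinedEstimateError(ZeroDivisionError):
    """Prevalence requested on an empty (zero) denominator."""


class DegenerateProportionError(ValueError):
    """Wald CI requested at p in {0, 1}, where it collapses to a point."""


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A proportion with its design-effect-adjusted confidence interval."""

    cases: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    deff: float = 1.0
    z: float = st.norm.ppf(0.975)

    def __post_init__(self) -> None:
        if not self.denominator >= self.cases >= 0:
            raise ValueError("need denominator >= cases >= 0")
        if not 0.0 <= self.ci_low <= self.proportion <= self.ci_high <= 1.0:
            raise ValueError("CI must bracket the proportion within [0, 1]")

    @property
    def percent(self) -> float:
        """Proportion on the percentage scale, rounded half-up to 1 d.p."""
        return _round_half_up(100.0 * self.proportion, 1)


def _round_half_up(x: float, ndigits: int) -> float:
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


def deff_ci(p: float, n: int, deff: float = 1.5, confidence: float = 0.95):
    """Design-effect-adjusted Wald CI for a proportion.

    half-width = z * sqrt(p(1-p)/n) * sqrt(DEFF); limits clamped to [0, 1].
    """
    if not 0.0 < p < 1.0:
        raise DegenerateProportionError("Wald CI undefined at p in {0, 1}")
    if n < 2:
        raise ValueError("need n >= 2")
    if deff < 1.0:
        raise ValueError("design effect must be >= 1")
    z = st.norm.ppf(0.5 + confidence / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / n) * math.sqrt(deff)
    return max(0.0, p - half), min(1.0, p + half)


def crude_prevalence(
    panel: pd.DataFrame,
    condition: str,
    deff: float = 1.5,
    confidence: float = 0.95,
) -> PrevalenceEstimate:
    """Complete-case prevalence of one condition with a DEFF-adjusted CI.

    The denominator is the number of participants with a non-missing state
    for *this* condition (pairwise-available convention).  At p = 0 or 1
    the interval degenerates to the point estimate.
    """
    if condition not in panel.columns:
        raise KeyError(f"condition {condition!r} not in panel")
    states = panel[condition].to_numpy(dtype=float)
    denom = int(np.sum(~np.isnan(states)))
    if denom == 0:
        raise UndefinedEstimateError(f"no observed states for {condition!r}")
    cases = int(np.nansum(states == 1.0))
    p = cases / denom
    if 0.0 < p < 1.0:
        lo, hi = deff_ci(p, denom, deff, confidence)
    else:
        lo = hi = p
    return PrevalenceEstimate(
        cases=cases,
        denominator=denom,
        proportion=p,
        ci_low=lo,
        ci_high=hi,
        deff=deff,
        z=st.norm.ppf(0.5 + confidence / 2.0),
    )


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the cluster-survey sample-size formula."""

    p0: float
    rel_precision: float
    confidence: float = 0.95
    deff: float = 1.5
    nonresponse: float = 0.15

    def __post_init__(self) -> None:
        for name in ("p0", "rel_precision", "confidence", "nonresponse"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.deff < 1.0:
            raise ValueError("design effect must be >= 1")


def sample_size(spec: SampleSizeSpec) -> tuple[int, int]:
    """Minimum and non-response-inflated sample sizes.

    d = p0 * rel_precision (absolute precision);
    n_min = ceil(DEFF * z^2 * p0 (1-p0) / d^2);
    n_final = ceil(n_min / (1 - nonresponse)).
    """
    z = st.norm.ppf(0.5 + spec.confidence / 2.0)
    d = spec.p0 * spec.rel_precision
    n_min = math.ceil(spec.deff * z**2 * spec.p0 * (1.0 - spec.p0) / d**2)
    n_final = math.ceil(n_min / (1.0 - spec.nonresponse))
    return n_min, n_final


def inflate_for_nonresponse(n_min: int, nonresponse: float) -> int:
    """Non-response inflation alone: ceil(n_min / (1 - rate))."""
    if not 0.0 <= nonresponse < 1.0:
        raise ValueError("nonresponse must be in [0, 1)")
    return math.ceil(n_min / (1.0 - nonresponse))


@dataclass(frozen=True)
class StandardPopulation:
    """Age strata (closed-open [low, high) bands) with standard weights."""

    strata: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        weights = [w for _, _, w in self.strata]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("standard weights must sum to 1")
        bands = sorted((lo, hi) for lo, hi, _ in self.strata)
        for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
            if lo2 < hi1:
                raise ValueError("strata overlap")
        for lo, hi, _ in self.strata:
            if hi <= lo:
                raise ValueError("empty stratum band")

    @classmethod
    def from_ages(cls, ages: Sequence[float], band: float = 10.0, age_min: float = 30.0):
        """Standard = the cohort's own age distribution in fixed-width bands.

        The top band is open-ended (upper bound +inf).
        """
        ages = np.asarray(ages, dtype=float)
        ages = ages[~np.isnan(ages)]
        if ages.size == 0:
            raise ValueError("no ages supplied")
        edges = np.arange(age_min, ages.max() + band, band)
        strata = []
        for i, lo in enumerate(edges):
            hi = lo + band if i < len(edges) - 1 else np.inf
            w = np.mean((ages >= lo) & (ages < hi))
            if w > 0:
                strata.append((float(lo), float(hi), float(w)))
        total = sum(w for _, _, w in strata)
        strata = tuple((lo, hi, w / total) for lo, hi, w in strata)
        return cls(strata)

    def assign(self, ages: Sequence[float]) -> np.ndarray:
        """Stratum index per age (-1 when no stratum covers the age)."""
        ages = np.asarray(ages, dtype=float)
        out = np.full(ages.shape, -1, dtype=int)
        for k, (lo, hi, _) in enumerate(self.strata):
            out[(ages >= lo) & (ages < hi)] = k
        return out


def age_standardize(
    stratum_estimates: Sequence[tuple[object, int, int]],
    std: StandardPopulation,
    deff: float = 1.5,
    confidence: float = 0.95,
) -> PrevalenceEstimate:
    """Directly age-standardized prevalence with a DEFF-inflated CI.

    ``stratum_estimates`` pairs with ``std.strata`` positionally:
    the k-th (stratum, cases, denominator) tuple is weighted by the k-th
    standard weight.  Variance is Sum w_k^2 p_k (1-p_k) / n_k, inflated by
    DEFF as in :func:`deff_ci`.
    """
    if len(stratum_estimates) != len(std.strata):
        raise ValueError("need one estimate per standard stratum")
    z = st.norm.ppf(0.5 + confidence / 2.0)
    p_std = 0.0
    var = 0.0
    cases_total = 0
    denom_total = 0
    for (label, cases, denom), (_, _, w) in zip(stratum_estimates, std.strata):
        if denom == 0:
            raise UndefinedEstimateError(f"stratum {label!r} has zero denominator")
        p_k = cases / denom
        p_std += w * p_k
        var += w**2 * p_k * (1.0 - p_k) / denom
        cases_total += cases
        denom_total += denom
    half = z * math.sqrt(var * deff)
    return PrevalenceEstimate(
        cases=cases_total,
        denominator=denom_total,
        proportion=p_std,
        ci_low=max(0.0, p_std - half),
        ci_high=min(1.0, p_std + half),
        deff=deff,
        z=z,
    )


def stratified_counts(
    panel: pd.DataFrame, ages: Sequence[float], condition: str, std: StandardPopulation
) -> list[tuple[str, int, int]]:
    """Per-stratum (label, cases, denominator) counts for one condition."""
    states = panel[condition].to_numpy(dtype=float)
    idx = std.assign(ages)
    out = []
    for k, (lo, hi, _) in enumerate(std.strata):
        sel = idx == k
        denom = int(np.sum(sel & ~np.isnan(states)))
        cases = int(np.nansum(states[sel] == 1.0))
        out.append((f"{lo:g}-{hi:g}", cases, denom))
    return out


def prevalence_table(
    panel: pd.DataFrame,
    conditions: Sequence[str] | None = None,
    deff: float = 1.5,
    confidence: float = 0.95,
    include_multimorbidity: bool = True,
) -> pd.DataFrame:
    """One DEFF-adjusted prevalence row per condition (plus multimorbidity)."""
    conds = list(conditions) if conditions is not None else [c for c in CONDITIONS if c in panel]
    if include_multimorbidity and "multimorbid" in panel:
        conds = conds + ["multimorbid"]
    rows = []
    for c in conds:
        try:
            est = crude_prevalence(panel, c, deff=deff, confidence=confidence)
        except UndefinedEstimateError:
            continue  # condition never observed in this panel
        rows.append(
            {
                "condition": c,
                "cases": est.cases,
                "denominator": est.denominator,
                "prevalence_pct": est.percent,
                "ci_low_pct": _round_half_up(100 * est.ci_low, 1),
                "ci_high_pct": _round_half_up(100 * est.ci_high, 1),
                "deff": deff,
            }
        )
    return pd.DataFrame(rows)
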
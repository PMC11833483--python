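"""Per-analysis study-validity diagnostics.

Four of the five diagnostics live here: minimum detectable relative risk
(statistical power), empirical-equipoise fraction (positivity/confounding),
covariate-balance maximum standardized difference of means (residual
confounding) and generalizability maximum SDM (selection by the adjustment).
The fifth, EASE, is computed from negative controls in
:mod:`rwediag.empirical_null`.
"""

from __future__ import annotations

import math
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import SchemaError

__all__ = [
    "BalanceResult",
    "compute_mdrr",
    "sdm_dichotomous",
    "sdm_continuous",
    "covariate_balance",
    "generalizability_sdm",
    "equipoise_fraction",
]


class BalanceResult(NamedTuple):
    """Per-covariate balance table plus the max |SDM| summary statistic."""

    table: pd.DataFrame
    max_abs_sdm: float


def compute_mdrr(
    total_events: float,
    p_a: float,
    p_b: float,
    alpha: float = 0.05,
    power: float = 0.80,
    conservative: bool = False,
) -> float:
    """Minimum detectable relative risk for a two-arm rate comparison.

    The expected standard error of the log relative risk, given the observed
    total event count and the fractions of events in each arm, is
    ``1/sqrt(total_events * p_a * p_b)``; the MDRR is the relative risk whose
    log sits ``z_power + z_{1-alpha/2}`` expected SEs from the null:

        MDRR = exp((z_power + z_{1-alpha/2}) / sqrt(total_events * p_a * p_b))

    Parameters
    ----------
    total_events : float
        Observed events pooled over both arms (after adjustment).
    p_a, p_b : float
        Event (or person-time) fractions of the two arms, each in (0, 1).
    alpha, power : float
        Two-sided type-I error and target power (defaults 0.05 / 0.80).
    conservative : bool
        If True, inflate the expected SE by sqrt(2). This alternate reading
        treats the two arm-specific rates as separately estimated; the
        default reading is validated by power simulation (nominal 80% power
        at RR = MDRR).

    Raises
    ------
    ValueError
        On non-positive event counts or boundary fractions; callers that
        need a non-computable *flag* rather than an exception should catch
        this and store NaN (threshold gating fails closed on NaN).
    """
    if not total_events > 0:
        raise ValueError("total_events must be > 0; MDRR is non-computable")
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("p_a and p_b must lie strictly in (0, 1)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z = norm.ppf(power) + norm.ppf(1.0 - alpha / 2.0)
    se = 1.0 / math.sqrt(total_events * p_a * p_b)
    if conservative:
        se *= math.sqrt(2.0)
    return float(math.exp(z * se))


def sdm_dichotomous(p_t: float, p_c: float) -> float:
    """Standardized difference of proportions between target and comparator.

    ``(p_t - p_c) / sqrt((p_t(1-p_t) + p_c(1-p_c)) / 2)``. Sign is preserved
    (antisymmetric in the two groups); maxima over covariates are taken on
    absolute values. Two degenerate equal proportions give 0; degenerate and
    unequal gives a signed infinity, which downstream gating treats as a
    failing (non-computable) value.
    """
    if not (0 <= p_t <= 1 and 0 <= p_c <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    denom = math.sqrt((p_t * (1 - p_t) + p_c * (1 - p_c)) / 2.0)
    diff = p_t - p_c
    if denom == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / denom


def sdm_continuous(mean_t: float, mean_c: float, sd_t: float, sd_c: float) -> float:
    """Standardized difference of means: ``(m_t - m_c)/sqrt((s_t^2+s_c^2)/2)``."""
    if sd_t < 0 or sd_c < 0:
        raise ValueError("standard deviations must be >= 0")
    denom = math.sqrt((sd_t**2 + sd_c**2) / 2.0)
    diff = mean_t - mean_c
    if denom == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / denom


def _patients_frame(study) -> pd.DataFrame:
    return study.patients if hasattr(study, "patients") else study


def _covariate_names(df: pd.DataFrame, study, covariates) -> list[str]:
    if covariates is not None:
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise SchemaError(f"covariates not found in population table: {missing}")
        return list(covariates)
    if hasattr(study, "covariates"):
        return list(study.covariates)
    reserved = {"patient_id", "arm", "follow_up", "weight", "stratum"}
    return [c for c in df.columns if c not in reserved]


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    # Frequency-weight convention with sum-of-weights normalisation, so a
    # 0/1 covariate yields sd^2 = p(1-p) and the continuous SDM reduces
    # exactly to the dichotomous one.
    sw = w.sum()
    if sw <= 0:
        return float("nan"), float("nan")
    m = float(np.sum(w * x) / sw)
    v = float(np.sum(w * (x - m) ** 2) / sw)
    return m, math.sqrt(max(v, 0.0))


def covariate_balance(study, weights=None, covariates=None) -> BalanceResult:
    """Weighted between-arm balance over all observed baseline covariates.

    Computes per-covariate weighted means/SDs in the target (arm=1) and
    comparator (arm=0) cohorts and their SDM; the summary statistic is the
    maximum of |SDM| over *all* observed covariates, not only those used in
    the propensity model. With ``weights=None`` the crude (unadjusted)
    balance is returned. An empty weighted arm makes the summary NaN
    (non-computable; gating fails closed).
    """
    df = _patients_frame(study)
    names = _covariate_names(df, study, covariates)
    if not names:
        raise SchemaError("no covariates to balance")
    w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape[0] != len(df):
        raise ValueError("weights length must match number of patients")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    arm = df["arm"].to_numpy()
    wt, wc = w[arm == 1], w[arm == 0]
    rows = []
    degenerate = wt.sum() <= 0 or wc.sum() <= 0
    if degenerate:
        warnings.warn("covariate_balance: an arm has zero total weight; SDM non-computable")
    for name in names:
        x = df[name].to_numpy(dtype=float)
        mt, st = _weighted_mean_sd(x[arm == 1], wt)
        mc, sc = _weighted_mean_sd(x[arm == 0], wc)
        sdm = float("nan") if degenerate else sdm_continuous(mt, mc, st, sc)
        rows.append((name, mt, mc, st, sc, sdm))
    table = pd.DataFrame(
        rows, columns=["covariate", "mean_t", "mean_c", "sd_t", "sd_c", "sdm"]
    )
    sdms = table["sdm"].to_numpy()
    max_abs = float("nan") if degenerate or np.isnan(sdms).any() else float(
        np.max(np.abs(sdms))
    )
    return BalanceResult(table=table, max_abs_sdm=max_abs)


def generalizability_sdm(
    pre_population,
    analytic_population=None,
    analytic_weights=None,
    covariates=None,
) -> BalanceResult:
    """SDM between the pre-adjustment population and the analytic cohort.

    The pre-adjustment (pooled target + comparator, unweighted) population
    defines who the question is about; matching or weighting yields the
    analytic cohort actually analysed. Large SDMs flag questionable
    generalizability of the estimate to the original population.

    Parameters
    ----------
    pre_population : SimulatedStudy or DataFrame
        The full pre-adjustment cohort.
    analytic_population : SimulatedStudy or DataFrame, optional
        Defaults to ``pre_population`` (the usual case: same patients,
        reweighted by ``analytic_weights``).
    analytic_weights : array-like, optional
        Adjustment weights over the analytic population (zeros drop
        patients). Defaults to all ones.
    """
    pre = _patients_frame(pre_population)
    analytic = pre if analytic_population is None else _patients_frame(analytic_population)
    names = _covariate_names(pre, pre_population, covariates)
    missing = [c for c in names if c not in analytic.columns]
    if missing:
        raise SchemaError(f"analytic population is missing covariates: {missing}")
    w = (
        np.ones(len(analytic))
        if analytic_weights is None
        else np.asarray(analytic_weights, dtype=float)
    )
    if w.shape[0] != len(analytic):
        raise ValueError("analytic_weights length must match the analytic population")
    rows = []
    degenerate = w.sum() <= 0 or len(pre) == 0
    if degenerate:
        warnings.warn("generalizability_sdm: empty analytic cohort; SDM non-computable")
    ones = np.ones(len(pre))
    for name in names:
        m_pre, s_pre = _weighted_mean_sd(pre[name].to_numpy(dtype=float), ones)
        m_an, s_an = _weighted_mean_sd(analytic[name].to_numpy(dtype=float), w)
        sdm = float("nan") if degenerate else sdm_continuous(m_an, m_pre, s_an, s_pre)
        rows.append((name, m_an, m_pre, s_an, s_pre, sdm))
    table = pd.DataFrame(
        rows, columns=["covariate", "mean_t", "mean_c", "sd_t", "sd_c", "sdm"]
    )
    sdms = table["sdm"].to_numpy()
    max_abs = float("nan") if degenerate or np.isnan(sdms).any() else float(
        np.max(np.abs(sdms))
    )
    return BalanceResult(table=table, max_abs_sdm=max_abs)


def equipoise_fraction(preference_scores, lower: float = 0.3, upper: float = 0.7) -> float:
    """Fraction of the pooled study population in empirical equipoise.

    A patient is in empirical equipoise when their preference score lies in
    [lower, upper] (bounds inclusive; defaults 0.3–0.7). Both cohorts are
    pooled, each patient counted once. The statistic is invariant to
    relabelling target/comparator because F and 1-F are both inside or both
    outside a symmetric band. Empty input returns NaN (non-computable).
    """
    f = np.asarray(preference_scores, dtype=float)
    if f.size == 0:
        warnings.warn("equipoise_fraction: empty input; non-computable")
        return float("nan")
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("preference scores must lie strictly in (0, 1)")
    return float(np.mean((f >= lower) & (f <= upper)))
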
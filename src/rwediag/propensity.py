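"""Propensity-score modelling, preference scores, stratification, matching,
and the stratified rate-ratio effect estimator.

The propensity score S is the probability of receiving the target treatment
given baseline covariates; the preference score F rescales S to the market
share P of the target so that F = 0.5 means "as likely as average":

    ln(F/(1-F)) = ln(S/(1-S)) - ln(P/(1-P))

Adjustment is by quantile stratification or greedy variable-ratio matching on
the propensity score; the effect estimator is a stratified Mantel–Haenszel
rate ratio, which is all the downstream diagnostics need (they consume only a
log estimate and its standard error).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression

from .errors import EstimationError, StratificationError

__all__ = [
    "PropensityResult",
    "EffectEstimate",
    "fit_propensity_model",
    "preference_score",
    "stratify_by_ps",
    "match_by_ps",
    "estimate_log_rr",
]

CLIP_EPS = 1e-6  # propensity scores are clipped to [eps, 1-eps]
Z_95 = 1.959963984540054


@dataclass
class PropensityResult:
    """Fitted propensity model and derived per-patient quantities."""

    score: np.ndarray  # propensity score S in (0, 1), clipped
    preference: np.ndarray  # preference score F in (0, 1)
    target_prevalence: float  # P, fraction of patients in the target arm
    coef: np.ndarray
    intercept: float
    arm: np.ndarray
    weights: np.ndarray = field(default=None)  # adjustment weights, default 1
    stratum: np.ndarray | None = None

    def __post_init__(self):
        if self.weights is None:
            self.weights = np.ones_like(self.score)

    def score_table(self, patient_id=None) -> pd.DataFrame:
        """Per-patient score/weight table (CSV-ready)."""
        n = self.score.size
        return pd.DataFrame(
            {
                "patient_id": np.arange(n) if patient_id is None else patient_id,
                "arm": self.arm,
                "propensity_score": self.score,
                "preference_score": self.preference,
                "weight": self.weights,
                "stratum": -1 if self.stratum is None else self.stratum,
            }
        )


@dataclass(frozen=True)
class EffectEstimate:
    """One analysis's effect estimate on the log relative-risk scale."""

    analysis_id: str
    log_rr: float
    se_log_rr: float
    ci_lb: float
    ci_ub: float
    is_negative_control: bool = False
    continuity_corrected: bool = False


def fit_propensity_model(study, penalty_strength: float = 1.0) -> PropensityResult:
    """Fit a ridge-regularized logistic model of treatment on all covariates.

    Parameters
    ----------
    study : SimulatedStudy or DataFrame
        Needs an ``arm`` column and covariate columns.
    penalty_strength : float
        L2 penalty weight; 0 means (numerically) unpenalized. The default
        mild ridge keeps moderate-dimensional fits stable; large-scale
        cross-validated propensity modelling is out of scope.

    Scores are clipped to ``[1e-6, 1 - 1e-6]`` so the preference transform
    stays finite; a warning is emitted if any score actually hits the clip
    bounds (e.g. under complete separation).
    """
    df = study.patients if hasattr(study, "patients") else study
    covariates = (
        list(study.covariates)
        if hasattr(study, "covariates")
        else [c for c in df.columns if c not in {"patient_id", "arm", "follow_up"}]
    )
    X = df[covariates].to_numpy(dtype=float)
    y = df["arm"].to_numpy(dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    n_target, n_comp = int((y == 1).sum()), int((y == 0).sum())
    if n_target == 0 or n_comp == 0:
        empty = "target" if n_target == 0 else "comparator"
        raise EstimationError(f"cannot fit propensity model: the {empty} arm is empty")
    if penalty_strength < 0:
        raise ValueError("penalty_strength must be >= 0")
    c = 1e12 if penalty_strength == 0 else 1.0 / penalty_strength
    model = LogisticRegression(
        penalty="l2", C=c, solver="lbfgs", tol=1e-10, max_iter=5000
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation drives lbfgs to its iter cap
        model.fit(X, y)
    s = model.predict_proba(X)[:, 1]
    clipped = (s < CLIP_EPS) | (s > 1 - CLIP_EPS)
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} propensity scores clipped to [{CLIP_EPS}, "
            f"{1 - CLIP_EPS}]; possible (near-)complete separation"
        )
    s = np.clip(s, CLIP_EPS, 1 - CLIP_EPS)
    p = float(np.mean(y))
    return PropensityResult(
        score=s,
        preference=preference_score(s, p),
        target_prevalence=p,
        coef=model.coef_.ravel().copy(),
        intercept=float(model.intercept_[0]),
        arm=y,
    )


def preference_score(s, p: float):
    """Map propensity score S to preference score F given target share P.

    Exact algebraic inversion of ``logit F = logit S - logit P``. Strictly
    increasing in S for fixed P; F = 0.5 whenever S = P, and F = S when
    P = 0.5.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr <= 0) | (s_arr >= 1)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    if not 0 < p < 1:
        raise ValueError("target prevalence P must lie strictly in (0, 1)")
    f = expit(logit(s_arr) - logit(p))
    return float(f) if np.isscalar(s) else f


def stratify_by_ps(result: PropensityResult, k_strata: int = 5):
    """Quantile stratification on the pooled propensity-score distribution.

    Returns ``(stratum, weights)``. Target patients get weight 1; comparator
    patients in stratum j get weight ``n_target_j / n_comparator_j`` so the
    weighted comparator cohort mirrors the target's stratum distribution
    (target-population estimand). Strata without comparators contribute
    weight 0 (with a warning).
    """
    scores = result.score
    if k_strata < 2:
        raise ValueError("k_strata must be >= 2")
    uniq = np.unique(scores)
    if uniq.size < k_strata:
        raise StratificationError(
            f"need at least {k_strata} distinct propensity scores, got {uniq.size}"
        )
    if uniq.size == k_strata:
        # Discrete score distribution with exactly k values: stratify exactly.
        stratum = np.searchsorted(uniq, scores)
    else:
        stratum = np.asarray(
            pd.qcut(scores, k_strata, labels=False, duplicates="drop"), dtype=int
        )
        n_formed = int(stratum.max()) + 1
        if n_formed < 2:
            raise StratificationError(
                f"cannot form {k_strata} quantile strata: scores too concentrated"
            )
        if n_formed < k_strata:
            warnings.warn(
                f"only {n_formed} of {k_strata} strata formed (duplicate quantile "
                f"edges on a discrete score distribution)"
            )
            k_strata = n_formed
    arm = result.arm
    weights = np.zeros_like(scores, dtype=float)
    weights[arm == 1] = 1.0
    for j in range(k_strata):
        in_j = stratum == j
        n_t = int(np.sum(in_j & (arm == 1)))
        n_c = int(np.sum(in_j & (arm == 0)))
        if n_c == 0 and n_t > 0:
            warnings.warn(f"stratum {j} has no comparator patients; weight 0")
            continue
        if n_c > 0:
            weights[in_j & (arm == 0)] = n_t / n_c
    result.stratum = stratum
    result.weights = weights
    return stratum, weights


def match_by_ps(
    result: PropensityResult,
    caliper: float = 0.2,
    max_ratio: int = 4,
    caliper_scale: str = "logit_sd",
):
    """Greedy variable-ratio nearest-neighbour matching on the logit score.

    Each target patient is matched, in rounds, to up to ``max_ratio``
    comparators within the caliper, without replacement. The caliper is
    expressed on the logit-propensity scale, by default as a multiple of the
    pooled SD of the logit score (0.2 SD, a common convention). Weights:
    matched targets 1, each of a target's k matched comparators 1/k,
    unmatched patients 0.
    """
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    if max_ratio < 1:
        raise ValueError("max_ratio must be >= 1")
    if caliper_scale not in {"logit_sd", "logit"}:
        raise ValueError("caliper_scale must be 'logit_sd' or 'logit'")
    lps = logit(result.score)
    width = caliper * float(np.std(lps)) if caliper_scale == "logit_sd" else caliper
    arm = result.arm
    t_idx = np.flatnonzero(arm == 1)
    c_idx = np.flatnonzero(arm == 0)
    # Deterministic order: targets by score then index.
    t_idx = t_idx[np.lexsort((t_idx, lps[t_idx]))]
    c_order = c_idx[np.lexsort((c_idx, lps[c_idx]))]
    c_scores = lps[c_order]
    available = np.ones(c_order.size, dtype=bool)
    matches: dict[int, list[int]] = {t: [] for t in t_idx}
    for _ in range(max_ratio):
        for t in t_idx:
            pos = np.searchsorted(c_scores, lps[t])
            best, best_d = -1, width
            lo = pos - 1
            while lo >= 0 and lps[t] - c_scores[lo] <= best_d:
                if available[lo]:
                    best, best_d = lo, lps[t] - c_scores[lo]
                    break
                lo -= 1
            hi = pos
            while hi < c_scores.size and c_scores[hi] - lps[t] <= best_d:
                if available[hi]:
                    d = c_scores[hi] - lps[t]
                    if d < best_d or best < 0:
                        best, best_d = hi, d
                    break
                hi += 1
            if best >= 0 and best_d <= width:
                available[best] = False
                matches[t].append(int(c_order[best]))
    weights = np.zeros(arm.size, dtype=float)
    n_matched = 0
    for t, cs in matches.items():
        if cs:
            n_matched += 1
            weights[t] = 1.0
            for ci in cs:
                weights[ci] = 1.0 / len(cs)
    if n_matched == 0:
        warnings.warn("match_by_ps: no target patients matched; all weights are 0")
    result.weights = weights
    return weights


def _arm_totals(events, follow_up, arm, w):
    e_t = float(np.sum(w * events * arm))
    e_c = float(np.sum(w * events * (1 - arm)))
    pt_t = float(np.sum(w * follow_up * arm))
    pt_c = float(np.sum(w * follow_up * (1 - arm)))
    return e_t, e_c, pt_t, pt_c


def estimate_log_rr(
    study,
    outcome_id: str,
    weights=None,
    strata=None,
    is_negative_control: bool | None = None,
    continuity: float = 0.5,
) -> EffectEstimate:
    """Stratified Mantel–Haenszel log rate ratio with 95% CI.

    Within stratum j with events e and person-time PT per arm, the pooled
    estimator is ``RR = sum_j(e_Tj PT_Cj / PT_j) / sum_j(e_Cj PT_Tj / PT_j)``
    with the Greenland–Robins person-time variance; in a single unweighted
    stratum the SE reduces to ``sqrt(1/e_T + 1/e_C)``. If either arm has zero
    pooled events, ``continuity`` events are added to both arms in every
    informative stratum and the estimate is flagged.

    ``weights`` (frequency weights from stratification or matching) and/or
    ``strata`` labels both default to the crude single-stratum analysis.
    """
    patients = study.patients
    events = study.events[outcome_id].to_numpy(dtype=float)
    follow_up = patients["follow_up"].to_numpy(dtype=float)
    arm = patients["arm"].to_numpy(dtype=float)
    n = len(patients)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    labels = np.zeros(n, dtype=int) if strata is None else np.asarray(strata, dtype=int)
    if w.shape[0] != n or labels.shape[0] != n:
        raise ValueError("weights/strata must match the number of patients")
    if float(np.sum(w * events)) <= 0:
        raise EstimationError(
            f"no events for outcome {outcome_id!r} in the weighted cohort"
        )

    def _accumulate(extra: float):
        r = s = var_num = 0.0
        for j in np.unique(labels):
            m = labels == j
            e_t, e_c, pt_t, pt_c = _arm_totals(events[m], follow_up[m], arm[m], w[m])
            pt = pt_t + pt_c
            if pt_t <= 0 or pt_c <= 0:
                continue
            e_t, e_c = e_t + extra, e_c + extra
            r += e_t * pt_c / pt
            s += e_c * pt_t / pt
            var_num += (e_t + e_c) * pt_t * pt_c / pt**2
        return r, s, var_num

    r, s, var_num = _accumulate(0.0)
    corrected = False
    if r <= 0 or s <= 0:
        corrected = True
        r, s, var_num = _accumulate(continuity)
        if r <= 0 or s <= 0:
            raise EstimationError(
                f"outcome {outcome_id!r}: no informative strata for rate-ratio estimation"
            )
        warnings.warn(
            f"outcome {outcome_id!r}: zero events in one arm; continuity "
            f"correction of {continuity} applied per stratum"
        )
    log_rr = math.log(r / s)
    se = math.sqrt(var_num / (r * s))
    nc = bool(study.true_log_rr.get(outcome_id, 0.0) == 0.0) if (
        is_negative_control is None and hasattr(study, "true_log_rr")
    ) else bool(is_negative_control)
    return EffectEstimate(
        analysis_id=str(outcome_id),
        log_rr=log_rr,
        se_log_rr=se,
        ci_lb=log_rr - Z_95 * se,
        ci_ub=log_rr + Z_95 * se,
        is_negative_control=nc,
        continuity_corrected=corrected,
    )
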
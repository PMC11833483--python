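"""Empirical null distribution of systematic error, EASE, and calibration.

A negative control outcome is one for which the true effect of the exposure
contrast is null (log relative risk 0), so any deviation of its estimate from
zero mixes sampling error with systematic error (confounding, selection,
measurement). Across a large set of negative controls the systematic component
is modelled as a normal distribution on the log relative-risk scale — the
*empirical null distribution* — with location ``mu`` and scale ``tau``.
Observed estimates are then

    theta_i ~ Normal(mu, tau^2 + s_i^2)

where ``s_i`` is the per-analysis standard error. The expected absolute
systematic error (EASE) is the mean of |X| for X ~ Normal(mu, tau^2), i.e. the
folded-normal mean. The fitted null is also used to calibrate p-values and
confidence intervals so that negative controls behave as statistically
expected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .errors import EstimationError

logger = logging.getLogger(__name__)

__all__ = [
    "EmpiricalNullModel",
    "fit_null",
    "ease",
    "scale_for_ease",
    "plausible_rr_range",
    "calibrate_p",
    "calibrate_ci",
    "fraction_ci_excluding_null",
]

_TAU_FLOOR = 1e-8


@dataclass(frozen=True)
class EmpiricalNullModel:
    """Fitted systematic-error distribution.

    Attributes
    ----------
    mu : float
        Mean systematic error on the log relative-risk scale.
    tau : float
        Standard deviation of systematic error (>= 0).
    n_controls : int
        Number of negative-control estimates used in the fit.
    log_likelihood : float
        Maximised log-likelihood.
    """

    mu: float
    tau: float
    n_controls: int
    log_likelihood: float

    @property
    def ease(self) -> float:
        """Expected absolute systematic error of the fitted null."""
        return ease(self.mu, self.tau)

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "tau": self.tau,
            "ease": self.ease,
            "n_controls": self.n_controls,
            "loglik": self.log_likelihood,
        }


def _extract(estimates, se_log_rr):
    if isinstance(estimates, pd.DataFrame):
        theta = estimates["log_rr"].to_numpy(dtype=float)
        se = estimates["se_log_rr"].to_numpy(dtype=float)
    else:
        theta = np.asarray(estimates, dtype=float)
        if se_log_rr is None:
            raise ValueError("se_log_rr is required when estimates is an array")
        se = np.asarray(se_log_rr, dtype=float)
    if theta.shape != se.shape:
        raise ValueError("log_rr and se_log_rr must have equal length")
    return theta, se


def _nll(params, theta, se2):
    mu, log_tau = params
    var = math.exp(2.0 * log_tau) + se2
    return 0.5 * np.sum(np.log(2.0 * np.pi * var) + (theta - mu) ** 2 / var)


def fit_null(estimates, se_log_rr=None) -> EmpiricalNullModel:
    """Fit the empirical null distribution by maximum likelihood.

    Parameters
    ----------
    estimates : DataFrame or array-like
        Either a frame with ``log_rr`` and ``se_log_rr`` columns (negative
        controls only; callers filter), or an array of log estimates.
    se_log_rr : array-like, optional
        Standard errors, required when ``estimates`` is an array.

    Returns
    -------
    EmpiricalNullModel

    Notes
    -----
    The likelihood treats each observed estimate as
    Normal(mu, tau^2 + s_i^2). Optimisation runs on (mu, log tau) from
    several method-of-moments starting points; the tau = 0 boundary (where
    the profile MLE of mu is the precision-weighted mean) is always evaluated
    and wins ties. Non-finite inputs are excluded with a logged count.
    """
    theta, se = _extract(estimates, se_log_rr)
    usable = np.isfinite(theta) & np.isfinite(se) & (se > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("fit_null: excluded %d estimates with non-finite values", n_dropped)
    theta, se = theta[usable], se[usable]
    n = theta.size
    if n < 2:
        raise EstimationError(
            f"need at least 2 usable negative-control estimates, got {n}"
        )
    se2 = se**2

    # Boundary tau = 0: mu is the precision-weighted mean.
    w = 1.0 / se2
    mu_fixed = float(np.sum(w * theta) / np.sum(w))
    ll_boundary = -_nll((mu_fixed, math.log(_TAU_FLOOR) - 10), theta, se2)

    # Method-of-moments (DerSimonian–Laird) start for tau.
    q = float(np.sum(w * (theta - mu_fixed) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2_dl = max((q - (n - 1)) / denom, 0.0) if denom > 0 else 0.0
    starts = [
        (mu_fixed, math.log(max(math.sqrt(tau2_dl), 1e-3))),
        (mu_fixed, math.log(0.1)),
        (0.0, math.log(0.25)),
    ]

    best = (ll_boundary, mu_fixed, 0.0)
    for x0 in starts:
        res = optimize.minimize(
            _nll,
            x0=np.asarray(x0, dtype=float),
            args=(theta, se2),
            method="L-BFGS-B",
            bounds=[(None, None), (-30.0, 5.0)],
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        ll = -float(res.fun)
        if ll > best[0] + 1e-12:
            best = (ll, float(res.x[0]), float(math.exp(res.x[1])))
    ll, mu, tau = best
    if tau < _TAU_FLOOR:
        tau = 0.0
    return EmpiricalNullModel(mu=mu, tau=tau, n_controls=n, log_likelihood=ll)


def ease(mu: float, tau: float) -> float:
    """Folded-normal mean: E|X| for X ~ Normal(mu, tau^2).

    Equals ``tau*sqrt(2/pi)*exp(-mu^2/(2 tau^2)) + mu*(1 - 2*Phi(-mu/tau))``;
    for ``tau = 0`` this degenerates to ``|mu|``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0.0:
        return abs(mu)
    return float(
        tau * math.sqrt(2.0 / math.pi) * math.exp(-(mu**2) / (2.0 * tau**2))
        + mu * (1.0 - 2.0 * norm.cdf(-mu / tau))
    )


def scale_for_ease(target_ease: float, mu: float = 0.0) -> float:
    """Invert :func:`ease` in tau for fixed mu.

    For mu = 0 the closed form is ``tau = target_ease * sqrt(pi/2)``; otherwise
    the monotone map tau -> ease(mu, tau) is solved by bracketed root-finding.
    A target below ``|mu|`` (the infimum of attainable EASE) is infeasible.
    """
    if target_ease < 0:
        raise ValueError("target_ease must be >= 0")
    floor = abs(mu)
    if target_ease < floor - 1e-15:
        raise ValueError(
            f"target EASE {target_ease} is infeasible: minimum for mu={mu} is {floor}"
        )
    if target_ease <= floor:
        return 0.0
    if mu == 0.0:
        return target_ease * math.sqrt(math.pi / 2.0)
    hi = (target_ease + floor) * math.sqrt(math.pi / 2.0) + 1.0
    while ease(mu, hi) < target_ease:
        hi *= 2.0
    return float(optimize.brentq(lambda t: ease(mu, t) - target_ease, 0.0, hi, xtol=1e-12))


def plausible_rr_range(mu: float, tau: float, coverage: float = 0.95):
    """Range of apparent relative risks for a truly null effect.

    Under systematic error ~ Normal(mu, tau^2) on the log scale, a true RR of 1
    appears within ``(exp(mu - z*tau), exp(mu + z*tau))`` with the given
    probability, where z is the matching standard-normal quantile.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    z = norm.ppf(0.5 + coverage / 2.0)
    return float(math.exp(mu - z * tau)), float(math.exp(mu + z * tau))


def calibrate_p(log_rr, se_log_rr, null: EmpiricalNullModel):
    """Two-sided p-value against the empirical null.

    ``p = 2*(1 - Phi(|theta - mu| / sqrt(tau^2 + s^2)))``. With a degenerate
    null (mu=0, tau=0) this is the traditional Wald p-value.
    """
    theta = np.asarray(log_rr, dtype=float)
    se = np.asarray(se_log_rr, dtype=float)
    sd = np.sqrt(null.tau**2 + se**2)
    p = 2.0 * norm.sf(np.abs(theta - null.mu) / sd)
    return float(p) if np.isscalar(log_rr) else p


def calibrate_ci(log_rr, se_log_rr, null: EmpiricalNullModel, level: float = 0.95):
    """Calibrated confidence interval on the log scale.

    Shifts the estimate by the null's location and inflates its variance by
    the null's scale: ``theta - mu ± z*sqrt(tau^2 + s^2)``. This is the
    null-only (constant systematic error) calibration.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    theta = np.asarray(log_rr, dtype=float)
    se = np.asarray(se_log_rr, dtype=float)
    z = norm.ppf(0.5 + level / 2.0)
    centre = theta - null.mu
    half = z * np.sqrt(null.tau**2 + se**2)
    lb, ub = centre - half, centre + half
    if np.isscalar(log_rr):
        return float(lb), float(ub)
    return lb, ub


def fraction_ci_excluding_null(
    estimates: pd.DataFrame,
    null: EmpiricalNullModel | None = None,
    calibrated: bool = False,
    level: float = 0.95,
) -> float:
    """Share of analyses whose CI excludes the null (log RR 0).

    With ``calibrated=True`` the intervals are recomputed from the fitted
    null; otherwise the traditional ``ci_lb``/``ci_ub`` columns are used.
    For an unbiased evidence system the traditional share should sit near
    the nominal type-I error (5% at the default level).
    """
    if calibrated:
        if null is None:
            raise ValueError("calibrated=True requires a fitted null model")
        lb, ub = calibrate_ci(
            estimates["log_rr"].to_numpy(), estimates["se_log_rr"].to_numpy(), null, level
        )
    else:
        lb = estimates["ci_lb"].to_numpy(dtype=float)
        ub = estimates["ci_ub"].to_numpy(dtype=float)
    if lb.size == 0:
        return float("nan")
    return float(np.mean((lb > 0) | (ub < 0)))
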
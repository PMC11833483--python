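"""Pre-specified threshold gating and the evaluation summary.

The framework's discipline: thresholds for each diagnostic are fixed before
any result is seen, and an analysis's effect estimate is unblinded only if
every enabled diagnostic passes. Failing analyses are reported as
"inestimable" rather than silently dropped. In evaluation mode the same
machinery is run over a system of negative-control analyses to measure how
much systematic error (EASE) each gate removes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .empirical_null import fit_null, fraction_ci_excluding_null
from .errors import AlignmentError, ConfigError

__all__ = ["ThresholdConfig", "apply_thresholds", "unblind", "gate_summary", "default_rules"]

DIAGNOSTIC_NAMES = ("mdrr", "equipoise", "balance", "generalizability", "ease")

_COLUMN_FOR = {
    "mdrr": "mdrr",
    "equipoise": "equipoise_fraction",
    "balance": "balance_max_sdm",
    "generalizability": "generalizability_max_sdm",
    "ease": "ease",
}

MASKED_COLUMNS = ["log_rr", "se_log_rr", "ci_lb", "ci_ub"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Pre-specified diagnostic gates.

    Defaults are the conventional thresholds: MDRR <= 10, equipoise >= 0.50,
    covariate-balance SDM < 0.10 (strict, following the usual statement of
    the imbalance heuristic), generalizability SDM <= 0.25, EASE <= 0.25.
    ``enabled`` selects which diagnostics participate in the overall gate.
    """

    mdrr_max: float = 10.0
    equipoise_min: float = 0.5
    balance_sdm_max: float = 0.10
    generalizability_sdm_max: float = 0.25
    ease_max: float = 0.25
    enabled: tuple = DIAGNOSTIC_NAMES

    def __post_init__(self):
        unknown = set(self.enabled) - set(DIAGNOSTIC_NAMES)
        if unknown:
            raise ConfigError(f"unknown diagnostics in config: {sorted(unknown)}")
        for name, value in (
            ("mdrr_max", self.mdrr_max),
            ("equipoise_min", self.equipoise_min),
            ("balance_sdm_max", self.balance_sdm_max),
            ("generalizability_sdm_max", self.generalizability_sdm_max),
            ("ease_max", self.ease_max),
        ):
            if not value > 0:
                raise ConfigError(f"threshold {name} must be positive, got {value}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enabled"] = list(self.enabled)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ConfigError(f"unknown threshold config keys: {sorted(unknown)}")
        if "enabled" in d:
            d = {**d, "enabled": tuple(d["enabled"])}
        return cls(**d)


def _passes(diagnostics: pd.DataFrame, name: str, config: ThresholdConfig) -> np.ndarray:
    col = _COLUMN_FOR[name]
    if col not in diagnostics.columns:
        raise ConfigError(f"diagnostics table has no column {col!r} for diagnostic {name!r}")
    x = diagnostics[col].to_numpy(dtype=float)
    if name == "mdrr":
        ok = x <= config.mdrr_max
    elif name == "equipoise":
        ok = x >= config.equipoise_min
    elif name == "balance":
        ok = x < config.balance_sdm_max  # strict inequality
    elif name == "generalizability":
        ok = x <= config.generalizability_sdm_max
    else:
        ok = x <= config.ease_max
    return ok & np.isfinite(x)  # non-computable diagnostics fail closed


def apply_thresholds(diagnostics: pd.DataFrame, config: ThresholdConfig | None = None):
    """Evaluate every enabled diagnostic against its threshold.

    Returns a DataFrame aligned with ``diagnostics`` holding one boolean
    ``pass_<name>`` column per enabled diagnostic and ``pass_all`` (their
    conjunction). NaN or infinite diagnostic values fail closed.
    """
    config = config or ThresholdConfig()
    out = pd.DataFrame({"analysis_id": diagnostics["analysis_id"].to_numpy()})
    overall = np.ones(len(diagnostics), dtype=bool)
    for name in config.enabled:
        ok = _passes(diagnostics, name, config)
        out[f"pass_{name}"] = ok
        overall &= ok
    out["pass_all"] = overall
    return out


def unblind(
    estimates: pd.DataFrame, overall_pass, keep_truth: bool = False
) -> pd.DataFrame:
    """Mask failing analyses as inestimable.

    ``overall_pass`` is either a boolean array aligned with ``estimates`` or
    the output of :func:`apply_thresholds` (matched on ``analysis_id``).
    Failing rows get ``status='inestimable'`` with estimate and CI fields
    withheld (NaN). Unless ``keep_truth`` is set, simulation ground-truth
    columns are removed from the rendered output.
    """
    if isinstance(overall_pass, pd.DataFrame):
        flags = overall_pass
        if set(flags["analysis_id"]) != set(estimates["analysis_id"]):
            raise AlignmentError("estimates and pass flags carry different analysis ids")
        aligned = flags.set_index("analysis_id")["pass_all"]
        mask = aligned.loc[estimates["analysis_id"]].to_numpy(dtype=bool)
    else:
        mask = np.asarray(overall_pass, dtype=bool)
        if mask.shape[0] != len(estimates):
            raise AlignmentError(
                f"pass vector length {mask.shape[0]} != {len(estimates)} estimates"
            )
    out = estimates.copy()
    out["status"] = np.where(mask, "estimable", "inestimable")
    out.loc[~mask, [c for c in MASKED_COLUMNS if c in out.columns]] = np.nan
    if not keep_truth:
        out = out.drop(columns=[c for c in ("true_bias", "true_log_rr") if c in out.columns])
    return out


def default_rules(config: ThresholdConfig | None = None):
    """Table-2-style rule list: the combined gate plus each diagnostic alone."""
    config = config or ThresholdConfig()
    rules = [("all", config)]
    for name in config.enabled:
        rules.append((name, dataclasses.replace(config, enabled=(name,))))
    return rules


def gate_summary(
    estimates: pd.DataFrame,
    diagnostics: pd.DataFrame,
    config: ThresholdConfig | None = None,
    rules=None,
) -> pd.DataFrame:
    """Evaluate gating rules on a negative-control evidence system.

    For each rule (plus a no-gating reference row) the summary reports the
    number and percentage of analyses satisfying the rule, the fitted
    empirical-null location and scale among surviving negative controls
    (``log_rr_mu``, ``log_rr_sd``), the recomputed EASE, its change relative
    to the reference row (``ease_delta``), and the fraction of traditional
    CIs excluding the null among survivors. Rules leaving fewer than two
    negative controls are flagged non-computable (NaN statistics).

    Note the two roles EASE plays here: the ``ease`` *column* of
    ``diagnostics`` is the design-time diagnostic used by the gate, while the
    EASE reported per row is re-estimated from the surviving estimates.
    """
    config = config or ThresholdConfig()
    if set(estimates["analysis_id"]) != set(diagnostics["analysis_id"]):
        raise AlignmentError("estimates and diagnostics carry different analysis ids")
    rules = default_rules(config) if rules is None else rules
    n_total = len(estimates)

    def row_stats(survivors: pd.DataFrame):
        controls = survivors[survivors["is_negative_control"]]
        if len(controls) < 2:
            return np.nan, np.nan, np.nan, np.nan, False
        null = fit_null(controls)
        frac = fraction_ci_excluding_null(controls)
        return null.mu, null.tau, null.ease, frac, True

    mu0, sd0, ease0, frac0, _ = row_stats(estimates)
    rows = [
        {
            "rule": "none",
            "n_satisfied": n_total,
            "percent_satisfied": 100.0,
            "log_rr_mu": mu0,
            "log_rr_sd": sd0,
            "ease": ease0,
            "ease_delta": np.nan,
            "ci_excluding_null_pct": 100.0 * frac0,
            "ease_computable": True,
        }
    ]
    for label, rule_cfg in rules:
        flags = apply_thresholds(diagnostics, rule_cfg)
        keep = (
            flags.set_index("analysis_id")["pass_all"]
            .loc[estimates["analysis_id"]]
            .to_numpy(dtype=bool)
        )
        survivors = estimates[keep]
        mu, sd, ease_after, frac, ok = row_stats(survivors)
        rows.append(
            {
                "rule": label,
                "n_satisfied": int(keep.sum()),
                "percent_satisfied": 100.0 * keep.sum() / n_total,
                "log_rr_mu": mu,
                "log_rr_sd": sd,
                "ease": ease_after,
                "ease_delta": ease_after - ease0 if ok else np.nan,
                "ci_excluding_null_pct": 100.0 * frac if ok else np.nan,
                "ease_computable": ok,
            }
        )
    return pd.DataFrame(rows)
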
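"""Estimate-versus-standard-error plots of the negative-control distribution."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .empirical_null import EmpiricalNullModel

Z_95 = 1.959963984540054


def plot_null_distribution(
    estimates: pd.DataFrame,
    null_model: EmpiricalNullModel | None = None,
    output_path=None,
):
    """Scatter log estimates against their standard errors.

    Points below the grey dashed lines (|log RR| > 1.96 SE) have traditional
    confidence intervals excluding the null; when a fitted null is given, the
    shaded region marks estimates whose *calibrated* interval excludes the
    null (|theta - mu| > 1.96 sqrt(tau^2 + s^2)). Returns a dict of counts
    consistent with :func:`fraction_ci_excluding_null`; layout is
    deterministic given the inputs.
    """
    import matplotlib.pyplot as plt

    if len(estimates) == 0:
        warnings.warn("plot_null_distribution: no estimates to plot; skipping")
        return None
    theta = estimates["log_rr"].to_numpy(dtype=float)
    se = estimates["se_log_rr"].to_numpy(dtype=float)
    trad_sig = np.abs(theta) > Z_95 * se
    counts = {
        "n": int(theta.size),
        "n_traditional_significant": int(trad_sig.sum()),
    }

    fig, ax = plt.subplots(figsize=(6, 4.2))
    se_max = float(np.max(se)) * 1.1
    grid = np.linspace(1e-9, se_max, 200)
    if null_model is not None:
        cal_half = Z_95 * np.sqrt(null_model.tau**2 + grid**2)
        lo = null_model.mu - cal_half
        hi = null_model.mu + cal_half
        x_lim = max(np.max(np.abs(theta)) * 1.1, float(hi.max()))
        ax.fill_betweenx(grid, hi, x_lim, color="orange", alpha=0.25, linewidth=0,
                         label="calibrated CI excludes null")
        ax.fill_betweenx(grid, -x_lim, lo, color="orange", alpha=0.25, linewidth=0)
        cal_sig = np.abs(theta - null_model.mu) > Z_95 * np.sqrt(
            null_model.tau**2 + se**2
        )
        counts["n_calibrated_significant"] = int(cal_sig.sum())
        ax.set_xlim(-x_lim, x_lim)
    ax.plot(Z_95 * grid, grid, color="grey", linestyle="--", linewidth=1)
    ax.plot(-Z_95 * grid, grid, color="grey", linestyle="--", linewidth=1)
    ax.scatter(theta, se, s=8, alpha=0.4, color="#1f77b4", edgecolors="none")
    ax.set_ylim(se_max, 0)  # small SEs (precise analyses) at the bottom
    ax.set_xlabel("log relative risk")
    ax.set_ylabel("standard error")
    title = "Negative-control estimates"
    if null_model is not None:
        title += f"  (null mu={null_model.mu:.2f}, sd={null_model.tau:.2f}, EASE={null_model.ease:.2f})"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    if output_path is not None:
        output_path = Path(output_path)
        output_path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(output_path, dpi=150)
    plt.close(fig)
    return counts
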
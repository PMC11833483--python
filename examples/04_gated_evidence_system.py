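"""Threshold gating on a simulated evidence system.

Simulates 2000 negative-control analyses in which systematic error is
correlated with the equipoise and balance diagnostics, then applies the
pre-specified thresholds and prints the Table-style evaluation: how many
analyses each rule blinds and how much expected absolute systematic error
(EASE) it removes.
"""

from rwediag import ThresholdConfig, apply_thresholds, gate_summary, unblind
from rwediag.simulate import legend_like_scenario, simulate_estimate_set

scenario = legend_like_scenario(n_analyses=2000, seed=7)
estimates, diagnostics = simulate_estimate_set(scenario)

summary = gate_summary(estimates, diagnostics, ThresholdConfig())
cols = ["rule", "n_satisfied", "percent_satisfied", "log_rr_mu", "log_rr_sd",
        "ease", "ease_delta", "ci_excluding_null_pct"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:7.3f}"))

flags = apply_thresholds(diagnostics, ThresholdConfig())
masked = unblind(estimates, flags)
n_masked = int((masked["status"] == "inestimable").sum())
print(f"\n{n_masked} of {len(masked)} analyses blinded as 'inestimable'; "
      "the surviving subset behaves like an unbiased evidence system "
      "(EASE near 0, ~5% of CIs excluding the null).")
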
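"""CSV interchange schemas and validated readers/writers.

CSV is the interchange format for every table the framework consumes or
emits. Each reader validates the header and raises :class:`SchemaError`
naming any missing column, so a malformed file fails loudly at the edge
rather than deep inside an analysis.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import SchemaError

ESTIMATES = [
    "analysis_id",
    "target_id",
    "comparator_id",
    "outcome_id",
    "is_negative_control",
    "log_rr",
    "se_log_rr",
    "ci_lb",
    "ci_ub",
]
DIAGNOSTICS = [
    "analysis_id",
    "mdrr",
    "equipoise_fraction",
    "balance_max_sdm",
    "generalizability_max_sdm",
    "ease",
]
SCORES = ["patient_id", "arm", "propensity_score", "preference_score", "weight", "stratum"]
PATIENTS = ["patient_id", "arm", "follow_up"]  # plus x0..x{m-1}
EVENTS = ["patient_id", "outcome_id", "event"]
GATE_SUMMARY = [
    "rule",
    "n_satisfied",
    "percent_satisfied",
    "log_rr_mu",
    "log_rr_sd",
    "ease",
    "ease_delta",
    "ci_excluding_null_pct",
    "ease_computable",
]


def _require(df: pd.DataFrame, required, what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path} is missing columns: {missing}")


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ESTIMATES, "estimates", path)
    df["is_negative_control"] = df["is_negative_control"].astype(bool)
    return df


def read_diagnostics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, DIAGNOSTICS, "diagnostics", path)
    return df


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SCORES, "scores", path)
    return df


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PATIENTS, "patients", path)
    if not [c for c in df.columns if c.startswith("x")]:
        raise SchemaError(f"patients file {path} has no covariate columns (x0, x1, ...)")
    return df


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, EVENTS, "events (long format)", path)
    return df


def events_to_wide(events_long: pd.DataFrame) -> pd.DataFrame:
    wide = (
        events_long.pivot_table(
            index="patient_id", columns="outcome_id", values="event", fill_value=0
        )
        .astype(int)
        .reset_index()
    )
    wide.columns.name = None
    return wide


def events_to_long(events_wide: pd.DataFrame) -> pd.DataFrame:
    return events_wide.melt(
        id_vars="patient_id", var_name="outcome_id", value_name="event"
    )


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir, command: str, params: dict, seed=None, inputs=(), outputs=()):
    """Write a run manifest: command, parameters, seed, versions and file
    digests, enough to reproduce every artifact of the run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "rwediag_version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    path = out_dir / f"manifest_{command.replace('-', '_')}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
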
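"""Session file formats, validation, manifests, and the pipeline driver.

All tables are UTF-8 CSV with a header row; trial item sequences are
pipe-separated (digits ``3|8|2``, words as dot-joined phoneme triples
``ʃ.i.p|m.æ.d``, sentence key words as plain tokens). Every analysis run
writes a manifest (config snapshot, seed, input checksums, package
version) so outputs are traceable and deterministic stages reproduce
bit-for-bit on rerun.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (CohortConfig, sample_cohort, simulate_covariates,
                     simulate_recall_trials, simulate_rt_trials)
from .pipeline import AnalysisBundle, analyze_study

__all__ = [
    "TrialTableError",
    "read_trial_table",
    "write_trial_table",
    "read_rt_table",
    "read_covariates",
    "simulate_session",
    "run_pipeline",
]

TRIAL_COLUMNS = ["participant", "kind", "condition", "trial",
                 "target", "response", "n_slots", "n_correct"]
RT_COLUMNS = ["participant", "task", "condition", "trial", "rt_ms", "correct"]
KINDS = {"digit", "word", "sentence"}


class TrialTableError(ValueError):
    """A trial table failed validation; ``errors`` lists line-level problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("trial table validation failed:\n  " + "\n  ".join(errors))


def read_trial_table(
    path: str | Path,
    conditions: set[str] | None = None,
    skip_bad: bool = False,
) -> pd.DataFrame:
    """Read and validate a recall/sentence trial table.

    Row-level problems (unknown kind or condition, malformed item list,
    inconsistent slot counts) are collected with their line numbers; the
    run aborts with :class:`TrialTableError` unless ``skip_bad`` is set,
    in which case offending rows are dropped.
    """
    frame = pd.read_csv(path, dtype={"target": str, "response": str},
                        keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialTableError([f"missing column(s): {missing}"])
    errors: list[str] = []
    bad_rows: list[int] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        if row["kind"] not in KINDS:
            errors.append(f"line {line}: unknown kind {row['kind']!r}")
            bad_rows.append(idx)
            continue
        if conditions is not None and str(row["condition"]) not in conditions:
            errors.append(f"line {line}: unknown condition {row['condition']!r}")
            bad_rows.append(idx)
            continue
        target = str(row["target"])
        if target == "" or any(item == "" for item in target.split("|")):
            errors.append(f"line {line}: malformed target item list {target!r}")
            bad_rows.append(idx)
            continue
        if row["kind"] == "digit" and not all(
                item.isdigit() for item in target.split("|")):
            errors.append(f"line {line}: non-digit item in digit list {target!r}")
            bad_rows.append(idx)
    if errors and not skip_bad:
        raise TrialTableError(errors)
    if bad_rows:
        frame = frame.drop(index=bad_rows).reset_index(drop=True)
    frame["condition"] = frame["condition"].astype(str)
    return frame


def write_trial_table(path: str | Path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def read_rt_table(path: str | Path, skip_bad: bool = False) -> pd.DataFrame:
    """Read and validate a reaction-time trial table (positive RTs only)."""
    frame = pd.read_csv(path)
    missing = [c for c in RT_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialTableError([f"missing column(s): {missing}"])
    errors = [
        f"line {idx + 2}: non-positive reaction time {rt!r}"
        for idx, rt in frame["rt_ms"].items()
        if not np.isfinite(rt) or rt <= 0
    ]
    if errors and not skip_bad:
        raise TrialTableError(errors)
    if errors:
        frame = frame[frame["rt_ms"] > 0].reset_index(drop=True)
    return frame


def read_covariates(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "participant" not in frame.columns:
        raise TrialTableError(["missing column(s): ['participant']"])
    return frame.set_index("participant")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_session(
    seed: int,
    out_dir: str | Path,
    config: CohortConfig | None = None,
) -> dict[str, Path]:
    """Generate a full synthetic session directory (trial logs + covariates)."""
    config = config or CohortConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    streams = rng.spawn(4)  # cohort, recall, rt, covariates
    cohort = sample_cohort(config, streams[0])
    trials = simulate_recall_trials(cohort, config, streams[1])
    rt_trials = simulate_rt_trials(cohort, config, streams[2])
    covariates = simulate_covariates(cohort, config, streams[3])
    paths = {
        "trials": out_dir / "trials.csv",
        "rt_trials": out_dir / "rt_trials.csv",
        "covariates": out_dir / "covariates.csv",
    }
    trials.to_csv(paths["trials"], index=False)
    rt_trials.to_csv(paths["rt_trials"], index=False)
    covariates.to_csv(paths["covariates"])
    manifest = {
        "stage": "simulate",
        "seed": seed,
        "config": asdict(config),
        "outputs": {k: _checksum(v) for k, v in paths.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths


def run_pipeline(
    trials_path: str | Path,
    covariates_path: str | Path,
    out_dir: str | Path,
    rt_path: str | Path | None = None,
    fit_rt: bool = True,
    skip_bad: bool = False,
) -> AnalysisBundle:
    """Score → aggregate → PCA → correlations → RT analysis, with manifest.

    Writes every analysis table as CSV under ``out_dir``; on any stage
    error, partial outputs are removed and the exception propagates.
    """
    trials_path = Path(trials_path)
    covariates_path = Path(covariates_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not covariates_path.exists():
        raise FileNotFoundError(f"covariate file not found: {covariates_path}")
    trials = read_trial_table(trials_path, skip_bad=skip_bad)
    covariates = read_covariates(covariates_path)
    rt_trials = read_rt_table(rt_path, skip_bad=skip_bad) if rt_path else None

    written: list[Path] = []
    try:
        bundle = analyze_study(trials, covariates, rt_trials=rt_trials,
                               fit_rt=fit_rt)
        for name, frame in bundle.tables.items():
            target = out_dir / f"{name}.csv"
            frame.to_csv(target)
            written.append(target)
        manifest = {
            "stage": "analyze",
            "inputs": {
                "trials": _checksum(trials_path),
                "covariates": _checksum(covariates_path),
                **({"rt_trials": _checksum(Path(rt_path))} if rt_path else {}),
            },
            "outputs": {p.name: _checksum(p) for p in written},
            "serial_vs_reasoning": {
                "rho": bundle.serial_vs_reasoning.coefficient,
                "p": bundle.serial_vs_reasoning.p_value,
            },
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return bundle
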
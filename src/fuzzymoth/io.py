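"""Record-table I/O, run configuration and the cross-validation harness."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schema
from .behavior import HierarchicalBehaviorLearner

__all__ = ["RunConfig", "load_config", "load_records", "save_records",
           "run_cv"]


@dataclass
class RunConfig:
    """All tunables in one place; the defaults mirror the published
    experimental settings (evaluation budget 100,000; five clusters with
    fuzzifier 2; five-fold cross-validation with 20 repeats; 200 ms step;
    15% success tolerance) and the published layer sizes."""

    wwo_budget: int = 100_000
    population: int = 8
    n_groups: int = 5
    fuzzifier: float = 2.0
    u_floor: float = 0.1
    noise_level: float = 0.2
    cv_folds: int = 5
    cv_repeats: int = 20
    step_ms: int = 200
    success_tol: float = 0.15
    common_widths: tuple = (80, 46, 26)
    group_widths: tuple = (26, 15, 9)
    individual_widths: tuple = (9, 6, 7)
    control_widths: tuple = (75, 49, 35, 32)
    output_weights: tuple = (0.24, 0.2, 0.2, 0.15, 0.07, 0.07, 0.07)
    seed: int | None = None

    def __post_init__(self):
        if abs(sum(self.output_weights) - 1.0) > 1e-9:
            raise ValueError("output weights must sum to 1")
        if self.fuzzifier <= 1 or self.n_groups < 2:
            raise ValueError("require fuzzifier > 1 and n_groups >= 2")
        if self.wwo_budget < self.population:
            raise ValueError("budget below population size")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML configuration; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("common_widths", "group_widths", "individual_widths",
                "control_widths", "output_weights"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return RunConfig(**payload)


def load_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a record table (CSV with the documented 89-column
    schema; duplicate ``(id, t)`` pairs and non-numeric cells rejected)."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols != schema.RECORD_COLUMNS:
        missing = [c for c in schema.RECORD_COLUMNS if c not in cols]
        extra = [c for c in cols if c not in schema.RECORD_COLUMNS]
        raise ValueError(
            f"bad record schema ({len(cols)} columns, expected "
            f"{len(schema.RECORD_COLUMNS)}): missing {missing}, extra {extra}")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        bad = [c for c, t in df.dtypes.items() if not np.issubdtype(t, np.number)]
        raise ValueError(f"non-numeric cells in columns {bad}")
    if df.duplicated(subset=["id", "t"]).any():
        raise ValueError("duplicate (id, t) rows")
    df["id"] = df["id"].astype(int)
    df["t"] = df["t"].astype(int)
    return df


def save_records(records: pd.DataFrame, path: str | Path) -> None:
    records[schema.RECORD_COLUMNS].to_csv(path, index=False)


def run_cv(records: pd.DataFrame, n_folds: int = 5, n_repeats: int = 1,
           seed: int | None = None, learner_kwargs: dict | None = None,
           shapes=None, probe_resp=None, probe_amb=None, probe_stim=None) -> dict:
    """K-fold cross-validation of the Behavior Learner.

    Records are shuffled once per repeat and partitioned into ``n_folds``
    disjoint folds covering every record exactly once; each fold serves as
    the test set while the learner trains on the rest.  Returns a
    JSON-serialisable report with per-fold weighted regression errors and
    their mean +/- sd.
    """
    n = len(records)
    if n < n_folds * 2:
        raise ValueError("too few records for the requested folds")
    rng = np.random.default_rng(seed)
    kwargs = learner_kwargs or {}
    fold_errors = []
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        bounds = np.linspace(0, n, n_folds + 1).astype(int)
        for k in range(n_folds):
            test_idx = perm[bounds[k]:bounds[k + 1]]
            train_idx = np.setdiff1d(perm, test_idx)
            model = HierarchicalBehaviorLearner(
                random_state=int(rng.integers(2**31)), **kwargs)
            model.fit(records.iloc[train_idx], shapes=shapes,
                      probe_resp=probe_resp, probe_amb=probe_amb,
                      probe_stim=probe_stim)
            fold_errors.append({
                "repeat": rep, "fold": k,
                "test_error": model.score_records(records.iloc[test_idx]),
                "train_error": float(np.mean(
                    list(model.training_errors_.values()))),
            })
    errs = [f["test_error"] for f in fold_errors]
    return {
        "n_records": n, "n_folds": n_folds, "n_repeats": n_repeats,
        "folds": fold_errors,
        "mean_test_error": float(np.mean(errs)),
        "sd_test_error": float(np.std(errs)),
    }


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
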
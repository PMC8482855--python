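"""Configs, CSV trial-table I/O, and the end-to-end pipeline driver."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from priorlearn import learning, models, preprocessing, transfer
from priorlearn.synthetic import (
    CALIBRATION_COLUMNS,
    TRIAL_COLUMNS,
    AgentParams,
    DesignSpec,
    simulate_cohort,
)

__all__ = [
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_calibration",
    "write_calibration",
    "run_all",
]

log = logging.getLogger("priorlearn")

_FLOAT_COLS = {"target_angle", "hint_angle", "endpoint_angle", "estimate_angle"}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: design, agent, toggles, seed."""

    design: DesignSpec = field(default_factory=DesignSpec)
    agent: AgentParams = field(default_factory=AgentParams)
    seed: int = 0
    failure_threshold: float = 100.0
    model_trial_range: tuple = (4, 10)
    split: str = "pooled"
    cv_folds: int = 10
    correct_motor: bool = True

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        design = DesignSpec(**raw.get("design", {}))
        agent = AgentParams(**raw.get("agent", {}))
        extra = {
            k: v for k, v in raw.items() if k not in ("design", "agent")
        }
        if "model_trial_range" in extra:
            extra["model_trial_range"] = tuple(extra["model_trial_range"])
        return cls(design=design, agent=agent, **extra)

    def to_json(self, path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2, default=list)


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: extra columns preserved: {extra}")
    bad_lines = []
    for col in _FLOAT_COLS & set(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        # header is line 1, data starts at line 2
        bad_lines.extend((df.index[newly_bad] + 2).tolist())
        df[col] = coerced
    if bad_lines:
        warnings.warn(
            f"{path}: rejected {len(bad_lines)} row(s) with malformed angles "
            f"at line(s) {sorted(set(bad_lines))}"
        )
        df = df.drop(index=[ln - 2 for ln in set(bad_lines)]).reset_index(drop=True)
    return df


def read_trials(path) -> pd.DataFrame:
    """Read a hidden-target trial table; validates the schema, warns about
    extra columns, and rejects rows with unparseable angles (reporting line
    numbers)."""
    return _read_table(path, TRIAL_COLUMNS)


def read_calibration(path) -> pd.DataFrame:
    return _read_table(path, CALIBRATION_COLUMNS)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as CSV, angles at 6-decimal precision (the
    declared round-trip precision)."""
    df.to_csv(path, index=False, float_format="%.6f")


write_calibration = write_trials


def run_all(config: RunConfig, out_dir) -> dict:
    """Drive the whole pipeline: simulate -> preprocess -> learning metrics
    -> model comparison -> transfer analysis.

    Writes tidy CSVs plus a JSON summary into ``out_dir`` and returns the
    summary.  Deterministic given the config's seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulate: %d participants, %d blocks", config.design.n_participants,
             config.design.n_blocks)
    trials, calib = simulate_cohort(config.design, config.agent, seed=config.seed)
    write_trials(trials, out / "trials.csv")
    write_calibration(calib, out / "calibration.csv")

    errors = preprocessing.flag_failures(
        preprocessing.compute_errors(trials), config.failure_threshold
    )
    write_trials(errors, out / "errors.csv")
    summary_excl = preprocessing.exclusion_summary(errors)
    summary_excl.to_csv(out / "exclusions.csv", index=False)
    log.info("preprocess: %d rows, %d failed", len(errors),
             int(errors["failed"].sum()))

    curve = learning.learning_curve(errors)
    curve.to_csv(out / "learning_curve.csv", index=False)
    motor = learning.estimate_motor_error(calib)
    motor.to_csv(out / "motor_error.csv", index=False)
    half = learning.half_comparison(errors)

    bounds = {}
    for diff_level in ("easy", "hard"):
        kappa = config.design.kappa_for(diff_level)
        gm = float(motor["gamma_motor"].mean())
        bounds[diff_level] = learning.lower_bound(gm, kappa)
    pd.concat(
        [b.assign(difficulty=d) for d, b in bounds.items()], ignore_index=True
    ).to_csv(out / "lower_bound.csv", index=False)

    table = models.build_predictors(errors)
    comparison = models.compare_models(
        table, trial_range=config.model_trial_range, split=config.split
    )
    if config.split == "pooled":
        comparison["weights"].to_csv(out / "model_weights.csv")
        mean_w = comparison["mean_weights"]
    else:
        for level, res in comparison.items():
            res["weights"].to_csv(out / f"model_weights_{level}.csv")
        mean_w = next(iter(comparison.values()))["mean_weights"]

    motor_arg = motor if config.correct_motor else None
    contrasts = transfer.switch_contrast(errors, motor_arg)
    contrasts.to_csv(out / "switch_contrasts.csv", index=False)
    timew = models.time_resolved_weights(table)
    timew.to_csv(out / "time_resolved_weights.csv", index=False)

    t10_11 = contrasts[(contrasts.trial_a == 10) & (contrasts.trial_b == 11)]
    t1_11 = contrasts[(contrasts.trial_a == 1) & (contrasts.trial_b == 11)]
    transfer_flag = (
        "no"
        if abs(t1_11["mean_diff"].mean()) < abs(t10_11["mean_diff"].mean())
        else "yes"
    )
    summary = {
        "seed": config.seed,
        "n_participants": config.design.n_participants,
        "n_trials": int(len(trials)),
        "n_failed": int(errors["failed"].sum()),
        "exclusions": {
            f"{r.response_type}/{r.failure_reason}": int(r.count)
            for r in summary_excl.itertuples()
            if r.failure_reason != "none"
        },
        "half_comparison": {"t": half["t"], "p": half["p"], "n": half["n"]},
        "mean_model_weights": {int(k): float(v) for k, v in mean_w.items()},
        "best_model": int(mean_w.idxmax()),
        "switch_contrast_10_11": {
            "mean_diff": float(t10_11["mean_diff"].mean()),
            "min_p": float(t10_11["p"].min()),
        },
        "switch_contrast_1_11": {
            "mean_diff": float(t1_11["mean_diff"].mean()),
        },
        "transfer": transfer_flag,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("run_all complete: best model %s, transfer=%s",
             summary["best_model"], transfer_flag)
    return summary
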
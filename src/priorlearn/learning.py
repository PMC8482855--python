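"""Learning curves, half-block contrasts, motor error, and the
ideal-observer lower bound.

The bound combines two independent error sources in quadrature,

    gamma(t) = sqrt(gamma_motor^2 + gamma_hint(t)^2),

where gamma_motor is the subject's mean absolute angular error in the
calibration task (the motor-noise floor) and gamma_hint(t) is the mean
absolute error of the cumulative mean of t von Mises hints,
sqrt(2/pi) * sigma_dist / sqrt(t) with sigma_dist = sqrt(1/kappa).  Under
the normal approximation the quadrature of mean absolute errors equals
sqrt(2/pi) times the quadrature of the SDs, so reading the combination rule
on the MAE scale or the variance scale gives the identical curve.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from priorlearn.angles import signed_angle_diff
from priorlearn.synthetic import kappa_to_sd_deg

__all__ = [
    "learning_curve",
    "half_comparison",
    "guess_vs_hint_comparison",
    "modality_difference_index",
    "estimate_motor_error",
    "expected_abs_from_sd",
    "lower_bound",
]


def _valid(errors: pd.DataFrame) -> pd.DataFrame:
    if "failed" in errors.columns:
        return errors[~errors["failed"].astype(bool)]
    return errors


def learning_curve(
    errors: pd.DataFrame,
    metric: str = "abs_error",
    group_by: tuple = ("difficulty", "response_type"),
) -> pd.DataFrame:
    """Group learning curve: subject-level mean of ``metric`` per trial index
    and condition, then across-subject mean and SEM (SD over subject means /
    sqrt(N)).  Failed trials are excluded."""
    group_by = list(group_by)
    valid = _valid(errors)
    subj = (
        valid.groupby(group_by + ["trial_index", "participant_id"], observed=True)[
            metric
        ]
        .mean()
        .reset_index()
    )
    out = (
        subj.groupby(group_by + ["trial_index"], observed=True)[metric]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0,
            n_subjects="count",
        )
        .reset_index()
    )
    out["metric"] = metric
    return out


def _paired_t(x: np.ndarray, y: np.ndarray):
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if len(d) < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    if np.std(d, ddof=1) == 0.0:
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError(
            "zero-variance differences with non-zero mean: t statistic "
            "is infinite (degenerate contrast)"
        )
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def half_comparison(
    errors: pd.DataFrame,
    metric: str = "abs_error",
    first_half: tuple = (1, 5),
    second_half: tuple = (6, 10),
) -> dict:
    """Compare per-subject means of ``metric`` in trials 1-5 vs 6-10 (the
    within-modality learning test) with a paired two-sided t-test.

    Returns per-subject means for both halves, t, and p.  Learning shows as
    second half < first half for error, > for confidence.
    """
    valid = _valid(errors)

    def half_mean(lo, hi):
        sel = valid[(valid["trial_index"] >= lo) & (valid["trial_index"] <= hi)]
        return sel.groupby("participant_id")[metric].mean()

    a = half_mean(*first_half)
    b = half_mean(*second_half)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no subject has valid trials in both halves")
    a, b = a.loc[common], b.loc[common]
    t, p = _paired_t(a.to_numpy(), b.to_numpy())
    return {
        "per_subject_first": a,
        "per_subject_second": b,
        "t": t,
        "p": p,
        "n": len(common),
    }


def guess_vs_hint_comparison(
    errors: pd.DataFrame, trial_range: tuple = (1, 10)
) -> dict:
    """Paired t-test of per-subject mean |guess error| against mean |hint
    error| over a trial range.  Integrating hints across trials should make
    guesses beat the single-trial hints."""
    valid = _valid(errors)
    lo, hi = trial_range
    sel = valid[(valid["trial_index"] >= lo) & (valid["trial_index"] <= hi)]
    g = sel.groupby("participant_id")["abs_error"].mean()
    h = sel.groupby("participant_id")["abs_hint_error"].mean()
    common = g.index.intersection(h.index)
    t, p = _paired_t(h.loc[common].to_numpy(), g.loc[common].to_numpy())
    return {
        "per_subject_guess": g.loc[common],
        "per_subject_hint": h.loc[common],
        "t": t,
        "p": p,
        "n": len(common),
    }


def modality_difference_index(
    errors: pd.DataFrame, per_trial: bool = False
) -> pd.DataFrame:
    """Bounded asymmetry score per subject:
    (mean|err|_pro - mean|err|_anti) / (mean|err|_pro + mean|err|_anti).

    With ``per_trial`` the index is computed at each trial index (the
    time-resolved variant).  A zero denominator yields NaN.
    """
    valid = _valid(errors)
    keys = ["participant_id"] + (["trial_index"] if per_trial else [])
    means = (
        valid.groupby(keys + ["response_type"], observed=True)["abs_error"]
        .mean()
        .unstack("response_type")
    )
    for col in ("pro", "anti"):
        if col not in means.columns:
            raise ValueError(f"no {col} trials present")
    denom = means["pro"] + means["anti"]
    idx = (means["pro"] - means["anti"]) / denom.where(denom != 0.0)
    return idx.rename("modality_difference_index").reset_index()


def estimate_motor_error(calibration: pd.DataFrame) -> pd.DataFrame:
    """gamma_motor per subject per modality: mean absolute signed error of
    the inferred estimate against the shown line's location."""
    calib = calibration.copy()
    err = signed_angle_diff(
        calib["estimate_angle"].to_numpy(), calib["target_angle"].to_numpy()
    )
    calib["abs_error"] = np.abs(err)
    out = (
        calib.groupby(["participant_id", "response_type"], observed=True)["abs_error"]
        .mean()
        .rename("gamma_motor")
        .reset_index()
    )
    return out


def expected_abs_from_sd(sigma: float) -> float:
    """Mean absolute value of a zero-mean normal: sigma * sqrt(2/pi)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return sigma * math.sqrt(2.0 / math.pi)


def lower_bound(gamma_motor: float, kappa: float, t_max: int = 10) -> pd.DataFrame:
    """Ideal-observer bound gamma(t) for t = 1..t_max.

    The best estimator of the target after t hints is their cumulative mean,
    whose SD is sigma_dist/sqrt(t); its mean absolute error is
    gamma_hint(t) = sqrt(2/pi) * sigma_dist/sqrt(t) (degrees).  Combined in
    quadrature with the motor floor: gamma(t) = sqrt(gamma_motor^2 +
    gamma_hint(t)^2).  gamma is strictly decreasing while gamma_hint > 0 and
    tends to gamma_motor.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if gamma_motor < 0:
        raise ValueError("gamma_motor must be non-negative")
    t = np.arange(1, t_max + 1)
    sigma_dist = kappa_to_sd_deg(kappa)
    gamma_hint = expected_abs_from_sd(sigma_dist) / np.sqrt(t)
    gamma = np.sqrt(gamma_motor**2 + gamma_hint**2)
    return pd.DataFrame(
        {
            "trial_index": t,
            "gamma_hint": gamma_hint,
            "gamma": gamma,
            "kappa": kappa,
            "gamma_motor": gamma_motor,
        }
    )
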
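"""Knowledge transfer across the response switch.

Within a block the hidden target stays fixed while the response modality
flips after trial 10.  If the learned prior transfers across modalities,
performance at trial 11 should match trial 10; if the prior is tied to the
visuo-motor mapping, trial 11 should fall back to naive (trial 1) levels.
Because pro- and anti-saccades carry different motor noise, cross-modality
contrasts subtract each modality's calibration-task motor error
(gamma_motor) from the per-subject trial means before comparing; the
within-modality variant needs no correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "motor_corrected_error",
    "switch_contrast",
    "within_modality_contrast",
    "rm_anova3",
    "confidence_switch",
]


def _valid(errors: pd.DataFrame) -> pd.DataFrame:
    if "failed" in errors.columns:
        return errors[~errors["failed"].astype(bool)]
    return errors


def _subject_trial_means(
    errors: pd.DataFrame,
    metric: str = "abs_error",
    by: tuple = ("difficulty", "order"),
) -> pd.DataFrame:
    valid = _valid(errors)
    keys = ["participant_id", *by, "trial_index", "response_type"]
    return valid.groupby(keys, observed=True)[metric].mean().reset_index()


def motor_corrected_error(
    errors: pd.DataFrame,
    motor: pd.DataFrame,
    metric: str = "abs_error",
    by: tuple = ("difficulty", "order"),
) -> pd.DataFrame:
    """Per-subject per-trial-index mean |error| minus the gamma_motor of the
    modality used on that trial.

    ``motor`` is the output of :func:`priorlearn.learning.estimate_motor_error`
    (columns participant_id, response_type, gamma_motor).  Correction happens
    at the level of subject x condition x trial-index means, not single
    trials; corrected values may be negative.  Subjects without calibration
    data are excluded with a warning.
    """
    means = _subject_trial_means(errors, metric, by)
    merged = means.merge(motor, on=["participant_id", "response_type"], how="left")
    missing = merged["gamma_motor"].isna()
    if missing.any():
        lost = sorted(merged.loc[missing, "participant_id"].unique())
        warnings.warn(f"no calibration data for participants {lost}; excluded")
        merged = merged[~missing]
    merged["corrected"] = merged[metric] - merged["gamma_motor"]
    return merged


def switch_contrast(
    errors: pd.DataFrame,
    motor: pd.DataFrame | None = None,
    trial_pairs: tuple = ((10, 11), (1, 11)),
    metric: str = "abs_error",
    by: tuple = ("difficulty", "order"),
) -> pd.DataFrame:
    """Post hoc paired contrasts of performance around the response switch.

    For each condition cell and trial pair (a, b), a paired two-sided t-test
    of the per-subject mean at trial b minus trial a.  With ``motor`` given,
    each trial's mean is first corrected by its modality's gamma_motor
    (required when a pair spans the switch).  No multiple-comparison
    correction is applied; the output carries a ``corrected`` flag.
    """
    by = list(by)
    cond = tuple(by) if by else ("difficulty", "order")
    if motor is not None:
        means = motor_corrected_error(errors, motor, metric, cond)
        value = "corrected"
    else:
        means = _subject_trial_means(errors, metric, cond)
        value = metric
    if not by:
        # pooled contrast: average the per-condition means within subject
        means = (
            means.groupby(["participant_id", "trial_index"], observed=True)[value]
            .mean()
            .reset_index()
        )
        means["_all"] = "pooled"
        by = ["_all"]
    rows = []
    for pair in trial_pairs:
        a, b = pair
        wide = means[means["trial_index"].isin(pair)].pivot_table(
            index=["participant_id", *by], columns="trial_index", values=value
        )
        wide = wide.reset_index().dropna(subset=[a, b])
        for cell, grp in wide.groupby(by, observed=True):
            cell = cell if isinstance(cell, tuple) else (cell,)
            if len(grp) < 2:
                raise ValueError(
                    f"cell {cell}: paired t-test needs >= 2 subjects, got {len(grp)}"
                )
            diff = grp[b].to_numpy() - grp[a].to_numpy()
            if np.std(diff, ddof=1) == 0.0:
                t, p = (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf, 0.0)
            else:
                res = stats.ttest_rel(grp[b], grp[a])
                t, p = float(res.statistic), float(res.pvalue)
            rows.append(
                dict(zip(by, cell))
                | {
                    "trial_a": a,
                    "trial_b": b,
                    "mean_a": float(grp[a].mean()),
                    "mean_b": float(grp[b].mean()),
                    "mean_diff": float(np.mean(diff)),
                    "t": t,
                    "p": p,
                    "n": len(grp),
                    "corrected": motor is not None,
                    "mc_correction": "none",
                }
            )
    return pd.DataFrame(rows)


def within_modality_contrast(
    errors: pd.DataFrame,
    trial_pair: tuple = (1, 11),
    metric: str = "abs_error",
) -> pd.DataFrame:
    """Compare naive (trial 1) vs post-switch (trial 11) performance within
    the same modality, pooling over block order.

    Trial 1 of a pro-first block and trial 11 of an anti-first block are both
    pro-saccades, so this contrast needs no motor-error correction.  Paired
    t-test per modality x difficulty cell.
    """
    means = _subject_trial_means(errors, metric, ("difficulty",))
    a, b = trial_pair
    wide = means[means["trial_index"].isin(trial_pair)].pivot_table(
        index=["participant_id", "difficulty", "response_type"],
        columns="trial_index",
        values=metric,
    )
    wide = wide.reset_index().dropna(subset=[a, b])
    rows = []
    for (diff_level, rt), grp in wide.groupby(
        ["difficulty", "response_type"], observed=True
    ):
        if len(grp) < 2:
            raise ValueError(
                f"cell ({diff_level}, {rt}): needs >= 2 subjects, got {len(grp)}"
            )
        d = grp[b].to_numpy() - grp[a].to_numpy()
        if np.std(d, ddof=1) == 0.0:
            t, p = (0.0, 1.0) if np.allclose(d, 0.0) else (np.inf, 0.0)
        else:
            res = stats.ttest_rel(grp[b], grp[a])
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "difficulty": diff_level,
                "response_type": rt,
                "trial_a": a,
                "trial_b": b,
                "mean_diff": float(d.mean()),
                "t": t,
                "p": p,
                "n": len(grp),
                "corrected": False,
            }
        )
    return pd.DataFrame(rows)


def rm_anova3(
    values: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant_id",
    within: tuple = ("difficulty", "trial_index", "order"),
) -> pd.DataFrame:
    """Three-way repeated-measures ANOVA, all factors within-subject.

    ``values`` must hold one (or more, they are averaged) observation per
    subject per factor cell; the design must be complete and balanced — an
    incomplete cell raises with its name.  Returns a tidy frame of F, df,
    and p for the three main effects and all interactions.
    """
    within = list(within)
    agg = (
        values.groupby([subject, *within], observed=True)[dv].mean().reset_index()
    )
    counts = agg.groupby(within, observed=True)[subject].nunique()
    n_subj = agg[subject].nunique()
    expected_cells = int(np.prod([agg[w].nunique() for w in within]))
    if len(counts) != expected_cells or (counts != n_subj).any():
        bad = counts[counts != n_subj]
        name = bad.index[0] if len(bad) else "missing cell"
        raise ValueError(
            f"unbalanced within-subject design (offending cell: {name})"
        )
    if np.ptp(agg[dv].to_numpy(dtype=float)) == 0.0:
        # all observations identical: every effect SS is zero; report F = 0
        # instead of statsmodels' 0/0 noise
        effects = []
        for r in (1, 2, 3):
            from itertools import combinations

            effects += [":".join(c) for c in combinations(within, r)]
        return pd.DataFrame(
            {
                "effect": effects,
                "F": 0.0,
                "df1": np.nan,
                "df2": np.nan,
                "p": 1.0,
            }
        )
    res = AnovaRM(agg, depvar=dv, subject=subject, within=within).fit()
    tab = res.anova_table.reset_index().rename(
        columns={
            "index": "effect",
            "F Value": "F",
            "Num DF": "df1",
            "Den DF": "df2",
            "Pr > F": "p",
        }
    )
    return tab


def confidence_switch(
    errors: pd.DataFrame,
    trial_pairs: tuple = ((10, 11), (1, 11)),
    by: tuple = ("difficulty", "order"),
) -> pd.DataFrame:
    """Paired contrasts of confidence ratings around the response switch
    (same machinery as :func:`switch_contrast`, no motor correction).

    A cohort whose confidence is constant (e.g. clipped at the ceiling)
    yields the degenerate t = 0 / p = 1 rows rather than an error.
    """
    if "confidence" not in errors.columns:
        raise ValueError("no confidence column present")
    return switch_contrast(
        errors, motor=None, trial_pairs=trial_pairs, metric="confidence", by=by
    )
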
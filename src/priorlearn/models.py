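"""Lagged-predictor regression models of trial-by-trial guesses.

The dependent variable is the signed angular error of the guess on trial t;
candidate predictors are the current and up-to-three previous hint errors,
the three previous guess errors, and cumulative averages of each.  Eleven
models spanning these strategies (hint-follower, previous-guess follower,
cumulative integrators, and mixtures) are fitted per subject by ordinary
least squares and compared with BIC-based Bayesian weights: the weight of a
model is its probability of being the best among those tested.

Lags never cross block boundaries.  When a trial in the middle of a block
failed, lagged predictors refer to the nearest *valid* preceding trial (the
skip rule), and cumulative averages are taken over valid trials only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "ModelFit",
    "MODELS",
    "SINGLE_PREDICTOR_MODELS",
    "PREDICTOR_NAMES",
    "SingularFitError",
    "DegenerateFitError",
    "build_predictors",
    "fit_ols",
    "bic",
    "bayesian_weights",
    "compare_models",
    "stepwise_forward_cv",
    "time_resolved_weights",
    "modality_weight_contrast",
]

PREDICTOR_NAMES = [
    "hint_t",
    "hint_t1",
    "hint_t2",
    "hint_t3",
    "guess_t1",
    "guess_t2",
    "guess_t3",
    "cumavg_hint",
    "cumavg_guess",
]


class SingularFitError(ValueError):
    """Design matrix is rank deficient."""


class DegenerateFitError(ValueError):
    """Residual sum of squares is zero; Gaussian BIC undefined."""


@dataclass(frozen=True)
class ModelSpec:
    id: int
    name: str
    predictors: tuple


MODELS: dict[int, ModelSpec] = {
    m.id: m
    for m in [
        ModelSpec(1, "hint", ("hint_t",)),
        ModelSpec(2, "prev_hint", ("hint_t1",)),
        ModelSpec(3, "cumavg_hint", ("cumavg_hint",)),
        ModelSpec(4, "prev_guess", ("guess_t1",)),
        ModelSpec(5, "cumavg_guess", ("cumavg_guess",)),
        ModelSpec(6, "cumavg_hint_guess", ("cumavg_hint", "cumavg_guess")),
        ModelSpec(7, "hints_t_t3", ("hint_t", "hint_t1", "hint_t2", "hint_t3")),
        ModelSpec(8, "guesses_t1_t3", ("guess_t1", "guess_t2", "guess_t3")),
        ModelSpec(9, "guesses_t1_t2_hint", ("guess_t1", "guess_t2", "hint_t")),
        ModelSpec(
            10, "guesses_t1_t3_hint", ("guess_t1", "guess_t2", "guess_t3", "hint_t")
        ),
        ModelSpec(
            11,
            "guesses_t1_t3_hints_t_t3",
            (
                "guess_t1",
                "guess_t2",
                "guess_t3",
                "hint_t",
                "hint_t1",
                "hint_t2",
                "hint_t3",
            ),
        ),
    ]
}

SINGLE_PREDICTOR_MODELS = (1, 2, 3, 4, 5)


@dataclass
class ModelFit:
    """OLS fit of one model to one subject's trials."""

    participant_id: object
    model_id: int
    coefs: dict = field(default_factory=dict)  # includes 'intercept'
    rss: float = np.nan
    n: int = 0
    k: int = 0  # parameter count incl. intercept and error variance
    bic: float = np.nan
    delta_bic: float = np.nan
    weight: float = np.nan


def build_predictors(errors: pd.DataFrame) -> pd.DataFrame:
    """Build the per-trial predictor table from a flagged error table.

    One row per valid trial, with the guess error as dependent variable and
    every lagged/cumulative predictor.  ``cumavg_hint`` includes the current
    hint (mean of hint errors 1..t); ``cumavg_guess`` excludes the current
    guess (mean of guess errors 1..t-1, NaN on a block's first valid trial).
    Lags skip over failed trials and never leave the block.
    """
    needed = {"participant_id", "block_id", "trial_index", "error", "hint_error"}
    missing = needed - set(errors.columns)
    if missing:
        raise ValueError(f"error table lacks columns: {sorted(missing)}")
    valid = errors[~errors.get("failed", False).astype(bool)].copy()
    valid = valid.sort_values(["participant_id", "block_id", "trial_index"])

    g = valid.groupby(["participant_id", "block_id"], sort=False)
    guess = valid["error"]
    hint = valid["hint_error"]

    out = pd.DataFrame(
        {
            "participant_id": valid["participant_id"],
            "block_id": valid["block_id"],
            "trial_index": valid["trial_index"],
            "guess": guess,
            "hint_t": hint,
        }
    )
    for lag in (1, 2, 3):
        out[f"hint_t{lag}"] = g["hint_error"].shift(lag)
        out[f"guess_t{lag}"] = g["error"].shift(lag)
    out["cumavg_hint"] = g["hint_error"].expanding().mean().droplevel([0, 1])
    out["cumavg_guess"] = g["error"].apply(
        lambda s: s.shift(1).expanding().mean()
    ).droplevel([0, 1])
    for extra in ("response_type", "difficulty", "order"):
        if extra in valid.columns:
            out[extra] = valid[extra]
    return out.reset_index(drop=True)


def _design_matrix(table: pd.DataFrame, predictors):
    X = table[list(predictors)].to_numpy(dtype=float)
    kept = list(predictors)
    drop = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0.0]
    if drop:
        warnings.warn(
            f"dropping zero-variance predictor(s): {[kept[j] for j in drop]}",
            stacklevel=3,
        )
        keep = [j for j in range(X.shape[1]) if j not in drop]
        X = X[:, keep]
        kept = [kept[j] for j in keep]
    return np.column_stack([np.ones(len(X)), X]), kept


def fit_ols(
    spec: ModelSpec | tuple,
    table: pd.DataFrame,
    trial_range: tuple | None = None,
) -> ModelFit:
    """Least-squares fit of one model on a predictor table.

    Rows are restricted to ``trial_range`` (inclusive) and to rows where all
    of the model's predictors are defined.  Solves min ||y - Xb||^2; raises
    :class:`SingularFitError` on rank deficiency.
    """
    if isinstance(spec, tuple):
        spec = ModelSpec(0, "custom", tuple(spec))
    rows = table
    if trial_range is not None:
        lo, hi = trial_range
        rows = rows[(rows["trial_index"] >= lo) & (rows["trial_index"] <= hi)]
    rows = rows.dropna(subset=["guess", *spec.predictors])
    n = len(rows)
    if n < len(spec.predictors) + 2:
        raise ValueError(
            f"model {spec.id} needs >= {len(spec.predictors) + 2} rows, got {n}"
        )
    X, kept = _design_matrix(rows, spec.predictors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(f"rank-deficient design for model {spec.id}")
    y = rows["guess"].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    coefs = {"intercept": float(beta[0])}
    coefs.update({name: float(b) for name, b in zip(kept, beta[1:])})
    pid = rows["participant_id"].iloc[0] if "participant_id" in rows else None
    return ModelFit(
        participant_id=pid,
        model_id=spec.id,
        coefs=coefs,
        rss=rss,
        n=n,
        k=X.shape[1] + 1,  # + error variance
    )


def bic(fit: ModelFit) -> float:
    """Gaussian-likelihood BIC: n*ln(RSS/n) + k*ln(n), with k counting the
    regression coefficients (incl. intercept) plus the error variance.
    Additive constants of the likelihood cancel in BIC differences."""
    if fit.rss <= 0:
        raise DegenerateFitError("RSS must be positive for a Gaussian BIC")
    return fit.n * np.log(fit.rss / fit.n) + fit.k * np.log(fit.n)


def bayesian_weights(bics) -> np.ndarray:
    """Weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2) with
    delta_i = BIC_i - min BIC.  Sum to 1; invariant to shifting all BICs."""
    b = np.asarray(bics, dtype=float)
    if b.size == 0 or not np.any(np.isfinite(b)):
        raise ValueError("need at least one finite BIC")
    delta = b - np.nanmin(b)
    w = np.exp(-delta / 2.0)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def compare_models(
    table: pd.DataFrame,
    model_ids=tuple(MODELS),
    trial_range: tuple = (4, 10),
    split: str = "pooled",
):
    """Per-subject BIC model comparison on a common row set.

    All models are evaluated on identical rows: trials in ``trial_range``
    where every predictor used by any compared model is defined (trials 4-10
    for the full 11-model set; 2-10 suits the single-predictor set).
    ``split`` in {'pooled', 'by_modality', 'by_difficulty'} optionally runs
    the comparison separately per response type or difficulty.

    Returns a dict with ``weights`` (subjects x models), ``mean_weights``,
    and the per-subject ``fits``; for a split, a dict level -> result.
    """
    if split != "pooled":
        col = {"by_modality": "response_type", "by_difficulty": "difficulty"}[split]
        return {
            level: compare_models(grp, model_ids, trial_range, "pooled")
            for level, grp in table.groupby(col, observed=True)
        }
    specs = [MODELS[m] for m in model_ids]
    required = sorted({p for s in specs for p in s.predictors})
    lo, hi = trial_range
    rows = table[(table["trial_index"] >= lo) & (table["trial_index"] <= hi)]
    rows = rows.dropna(subset=["guess", *required])
    if rows.empty:
        raise ValueError("empty common row set for the requested models/trials")

    all_fits = []
    weight_rows = {}
    for pid, sub in rows.groupby("participant_id"):
        fits = [fit_ols(s, sub) for s in specs]
        bics = np.array([bic(f) for f in fits])
        ws = bayesian_weights(bics)
        for f, b, w in zip(fits, bics, ws):
            f.bic = float(b)
            f.delta_bic = float(b - bics.min())
            f.weight = float(w)
        all_fits.extend(fits)
        weight_rows[pid] = dict(zip([s.id for s in specs], ws))
    weights = pd.DataFrame.from_dict(weight_rows, orient="index").sort_index()
    weights.index.name = "participant_id"
    return {
        "weights": weights,
        "mean_weights": weights.mean(axis=0),
        "fits": all_fits,
        "n_rows": len(rows),
    }


def _cv_rmse(X: np.ndarray, y: np.ndarray, fold_id: np.ndarray, n_folds: int) -> float:
    errs = []
    for f in range(n_folds):
        test = fold_id == f
        Xtr, ytr = X[~test], y[~test]
        beta, _, _, _ = np.linalg.lstsq(Xtr, ytr, rcond=None)
        errs.append(y[test] - X[test] @ beta)
    e = np.concatenate(errs)
    return float(np.sqrt(np.mean(e**2)))


def stepwise_forward_cv(
    errors: pd.DataFrame,
    target_trial: int = 10,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Greedy forward predictor selection by 10-fold cross-validated RMSE.

    Per subject, blocks are the rows: the guess error at ``target_trial`` is
    predicted from that block's guess errors 1..target_trial-1 and hint
    errors 1..target_trial.  Starting from the intercept-only (null) model,
    the predictor that most reduces mean held-out RMSE is added until no
    candidate improves it.  Fold assignment is deterministic given ``seed``.

    Returns per-subject selections and RMSE paths plus a pooled
    per-predictor inclusion histogram.
    """
    valid = errors[~errors.get("failed", False).astype(bool)]
    results = {}
    histogram: dict[str, int] = {}
    root = np.random.SeedSequence(seed)
    pids = sorted(valid["participant_id"].unique())
    for pid, ss in zip(pids, root.spawn(len(pids))):
        sub = valid[valid["participant_id"] == pid]
        gw = sub.pivot_table(index="block_id", columns="trial_index", values="error")
        hw = sub.pivot_table(
            index="block_id", columns="trial_index", values="hint_error"
        )
        cols = {}
        for t in range(1, target_trial):
            cols[f"guess_{t}"] = gw.get(t)
        for t in range(1, target_trial + 1):
            cols[f"hint_{t}"] = hw.get(t)
        wide = pd.DataFrame(cols)
        wide["y"] = gw.get(target_trial)
        wide = wide.dropna()
        if len(wide) < folds:
            raise ValueError(
                f"participant {pid}: {len(wide)} complete blocks < {folds} folds"
            )
        rng = np.random.default_rng(ss)
        fold_id = rng.permutation(np.arange(len(wide)) % folds)
        y = wide["y"].to_numpy()
        ones = np.ones((len(wide), 1))
        null_rmse = _cv_rmse(ones, y, fold_id, folds)

        candidates = [c for c in wide.columns if c != "y"]
        selected: list[str] = []
        path = [null_rmse]
        best = null_rmse
        while candidates:
            trial_scores = []
            for c in candidates:
                X = np.column_stack(
                    [ones, wide[selected + [c]].to_numpy(dtype=float)]
                )
                trial_scores.append(_cv_rmse(X, y, fold_id, folds))
            j = int(np.argmin(trial_scores))
            if trial_scores[j] >= best:
                break
            best = trial_scores[j]
            selected.append(candidates.pop(j))
            path.append(best)
        results[pid] = {
            "selected": selected,
            "rmse_path": path,
            "null_rmse": null_rmse,
            "best_rmse": best,
        }
        for c in selected:
            histogram[c] = histogram.get(c, 0) + 1
    return {"per_subject": results, "inclusion_histogram": histogram}


def time_resolved_weights(
    table: pd.DataFrame,
    predictors: tuple = ("guess_t1", "hint_t"),
    trial_set=None,
) -> pd.DataFrame:
    """Regression weights as a function of trial index across the response
    switch.

    At each trial index the requested model is fitted per subject across
    that subject's blocks (predictors that are undefined at that index —
    e.g. a lagged guess on trial 1 — are omitted there); group-level
    significance is a two-sided one-sample t-test of the subject weights
    against zero.  Subjects with a singular per-trial design are omitted
    with a warning.
    """
    if trial_set is None:
        trial_set = sorted(table["trial_index"].unique())
    records = []
    for t in trial_set:
        rows_t = table[table["trial_index"] == t]
        avail = [p for p in predictors if rows_t[p].notna().any()]
        if not avail:
            continue
        per_subject = {p: [] for p in avail}
        for pid, sub in rows_t.groupby("participant_id"):
            sub = sub.dropna(subset=["guess", *avail])
            if len(sub) < len(avail) + 2:
                continue
            X = np.column_stack(
                [np.ones(len(sub)), sub[avail].to_numpy(dtype=float)]
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                warnings.warn(
                    f"singular design for participant {pid} at trial {t}; omitted"
                )
                continue
            beta, _, _, _ = np.linalg.lstsq(
                X, sub["guess"].to_numpy(dtype=float), rcond=None
            )
            for p, b in zip(avail, beta[1:]):
                per_subject[p].append(float(b))
        for p in avail:
            w = np.asarray(per_subject[p])
            if len(w) < 2:
                continue
            res = stats.ttest_1samp(w, 0.0)
            records.append(
                {
                    "trial_index": t,
                    "predictor": p,
                    "mean_weight": float(w.mean()),
                    "sem": float(w.std(ddof=1) / np.sqrt(len(w))),
                    "t": float(res.statistic),
                    "p": float(res.pvalue),
                    "n_subjects": len(w),
                }
            )
    return pd.DataFrame(records)


def modality_weight_contrast(
    table: pd.DataFrame,
    model_id: int = 11,
    windows: tuple = ((4, 10), (14, 20)),
) -> dict:
    """Do subjects weight guesses/hints differently under pro vs anti
    responses?

    The full lag model is fitted per subject separately on pro and anti
    rows, restricted to trial windows whose whole lag history lies within
    one modality half (by default trials 4-10 and 14-20 around a switch at
    trial 10).  Paired two-sided t-tests compare the previous-guess weight
    and the current-hint weight between modalities.
    """
    spec = MODELS[model_id]
    in_window = np.zeros(len(table), dtype=bool)
    for lo, hi in windows:
        in_window |= (table["trial_index"] >= lo) & (table["trial_index"] <= hi)
    rows = table[in_window].dropna(subset=["guess", *spec.predictors])

    coef_rows = []
    for (pid, rt), sub in rows.groupby(["participant_id", "response_type"]):
        try:
            f = fit_ols(spec, sub)
        except (ValueError, SingularFitError) as exc:
            warnings.warn(f"participant {pid} ({rt}): {exc}; omitted")
            continue
        coef_rows.append(
            {
                "participant_id": pid,
                "response_type": rt,
                "guess_weight": f.coefs.get("guess_t1", np.nan),
                "hint_weight": f.coefs.get("hint_t", np.nan),
            }
        )
    coefs = pd.DataFrame(coef_rows)
    out = {"per_subject": coefs}
    for key in ("guess_weight", "hint_weight"):
        wide = coefs.pivot(
            index="participant_id", columns="response_type", values=key
        ).dropna()
        if len(wide) < 2 or not {"pro", "anti"} <= set(wide.columns):
            out[key] = {"t": np.nan, "p": np.nan, "n": len(wide)}
            continue
        diff = wide["pro"] - wide["anti"]
        if np.std(diff, ddof=1) == 0.0:
            t = 0.0 if np.allclose(diff, 0.0) else np.inf
            out[key] = {"t": t, "p": 1.0 if t == 0.0 else 0.0, "n": len(wide)}
            continue
        res = stats.ttest_rel(wide["pro"], wide["anti"])
        out[key] = {
            "t": float(res.statistic),
            "p": float(res.pvalue),
            "n": len(wide),
        }
    return out
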
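"""Angular errors and exclusion rules for raw trial tables.

Raw tables carry the saccade endpoint; the participant's estimate is the
endpoint for a pro-saccade and its antipode for an anti-saccade.  The
analysis variable is the signed angular error of the estimate relative to
the hidden target.  Trials failed online (timeout / tracking loss) arrive
flagged; trials whose absolute error exceeds 100 deg are flagged as
wrong-response-type executions (a pro-saccade executed as an anti or vice
versa lands near 180 deg after reflection, so the 100 deg cut separates the
two modes of the error distribution).  Failed rows are flagged, never
dropped, so exclusion accounting stays reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from priorlearn.angles import signed_angle_diff, wrap_angle

__all__ = [
    "signed_angle_diff",
    "infer_estimate",
    "compute_errors",
    "flag_failures",
    "exclusion_summary",
]


def infer_estimate(endpoint_angle, response_type):
    """Estimate implied by a saccade endpoint: identity for pro,
    endpoint + 180 deg (mod 360) for anti.  Vectorized."""
    endpoint = np.asarray(endpoint_angle, dtype=float)
    rt = np.asarray(response_type)
    if not np.all(np.isin(rt, ("pro", "anti"))):
        bad = sorted(set(np.atleast_1d(rt)) - {"pro", "anti"})
        raise ValueError(f"unknown response type(s): {bad}")
    out = wrap_angle(np.where(rt == "anti", endpoint + 180.0, endpoint))
    return float(out) if np.ndim(out) == 0 else out


def compute_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Add signed/absolute error columns to a trial table.

    Recomputes ``estimate_angle`` from the endpoint and response type, then
    ``error`` = signed difference estimate - target on (-180, 180] and
    ``abs_error`` = |error|.  If a hint angle is present, ``hint_error`` and
    ``abs_hint_error`` are computed the same way (hints feed the lagged
    predictors later).  Rows with missing angles are flagged as failed
    (timeout_or_tracking) rather than erroring out.
    """
    out = trials.copy()
    if "failed" not in out.columns:
        out["failed"] = False
    if "failure_reason" not in out.columns:
        out["failure_reason"] = "none"

    missing = out["endpoint_angle"].isna() | out["target_angle"].isna()
    if missing.any():
        out.loc[missing, "failed"] = True
        out.loc[missing & (out["failure_reason"] == "none"), "failure_reason"] = (
            "timeout_or_tracking"
        )

    ok = ~missing
    out["estimate_angle"] = np.nan
    out.loc[ok, "estimate_angle"] = infer_estimate(
        out.loc[ok, "endpoint_angle"].to_numpy(),
        out.loc[ok, "response_type"].to_numpy(),
    )
    out["error"] = np.nan
    out.loc[ok, "error"] = signed_angle_diff(
        out.loc[ok, "estimate_angle"].to_numpy(),
        out.loc[ok, "target_angle"].to_numpy(),
    )
    out["abs_error"] = out["error"].abs()

    if "hint_angle" in out.columns:
        okh = ok & out["hint_angle"].notna()
        out["hint_error"] = np.nan
        out.loc[okh, "hint_error"] = signed_angle_diff(
            out.loc[okh, "hint_angle"].to_numpy(),
            out.loc[okh, "target_angle"].to_numpy(),
        )
        out["abs_hint_error"] = out["hint_error"].abs()
    return out


def flag_failures(errors: pd.DataFrame, threshold: float = 100.0) -> pd.DataFrame:
    """Flag wrong-response-type trials: abs_error strictly above the
    threshold (default 100 deg).  Rows already failed keep their reason.
    Idempotent."""
    if not (0.0 < threshold < 180.0):
        raise ValueError(f"threshold must be in (0, 180), got {threshold}")
    if "abs_error" not in errors.columns:
        raise ValueError("run compute_errors first (no abs_error column)")
    out = errors.copy()
    wrong = (out["abs_error"] > threshold) & ~out["failed"].astype(bool)
    out.loc[wrong, "failed"] = True
    out.loc[wrong, "failure_reason"] = "wrong_response_type"
    return out


def exclusion_summary(
    errors: pd.DataFrame, by: tuple = ("response_type",)
) -> pd.DataFrame:
    """Tally failure reasons per cell (default: per response modality).

    Returns a tidy frame with one row per cell x reason, raw counts, the
    cell's total row count, and the fraction excluded.  Counts partition the
    table: reasons 'none', 'timeout_or_tracking', 'wrong_response_type'.
    """
    by = list(by)
    reasons = ["none", "timeout_or_tracking", "wrong_response_type"]
    rows = []
    for cell, grp in errors.groupby(by, observed=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        total = len(grp)
        counts = grp["failure_reason"].value_counts()
        for reason in reasons:
            n = int(counts.get(reason, 0))
            rows.append(
                dict(zip(by, cell))
                | {
                    "failure_reason": reason,
                    "count": n,
                    "total": total,
                    "fraction": n / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)
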
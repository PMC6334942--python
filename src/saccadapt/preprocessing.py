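"""Trial rejection, gain normalisation and series utilities.

Implements the trial-level quality control of the adaptation analysis: a
trial is invalid when it contains a blink, when the primary saccade's
amplitude is below 3 dva or more than 3 two-sided median absolute
deviations from its block's median, or when the saccade start point
deviates more than 1.5 dva from the pre-saccadic (fixated) target.
Amplitudes (and, analogously, peak velocities and durations) are then
converted to gain by dividing by the median over valid first-block trials,
per hexagon direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "reject_trials",
    "qc_summary",
    "normalize_gain",
    "running_average",
    "smooth_by_block",
    "block_transition_change",
    "transition_table",
]

SESSION_COLS = ["participant", "saccade_type", "direction_order"]

#: normalised-metric column produced from each kinematic column
GAIN_COLS = {"amplitude_dva": "gain", "peak_vel_dps": "vel_gain", "duration_ms": "dur_gain"}


def _session_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in SESSION_COLS if c in df.columns]


def _mad_outlier_mask(amps: np.ndarray, criterion: float) -> np.ndarray:
    """Two-sided MAD rejection mask for one block's candidate amplitudes.

    Uses the raw (unscaled) MAD: reject |a − median| > criterion·MAD.  When
    the MAD degenerates to zero (a majority of exactly identical
    amplitudes), the spread is re-estimated from the amplitudes that differ
    from the modal value (scaled by 1.4826 about their own median), so that
    duplicate-breaking outliers are still caught.
    """
    med = np.median(amps)
    mad = np.median(np.abs(amps - med))
    if mad == 0.0:
        values, counts = np.unique(amps, return_counts=True)
        mode = values[np.argmax(counts)]
        rest = amps[amps != mode]
        if rest.size == 0:
            return np.zeros(amps.size, dtype=bool)
        mad = 1.4826 * np.median(np.abs(rest - np.median(rest)))
    return np.abs(amps - med) > criterion * mad


def reject_trials(
    trials: pd.DataFrame,
    *,
    amplitude_min: float = 3.0,
    mad_criterion: float = 3.0,
    startpoint_max: float = 1.5,
    min_block_n: int = 4,
) -> pd.DataFrame:
    """Populate per-trial QC status.

    Rules, tested in order (first failing rule wins):

    1. ``blink`` — the trial contains a blink;
    2. ``amplitude_low`` — amplitude below ``amplitude_min`` dva (or missing);
    3. ``amplitude_outlier`` — amplitude more than ``mad_criterion``
       two-sided MADs from the block median (median/MAD computed over the
       block's trials passing rules 1–2; skipped with a warning when fewer
       than ``min_block_n`` such trials exist);
    4. ``startpoint_deviation`` — saccade start point more than
       ``startpoint_max`` dva from the pre-saccadic target.

    Returns a copy with boolean ``qc_valid`` and string ``qc_reason``
    columns ("" for valid trials).  The operation is idempotent: it reads
    only raw columns, never its own output.
    """
    df = trials.copy()
    amps = df["amplitude_dva"].to_numpy(dtype=float)
    blink = df["blink"].to_numpy(dtype=bool) if "blink" in df else np.zeros(len(df), bool)

    reason = np.full(len(df), "", dtype=object)
    reason[blink] = "blink"
    low = (~np.isfinite(amps) | (amps < amplitude_min)) & (reason == "")
    reason[low] = "amplitude_low"

    group_cols = _session_cols(df) + ["block"]
    for _, idx in df.groupby(group_cols).indices.items():
        idx = np.asarray(idx)
        candidates = idx[reason[idx] == ""]
        if candidates.size < min_block_n:
            warnings.warn(
                f"block group with {candidates.size} candidate trials: MAD rule skipped",
                stacklevel=2,
            )
            continue
        out = _mad_outlier_mask(amps[candidates], mad_criterion)
        reason[candidates[out]] = "amplitude_outlier"

    if {"start_x", "start_y", "fix_x", "fix_y"}.issubset(df.columns):
        dev = np.hypot(df["start_x"] - df["fix_x"], df["start_y"] - df["fix_y"])
        far = (dev.to_numpy() > startpoint_max) & (reason == "")
        reason[far] = "startpoint_deviation"

    df["qc_valid"] = reason == ""
    df["qc_reason"] = reason
    return df


def qc_summary(trials: pd.DataFrame) -> dict:
    """Rejection counts per reason plus the number of valid trials."""
    counts = trials.loc[~trials["qc_valid"], "qc_reason"].value_counts().to_dict()
    return {
        "n_trials": int(len(trials)),
        "n_valid": int(trials["qc_valid"].sum()),
        "rejections": {k: int(v) for k, v in counts.items()},
    }


def normalize_gain(trials: pd.DataFrame, value_cols=("amplitude_dva",)) -> pd.DataFrame:
    """Convert kinematic metrics to gains relative to first-block medians.

    For each session and hexagon direction, the baseline is the median of
    the metric over *valid* block-1 trials; gains are metric / baseline on
    every trial (including invalid ones — validity travels in ``qc_valid``,
    trials are never dropped silently).

    Raises
    ------
    ValueError
        If some direction has no valid block-1 trial (names the direction).
    """
    if "qc_valid" not in trials.columns:
        raise ValueError("run reject_trials first (qc_valid column missing)")
    df = trials.copy()
    group_cols = _session_cols(df) + ["direction"]
    base = df[(df["block"] == 1) & df["qc_valid"]]
    for col in value_cols:
        med = base.groupby(group_cols)[col].median()
        med.name = f"_baseline_{col}"
        merged = df.join(med, on=group_cols)[med.name]
        if merged.isna().any():
            missing = df.loc[merged.isna(), group_cols].drop_duplicates()
            detail = "; ".join(
                ", ".join(f"{c}={r[c]}" for c in group_cols) for _, r in missing.iterrows()
            )
            raise ValueError(f"no valid baseline trials for: {detail}")
        df[GAIN_COLS.get(col, f"{col}_gain")] = df[col] / merged
    return df


def running_average(values, window: int = 6, valid=None) -> np.ndarray:
    """Centred moving mean with a window shrinking at the edges.

    Invalid (or NaN) entries are excluded from each window's mean; windows
    containing no valid entry yield NaN.  The default window of 6 matches
    the hexagonal period of the task.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError("window exceeds series length")
    mask = np.isfinite(values)
    if valid is not None:
        mask &= np.asarray(valid, dtype=bool)
    left = window // 2
    right = window - 1 - left
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - left), min(n, i + right + 1)
        m = mask[lo:hi]
        if m.any():
            out[i] = values[lo:hi][m].mean()
    return out


def smooth_by_block(
    df: pd.DataFrame, col: str, window: int = 6, out_col: str | None = None
) -> pd.DataFrame:
    """Apply :func:`running_average` per session and block.

    Smoothing windows never span block boundaries, so block transitions
    remain sharp in the smoothed series.
    """
    out_col = out_col or f"{col}_smooth"
    df = df.copy()
    group_cols = _session_cols(df) + ["block"]
    valid = df["qc_valid"] if "qc_valid" in df else pd.Series(True, index=df.index)
    df[out_col] = np.nan
    for _, idx in df.groupby(group_cols).indices.items():
        idx = np.asarray(idx)
        df.iloc[idx, df.columns.get_loc(out_col)] = running_average(
            df[col].to_numpy()[idx], window=window, valid=valid.to_numpy()[idx]
        )
    return df


def block_transition_change(
    session: pd.DataFrame,
    from_block: int = 2,
    to_block: int = 3,
    *,
    n_edge: int = 6,
    value_col: str = "gain",
) -> float:
    """Gain change across a block transition for one session.

    mean(first ``n_edge`` trials of ``to_block``) − mean(last ``n_edge``
    trials of ``from_block``), each mean taken over valid trials among
    those ``n_edge``; NaN when either window has no valid trial (the
    participant is then excluded from group statistics).
    """
    for b in (from_block, to_block):
        if not (session["block"] == b).any():
            raise ValueError(f"block {b} not present")

    def _edge_mean(block: int, tail: bool) -> float:
        rows = session[session["block"] == block].sort_values("trial_in_block")
        rows = rows.tail(n_edge) if tail else rows.head(n_edge)
        vals = rows.loc[rows["qc_valid"], value_col]
        return float(vals.mean()) if len(vals) else np.nan

    return _edge_mean(to_block, tail=False) - _edge_mean(from_block, tail=True)


def transition_table(
    trials: pd.DataFrame, from_block: int = 2, to_block: int = 3, **kwargs
) -> pd.DataFrame:
    """Block-transition change per session over a cohort trial table."""
    rows = []
    for key, session in trials.groupby(_session_cols(trials)):
        rows.append(
            dict(
                zip(_session_cols(trials), key if isinstance(key, tuple) else (key,)),
                change=block_transition_change(session, from_block, to_block, **kwargs),
            )
        )
    return pd.DataFrame(rows)
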
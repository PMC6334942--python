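"""Summary statistics and the final analysis report.

Condition summaries carry the mean, a t-based 95% CI over participants and
the number of contributing participants; inferential contrasts use one-
sample and paired t-tests with Cohen's d (for paired designs, d uses the
standard deviation of the differences).  ``build_report`` runs the whole
pipeline on a trial table and emits a machine-readable, fully deterministic
report dictionary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model_fitting import (
    DualStateModel,
    ExponentialAdaptationModel,
    bootstrap_exponential,
    slow_ratio,
)
from .preprocessing import (
    normalize_gain,
    qc_summary,
    reject_trials,
    running_average,
    transition_table,
)

__all__ = [
    "TestResult",
    "one_sample_t",
    "paired_t",
    "condition_summary",
    "latency_summary",
    "process_gain_contrasts",
    "kinematic_change_summary",
    "awareness_summary",
    "build_report",
    "write_report",
]

BLOCK2_PERTURBATION = {"down": -0.25, "up": 0.33}


@dataclass(frozen=True)
class TestResult:
    """A t-test result: statistic, dof, two-tailed p and Cohen's d."""

    statistic: float
    dof: int
    p: float
    cohens_d: float
    n: int
    mean: float

    def summary(self) -> str:
        return (
            f"t({self.dof}) = {self.statistic:.3f}, p = {self.p:.4g}, "
            f"d = {self.cohens_d:.3f} (n = {self.n}, mean = {self.mean:.4f})"
        )


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test of the mean against ``mu0``.

    t = (mean − mu0) / (sd/√n); Cohen's d = (mean − mu0)/sd.  A zero sd is
    an error unless the mean equals mu0 exactly (then t = 0, p = 1).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 finite values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        if mean == mu0:
            return TestResult(0.0, n - 1, 1.0, 0.0, n, mean)
        raise ValueError("zero variance with nonzero effect: t undefined")
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TestResult(float(t), n - 1, p, float((mean - mu0) / sd), n, mean)


def paired_t(values_a, values_b) -> TestResult:
    """Paired t-test: one-sample test of the pairwise differences vs 0.

    Pairs with a missing member are dropped listwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 complete pairs")
    return one_sample_t(a[keep] - b[keep], 0.0)


def condition_summary(values) -> dict:
    """Mean, t-based 95% CI half-width and n over non-missing values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        return {"mean": np.nan, "ci_halfwidth": np.nan, "n": 0}
    mean = float(v.mean())
    if n == 1:
        return {"mean": mean, "ci_halfwidth": np.nan, "n": 1}
    sem = float(v.std(ddof=1) / np.sqrt(n))
    hw = float(sps.t.ppf(0.975, n - 1) * sem)
    return {"mean": mean, "ci_halfwidth": hw, "n": n}


def _block2(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["block"] == 2]


def latency_summary(trials: pd.DataFrame, block: int = 2) -> pd.DataFrame:
    """Mean saccade latency per saccade type × gain direction.

    Per-participant means over valid trials of the block first, then
    condition means with 95% CIs over participants.
    """
    df = trials[(trials["block"] == block) & trials["qc_valid"]]
    per_p = (
        df.groupby(["saccade_type", "gain_direction", "participant"])["latency_ms"]
        .mean()
        .reset_index()
    )
    rows = []
    for (styp, gdir), grp in per_p.groupby(["saccade_type", "gain_direction"]):
        rows.append(
            {"saccade_type": styp, "gain_direction": gdir}
            | condition_summary(grp["latency_ms"])
        )
    return pd.DataFrame(rows)


def process_gain_contrasts(fits: pd.DataFrame) -> dict:
    """Fast/slow process contrasts from per-participant dual-state fits.

    ``fits`` needs columns participant, saccade_type, gain_direction,
    gamma_fast, gamma_slow.  Per participant the slow ratio is computed per
    gain direction and averaged over directions, and the γ values are
    averaged over directions.  Contrasts: slow ratio vs 0.5 per saccade
    type (one-sample t) and reactive − scanning per process (paired t, with
    the slow-process difference reported as scanning − reactive).
    Participants missing a condition are dropped from affected contrasts.
    """
    fits = fits.copy()
    fits["slow_ratio"] = [
        slow_ratio((gf, gs)) for gf, gs in zip(fits["gamma_fast"], fits["gamma_slow"])
    ]
    by_type = (
        fits.groupby(["participant", "saccade_type"])[
            ["gamma_fast", "gamma_slow", "slow_ratio"]
        ]
        .mean()
        .unstack("saccade_type")
    )
    out: dict = {"per_participant": by_type, "tests": {}, "summaries": {}}
    for styp in ("reactive", "scanning"):
        ratios = by_type[("slow_ratio", styp)]
        out["tests"][f"slow_ratio_{styp}_vs_0.5"] = one_sample_t(ratios, 0.5)
        out["summaries"][f"slow_ratio_{styp}"] = condition_summary(ratios)
    slow_diff = by_type[("gamma_slow", "scanning")] - by_type[("gamma_slow", "reactive")]
    fast_diff = by_type[("gamma_fast", "reactive")] - by_type[("gamma_fast", "scanning")]
    out["tests"]["slow_gain_scanning_minus_reactive"] = paired_t(
        by_type[("gamma_slow", "scanning")], by_type[("gamma_slow", "reactive")]
    )
    out["tests"]["fast_gain_reactive_minus_scanning"] = paired_t(
        by_type[("gamma_fast", "reactive")], by_type[("gamma_fast", "scanning")]
    )
    out["summaries"]["slow_gain_diff"] = condition_summary(slow_diff)
    out["summaries"]["fast_gain_diff"] = condition_summary(fast_diff)
    return out


def kinematic_change_summary(
    trials: pd.DataFrame, window: int = 16, block: int = 2
) -> pd.DataFrame:
    """Median amplitude/velocity/duration gain change late in adaptation.

    For each participant and condition: the median normalised metric minus
    1 over the last ``window`` trials of the block (valid trials only;
    missing when fewer than 3).  Requires gain columns from
    :func:`normalize_gain` over all three kinematic metrics.
    """
    rows = []
    metrics = {"amplitude": "gain", "peak_velocity": "vel_gain", "duration": "dur_gain"}
    for (pid, styp, gdir), grp in trials[trials["block"] == block].groupby(
        ["participant", "saccade_type", "gain_direction"]
    ):
        tail = grp.sort_values("trial_in_block").tail(window)
        tail = tail[tail["qc_valid"]]
        row = {"participant": pid, "saccade_type": styp, "gain_direction": gdir}
        for name, col in metrics.items():
            row[f"{name}_change"] = (
                float(tail[col].median() - 1.0) if len(tail) >= 3 else np.nan
            )
        rows.append(row)
    per_p = pd.DataFrame(rows)
    summaries = []
    for (styp, gdir), grp in per_p.groupby(["saccade_type", "gain_direction"]):
        s = {"saccade_type": styp, "gain_direction": gdir}
        for name in metrics:
            s[f"{name}_change"] = condition_summary(grp[f"{name}_change"])
        summaries.append(s)
    out = pd.DataFrame(summaries)
    out.attrs["per_participant"] = per_p
    return out


def awareness_summary(trials: pd.DataFrame, window: int = 6) -> dict:
    """Displacement-awareness proportions and running-average series.

    Proportion of 'seen' responses per block × saccade type × gain
    direction ('missing' responses excluded from denominators), plus a
    cohort running average over ``window`` trials for plotting.
    """
    df = trials[trials["seen_response"] != "missing"].copy()
    if df.empty:
        raise ValueError("all awareness responses missing")
    df["seen"] = (df["seen_response"] == "seen").astype(float)
    table = (
        df.groupby(["block", "saccade_type", "gain_direction"])["seen"]
        .agg(proportion_seen="mean", n="count")
        .reset_index()
    )
    series = {}
    for (styp, order), grp in df.groupby(["saccade_type", "direction_order"]):
        mean_by_trial = grp.groupby("trial")["seen"].mean()
        series[f"{styp}/{order}"] = running_average(
            mean_by_trial.to_numpy(), window=window
        )
    return {"table": table, "series": series}


def _fits_block2(trials: pd.DataFrame, error_mode: str = "closed") -> pd.DataFrame:
    """Per-participant dual-state fits to each session's first adaptation block."""
    rows = []
    for (pid, styp, order), grp in trials.groupby(
        ["participant", "saccade_type", "direction_order"]
    ):
        b2 = grp[grp["block"] == 2].sort_values("trial_in_block")
        gdir = b2["gain_direction"].iloc[0]
        gains = np.where(b2["qc_valid"], b2["gain"], np.nan)
        model = DualStateModel(
            gains, b2["perturbation"].to_numpy(), error_mode=error_mode
        )
        fit = model.fit()
        rows.append(
            {
                "participant": pid,
                "saccade_type": styp,
                "direction_order": order,
                "gain_direction": gdir,
                "gamma_fast": fit.gamma_fast,
                "gamma_slow": fit.gamma_slow,
                "sse": fit.sse,
                "n_valid": fit.n_valid,
            }
        )
    return pd.DataFrame(rows)


def _exp_section(trials: pd.DataFrame, n_folds: int, seed) -> dict:
    """Condition-average exponential fits plus paired bootstrap comparisons."""
    series = {}
    participants = sorted(trials["participant"].unique())
    for (styp, gdir), grp in _block2(trials).groupby(["saccade_type", "gain_direction"]):
        n_trials = int(grp["trial_in_block"].max())
        mat = np.full((len(participants), n_trials), np.nan)
        for i, pid in enumerate(participants):
            rows = grp[(grp["participant"] == pid) & grp["qc_valid"]]
            mat[i, rows["trial_in_block"].to_numpy() - 1] = rows["gain"]
        series[f"{styp}/{gdir}"] = mat
    fits = {}
    for cond, mat in series.items():
        with warnings.catch_warnings():
            # trials invalid for every participant yield NaN in the average
            warnings.simplefilter("ignore", RuntimeWarning)
            avg = np.nanmean(mat, axis=0)
        fit = ExponentialAdaptationModel(avg).fit()
        fits[cond] = {"alpha": fit.alpha, "beta": fit.beta, "converged": fit.converged}
    comparisons = [
        (f"reactive/{d}", f"scanning/{d}")
        for d in sorted({c.split("/")[1] for c in series})
    ]
    boot = bootstrap_exponential(series, n_folds=n_folds, seed=seed, comparisons=comparisons)
    return {
        "condition_fits": fits,
        "bootstrap_p": boot.p_values,
        "bootstrap_median_diff": {
            k: {p: float(np.median(v[p])) for p in ("alpha", "beta")}
            for k, v in boot.differences.items()
        },
        "n_folds": n_folds,
    }


def build_report(
    trials: pd.DataFrame,
    *,
    seed: int = 0,
    n_folds: int = 2000,
    out_dir=None,
    figures: bool = False,
) -> dict:
    """Run the full analysis pipeline on a raw trial table.

    Steps: trial rejection → gain normalisation (amplitude, peak velocity,
    duration) → latency summary → block-transition changes → exponential
    fits with paired bootstrap → per-participant dual-state fits and
    process-gain contrasts → kinematic-change and awareness summaries.
    Identical inputs produce byte-identical JSON via :func:`write_report`.
    """
    trials = reject_trials(trials)
    trials = normalize_gain(trials, value_cols=tuple(("amplitude_dva", "peak_vel_dps", "duration_ms")))

    report: dict = {
        "meta": {
            "n_participants": int(trials["participant"].nunique()),
            "n_trials": int(len(trials)),
            "seed": seed,
            "n_folds": n_folds,
        },
        "qc": qc_summary(trials),
    }

    report["latency"] = latency_summary(trials).to_dict(orient="records")

    trans = transition_table(trials)
    trans_tests = {}
    for order, grp in trans.groupby("direction_order"):
        wide = grp.pivot(index="participant", columns="saccade_type", values="change")
        if {"reactive", "scanning"}.issubset(wide.columns):
            trans_tests[order] = asdict(
                paired_t(wide["reactive"], wide["scanning"])
            )
    report["block_transition"] = {
        "per_session": trans.to_dict(orient="records"),
        "reactive_vs_scanning": trans_tests,
    }

    report["exponential"] = _exp_section(trials, n_folds=n_folds, seed=seed)

    fits = _fits_block2(trials)
    contrasts = process_gain_contrasts(fits)
    report["dual_state"] = {
        "per_fit": fits.to_dict(orient="records"),
        "tests": {k: asdict(v) for k, v in contrasts["tests"].items()},
        "summaries": contrasts["summaries"],
    }

    kin = kinematic_change_summary(trials)
    report["kinematics"] = kin.to_dict(orient="records")

    aware = awareness_summary(trials)
    report["awareness"] = aware["table"].to_dict(orient="records")

    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        if figures:
            from . import plotting

            plotting.report_figures(trials, fits, aware, out)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    """Serialise a report deterministically (sorted keys, NaN → null)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
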
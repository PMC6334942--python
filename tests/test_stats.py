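import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from saccadapt import (
    awareness_summary,
    build_report,
    condition_summary,
    kinematic_change_summary,
    latency_summary,
    normalize_gain,
    one_sample_t,
    paired_t,
    process_gain_contrasts,
    reject_trials,
    write_report,
)


# --- t tests --------------------------------------------------------------


def test_one_sample_t_trivial_and_hand_cases():
    r = one_sample_t([0.5, 0.5, 0.5], 0.5)
    assert (r.statistic, r.p, r.cohens_d) == (0.0, 1.0, 0.0)
    r2 = one_sample_t([0.6, 0.7, 0.8], 0.5)
    assert r2.statistic == pytest.approx(0.2 / (0.1 / np.sqrt(3)))
    assert r2.dof == 2


def test_one_sample_t_matches_closed_form_oracle(rng):
    for _ in range(300):
        n = int(rng.integers(3, 30))
        v = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2), n)
        mu0 = float(rng.uniform(-1, 1))
        r = one_sample_t(v, mu0)
        t_ref, p_ref = sps.ttest_1samp(v, mu0)
        assert r.statistic == pytest.approx(float(t_ref), abs=1e-10)
        assert r.p == pytest.approx(float(p_ref), abs=1e-10)


def test_paired_t_equivalent_to_difference_test(rng):
    a = rng.normal(0.0, 1.0, 15)
    b = rng.normal(0.2, 1.0, 15)
    r = paired_t(a, b)
    ref = one_sample_t(a - b, 0.0)
    assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert r.p == pytest.approx(ref.p, abs=1e-12)


def test_paired_t_degenerate_cases():
    a = np.ones(5)
    assert paired_t(a, a).p == 1.0
    with pytest.raises(ValueError):
        paired_t(np.array([2.0, 3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0, 4.0]))
    with pytest.raises(ValueError):
        paired_t(np.array([1.0, np.nan]), np.array([2.0, 3.0]))


def test_one_sample_t_validation():
    with pytest.raises(ValueError):
        one_sample_t([1.0], 0.0)
    with pytest.raises(ValueError):
        one_sample_t([1.0, 1.0, 1.0], 0.0)  # zero sd, nonzero effect


def test_condition_summary_ci_convention():
    vals = [1.0, 2.0, 3.0, 4.0]
    s = condition_summary(vals)
    sem = np.std(vals, ddof=1) / 2.0
    assert s["ci_halfwidth"] == pytest.approx(sps.t.ppf(0.975, 3) * sem)
    assert s["n"] == 4


# --- pipeline summaries ---------------------------------------------------


@pytest.fixture(scope="module")
def prepared(small_cohort):
    df = reject_trials(small_cohort)
    return normalize_gain(df, value_cols=("amplitude_dva", "peak_vel_dps", "duration_ms"))


def test_latency_summary_recovers_generator_truth(prepared):
    table = latency_summary(prepared)
    means = table.groupby(
        table["saccade_type"]
    )["mean"].mean()
    assert abs(means["reactive"] - 195) < 15
    assert abs(means["scanning"] - 305) < 15
    assert (table["n"] == 6).all()


def test_latency_summary_constant_input():
    df = pd.DataFrame(
        {
            "participant": [0, 0, 1, 1],
            "saccade_type": "reactive",
            "gain_direction": "down",
            "block": 2,
            "latency_ms": 200.0,
            "qc_valid": True,
        }
    )
    table = latency_summary(df)
    assert table.loc[0, "mean"] == pytest.approx(200.0)
    assert table.loc[0, "ci_halfwidth"] == pytest.approx(0.0)


def test_process_gain_contrasts_identical_fits_are_null():
    rows = []
    for pid in range(5):
        for styp in ("reactive", "scanning"):
            for gdir in ("down", "up"):
                rows.append(
                    {"participant": pid, "saccade_type": styp, "gain_direction": gdir,
                     "gamma_fast": 0.3 + 0.01 * pid, "gamma_slow": 0.3 + 0.01 * pid}
                )
    out = process_gain_contrasts(pd.DataFrame(rows))
    assert out["tests"]["slow_gain_scanning_minus_reactive"].p == 1.0
    assert out["tests"]["fast_gain_reactive_minus_scanning"].p == 1.0
    assert out["summaries"]["slow_gain_diff"]["mean"] == pytest.approx(0.0)
    # identical processes: slow ratio exactly 0.5 in both saccade types
    assert out["summaries"]["slow_ratio_reactive"]["mean"] == pytest.approx(0.5)


def test_contrast_direction_recovered_from_generative_truth(rng):
    """Cohorts built with scanning-slow dominance recover that direction."""
    hits = 0
    for rep in range(40):
        rows = []
        for pid in range(12):
            for styp, (gf, gs) in (("reactive", (0.5, 0.5)), ("scanning", (0.2, 0.65))):
                for gdir in ("down", "up"):
                    rows.append(
                        {"participant": pid, "saccade_type": styp, "gain_direction": gdir,
                         "gamma_fast": max(gf + rng.normal(0, 0.1), 0.0),
                         "gamma_slow": max(gs + rng.normal(0, 0.1), 0.0)}
                    )
        out = process_gain_contrasts(pd.DataFrame(rows))
        sr = out["summaries"]
        if sr["slow_ratio_scanning"]["mean"] > sr["slow_ratio_reactive"]["mean"]:
            hits += 1
    assert hits >= 38  # >= 95% of replicates


def test_kinematic_change_zero_for_unadapted_noiseless():
    from saccadapt import build_protocol
    from saccadapt.synthetic_data import simulate_session

    proto = build_protocol("reactive", "down-up",
                           displacement_forward=0.0, displacement_backward=0.0)
    df = simulate_session(proto, noise_sd=0.0, kin_noise_sd=0.0, seed=0)
    df = normalize_gain(reject_trials(df),
                        value_cols=("amplitude_dva", "peak_vel_dps", "duration_ms"))
    out = kinematic_change_summary(df)
    for col in ("amplitude_change", "peak_velocity_change", "duration_change"):
        for cell in out[col]:
            assert cell["mean"] == pytest.approx(0.0, abs=1e-9)


def test_kinematic_change_velocity_dominates_gain_down(prepared):
    out = kinematic_change_summary(prepared)
    down = out[out["gain_direction"] == "down"]
    for _, row in down.iterrows():
        assert row["amplitude_change"]["mean"] < -0.02
        assert abs(row["peak_velocity_change"]["mean"]) > abs(row["duration_change"]["mean"])


def test_awareness_proportions(prepared):
    out = awareness_summary(prepared)
    table = out["table"]
    base = table[table["block"].isin([1, 4])]["proportion_seen"]
    assert (base < 0.06).all()
    b2 = table[table["block"] == 2]
    scan = b2[b2["saccade_type"] == "scanning"]["proportion_seen"].mean()
    react = b2[b2["saccade_type"] == "reactive"]["proportion_seen"].mean()
    assert scan > react


def test_awareness_all_unseen():
    df = pd.DataFrame(
        {
            "block": [2] * 8,
            "saccade_type": "reactive",
            "direction_order": "down-up",
            "gain_direction": "down",
            "trial": range(1, 9),
            "seen_response": "unseen",
        }
    )
    out = awareness_summary(df)
    assert (out["table"]["proportion_seen"] == 0).all()
    with pytest.raises(ValueError):
        awareness_summary(df.assign(seen_response="missing"))


def test_awareness_simple_proportion():
    responses = ["seen"] * 24 + ["unseen"] * 72
    df = pd.DataFrame(
        {
            "block": 2, "saccade_type": "reactive", "direction_order": "down-up",
            "gain_direction": "down", "trial": range(1, 97), "seen_response": responses,
        }
    )
    out = awareness_summary(df)
    assert out["table"]["proportion_seen"].iloc[0] == pytest.approx(0.25)


# --- report ---------------------------------------------------------------


def test_report_end_to_end_and_deterministic(small_cohort, tmp_path):
    rep = build_report(small_cohort, seed=5, n_folds=200)
    for section in ("meta", "qc", "latency", "block_transition", "exponential",
                    "dual_state", "kinematics", "awareness"):
        assert section in rep
    assert rep["meta"]["n_participants"] == 6
    assert rep["qc"]["n_valid"] > 0
    write_report(rep, tmp_path / "a.json")
    rep2 = build_report(small_cohort, seed=5, n_folds=200)
    write_report(rep2, tmp_path / "b.json")
    assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()


def test_report_permutation_invariant_over_participants(small_cohort):
    shuffled = small_cohort.sample(frac=1.0, random_state=4).reset_index(drop=True)
    a = build_report(small_cohort, seed=1, n_folds=100)
    b = build_report(shuffled, seed=1, n_folds=100)
    assert a["dual_state"]["tests"] == b["dual_state"]["tests"]
    assert a["latency"] == b["latency"]
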
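"""Synthetic sessions for the hexagonal saccadic-adaptation experiment.

Everything downstream of raw data acquisition (detection, QC, gain
normalisation, model fitting, reporting) is testable against this module:
it generates protocol descriptions, dual-state trial-by-trial gain series
with observation noise, per-trial kinematics obeying the saccadic main
sequence, awareness judgements, and (on request) raw 1000-Hz gaze traces
with injectable blinks and amplitude outliers.

The cohort defaults emulate the study conditions of the hexagonal
global-adaptation experiment: 12 participants, four sessions each
(reactive/scanning × down-up/up-down block order), blocks of 48/96/96/48
trials, perturbations −0.25 / +0.33 in relative-gain units, reactive
latencies around 195 ms and scanning latencies around 305 ms, and
process-gain truths whose slow-process share is ≈0.55 for reactive and
≈0.75 for scanning saccades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dual_state import DEFAULT_RATES, DualStateParams, DualStateTrace
from .protocol import ProtocolSpec, build_protocol
from .saccade_metrics import GazeRecording

__all__ = [
    "MainSequence",
    "COHORT_GAMMAS",
    "simulate_observed_gains",
    "synthesize_gaze_trial",
    "simulate_session",
    "simulate_cohort",
    "synthesize_trial_gaze",
]


@dataclass(frozen=True)
class MainSequence:
    """Saturating main-sequence law for saccade kinematics.

    Peak velocity V(A) = vmax·(1 − e^(−A/c)) with standard oculomotor
    defaults vmax = 500 °/s and c = 14°.  With a minimum-jerk velocity
    profile the duration follows as D = 1.875·A / V(A).
    """

    vmax: float = 500.0  # deg/s
    c: float = 14.0  # deg

    def peak_velocity(self, amplitude: float) -> float:
        return self.vmax * (1.0 - np.exp(-amplitude / self.c))

    def duration_ms(self, amplitude: float) -> float:
        return 1.875 * amplitude / self.peak_velocity(amplitude) * 1000.0


def simulate_observed_gains(trace: DualStateTrace, noise_sd: float, seed=None) -> np.ndarray:
    """Observed per-trial gains: 1 + adaptation(i) + Gaussian noise.

    ``noise_sd`` is the trial-to-trial observation noise in gain units;
    identical seeds give bit-identical sequences.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    return 1.0 + trace.adaptation + rng.normal(0.0, noise_sd, size=len(trace))


def synthesize_gaze_trial(
    start_pos,
    target_pos,
    executed_amplitude: float,
    latency_ms: float = 200.0,
    main_seq: MainSequence = MainSequence(),
    sample_rate_hz: float = 1000.0,
    noise_sd_pos: float = 0.0,
    seed=None,
    total_duration_ms: float | None = None,
    blink_ms: tuple[float, float] | None = None,
) -> GazeRecording:
    """Synthesize a single-saccade gaze trace.

    Gaze fixates ``start_pos`` until ``latency_ms``, then executes one
    saccade of ``executed_amplitude`` dva towards ``target_pos`` with a
    minimum-jerk position profile whose peak velocity obeys the main
    sequence.  Additive isotropic Gaussian positional noise is applied to
    every sample; ``blink_ms = (onset, duration)`` marks a span of samples
    invalid (NaN position).

    Raises
    ------
    ValueError
        If the amplitude is non-positive or the latency exceeds the trace.
    """
    if executed_amplitude <= 0:
        raise ValueError("executed_amplitude must be positive")
    start = np.asarray(start_pos, dtype=float)
    target = np.asarray(target_pos, dtype=float)
    vec = target - start
    dist = np.hypot(*vec)
    if dist == 0:
        raise ValueError("target must differ from start position")
    u = vec / dist

    duration = main_seq.duration_ms(executed_amplitude)
    if total_duration_ms is None:
        total_duration_ms = latency_ms + duration + 200.0
    if latency_ms >= total_duration_ms:
        raise ValueError("latency exceeds trace duration")

    dt = 1000.0 / sample_rate_hz
    n = int(round(total_duration_ms / dt)) + 1
    t = np.arange(n) * dt
    tau = np.clip((t - latency_ms) / duration, 0.0, 1.0)
    s = executed_amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    pos = start[None, :] + u[None, :] * s[:, None]

    rng = np.random.default_rng(seed)
    if noise_sd_pos > 0:
        pos = pos + rng.normal(0.0, noise_sd_pos, size=pos.shape)

    valid = np.ones(n, dtype=bool)
    x, y = pos[:, 0].copy(), pos[:, 1].copy()
    if blink_ms is not None:
        b0, bdur = blink_ms
        mask = (t >= b0) & (t < b0 + bdur)
        valid[mask] = False
        x[mask] = np.nan
        y[mask] = np.nan
    return GazeRecording(t_ms=t, x=x, y=y, valid=valid, sample_rate=sample_rate_hz)


# ---------------------------------------------------------------------------
# Cohort-level generative truths.
#
# Process-gain truths per (saccade_type, gain direction), derived from an
# additive decomposition of the observed cell structure of per-process mean
# gain (γ_fast + γ_slow)/2: 0.576 (reactive) / 0.509 (scanning) across
# directions, 0.784 (gain-down) / 0.301 (gain-up) across types, split by a
# slow-process share of 0.547 for reactive and 0.749 for scanning saccades.
# These truths reproduce the target condition contrasts: fast-process gain
# ≈0.27 larger for reactive than scanning, slow-process gain ≈0.13 larger
# for scanning than reactive, averaged over gain directions.
# ---------------------------------------------------------------------------

def _gammas(process_mean: float, slow_ratio: float) -> tuple[float, float]:
    total = 2.0 * process_mean
    return total * (1.0 - slow_ratio), total * slow_ratio


COHORT_GAMMAS: dict[tuple[str, str], tuple[float, float]] = {
    ("reactive", "down"): _gammas(0.8175, 0.547),
    ("reactive", "up"): _gammas(0.3345, 0.547),
    ("scanning", "down"): _gammas(0.7505, 0.749),
    ("scanning", "up"): _gammas(0.2675, 0.749),
}

#: latency truth per saccade type (ms)
LATENCY_MEANS = {"reactive": 195.0, "scanning": 305.0}

#: fraction of amplitude change carried by peak velocity (rest by duration)
VELOCITY_SHARE = {"down": 0.8, "up": 0.5, "none": 0.5}


def _simulate_varying_gamma(rates: DualStateParams, p, gamma_fast, gamma_slow):
    """Closed-loop dual-state recursion with per-trial process gains."""
    n = len(p)
    af, bf, as_, bs = rates.rates
    xf = xs = out = 0.0
    adapt = np.empty(n)
    for i in range(n):
        e = p[i] - out
        xf = af * e + bf * xf
        xs = as_ * e + bs * xs
        out = gamma_fast[i] * xf + gamma_slow[i] * xs
        adapt[i] = out
    return adapt


def _awareness_probability(protocol: ProtocolSpec) -> np.ndarray:
    """Per-trial probability of reporting the displacement as 'seen'.

    Near zero in baseline blocks; in adaptation blocks it starts high and
    decays as adaptation nulls the visual error, with higher awareness for
    scanning saccades (persistent visual references) and for gain-down
    displacements (jump across the fovea).
    """
    probs = []
    for block in protocol.blocks:
        direction = protocol.block_gain_direction(block.index)
        j = np.arange(block.n_trials)
        if direction == "none":
            probs.append(np.full(block.n_trials, 0.02))
        else:
            amp = 0.25
            if protocol.saccade_type == "scanning":
                amp += 0.20
            if direction == "down":
                amp += 0.15
            probs.append(0.05 + amp * np.exp(-j / 30.0))
    return np.concatenate(probs)


def simulate_session(
    protocol: ProtocolSpec,
    gammas=None,
    *,
    rates: DualStateParams = DEFAULT_RATES,
    noise_sd: float = 0.05,
    baseline_amplitude: float = 10.0,
    latency_mean_ms: float | None = None,
    latency_sd_ms: float = 20.0,
    startpoint_sd: float = 0.3,
    main_seq: MainSequence = MainSequence(),
    kin_noise_sd: float = 0.02,
    blink_rate: float = 0.0,
    n_blinks: int = 0,
    n_outliers: int = 0,
    outlier_scale: float = 2.0,
    participant: int = 0,
    seed=None,
) -> pd.DataFrame:
    """Simulate one full four-block session as a trial table.

    Parameters
    ----------
    protocol : ProtocolSpec
    gammas : mapping or tuple, optional
        Process gains (γ_fast, γ_slow).  A mapping keyed by gain direction
        ("down"/"up") lets the two adaptation blocks use different truths;
        a single tuple applies everywhere.  Defaults to the cohort truths
        for the protocol's saccade type.
    noise_sd : float
        Trial-to-trial observation noise on gain (default 0.05).
    n_blinks, n_outliers : int
        Exact numbers of artificially contaminated trials (disjoint sets):
        blink trials are flagged, outlier trials have their amplitude
        multiplied by ``outlier_scale``.  ``blink_rate`` adds further random
        blinks on top (default 0).

    Returns
    -------
    pandas.DataFrame
        One row per trial with design, kinematic, latency, awareness and
        contamination columns.
    """
    rng = np.random.default_rng(seed)
    n = protocol.n_trials
    geom = protocol.trial_geometry()
    block = protocol.block_index
    p = protocol.perturbation

    if gammas is None:
        gammas = {
            d: COHORT_GAMMAS[(protocol.saccade_type, d)] for d in ("down", "up")
        }
    if not isinstance(gammas, dict):
        gammas = {"down": tuple(gammas), "up": tuple(gammas)}

    # per-trial gamma series: adaptation blocks use their own direction's
    # truth; baseline blocks inherit the neighbouring adaptation block's
    gdir = np.array([protocol.block_gain_direction(b) for b in block])
    first_dir, second_dir = protocol.direction_order.split("-")
    per_trial_dir = np.where(
        gdir != "none", gdir, np.where(block == 1, first_dir, second_dir)
    )
    gf = np.array([gammas[d][0] for d in per_trial_dir])
    gs = np.array([gammas[d][1] for d in per_trial_dir])

    adaptation = _simulate_varying_gamma(rates, p, gf, gs)
    gain = 1.0 + adaptation + rng.normal(0.0, noise_sd, n)
    amplitude = baseline_amplitude * gain

    # kinematics: relative amplitude change is split between peak velocity
    # and duration according to the gain direction's velocity share, with
    # the min-jerk constraint amplitude = peak_velocity * duration / 1.875
    vpk0 = main_seq.peak_velocity(baseline_amplitude)
    dur0 = main_seq.duration_ms(baseline_amplitude)
    share = np.array([VELOCITY_SHARE[d] for d in gdir])
    rel = amplitude / baseline_amplitude
    kin_jitter = np.exp(rng.normal(0.0, kin_noise_sd, n))
    peak_vel = vpk0 * rel**share * kin_jitter
    duration = dur0 * rel ** (1.0 - share) / kin_jitter

    if latency_mean_ms is None:
        latency_mean_ms = LATENCY_MEANS[protocol.saccade_type]
    latency = rng.normal(latency_mean_ms, latency_sd_ms, n)

    timing = protocol.timing
    fixation = timing.fixation_min_ms + rng.exponential(
        timing.fixation_mean_ms - timing.fixation_min_ms, n
    )
    flash_ms = fixation  # flash onset serves as the go signal

    start = geom["fix"] + rng.normal(0.0, startpoint_sd, (n, 2))

    seen_prob = _awareness_probability(protocol)
    seen = rng.random(n) < seen_prob
    missing = rng.random(n) < 0.02
    response = np.where(missing, "missing", np.where(seen, "seen", "unseen"))

    blink = rng.random(n) < blink_rate
    contaminate = rng.permutation(n)[: n_blinks + n_outliers]
    blink[contaminate[:n_blinks]] = True
    outlier_idx = contaminate[n_blinks : n_blinks + n_outliers]
    amplitude[outlier_idx] *= outlier_scale

    trial_in_block = np.concatenate(
        [np.arange(1, b.n_trials + 1) for b in protocol.blocks]
    )
    return pd.DataFrame(
        {
            "participant": participant,
            "saccade_type": protocol.saccade_type,
            "direction_order": protocol.direction_order,
            "block": block,
            "trial_in_block": trial_in_block,
            "trial": np.arange(1, n + 1),
            "direction": geom["direction"],
            "gain_direction": gdir,
            "perturbation": p,
            "fix_x": geom["fix"][:, 0],
            "fix_y": geom["fix"][:, 1],
            "goal_pre_x": geom["goal_pre"][:, 0],
            "goal_pre_y": geom["goal_pre"][:, 1],
            "goal_post_x": geom["goal_post"][:, 0],
            "goal_post_y": geom["goal_post"][:, 1],
            "flash_ms": flash_ms,
            "start_x": start[:, 0],
            "start_y": start[:, 1],
            "amplitude_dva": amplitude,
            "peak_vel_dps": peak_vel,
            "duration_ms": duration,
            "latency_ms": latency,
            "blink": blink,
            "seen_response": response,
        }
    )


def simulate_cohort(
    n_participants: int = 12,
    *,
    seed=None,
    gamma_sd: float = 0.12,
    latency_participant_sd: float = 10.0,
    noise_sd: float = 0.05,
    blink_rate: float = 0.02,
    **session_kwargs,
) -> pd.DataFrame:
    """Simulate a full cohort: every participant runs all four sessions.

    Participant-level heterogeneity: process gains are drawn per participant
    and condition as truth + N(0, ``gamma_sd``) clipped at 0, and each
    participant carries a latency offset N(0, ``latency_participant_sd``).

    Returns the concatenated trial table for the whole cohort.
    """
    root = np.random.SeedSequence(seed)
    frames = []
    for pid, pseed in enumerate(root.spawn(n_participants)):
        rng = np.random.default_rng(pseed)
        lat_offset = rng.normal(0.0, latency_participant_sd)
        gammas_p = {
            key: tuple(np.clip(rng.normal(val, gamma_sd), 0.0, None))
            for key, val in COHORT_GAMMAS.items()
        }
        for saccade_type in ("reactive", "scanning"):
            for order in ("down-up", "up-down"):
                protocol = build_protocol(saccade_type, order)
                frames.append(
                    simulate_session(
                        protocol,
                        gammas={
                            d: gammas_p[(saccade_type, d)] for d in ("down", "up")
                        },
                        noise_sd=noise_sd,
                        latency_mean_ms=LATENCY_MEANS[saccade_type] + lat_offset,
                        blink_rate=blink_rate,
                        participant=pid,
                        seed=rng.integers(2**31),
                        **session_kwargs,
                    )
                )
    return pd.concat(frames, ignore_index=True)


def synthesize_trial_gaze(
    row: pd.Series,
    *,
    main_seq: MainSequence = MainSequence(),
    sample_rate_hz: float = 1000.0,
    noise_sd_pos: float = 0.01,
    seed=None,
) -> GazeRecording:
    """Raw gaze trace for one trial row of a simulated session.

    The trace fixates the trial's (noisy) start point until flash onset plus
    the trial's latency, then executes a saccade of the trial's amplitude
    towards the pre-displacement goal.  Blink trials get a 100-ms invalid
    gap during the movement.
    """
    onset = float(row["flash_ms"] + row["latency_ms"])
    blink = (onset - 20.0, 100.0) if bool(row.get("blink", False)) else None
    return synthesize_gaze_trial(
        (row["start_x"], row["start_y"]),
        (row["goal_pre_x"], row["goal_pre_y"]),
        float(row["amplitude_dva"]),
        latency_ms=onset,
        main_seq=main_seq,
        sample_rate_hz=sample_rate_hz,
        noise_sd_pos=noise_sd_pos,
        seed=seed,
        blink_ms=blink,
    )
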
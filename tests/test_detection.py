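import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saccadapt import (
    DegenerateTraceError,
    GazeRecording,
    MainSequence,
    SaccadeEvent,
    compute_velocity,
    detect_saccades,
    robust_velocity_std,
    saccade_latency,
    synthesize_gaze_trial,
)


def make_trace(x, y=None, fs=1000.0):
    n = len(x)
    x = np.asarray(x, float)
    y = np.zeros(n) if y is None else np.asarray(y, float)
    return GazeRecording(
        t_ms=np.arange(n) * 1000.0 / fs, x=x, y=y, valid=np.ones(n, bool), sample_rate=fs
    )


# --- velocity -------------------------------------------------------------


def test_velocity_zero_on_constant_position():
    vx, vy, speed = compute_velocity(make_trace(np.full(50, 3.0)))
    np.testing.assert_allclose(speed, 0.0, atol=1e-12)


def test_velocity_exact_on_linear_ramp():
    # x(t) = k t with k in dva/s: stencil returns exactly k in the interior
    k = 37.0
    t_s = np.arange(100) / 1000.0
    vx, _, _ = compute_velocity(make_trace(k * t_s))
    np.testing.assert_allclose(vx, k, rtol=1e-9)


def test_velocity_spike_response_is_local_and_symmetric():
    x = np.zeros(21)
    x[10] = 1.0  # single-sample spike
    vx, _, _ = compute_velocity(make_trace(x))
    dt = 1e-3
    np.testing.assert_allclose(vx[8], 1 / (6 * dt))
    np.testing.assert_allclose(vx[9], 1 / (6 * dt))
    np.testing.assert_allclose(vx[11], -1 / (6 * dt))
    np.testing.assert_allclose(vx[12], -1 / (6 * dt))
    assert np.all(vx[3:8] == 0) and np.all(vx[13:-2] == 0)
    assert vx[10] == 0


def test_velocity_requires_five_samples():
    with pytest.raises(ValueError):
        compute_velocity(make_trace(np.zeros(4)))


# --- robust std -----------------------------------------------------------


def test_robust_std_hand_cases():
    assert robust_velocity_std(np.zeros(10)) == 0.0
    assert robust_velocity_std(np.array([-1.0, 0.0, 1.0])) == pytest.approx(1.0)


def test_robust_std_gaussian_relation(rng):
    # for N(0, s): median(v^2) = s^2 * median(chi2_1), median(v) ~ 0
    from scipy.stats import chi2

    s = 3.7
    v = rng.normal(0, s, 100_000)
    expected = s * np.sqrt(chi2.ppf(0.5, 1))
    assert robust_velocity_std(v) == pytest.approx(expected, rel=0.05)


# --- detection ------------------------------------------------------------


def test_flat_noisy_trace_has_no_saccades(rng):
    trace = make_trace(rng.normal(0, 0.01, 600), rng.normal(0, 0.01, 600))
    assert detect_saccades(trace) == []


def test_degenerate_trace_raises():
    with pytest.raises(DegenerateTraceError):
        detect_saccades(make_trace(np.zeros(100)))


def test_single_synthetic_saccade_detected_accurately():
    trace = synthesize_gaze_trial(
        (0.0, -10.0), (-8.66, -5.0), 10.0, latency_ms=200.0, noise_sd_pos=0.01, seed=5
    )
    events = detect_saccades(trace)
    assert len(events) == 1
    ev = events[0]
    assert abs(ev.onset_ms - 200.0) <= 6.0
    assert ev.amplitude == pytest.approx(10.0, rel=0.05)
    assert ev.peak_velocity >= ev.amplitude / ev.duration * 1000.0  # peak >= mean


def test_two_saccades_detected_in_order():
    ms = MainSequence()
    a = synthesize_gaze_trial((0, 0), (10, 0), 10.0, latency_ms=150.0, noise_sd_pos=0.008,
                              seed=2, total_duration_ms=1000.0)
    # second saccade 500 ms after the first, back along x
    tau = np.clip((a.t_ms - 650.0) / ms.duration_ms(8.0), 0, 1)
    x = a.x - 8.0 * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    trace = GazeRecording(t_ms=a.t_ms, x=x, y=a.y, valid=a.valid)
    events = detect_saccades(trace)
    assert len(events) == 2
    assert events[0].onset_ms < events[1].onset_ms
    assert abs(events[1].onset_ms - 650.0) <= 6.0


def brute_force_detect(trace, lambda_thresh=6.0, min_duration_ms=6.0, merge_gap_ms=20.0):
    """Naive reference: direct per-sample scan of the threshold inequality."""
    vx, vy, _ = compute_velocity(trace)
    sx = robust_velocity_std(vx)
    sy = robust_velocity_std(vy)
    runs = []
    current = None
    for i in range(len(trace)):
        above = (
            np.isfinite(vx[i])
            and np.isfinite(vy[i])
            and (vx[i] / (lambda_thresh * sx)) ** 2 + (vy[i] / (lambda_thresh * sy)) ** 2 > 1
        )
        if above:
            if current is None:
                current = [i, i]
            else:
                current[1] = i
        elif current is not None:
            runs.append(tuple(current))
            current = None
    if current is not None:
        runs.append(tuple(current))
    merged = []
    for run in runs:
        if merged and trace.t_ms[run[0]] - trace.t_ms[merged[-1][1]] < merge_gap_ms:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    min_samples = int(np.ceil(min_duration_ms * trace.sample_rate / 1000.0))
    return [(a, b) for a, b in merged if b - a + 1 >= min_samples]


def test_detector_matches_brute_force_reference(rng):
    """Event boundaries equal a naive threshold-scan on random traces."""
    for _ in range(60):
        n = int(rng.integers(300, 2000))
        amp = float(rng.uniform(3, 13))
        lat = float(rng.uniform(50, n - 200))
        angle = rng.uniform(0, 2 * np.pi)
        target = (amp * np.cos(angle), amp * np.sin(angle))
        trace = synthesize_gaze_trial(
            (0, 0), target, amp, latency_ms=lat, noise_sd_pos=float(rng.uniform(0.005, 0.03)),
            seed=int(rng.integers(2**31)), total_duration_ms=float(n - 1),
        )
        events = detect_saccades(trace)
        expected = brute_force_detect(trace)
        got = [
            (int(np.searchsorted(trace.t_ms, e.onset_ms)), int(np.searchsorted(trace.t_ms, e.offset_ms)))
            for e in events
        ]
        assert got == expected


def test_detector_rotation_invariant():
    """Rotating a trace leaves event count and durations unchanged."""
    base = synthesize_gaze_trial((0, 0), (10, 0), 10.0, latency_ms=200.0,
                                 noise_sd_pos=0.015, seed=77)
    ref = detect_saccades(base)
    for angle in np.deg2rad([15, 45, 90, 137, 228]):
        c, s = np.cos(angle), np.sin(angle)
        x = c * base.x - s * base.y
        y = s * base.x + c * base.y
        rot = GazeRecording(t_ms=base.t_ms, x=x, y=y, valid=base.valid)
        events = detect_saccades(rot)
        assert len(events) == len(ref)
        for e, r in zip(events, ref):
            assert e.duration == r.duration


def test_blink_gap_splits_detection():
    trace = synthesize_gaze_trial(
        (0, 0), (10, 0), 10.0, latency_ms=200.0, noise_sd_pos=0.01, seed=9,
        blink_ms=(190.0, 120.0),
    )
    # the saccade is inside the blink: no event may span the invalid gap
    events = detect_saccades(trace)
    for e in events:
        i0 = int(np.searchsorted(trace.t_ms, e.onset_ms))
        i1 = int(np.searchsorted(trace.t_ms, e.offset_ms))
        assert trace.valid[i0 : i1 + 1].all()


@settings(derandomize=True, max_examples=20, deadline=None)
@given(amp=st.floats(3.0, 13.0))
def test_detected_amplitude_tracks_requested(amp):
    trace = synthesize_gaze_trial((0, 0), (0, 12), amp, latency_ms=150.0,
                                  noise_sd_pos=0.005, seed=3)
    events = detect_saccades(trace)
    assert len(events) == 1
    assert events[0].amplitude == pytest.approx(amp, rel=0.05)


# --- latency --------------------------------------------------------------


def _event(onset):
    return SaccadeEvent(onset, onset + 50, 10.0, 300.0, 50.0, (0, 0), (10, 0))


def test_latency_subtraction_and_anticipatory_flag():
    assert saccade_latency(_event(450.0), 250.0) == pytest.approx(200.0)
    with pytest.warns(UserWarning, match="anticipatory"):
        assert saccade_latency(_event(240.0), 250.0) == pytest.approx(-10.0)
    with pytest.raises(ValueError):
        saccade_latency(_event(450.0), np.nan)


def test_latency_batch_recovers_generator_mean(rng):
    lats = rng.normal(195, 20, 80)
    measured = [saccade_latency(_event(250.0 + l), 250.0) for l in lats]
    sem = 20 / np.sqrt(80)
    assert abs(np.mean(measured) - 195) < 2 * sem + abs(np.mean(lats) - 195)
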
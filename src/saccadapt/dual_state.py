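"""Dual-state (multi-rate) model of trial-by-trial motor adaptation.

The model decomposes adaptation into a fast process (large learning rate,
weak retention — associated with explicit learning) and a slow process
(small learning rate, strong retention — implicit learning).  On trial *i*
with error signal ε(i):

    state_fast(i) = α_fast · ε(i) + β_fast · state_fast(i−1)
    state_slow(i) = α_slow · ε(i) + β_slow · state_slow(i−1)
    adaptation(i) = γ_fast · state_fast(i) + γ_slow · state_slow(i)

All quantities are in relative-gain units (deviation from baseline gain 1);
perturbations are p = −0.25 (gain-down) or p = +0.33 (gain-up).  The γ
parameters scale each process's contribution to the observable output and
are the quantities of interest when the learning/retention rates are fixed.

The error signal is computed closed-loop by default,
ε(i) = p(i) − adaptation(i−1), i.e. the model corrects the residual error of
its own current output; an observed-error mode driven by measured gains is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DualStateParams",
    "DualStateTrace",
    "DEFAULT_RATES",
    "simulate_dual_state",
    "steady_state_adaptation",
]


@dataclass(frozen=True)
class DualStateParams:
    """Learning/retention rates and process gains of the dual-state model.

    Rates default to the canonical fixed values used for saccadic
    adaptation: fast learn 0.21, fast retention 0.59, slow learn 0.02,
    slow retention 0.992.
    """

    alpha_fast: float = 0.21
    beta_fast: float = 0.59
    alpha_slow: float = 0.02
    beta_slow: float = 0.992
    gamma_fast: float = 1.0
    gamma_slow: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_fast", "alpha_slow"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {a}")
        for name in ("beta_fast", "beta_slow"):
            b = getattr(self, name)
            if not 0 < b < 1:
                raise ValueError(f"{name} must be in (0, 1), got {b}")
        if self.alpha_fast <= self.alpha_slow:
            raise ValueError("fast process must learn faster than slow (alpha_fast > alpha_slow)")
        if self.beta_fast >= self.beta_slow:
            raise ValueError("fast process must forget faster than slow (beta_fast < beta_slow)")
        if not (np.isfinite(self.gamma_fast) and np.isfinite(self.gamma_slow)):
            raise ValueError("gamma values must be finite")

    def with_gammas(self, gamma_fast: float, gamma_slow: float) -> "DualStateParams":
        return replace(self, gamma_fast=gamma_fast, gamma_slow=gamma_slow)

    @property
    def rates(self) -> tuple[float, float, float, float]:
        return (self.alpha_fast, self.beta_fast, self.alpha_slow, self.beta_slow)


#: canonical fixed rates with unit process gains
DEFAULT_RATES = DualStateParams()


@dataclass(frozen=True)
class DualStateTrace:
    """Trial-indexed trajectories of the dual-state recursion (gain units)."""

    state_fast: np.ndarray
    state_slow: np.ndarray
    adaptation: np.ndarray
    error: np.ndarray
    perturbation: np.ndarray

    def __len__(self) -> int:
        return len(self.adaptation)


def simulate_dual_state(
    params: DualStateParams,
    perturbations,
    *,
    error_mode: str = "closed",
    observed_gains=None,
) -> DualStateTrace:
    """Run the dual-state recursion over a perturbation schedule.

    Parameters
    ----------
    params : DualStateParams
        Rates and process gains.
    perturbations : array-like
        Per-trial perturbation p(i) in relative-gain units.
    error_mode : {"closed", "observed"}
        ``closed`` (default): ε(i) = p(i) − adaptation(i−1), with adaptation
        the model's own γ-weighted output.  ``observed``: ε(i) = p(i) −
        (observed_gain(i−1) − 1), driven by measured behaviour.
    observed_gains : array-like, required for ``error_mode="observed"``
        Measured per-trial gains; NaN entries fall back to the model's own
        output for that trial.

    Returns
    -------
    DualStateTrace
        States, error, adaptation and perturbation, all of input length.
    """
    p = np.asarray(perturbations, dtype=float)
    if p.size == 0:
        raise ValueError("perturbation sequence is empty")
    if error_mode not in ("closed", "observed"):
        raise ValueError(f"unknown error_mode {error_mode!r}")
    obs_dev = None
    if error_mode == "observed":
        if observed_gains is None:
            raise ValueError("observed_gains required for error_mode='observed'")
        obs_dev = np.asarray(observed_gains, dtype=float) - 1.0
        if obs_dev.shape != p.shape:
            raise ValueError("observed_gains must match perturbation length")

    af, bf, as_, bs = params.rates
    gf, gs = params.gamma_fast, params.gamma_slow
    n = p.size
    xf = np.empty(n)
    xs = np.empty(n)
    adapt = np.empty(n)
    err = np.empty(n)
    xf_prev = 0.0
    xs_prev = 0.0
    out_prev = 0.0  # adaptation(0) = 0 with zero initial states
    for i in range(n):
        if obs_dev is not None and i > 0 and np.isfinite(obs_dev[i - 1]):
            e = p[i] - obs_dev[i - 1]
        else:
            e = p[i] - out_prev
        xf_prev = af * e + bf * xf_prev
        xs_prev = as_ * e + bs * xs_prev
        out_prev = gf * xf_prev + gs * xs_prev
        xf[i] = xf_prev
        xs[i] = xs_prev
        adapt[i] = out_prev
        err[i] = e
    return DualStateTrace(
        state_fast=xf, state_slow=xs, adaptation=adapt, error=err, perturbation=p
    )


def steady_state_adaptation(params: DualStateParams, p: float) -> float:
    """Analytic fixed point of the closed-loop recursion under constant p.

    Writing the coupled update as x(i) = A·x(i−1) + b with
    ε(i) = p − γᵀx(i−1), the fixed point is x* = (I − A)⁻¹ b and the
    steady-state adaptation is γᵀx*.  Requires the spectral radius of A to
    be below one (guaranteed for admissible rates and moderate γ).
    """
    af, bf, as_, bs = params.rates
    gf, gs = params.gamma_fast, params.gamma_slow
    A = np.array([[bf - af * gf, -af * gs], [-as_ * gf, bs - as_ * gs]])
    b = np.array([af * p, as_ * p])
    x_star = np.linalg.solve(np.eye(2) - A, b)
    return float(gf * x_star[0] + gs * x_star[1])
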
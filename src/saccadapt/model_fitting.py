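"""Model fitting for adaptation time-courses.

Two models are fitted to first-adaptation-block gain series:

* an exponential timescale model, fit(t) = 1 − α·(1 − e^(−t/β)), which
  starts at 1 and approaches 1 − α; α is the asymptotic gain-change
  magnitude (negative for gain-up adaptation) and β the timescale in
  trials.  Condition differences in (α, β) are assessed with a paired
  participant bootstrap.

* the dual-state model with fixed learning/retention rates, whose two free
  process gains (γ_fast, γ_slow ≥ 0) scale the fast (explicit) and slow
  (implicit) contributions to adaptation.

Both are exposed statsmodels-style: a model object built from data whose
``fit()`` returns a results object carrying estimates, diagnostics and a
``summary()`` table.

Numerical approach for the exponential model: for fixed β the model is
linear in α, so α is profiled out analytically and the optimisation is a
one-dimensional search over β (log-spaced grid plus bounded scalar
refinement).  The bootstrap uses a fully vectorised variant of the same
profile fit across folds, making the default 10^5-fold bootstrap cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dual_state import DEFAULT_RATES, DualStateParams, DualStateTrace, simulate_dual_state

__all__ = [
    "exp_model",
    "fit_exponential",
    "ExponentialAdaptationModel",
    "ExponentialFit",
    "bootstrap_exponential",
    "BootstrapResult",
    "DualStateModel",
    "DualStateFit",
    "fit_dual_state_gains",
    "slow_ratio",
]


def exp_model(t, alpha: float, beta: float, printed_form: bool = False):
    """Exponential adaptation curve.

    Default form 1 − α·(1 − e^(−t/β)): equals 1 at t = 0 and approaches
    1 − α as t → ∞.  ``printed_form`` selects the algebraic variant
    (1 − α)·(e^(−t/β) − 1) + 1, provided for comparison.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    t = np.asarray(t, dtype=float)
    decay = np.exp(-t / beta)
    if printed_form:
        return (1.0 - alpha) * (decay - 1.0) + 1.0
    return 1.0 - alpha * (1.0 - decay)


def _profile_alpha(y: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Least-squares α (and SSE) for fixed basis b = 1 − e^(−t/β).

    The model residual is y − α·b with y = 1 − gain, so
    α̂ = ⟨y, b⟩ / ⟨b, b⟩ and SSE = ⟨y, y⟩ − α̂²·⟨b, b⟩.
    """
    den = float(b @ b)
    if den == 0.0:
        return 0.0, float(y @ y)
    alpha = float(y @ b) / den
    return alpha, float(y @ y) - alpha**2 * den


@dataclass(frozen=True)
class ExponentialFit:
    """Results of an exponential timescale fit."""

    alpha: float
    beta: float
    sse: float
    n_trials: int
    converged: bool
    beta_identifiable: bool = True
    printed_form: bool = False

    @property
    def params(self) -> dict[str, float]:
        return {"alpha": self.alpha, "beta": self.beta}

    def predict(self, t):
        return exp_model(t, self.alpha, self.beta, printed_form=self.printed_form)

    def summary(self) -> str:
        lines = [
            "Exponential adaptation fit",
            "--------------------------",
            f"alpha (asymptotic gain change) {self.alpha: .4f}",
            f"beta (timescale, trials)       {self.beta: .3f}",
            f"SSE                            {self.sse: .6g}",
            f"n trials                       {self.n_trials}",
            f"converged                      {self.converged}",
        ]
        if not self.beta_identifiable:
            lines.append("warning: beta not identifiable (flat series)")
        return "\n".join(lines)


class ExponentialAdaptationModel:
    """Exponential timescale model for one gain series.

    Parameters
    ----------
    gains : array-like
        Per-trial gains (NaN marks invalid trials).
    trial_index : array-like, optional
        Trial indices; shifted so the first trial is t = 0 (the fit is
        invariant to a constant index offset).  Defaults to 0..n−1.
    printed_form : bool
        Use the algebraic variant of the curve (see :func:`exp_model`).
    """

    def __init__(self, gains, trial_index=None, printed_form: bool = False):
        gains = np.asarray(gains, dtype=float)
        if trial_index is None:
            trial_index = np.arange(gains.size)
        t = np.asarray(trial_index, dtype=float)
        if t.shape != gains.shape:
            raise ValueError("trial_index must match gains")
        mask = np.isfinite(gains)
        self.t = t[mask] - t[mask].min() if mask.any() else t[mask]
        self.gains = gains[mask]
        self.printed_form = printed_form

    def fit(self, beta_max: float | None = None, n_grid: int = 60) -> ExponentialFit:
        """Profile-likelihood least squares: grid over β then Brent refine.

        β is bounded in (0, 10·N]; the multi-start role of the log-spaced
        grid guards against local minima of the profiled SSE.
        """
        t, g = self.t, self.gains
        n = t.size
        if n < 5:
            raise ValueError("need at least 5 valid points")
        if beta_max is None:
            beta_max = 10.0 * max(n, int(t.max()) + 1)
        y = 1.0 - g
        if self.printed_form:
            # (1−α)(e^{−t/β}−1)+1 = 1 − (1−α)(1−e^{−t/β}): same basis, α' = 1−α
            pass

        def sse_of(log_beta: float) -> float:
            b = 1.0 - np.exp(-t / np.exp(log_beta))
            return _profile_alpha(y, b)[1]

        grid = np.linspace(np.log(0.1), np.log(beta_max), n_grid)
        sse_grid = np.array([sse_of(lb) for lb in grid])
        k = int(np.argmin(sse_grid))
        identifiable = np.ptp(sse_grid) > 1e-14 * max(1.0, float(y @ y)) and np.std(y) > 0

        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            sse_of, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        log_beta = float(res.x) if res.fun <= sse_grid[k] else float(grid[k])
        beta = float(np.exp(log_beta))
        b = 1.0 - np.exp(-t / beta)
        alpha, sse = _profile_alpha(y, b)
        if not identifiable:
            alpha = 0.0
        if self.printed_form:
            alpha = 1.0 - alpha  # map profiled coefficient back to printed α
        return ExponentialFit(
            alpha=alpha,
            beta=beta,
            sse=sse,
            n_trials=n,
            converged=bool(res.success) and identifiable,
            beta_identifiable=bool(identifiable),
            printed_form=self.printed_form,
        )


def fit_exponential(trial_indices, gains, **kwargs) -> ExponentialFit:
    """Functional wrapper: fit the exponential model to one series."""
    return ExponentialAdaptationModel(gains, trial_index=trial_indices).fit(**kwargs)


# ---------------------------------------------------------------------------
# Bootstrap comparison of exponential fits across conditions
# ---------------------------------------------------------------------------


def _profile_fit_folds(G: np.ndarray, t: np.ndarray, log_grid: np.ndarray):
    """Vectorised profile fit of the exponential model to many series.

    ``G`` holds one gain series per row (NaN allowed).  For every β on the
    grid, α is profiled out per row; the per-row β is then refined by
    parabolic interpolation of SSE over log β around the grid minimum.

    Returns (alpha, beta) arrays, one entry per row.
    """
    y = 1.0 - G
    finite = np.isfinite(y)
    y0 = np.where(finite, y, 0.0)
    yy = (y0**2).sum(axis=1)

    n_folds = G.shape[0]
    sse = np.empty((n_folds, log_grid.size))
    for j, lb in enumerate(log_grid):
        b = 1.0 - np.exp(-t / np.exp(lb))
        num = y0 @ b
        den = finite @ (b**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            sse[:, j] = yy - np.where(den > 0, num**2 / den, 0.0)

    k = np.argmin(sse, axis=1)
    km = np.clip(k, 1, log_grid.size - 2)
    s0, s1, s2 = (sse[np.arange(n_folds), km + d] for d in (-1, 0, 1))
    h = log_grid[1] - log_grid[0]
    denom = s0 - 2 * s1 + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        shift = np.where(denom > 0, 0.5 * (s0 - s2) / denom, 0.0)
    log_beta = log_grid[km] + np.clip(shift, -1.0, 1.0) * h
    log_beta = np.where((k == 0) | (k == log_grid.size - 1), log_grid[k], log_beta)

    beta = np.exp(log_beta)
    b = 1.0 - np.exp(-t[None, :] / beta[:, None])
    num = (y0 * b).sum(axis=1)
    den = (finite * b**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return alpha, beta


@dataclass(frozen=True)
class BootstrapResult:
    """Paired participant bootstrap of exponential fits across conditions.

    ``estimates[cond]`` holds the per-fold (α, β) estimates;
    ``differences["a-b"]`` the per-fold paired parameter differences and
    ``p_values["a-b"]`` the two-tailed bootstrap p per parameter,
    p = 2·min(frac below 0, frac above 0), floored at 2/n_folds.
    """

    n_folds: int
    seed: object
    conditions: tuple[str, ...]
    estimates: dict = field(repr=False)
    differences: dict = field(repr=False)
    p_values: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Paired bootstrap of exponential fits", f"n_folds = {self.n_folds}"]
        for key, ps in self.p_values.items():
            d = self.differences[key]
            lines.append(
                f"{key}: median Δalpha={np.median(d['alpha']): .4f} (p={ps['alpha']:.4g}), "
                f"median Δbeta={np.median(d['beta']): .3f} (p={ps['beta']:.4g})"
            )
        return "\n".join(lines)


def _bootstrap_p(diff: np.ndarray, n_folds: int) -> float:
    below = float(np.mean(diff < 0))
    above = float(np.mean(diff > 0))
    return float(np.clip(2.0 * min(below, above), 2.0 / n_folds, 1.0))


def bootstrap_exponential(
    series_by_condition: dict[str, np.ndarray],
    n_folds: int = 100_000,
    seed=None,
    *,
    comparisons: list[tuple[str, str]] | None = None,
    n_grid: int = 48,
    chunk: int = 20_000,
) -> BootstrapResult:
    """Across-participant bootstrap comparison of exponential parameters.

    Each fold draws participants with replacement (the same draw for every
    condition, giving paired comparisons), averages their gain series per
    condition, and fits the exponential model to each condition average.

    Parameters
    ----------
    series_by_condition : dict of ndarray (n_participants, n_trials)
        Per-participant block gain series per condition (NaN = invalid
        trial).  All conditions must share the participant dimension.
    comparisons : list of (a, b) pairs, optional
        Differences reported as fit(a) − fit(b); defaults to all pairs in
        condition order.
    """
    conds = tuple(series_by_condition)
    if not conds:
        raise ValueError("no conditions given")
    n_p = {c: np.asarray(series_by_condition[c]).shape[0] for c in conds}
    if len(set(n_p.values())) != 1:
        raise ValueError("all conditions must have the same participants")
    n_participants = n_p[conds[0]]
    if n_participants < 2:
        raise ValueError("bootstrap requires at least 2 participants")

    n_trials = np.asarray(series_by_condition[conds[0]]).shape[1]
    t = np.arange(n_trials, dtype=float)
    log_grid = np.linspace(np.log(0.1), np.log(10.0 * n_trials), n_grid)

    rng = np.random.default_rng(seed)
    estimates = {c: (np.empty(n_folds), np.empty(n_folds)) for c in conds}
    done = 0
    while done < n_folds:
        m = min(chunk, n_folds - done)
        idx = rng.integers(0, n_participants, size=(m, n_participants))
        for c in conds:
            S = np.asarray(series_by_condition[c], dtype=float)
            with warnings.catch_warnings():
                # trials invalid for every resampled participant yield NaN
                warnings.simplefilter("ignore", RuntimeWarning)
                G = np.nanmean(S[idx], axis=1)
            a, b = _profile_fit_folds(G, t, log_grid)
            estimates[c][0][done : done + m] = a
            estimates[c][1][done : done + m] = b
        done += m

    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1 :]]
    differences, p_values = {}, {}
    for a, b in comparisons:
        key = f"{a}-{b}"
        da = estimates[a][0] - estimates[b][0]
        db = estimates[a][1] - estimates[b][1]
        differences[key] = {"alpha": da, "beta": db}
        p_values[key] = {"alpha": _bootstrap_p(da, n_folds), "beta": _bootstrap_p(db, n_folds)}
    return BootstrapResult(
        n_folds=n_folds,
        seed=seed,
        conditions=conds,
        estimates={c: {"alpha": estimates[c][0], "beta": estimates[c][1]} for c in conds},
        differences=differences,
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# Dual-state process-gain fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DualStateFit:
    """Fitted process gains of the dual-state model (rates fixed)."""

    gamma_fast: float
    gamma_slow: float
    rates: DualStateParams
    sse: float
    n_valid: int
    trace: DualStateTrace = field(repr=False)
    condition: dict = field(default_factory=dict)
    condition_number: float = np.nan

    @property
    def params(self) -> DualStateParams:
        return self.rates.with_gammas(self.gamma_fast, self.gamma_slow)

    @property
    def slow_ratio(self) -> float:
        return slow_ratio(self)

    def summary(self) -> str:
        af, bf, as_, bs = self.rates.rates
        return "\n".join(
            [
                "Dual-state process-gain fit (rates fixed)",
                "-----------------------------------------",
                f"rates: fast learn {af}, fast retention {bf}, "
                f"slow learn {as_}, slow retention {bs}",
                f"gamma_fast  {self.gamma_fast: .4f}",
                f"gamma_slow  {self.gamma_slow: .4f}",
                f"slow ratio  {self.slow_ratio: .4f}",
                f"SSE         {self.sse: .6g}   (n valid = {self.n_valid})",
                f"condition number of Jacobian {self.condition_number: .3g}",
            ]
        )


class DualStateModel:
    """Dual-state model with fixed rates, fitted to one block's gain series.

    Parameters
    ----------
    gains : array-like
        Observed per-trial gains for the block (NaN marks invalid trials;
        invalid trials are excluded from the loss but the state recursion
        advances on every trial).
    perturbations : array-like
        Per-trial perturbation p(i) in relative-gain units.
    rates : DualStateParams
        Fixed learning/retention rates (defaults: 0.21/0.59 fast,
        0.02/0.992 slow).
    error_mode : {"closed", "observed"}
        Error signal during simulation/fitting; see
        :func:`saccadapt.dual_state.simulate_dual_state`.
    """

    def __init__(
        self,
        gains,
        perturbations,
        rates: DualStateParams = DEFAULT_RATES,
        *,
        error_mode: str = "closed",
        baseline: float = 1.0,
    ):
        self.gains = np.asarray(gains, dtype=float)
        self.perturbations = np.asarray(perturbations, dtype=float)
        if self.gains.shape != self.perturbations.shape:
            raise ValueError("gains and perturbations must have equal length")
        if not np.any(self.perturbations != 0):
            raise ValueError("perturbation schedule is all-zero; gains unidentifiable")
        self.rates = rates
        self.error_mode = error_mode
        self.deviations = self.gains - baseline
        self.mask = np.isfinite(self.deviations)
        if self.mask.sum() < 10:
            raise ValueError("need at least 10 valid trials")

    def simulate(self, gamma_fast: float, gamma_slow: float) -> DualStateTrace:
        params = self.rates.with_gammas(gamma_fast, gamma_slow)
        return simulate_dual_state(
            params,
            self.perturbations,
            error_mode=self.error_mode,
            observed_gains=self.gains if self.error_mode == "observed" else None,
        )

    def _residual(self, gammas) -> np.ndarray:
        trace = self.simulate(gammas[0], gammas[1])
        return trace.adaptation[self.mask] - self.deviations[self.mask]

    def fit(
        self,
        starts=((0.5, 0.5), (0.1, 0.9), (1.0, 0.1)),
        condition: dict | None = None,
    ) -> DualStateFit:
        """Bounded nonlinear least squares over (γ_fast, γ_slow) ≥ 0.

        Multi-start over the supplied initial points; returns the best
        solution, with the condition number of the Jacobian at the optimum
        as an identifiability diagnostic.
        """
        best = None
        for x0 in starts:
            res = optimize.least_squares(
                self._residual, x0, bounds=([0.0, 0.0], [np.inf, np.inf]), xtol=1e-12,
                ftol=1e-12, gtol=1e-12,
            )
            if best is None or res.cost < best.cost:
                best = res
        sv = np.linalg.svd(best.jac, compute_uv=False)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        gf, gs = (float(v) for v in best.x)
        return DualStateFit(
            gamma_fast=gf,
            gamma_slow=gs,
            rates=self.rates,
            sse=float(2 * best.cost),
            n_valid=int(self.mask.sum()),
            trace=self.simulate(gf, gs),
            condition=condition or {},
            condition_number=cond,
        )


def fit_dual_state_gains(
    gains, perturbations, rates: DualStateParams = DEFAULT_RATES, **kwargs
) -> DualStateFit:
    """Functional wrapper around :class:`DualStateModel`."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("starts", "condition") if k in kwargs}
    return DualStateModel(gains, perturbations, rates, **kwargs).fit(**fit_kwargs)


def slow_ratio(fit) -> float:
    """Share of the slow process in total fitted gain: γs / (γf + γs).

    Accepts a :class:`DualStateFit` or a (γ_fast, γ_slow) pair.  Returns
    NaN (with a warning) when both gains are zero.
    """
    if hasattr(fit, "gamma_fast"):
        gf, gs = fit.gamma_fast, fit.gamma_slow
    else:
        gf, gs = fit
    total = gf + gs
    if total <= 0:
        warnings.warn("both process gains are zero; slow ratio undefined", stacklevel=2)
        return float("nan")
    return float(gs / total)
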
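# saccadapt

Analysis pipeline for **saccadic gain adaptation** experiments in which a
target is displaced mid-saccade — either further along the saccade
trajectory (gain-up) or back towards the origin (gain-down) — so that
saccade amplitude gradually adapts. The package targets the *hexagonal
global-adaptation* design: four blocks (48/96/96/48 trials) of saccades
around a clockwise hexagon with 10 dva between targets, run with both
*reactive* saccades (a single jumping target) and *scanning* saccades (six
persistent targets, the next one chosen internally), the question being
how much of the adaptation is explicit versus implicit learning.

It is written for motor-learning and oculomotor researchers who want a
tested, reusable implementation of this analysis: simulate the experiment,
detect saccades in raw gaze data, apply the trial-rejection and
gain-normalisation rules, and decompose adaptation time-courses with the
dual-state model.

## The models at the core

**Dual-state (multi-rate) model.** With per-trial error ε(i) and fixed
learning/retention rates (α_f, β_f, α_s, β_s) = (0.21, 0.59, 0.02, 0.992):

```
x_f(i) = α_f ε(i) + β_f x_f(i−1)         (fast: learns & forgets quickly)
x_s(i) = α_s ε(i) + β_s x_s(i−1)         (slow: learns & forgets slowly)
a(i)   = γ_fast x_f(i) + γ_slow x_s(i)   (adaptation, gain units)
```

Only the process gains γ_fast, γ_slow ≥ 0 are fitted (nonlinear least
squares, closed-loop error ε(i) = p(i) − a(i−1)). The **slow ratio**
γ_s/(γ_f+γ_s) quantifies the implicit share of adaptation.

**Exponential timescale model.** Block-2 gain series are also summarised
by `fit(t) = 1 − α(1 − e^(−t/β))` (starts at 1, approaches 1 − α), with
condition differences in the timescale β assessed by a paired participant
bootstrap (resample participants with replacement, refit per fold,
p = 2·min tail fraction of the fold differences).

Saccades are detected with the median-based velocity-threshold algorithm
(5-sample velocity filter, robust per-component thresholds η = λσ with
σ = sqrt(median(v²) − median(v)²), λ = 6).

## Worked example

Simulate a gain-down adaptation block with known process gains, add
trial noise, and fit the dual-state model:

```python
import numpy as np
from saccadapt import (DEFAULT_RATES, DualStateModel,
                       simulate_dual_state, simulate_observed_gains)

p = np.full(96, -0.25)                         # gain-down perturbation
truth = DEFAULT_RATES.with_gammas(0.741, 0.894)
trace = simulate_dual_state(truth, p)
gains = simulate_observed_gains(trace, noise_sd=0.05, seed=42)

fit = DualStateModel(gains, p).fit()
print(fit.summary())
```

```
Dual-state process-gain fit (rates fixed)
-----------------------------------------
rates: fast learn 0.21, fast retention 0.59, slow learn 0.02, slow retention 0.992
gamma_fast   0.7072
gamma_slow   0.9284
slow ratio   0.5676
SSE          0.140429   (n valid = 96)
condition number of Jacobian  2.77
```

The fitted gains recover the generating values (0.741, 0.894) to within
the noise-limited precision of a single 96-trial block; the slow ratio
0.568 says that just over half of this (simulated) adaptation is carried
by the slow — implicit — process. The condition number ≈ 3 confirms the
two processes are well separated by the data.

The same data summarised by the exponential model:

```python
from saccadapt import fit_exponential
print(fit_exponential(np.arange(96), gains).summary())
```

```
Exponential adaptation fit
--------------------------
alpha (asymptotic gain change)  0.1616
beta (timescale, trials)        17.856
SSE                             0.178537
n trials                       96
converged                      True
```

i.e. gain drops towards 1 − α ≈ 0.84 with a ~18-trial timescale.

## Command-line pipeline

Each stage is also a shell command (see `saccadapt --help`):

```
saccadapt simulate  --saccade-type reactive --direction-order down-up --seed 1 --out sim/
saccadapt detect    --gaze-dir sim/gaze --trials sim/trials.tsv --out saccades.tsv
saccadapt preprocess --trials sim/trials.tsv --out gains.tsv --qc-report qc.json
saccadapt fit       --gains gains.tsv --model dualstate --out fits.json
saccadapt report    --trials sim/trials.tsv --out report/
```

`report` runs the whole analysis (QC, normalisation, latencies, block
transitions, exponential + bootstrap, dual-state contrasts, kinematics,
awareness) and writes a deterministic `report.json` plus figures.

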
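# floquetbias

Bias-aware estimation of Floquet multipliers from noisy rhythmic time series.

## The problem

The local stability of steady rhythmic motion — walking, running, legged
robots, oscillating populations — is commonly quantified by the **Floquet
multiplier** λ of the linearized Poincaré return map: the state deviation
from the limit cycle one cycle later is λ times the current deviation, so
|λ| < 1 means the orbit is stable and smaller |λ| means faster recovery.
With per-cycle noise δ_k (zero mean, SD σ_δ, uncorrelated across cycles) the
observed deviations follow a first-order autoregression,

    x_1 = δ_1,    x_{k+1} = λ x_k + δ_{k+1},

and estimating orbital stability from an experiment means estimating an
AR(1) coefficient from a short record. Every standard estimator is biased
toward zero in small samples — it *overestimates* stability — and the bias
is independent of both the noise level and its distribution:

- **regression** (the convention in experimental gait studies): slope of the
  centered least-squares fit of x_{k+1} on x_k;
- **Yule-Walker**: λ̂_YW = Σ x_i x_{i+1} / Σ_{i≤n−1} x_i²;
- **Burg**: the order-1 reflection coefficient, always inside [−1, 1].

This package implements those estimators, closed-form approximations of the
expected bias of the first two,

    E(λ̂ − λ)    ≈ −((1+λ)/(n−1)) · (1 − (1 − λ^{n−1}) / ((n−1)(1−λ))),
    E(λ̂_YW − λ) ≈ −(λ³ − λ^{2n+1}) / ((n−1)(1 − λ²)),

and the **corrected estimator** that subtracts the Yule-Walker bias term
evaluated at the Burg plug-in estimate:

    λ̂_new = λ̂_YW + (λ̂_B³ − λ̂_B^{2n+1}) / ((n−1)(1 − λ̂_B²)).

It also ships the full Monte-Carlo validation protocol (bias tables across
λ, series length n, and three standardized noise families, with a Lilliefors
normality check and a one-sample t-test of unbiasedness), a Poincaré-section
extractor for sampled trajectories, and a CLI.

It is intended for researchers quantifying stability of rhythmic processes
from limited recordings, and for methodologists studying small-sample AR
bias.

## Worked example

```python
from floquetbias import (NoiseSpec, generate_ar1, fm_regression, fm_corrected)

noise = NoiseSpec("normal", 1.0)
series = generate_ar1(lam=0.75, n=50, noise=noise, seed=13)
print(fm_regression(series).to_record())
print(fm_corrected(series, center=False).to_record())
```

prints

```
{'method': 'regression', 'lambda_hat': 0.6617796638116537, 'n': 50, 'clamped': False, 'centered': True}
{'method': 'corrected', 'lambda_hat': 0.758834481937245, 'n': 50, 'clamped': False, 'centered': False}
```

The true multiplier is 0.75: on this 50-cycle record the regression estimate
(0.662) overstates stability by ~12%, while the corrected estimate (0.759)
lands next to the truth. (Single draws scatter, of course — the systematic
part of the gap is what the Monte-Carlo protocol quantifies.) From the shell the same works on CSV files:

```sh
floquetbias simulate --lam 0.75 --n 50 --seed 7 -o series.csv
floquetbias estimate series.csv --method corrected
floquetbias benchmark experiment.cfg -o report.csv   # full Monte-Carlo table
```

A per-cycle series can also be extracted from a sampled trajectory with
`floquetbias poincare` (threshold crossing with linear interpolation,
optional refractory filtering).

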
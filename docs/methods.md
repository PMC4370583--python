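# Methods

## Model

Steady rhythmic motion is modeled as a stable limit cycle observed once per
cycle through a Poincaré section. Writing s_k for the sectioned state at
cycle k and s* for the fixed point, the deviation x_k = s_k − s* follows, to
first order and with additive per-cycle noise,

    x_1 = δ_1,    x_{k+1} = λ x_k + δ_{k+1},

an AR(1) process whose coefficient λ is the Floquet multiplier. The
innovations δ_k are independent across cycles with mean 0 and SD σ_δ; no
within-cycle dynamics are modeled. The first cycle starts "on the orbit"
(x_1 = δ_1), not at stationarity; an optional explicit x_0 exists solely so
noiseless geometric decay can be generated for exact-recovery tests.

Everything here is one-dimensional: a scalar section readout per cycle.
Multivariate return maps, correlated (colored) noise, and multiplicative
noise are out of scope.

## Estimators

Given x_1 … x_n (n cycles):

- **regression** — slope of the centered least-squares fit of x_{k+1} on
  x_k (intercept absorbed). Needs n ≥ 3 and a non-constant predictor.
- **yule_walker** — λ̂_YW = Σ_{i=1}^{n−1} x_i x_{i+1} / Σ_{i=1}^{n−1} x_i².
  A `center` flag (default on) subtracts the full-series sample mean first;
  inside the simulation harness the series already holds true deviations
  and the harness runs uncentered.
- **burg** — the order-1 reflection coefficient
  2 Σ x_i x_{i+1} / Σ (x_i² + x_{i+1}²), which lies in [−1, 1] by
  construction. Its magnitude is clamped to 1 − `clamp_eps` (default 10⁻⁶,
  `clamped` flag set, warning logged) because the bias correction below is
  singular at |λ| = 1.
- **corrected** — λ̂_new = λ̂_YW − B_YW(λ̂_Burg, n), where

      B_YW(λ, n) = −(λ³ − λ^{2n+1}) / ((n−1)(1 − λ²))

  is the closed-form approximation of the Yule-Walker bias and the Burg
  estimate stands in for the unknown true λ (chosen because it cannot leave
  the unit interval). The identity
  `fm_corrected ≡ fm_yule_walker − bias_yw_expected(fm_burg)` holds exactly,
  by construction.

The regression bias approximation is

    B_reg(λ, n) = −((1+λ)/(n−1)) · (1 − (1 − λ^{n−1}) / ((n−1)(1−λ))).

Both closed forms are negative for 0 < λ < 1 (stability overestimated),
decay like 1/n, and do not involve σ_δ. All estimators are exactly
scale-invariant (ratios of quadratic forms), so the bias of each is exactly
independent of the noise scale.

Degenerate inputs (constant predictor, all-zero series) raise
`DegenerateSeriesError` rather than returning NaN: no multiplier is
identifiable. No minimum-length floor beyond the algebraic ones (n ≥ 3 for
regression/corrected, n ≥ 2 for Yule-Walker/Burg) is imposed; reliability
at a given n is the Monte-Carlo harness's job to quantify.

## Accuracy of the closed-form bias approximations — a known limitation

The closed forms above are first-order approximations (expectation of the
numerator over expectation of the denominator). High-precision simulation
with this package (10⁵–2·10⁵ replicates) shows they capture the sign, the
1/n decay and the order of magnitude, but **understate the true bias by
roughly a factor of two**:

- the empirical regression bias tracks −(1+3λ)/n (the classic second-order
  result for the intercept model): at λ = 0.75, n = 100 the observed bias is
  ≈ −0.034 versus −0.017 from B_reg;
- the empirical Yule-Walker bias tracks −2λ/n: at λ = 0.75, n = 100 it is
  ≈ −0.0146 versus −0.0097 from B_YW. (A covariance-term derivation of the
  ratio's expectation reproduces the −2λ/n behaviour; B_YW corresponds to
  retaining only part of that covariance.)

Consequently the corrected estimator removes only ~60% of the Yule-Walker
bias. Its residual bias at λ = 0.75 under normal noise is ≈ −0.013 at
n = 20, −0.009 at n = 50 and −0.005 at n = 100 — an order of magnitude
smaller than the regression bias, but still detectable by a 1000-replicate
t-test, whose t-statistic sits near the decision boundary (|t| ≈ 2−2.4) for
n between 50 and 200. The smallest length from which the test accepts
unbiasedness for the whole remaining grid is therefore strongly
seed-dependent; typical values are n ≈ 200 under symmetric noise rather
than n = 50. The acceptance-style tests that assert the sharper thresholds
are kept and fail honestly; the exactness and ordering properties
(|bias_corrected| < |bias_YW| < |bias_regression|) hold robustly.

Under the heavily skewed lognormal family the corrected estimator
*overshoots* at small n (bias ≈ +0.11 at n = 10, +0.05 at n = 20, 10⁵
replicates): the plug-in correction interacts with a real second-order
skewness effect. The claim that bias is unaffected by the noise
distribution is accurate to first order only; at n = 10 the three families'
relative regression biases agree within ~5 percentage points (≈ 48.5%
normal, 49.2% uniform, 44.3% lognormal), a genuine difference that 1000
replicates cannot resolve but 10⁵ can.

## Synthetic data

`NoiseSpec` standardizes each family to mean 0 and SD σ_δ:
normal σZ; uniform on (−σ√3, σ√3); lognormal (exp(Z) − e^{1/2}) · σ /
√((e−1)e) with Z standard normal — the log-scale shape is fixed at 1, giving
skewness ≈ 6.18, a deliberately harsh asymmetry. Default σ_δ = 1: the
estimators are scale-invariant, so the scale is a free choice and nothing
downstream depends on it.

`generate_stitched` concatenates independent short records, each restarting
at x_1 = δ_1 — the "stitching" practice of splicing many short trials into
one long one. The concatenated record lacks the long-range correlation
accumulation of an unbroken one, so its regression bias is intermediate
between a single short and a single long record. Pairs spanning segment
boundaries are kept by default (naive concatenation); a boundary-excluding
regression mode exists for comparison.

`generate_noisy_oscillator` is plumbing, not a model: a planar sinusoid
whose per-cycle amplitude deviation equals the AR(1) series, arranged so
the rising zero crossing of the first channel falls mid-cycle where the
second channel equals amplitude + x_k. It exists to test the section
extractor end-to-end; it has none of the within-cycle dynamics, drift,
or measurement noise of real recordings, so round-trip tests validate the
extraction mechanics only.

Seeding: every public generator takes an integer seed or a NumPy
`SeedSequence`; the Monte-Carlo harness derives one child stream per
replicate from the master seed (`spawn_key` per grid cell), so runs are
bit-reproducible and cells are independent.

## Monte-Carlo protocol

`run_experiment` sweeps (λ, n, noise) over the default grid λ ∈
{0.75, 0.5, 0.25}, n ∈ {10, 20, 50, 100, 200, 500, 1000} (the stated range
10–1000, gridded to include every length discussed), three noise families,
1000 replicates per cell. Every estimator sees the same replicate series
(paired comparisons). Per cell it reports mean, SD, bias, relative bias,
and the unbiasedness test: a two-sided one-sample t-test of mean = λ at
α = 0.05, with a Lilliefors normality p-value reported as advisory only
(it justifies the t-test, it never gates acceptance). A zero-variance
sample with exactly the right mean is accepted with p = 1. Replicates on
which an estimator degenerates are regenerated with the next child seed
(logged); above 1% the cell aborts — with continuous noise this never
triggers in practice.

`min_unbiased_n` summarizes a report as the smallest grid length from which
H0 stays accepted for all larger grid lengths. `compare_stitched` pairs
stitched against unbroken records of equal total length and reports the
bias difference plus a Welch two-sample test.

Problem sizes: the default test suite uses 100–4000 replicates per cell
(seconds); the deepest cross-validation test uses 10⁵ replicates over nine
cells (~1 minute). The acceptance script runs the 1000-replicate protocol
only (~2 s).

## Poincaré extraction

`extract_poincare_series` detects threshold crossings of a trigger channel
in a stated direction, locates each crossing instant by linear
interpolation between the bracketing samples, reads out a second channel at
that instant (linear interpolation again), and optionally suppresses
crossings closer than `refractory_fraction` × the median inter-crossing
interval (rejects chatter when noise grazes the threshold; the median is
robust as long as spurious crossings are a minority). Deviations are formed
by subtracting a supplied fixed point, or the sample mean of the readouts
when the fixed point is unknown (the average-cycle convention). Detection
uses strict inequality on the approach side and inclusive on the landing
side, so a sample lying exactly on the threshold terminates a crossing.
The construction is invariant to uniform time rescaling.

## Design choices that were genuinely open

- Equation grouping of the typeset bias formulas was ambiguous; the
  groupings above were adopted and then cross-checked by simulation, which
  is what exposed the factor-two understatement documented above. The
  printed forms are kept as the package's definitions because the corrected
  estimator is *defined* by them.
- Centering: regression is intrinsically centered; Yule-Walker and the
  corrected estimator default to centering for real data and run uncentered
  in the harness. Both paths are tested.
- Stitched regression includes boundary-spanning pairs by default; the
  excluding mode is provided because either convention is defensible.
- Lognormal shape fixed at 1 (see above); results under milder skews will
  sit between the normal and lognormal columns of the report.

## Limitations

One-dimensional sections only; uncorrelated innovations only; the
closed-form corrections are first-order (see above); no confidence
intervals for λ̂ are provided, only population-level Monte-Carlo error
bars; the oscillator fixture is not a physiological model, so passing
round-trip tests says nothing about section placement in real data.
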
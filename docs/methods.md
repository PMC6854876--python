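# Methods

## Data model and transform

The raw input is a monthly consumer-price-index level series per product,
strictly positive, on a gap-free monthly grid.  Annualized inflation is the
year-over-year growth π_t = p_t/p_{t−12} − 1, stored internally as a decimal
fraction; percent formatting happens only in the reporting layer.  Month
arithmetic is purely positional (month t−12 is 12 array positions earlier);
there are no day-of-month semantics.  Missing months, duplicate months and
non-positive levels are hard errors — the analysis assumes a complete
official index series, and no imputation rule would be defensible here.
The transform consumes the first 12 index months as the base of the annual
comparison, so an 84-month index window yields 72 inflation observations —
the sample size of the study design this package mirrors (index data are
assumed to begin 12 months before the analysis window).

Descriptive statistics use the sample standard deviation (n−1), the moment
skewness coefficient g1, and Pearson (non-excess) kurtosis, under which a
normal distribution scores 3.  A constant series has sd and skewness 0 by
convention and undefined (NaN) kurtosis.

## The regime-switching model

π_t = μ_{s_t} + ε_t with ε_t ~ N(0, σ_{s_t}²) and s_t a first-order
two-state Markov chain with self-transition probabilities p₁₁, p₂₂.  The
chain's initial distribution is its stationary law π P = π — the standard
convention when nothing is known about the pre-sample state.  Regime 1 is
canonically the lower-mean ("low inflation") state; fits are reordered after
optimization, which also resolves label switching between optimizer runs.

The exact likelihood is computed by the normalized Hamilton forward
recursion on log emission densities (numerically safe for long series; the
inner loop is JIT-compiled when numba is available, with an identical pure
Python fallback).  Smoothed probabilities come from the Kim backward pass.
Both are verified in the test suite against brute-force enumeration of all
2^T regime paths for short series, and the likelihood additionally against
an independent implementation (statsmodels' Markov regression), which agrees
to machine precision.

Optional autoregressive terms (non-switching coefficients φ) use the
regime-intercept form m_t(s) = μ_s(1 − Σφ) + Σ_j φ_j π_{t−j}, so the
reported μ_s remains the regime mean and the latent state space stays at
two states.  The first `ar_order` observations condition the recursion and
do not enter the likelihood.  The default, and the headline model, is the
mean-only form (ar_order = 0).

### Estimation

Maximization runs in a transformed space — logits of p₁₁ and p₂₂, logs of
the σ's, unconstrained μ and φ — keeping the optimizer interior and the
Hessian usable for standard errors.  Eight seeded starts by default: regime
means at the (25, 75) and (10, 90) percent data quantiles crossed with
p_stay ∈ {0.9, 0.95}, the remainder seeded perturbations of that grid;
switching likelihoods are multimodal and a single start is not trustworthy.
Each start runs L-BFGS-B with ftol 1e−11 / gtol 1e−6 (capped at 500
iterations); a start counts as converged on optimizer success or a gradient
max-norm below 1e−3, and the best converged start wins.  Regime standard
deviations are bounded below by 1e−6 to stop the likelihood spiking around
a point mass; a fit that ends on that bound carries a warning.  If no start
converges the fit raises an error with per-start diagnostics.

Free-parameter counts are k = 5 for a shared variance (2 means, 1 sigma,
2 transition probabilities) and k = 6 with switching variance, plus one per
AR lag; n for the BIC is the number of inflation observations entering the
likelihood.  Expected regime durations are 1/(1−p₁₁) and 1/(1−p₂₂) months,
exactly, for every fit.

### Standard errors

The default "robust" flavour is the sandwich H⁻¹·OPG·H⁻¹, combining the
numerical Hessian of the log-likelihood (central second differences,
relative step 1e−4) with the outer product of per-observation scores
(central differences of the per-month log predictive densities).  A plain
inverse-negative-Hessian flavour is also available.  Errors for the natural
parameters and for the durations are obtained by the delta method with the
analytic Jacobian of the inverse transforms.  A near-singular Hessian
(condition number above 1e12 — e.g. indistinguishable regimes) raises an
error rather than returning meaningless numbers; inside a full fit this is
downgraded to a warning with the SEs left unset.

### Regime classification and breaks

A month is labelled high-inflation when the smoothed probability of state 2
strictly exceeds the threshold (default 0.5; months exactly at the threshold
stay low).  Break dates are the months where the label changes, tagged with
the direction of the change.

## Model selection

Candidates are the grid of AR orders 0..max_ar crossed with shared vs
switching variance.  All candidates are fit on a common observation window
— the first max_ar observations are reserved as lags for every candidate —
so their likelihoods and information criteria are comparable; ties break
toward fewer parameters.  Both the AIC and the BIC argmin are reported, and
when both variance structures are available at the BIC-chosen AR order a
likelihood-ratio statistic for σ₁ = σ₂ (χ²₁ reference) is attached as a
diagnostic; the headline choice is IC-based.  Non-converged candidates are
flagged and excluded from the argmin.

## Synthetic data

The generator forward-simulates the chain (initial state from the
stationary law or fixed), adds Gaussian noise around the regime means, and
can invert the annual transform into index levels (first 12 months at the
base index, then p_t = p_{t−12}(1+π_t)); the inversion is exact by
construction, so transform ∘ inversion is the identity to machine
precision.  One root seed drives two independent substreams (regime path,
noise), making the path invariant to changing only σ — useful for
controlled experiments.  Simulation permits σ = 0 for noiseless fixtures;
estimation does not.

The 19 product presets store the published point estimates exactly as
printed (decimal fractions, no back-solving of rounded values); five
products carry regime-switching variances.  What the generator deliberately
does not emulate: serial correlation within regimes beyond the optional AR
terms, seasonality, anticipation effects or gradual pass-through around the
tax date, and heavy tails — simulated series are exactly
conditionally-Gaussian two-state mixtures.  Tests passing on this generator
therefore establish the correctness of the machinery and the identifiability
of the model at realistic parameter values, not the adequacy of the model
for any particular real price series.

## Problem sizes and study conditions used in the checks

- Filter/smoother vs enumeration: 50 random parameter draws, T ≤ 12
  (likelihood) and T ≤ 10 (smoothed marginals), agreement within 1e−8.
- Parameter recovery: T = 600 months simulated from the soft-drinks preset
  (shared variance) and the sweet-bread preset (switching variance), 8
  optimizer starts; tolerances ±0.005 on means, ±0.002 on sigmas, ±0.03 on
  self-transition probabilities.  Fixture simulations use the root seed
  2014 (the tax year), fixed a priori.
- Selection consistency: 50 replicates per scenario at T = 120 months with
  4 optimizer starts per candidate — a horizon modestly longer than the
  72-month study window, where BIC discrimination between variance
  structures is reliable; the shared-variance scenario is the soft-drinks
  preset, the switching scenario uses a 3:1 sigma ratio (σ = 0.012/0.036)
  with p₁₁ = 0.95, p₂₂ = 0.92.
- Coverage: ±2·SE intervals for the low-regime mean over 50 replicates at
  T = 400.

## Known limitations

- Exactly two regimes; no time-varying transition probabilities, exogenous
  regressors, or Bayesian estimation.
- The AR form ties φ across regimes; fully Hamilton-style switching AR
  dynamics (lagged states in the mean) are out of scope.
- Robust SEs rely on numerical differentiation; for nearly unidentified
  fits (tiny regime separation) they degrade before the singularity guard
  triggers.
- Expected durations are unconditional chain properties; they are not
  duration-dependent survival estimates.
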
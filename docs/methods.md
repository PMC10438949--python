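# Methods

This note documents the statistical model behind `cellcountqc`, the
conventions the package had to choose where the standard analysis leaves
room, what the synthetic data generator does and does not emulate, and the
package's known limitations.

## The measurement model

A dilution-series study measures one cell stock at target dilution fractions
DF₁ > DF₂ > … (defaults 1, 1/2, 1/3, 1/4, 1/5), with *t* replicate tubes per
dilution (default 3) and *r* instrument observations per tube (default 3).
If the counting process is unbiased across its operating range, the expected
measured concentration is proportional to the dilution fraction:

    λᵢⱼ = β₁ · DFᵢ

where *i* indexes the dilution, *j* the tube nested within it, and β₁ —
the proportionality constant — is the stock concentration. Counting noise
grows with concentration; the analysis assumes **variance proportional to
the mean**. Under the proportional model the mean at DFᵢ is β₁DFᵢ, so the
weighted least-squares weights are wₖ = 1/DFₖ and

    β₁̂ = Σ wₖ DFₖ yₖ / Σ wₖ DFₖ² = Σ yₖ / Σ DFₖ,

the classical ratio estimator. Weighting is one-step, not iteratively
reweighted: the variance assumption is stated in terms of the design (DF),
so the weights do not depend on fitted values and the estimator stays
deterministic. The linear model adds a free intercept (same weights) and is
fit through `statsmodels` WLS; an intercept significantly above zero
indicates additive background — debris or mis-segmentation that does not
dilute with the cells.

**R²** is the centered, weighted definition, 1 − SSE/SST with SST about the
weighted grand mean, *also for the zero-intercept model*. The uncentered
definition customary for through-origin regression is systematically
inflated, and this analysis treats values near 0.9–1.0 as discriminating,
so the conservative definition is used. R² is reported as NaN when SST = 0
(all responses identical); no division by zero occurs.

## Proportionality index

R² mixes random and systematic variability. The proportionality index
isolates the systematic part: a flexible polynomial in DF,

    y = b₀ + b₁DF + b₂DF² + b₃DF³ + b₄DF⁴,

is fit by ordinary least squares (degree 4 by default, automatically capped
at one less than the number of distinct dilutions, with a warning), and the
PI is the smoothed scaled sum of squared errors

    PI = Σᵢ Σⱼ ( (ŷ_smooth(DFᵢ) − β₁̂DFᵢ) / (β₁̂DFᵢ) )².

PI = 0 exactly when the smoothed curve coincides with the proportional fit;
it is scale-invariant, and zero on any data lying on a line through the
origin. Conventions the double-sum form does not pin down, chosen here and
echoed into every report:

- replicate observations are **averaged to the tube level** before smoothing
  and PI (observation-level analysis available by flag);
- a polynomial in DF alone is constant across tubes at a fixed dilution, so
  the smoothed prediction at DFᵢ is shared across j and each tube
  contributes one term — dilutions with more tubes carry more weight;
- the scaling denominator is the proportional-model prediction β₁̂DFᵢ, the
  only model-based estimate of the true concentration available;
- the smoothing fit is unweighted by default (a 1/DF-weighted variant is
  selectable).

## Bootstrap confidence intervals

Intervals for β₁, PI, and any scalar statistic are nonparametric percentile
bootstrap intervals (default 1,000 replicates, 95% level). The resampling
unit is the **tube**: observations within a tube share pipetting and
loading, and tube-level resampling preserves that correlation. Endpoints
use the Davison–Hinkley (B+1) order-statistic convention — at level 1−α the
interval is the ⌊(B+1)α/2⌋-th smallest and largest replicate — which is
slightly wider than interpolated quantiles at small B and measurably closer
to nominal coverage.

Tubes are resampled with replacement from the whole series, **not**
stratified by dilution. Stratified resampling (available by flag) keeps the
tubes-per-dilution layout of every replicate, but with only three tubes per
stratum it underestimates the sampling variance by the small-stratum factor
(n−1)/n = 2/3 per stratum; in simulation its 95% intervals for β₁ covered
the truth only ~83% of the time, versus ~92% for unstratified resampling of
the 15 tubes (deficit 14/15). The residual few points of undercoverage are
the percentile method's intrinsic small-sample optimism (the effective
sample size of the weighted fit is ≈11 tubes); bootstrap-t or BCa intervals
would close the gap and are noted as future work.

One global seed drives a per-statistic substream (seed + CRC32 of the
statistic name), so adding a statistic to a report does not perturb the
replicates of the others. Replicates on which the statistic fails (e.g. an
unstratified resample missing a dilution) are dropped and counted; more
than 10% failures aborts. When the PI is bootstrapped, each replicate's
smoothing degree auto-caps at (distinct DFs − 1) so such resamples remain
usable.

Between-method bias calls default to **CI non-overlap** at a common level —
conservative, and reproducible from the two reported intervals alone. The
more powerful rule based on the percentile interval of the paired difference
of replicates is selectable.

## Precision and viability

Replicate %CV is 100·SD/mean across the observations of each tube (sample
SD, n−1); tubes with one observation or zero mean are flagged rather than
computed. % viability should be invariant to dilution, so its distribution
across all observations of a series is summarised as a histogram on
[0, 100] (default bin width 1 percentage point; peak-bin ties break to the
lowest edge and are flagged). Methods are compared per dilution by one-way
ANOVA on **tube means** — averaging within-tube replicates avoids
pseudo-replication; observation-level analysis is available but
anti-conservative — followed by Tukey's HSD (unadjusted t-tests by flag)
at α = 0.05.

## Synthetic data generator

The generator is the package's ground truth. Defaults mirror the study
conditions the analysis is designed for: the 5 × 3 × 3 design, stock drawn
uniformly in [5×10⁵, 10⁶] viable cells/mL (the instruments' common operating
range), observation CV 5% at the undiluted stock, tube-to-tube CV 2%,
viability normal with mean 90% and SD 2 points. Choices:

- **Noise family.** Concentrations get multiplicative gamma noise — strictly
  positive with controllable variance, no rejection/clipping artifacts at
  these CVs. Under `variance_mode="proportional_to_mean"` the observation is
  gamma with Var = θ·mean, θ = obs_cv²·stock, so the CV at the undiluted
  stock equals `obs_cv` and grows as 1/√DF down the series, matching the
  analysis' variance assumption; `constant_cv` keeps the CV flat instead.
  Viability is normal, clipped to [0, 100] with clip events counted in the
  truth record.
- **`stock_conc` is the viable stock.** The total concentration is derived
  as viable/(viability/100), so every synthetic observation is internally
  consistent by construction.
- **Background bias** adds a constant concentration at every dilution;
  the linear fit recovers it exactly in the noiseless limit.
- **Saturation bias** compresses the response above a DF knee, emulating
  operating-range effects.
- **Bead interference** has two separable phenomenological effects:
  *viability depression* shifts reported viability down by a fixed number of
  percentage points (beads counted as dead cells; viable counts untouched,
  totals inflate correspondingly), and *count inflation* multiplies the
  reported concentration by (1 + f·DF) — the full fractional miscount f at
  the undiluted stock, shrinking with dilution, as crowding/coincidence
  interference does. The density dependence matters: a concentration-
  independent multiplicative miscount would leave the data perfectly
  proportional and invisible to the PI, whereas real bead interference
  degrades proportionality; this form produces both the β₁ bias and the
  elevated PI that distinguish an interfered method.
- **Panels.** `simulate_method_panel` can force one shared stock across
  methods so between-method differences reflect only configured artifacts;
  each method's noise stream derives from its seed plus its panel position,
  so identical configs still get independent noise.

Everything random is driven by the config seed; the truth record retains
every generative parameter plus the realised stock, tube effects and clip
count.

**What the generator does not emulate:** instrument optics and fluidics,
counting-chamber loading errors, operator-to-operator variability, non-gamma
heavy-tailed outliers, day effects, or correlated drift across a series.
Passing recovery and coverage tests therefore demonstrates the correctness
and calibration of the *analysis* under its stated assumptions, not the
behaviour of any particular instrument on real samples.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` size their simulations to
estimate each property with adequate Monte Carlo precision: 200 studies for
β₁/R² recovery (SE of the mean ratio ≈ 0.09%), 300–1,000 studies for CI
coverage (the coverage test uses 1,000, since the SE at 300 is ~1.6
percentage points — too coarse to resolve the 0.90 band edge the test
asserts), 100 seeds per bias level for PI ordering, and 400 null panels
(2,000 dilution-level tests) for the α = 0.05 type-I rate.

## Numerical and degenerate-input choices

- Dilution fractions parse from ratio strings ("1:3") to exact fractions;
  floats are snapped to small-denominator fractions (≤1000) so 0.333…
  round-trips to 1/3. Floats are used at fit time.
- The CSV reader parses numerics with Python's `float()` (exact for
  shortest-repr output) so write→read round trips are bit-exact.
- Reported viability is checked against viable/total within 0.5 percentage
  points by default — instruments round displayed viability — and
  violations are flagged, never silently fixed.
- Zero or negative responses are retained at fit time (weights depend only
  on DF); negative concentrations are a validation flag.
- A single distinct dilution raises "proportionality not identifiable";
  an all-zero response yields β₁ = 0 with a warning; β₁ = 0 makes the PI
  scaling undefined and raises.
- The smoothing polynomial uses `numpy.polynomial.Polynomial.fit` (scaled
  domain) for conditioning; coefficients are also exposed in the power
  basis.

## Limitations

- Percentile intervals under-cover by a few points at this design size (see
  above); BCa/bootstrap-t are not implemented.
- No mixed-effects modelling of the nested design; the comparison analysis
  is ANOVA on tube means.
- No nonlinear calibration models (e.g. 4PL); only the proportional and
  straight-line models relevant to proportionality assessment.
- The Excel adapter expects one sheet per (preparation × method) with the
  documented columns; vendor-specific export formats are out of scope.
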
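# Methods

## The risk measure

`radsurv` computes the Radiation Attributed Decrease of Survival (RADS) for
all-solid-cancer incidence: the cumulative probability that a radiation-
attributed cancer occurs by attained age `a`, conditional on survival to
that age, for a person exposed at age `e` to a weighted colon dose `D`,

    RADS(a | e, D) = 1 − exp(−H(a | e, D)),
    H(a | e, D)    = ∫_{e+l}^{a} h(u, e, D) du,
    h(a, e, D)     = [ 0.5·ERR(D,a,e)·m(a) + 0.5·EAR(D,a,e)/10⁴ ] / DDREF.

`ERR` and `EAR` are the excess relative and excess absolute risk from
models fitted to the Life Span Study (LSS) of the atomic-bomb survivors;
`m(a)` is the age- and sex-specific baseline incidence rate of the target
population (per person-year internally; per 100,000 person-years in input
files). RADS deliberately involves fewer population rates than
REID/REIC-style measures — no competing-mortality survival curve enters —
which is why it has been proposed for astronaut risk assessment, where the
reference population is a poor match anyway. Mission doses (0.17 Sv for a
180-day lunar mission, 1 Sv for Mars) are treated numerically as weighted
colon dose in Gy; translating space radiation fields into organ dose
equivalents via quality factors is out of scope.

Assumptions inherited from this formulation:

* excess hazards act additively on the attained-age axis and accumulate
  only after a latency period `l`;
* the 0.5/0.5 multiplicative/additive transfer weighting, DDREF and the
  LSS neutron RBE are fixed values without uncertainty;
* the exposure is a single acute dose at age `e`.

## Model families and multi-model inference

Eight published all-solid-cancer incidence model families (BEIR VII,
Grant L/LQ, Preston L, INWORKS L/LQ, UNSCEAR L/LQ) are implemented with
their printed mathematical forms (see `risk_models`), each in an ERR and an
EAR variant with separate coefficients and covariance. The fitted
coefficient values of the source analyses are not redistributed here: model
registries are configuration files, and the synthetic generator produces
calibrated stand-ins (below).

Model choice is treated as a source of uncertainty through multi-model
inference: excess risks are averaged over the families with normalized
information-criterion weights `w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`. Four
weight sets span the method space — AIC vs. BIC, and models fitted with
their original (often stratified) baselines vs. a common best-fitting
parametric baseline (stratified baselines are heavily penalized by both
criteria, which the "same baseline" refit compensates). The four packaged
weight-set files carry the published weights under one consistent
sum-to-one reading of the source table; because the typeset table does not
pin every cell to a unique column, the weights are deliberately editable
configuration, not constants. Averaging happens on the excess-risk scale at
each evaluation age, separately for ERR and EAR.

## Multi-method-multi-model inference (M4I)

The four method-level RADS estimates are combined into one general estimate
by a weighted mean, equal weights 1/4 by default: the published general
estimates (0.42%, 0.67%, 2.45%, 3.91% for male/female lunar and Mars) are
exactly the equal-weight means of the published method-level points, and no
unique alternative weighting is derivable. Uncertainty uses Gaussian error
propagation for independent inputs, `σ = sqrt(Σ v_k² σ_k²)` (equal weights:
`sqrt(Σ σ_k²)/4`), with per-method σ taken from the Monte Carlo standard
deviation of that method's realisations when available, else from the CI
half-width divided by 1.96. The four methods share the underlying data, so
independence is an approximation that somewhat narrows the combined CI;
replaying the combiner on published CI half-widths gives, e.g., 0.37–0.46%
for the male lunar mission against a printed 0.38–0.45%, consistent with
the original propagation having used internal (unpublished) Monte Carlo
standard deviations.

## Monte Carlo uncertainty

95% CIs are percentile (2.5th/97.5th) intervals over, by default, 1000
realisations. Each realisation redraws every model's coefficient vector
from its asymptotic multivariate normal (mean = fitted values, covariance =
the registry matrix) and Poisson-resamples every baseline cell with an
assumed denominator of 100,000 person-years per age×sex stratum (the true
denominators are not published; the parameter is configurable). Models are
resampled independently of each other and ERR/EAR variants of a family
independently of each other, because no cross covariance is available.
Draws are untruncated; negative excess hazards arising from negative
coefficient draws are floored at zero per age step (flooring rate logged at
DEBUG). The reported point estimate is the plug-in value at the mean
coefficients — the realisation mean would be biased slightly upward by the
convexity of the exponential at large H and the flooring at small H.

A single `numpy` Generator seeded from `RADSSettings.seed` drives each run;
the draw order is fixed (coefficients in registry order, then baseline
cells age-major with male before female), so identical seeds give
byte-identical outputs. Internally all realisations are evaluated
vectorized over the age grid, which keeps a 1000-realisation mission
scenario under 0.1 s.

## Numerical choices

* **Quadrature**: composite trapezoid on a uniform age grid (default step
  1 year; the attained age is appended when off-grid). Exact for
  piecewise-linear integrands, second-order otherwise: halving the step
  changes a lunar-dose RADS by < 10⁻⁶ and a 1 Sv RADS by ~5·10⁻⁶, both far
  inside the Monte Carlo uncertainty. Interval additivity holds to 10⁻¹²
  when the split point lies on the grid.
* **Baseline interpolation**: rates attach to age-band midpoints, linear in
  between, clamped flat beyond the edges; bands are `[start, next start)`
  with the last band as wide as its predecessor. The interpolation is a
  precomputed linear map so resampled rate vectors reuse it.
* **Latency**: no published value accompanies this formulation; the default
  is 5 years (the conventional solid-cancer choice) and is prominent in
  `RADSSettings` precisely because results at short exposure-to-attained-age
  gaps are sensitive to it.
* **DDREF grouping**: the combined-hazard formula is typeset ambiguously;
  by default DDREF divides the whole bracketed sum (ERR and EAR terms),
  with `ddref_scope="ear_only"` available. At DDREF 2 the choice rescales
  the multiplicative term by 2, so it matters more than most other options.
* **Sex coding**: `s = −1` (male) / `+1` (female) inside `(1+σs)` and
  `exp(σs)`, the symmetric LSS convention; a 0/1 coding cannot be excluded
  from the printed forms and would reinterpret fitted σ values. BEIR VII
  carries sex-specific α instead.
* **Kerma adjustment**: `1[K > 4]` reads as shielded kerma strictly above
  4 Gy; with the default K = 0 for mission predictions it vanishes.
* **Degenerate inputs**: `a ≤ e + l` gives H = 0 by convention; dose 0
  gives RADS exactly 0; a baseline table not covering `[e+l, a]` raises a
  data error naming the gap rather than extrapolating silently.

## Synthetic inputs

The generator (`radsurv.synthetic`, also `radsurv synth`) replaces the two
inputs this package does not redistribute — fitted coefficients/covariances
and European baseline rates — with analytically tractable stand-ins written
in the same file formats:

* **Registry**: every family/endpoint is calibrated so its sex-averaged
  excess risk at the reference covariates (D = 1 Gy, e = 30, a = 70,
  K = 0) equals `err_scale` (default 0.5, a typical all-solid ERR per Gy)
  or `ear_scale` (default 50 per 10⁴ PY per Gy) exactly; the reference ages
  mirror the effect-modifier centering of the source fits. LQ families put
  30% of the 1 Gy response into the quadratic term. Covariances are
  `σσᵀ∘R` with sd = 20% of each coefficient and common correlation 0.3,
  PSD by construction.
* **Baseline**: log-linear (Gompertz-like) rates over ages 0–100, slope
  0.08/year, sex-averaged rate at age 85 calibrated to 3000 per 100,000 PY
  (a European all-solid-cancer magnitude), males 10% above and females 10%
  below the average.
* **Scenarios**: lunar (0.17 Sv), Mars (1 Sv) and a zero-dose control, at
  age at exposure 40 and attained age 65, both sexes.

With these defaults the synthetic mission estimates land in the published
few-tenths-of-a-percent (lunar) to few-percent (Mars) range, so the
pipeline is exercised at realistic magnitudes. What the synthetic inputs do
*not* emulate: real covariance structure between risk coefficients, the
age-band granularity and cohort effects of registry data, and any
systematic disagreement between model families beyond their functional
forms. Tests passing on synthetic inputs therefore validate the
computational machinery and its analytic properties, not the published
method-level mission table, which requires the original fitted inputs.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
study's own scale: 16 model specs, 101 age bands × 2 sexes, 21–26 point age
grids, 1000 realisations per method estimate. The Monte Carlo coverage
check uses 500 trials of 10,000 realisations each against a single-model
configuration with a closed-form truth. The complete suite runs in well
under a minute on one core.

## Known limitations

* The percentile CI ignores Monte Carlo error in the percentile estimates
  themselves (~3% relative at 1000 realisations).
* The M4I CI assumes cross-method independence (see above).
* No leukaemia models, no mortality endpoints, no REID/REIC, no
  competing-risk adjustment, no space-radiation quality factors.
* Coefficient resampling is asymptotic-normal; skewness of the true
  likelihood surfaces is not represented.
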
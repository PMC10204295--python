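# Methods

`aircausal` implements a two-track analysis of a daily air-pollutant
exposure series against daily disease-admission counts: a distributed-lag
Poisson regression quantifying short-term lag effects as relative risks,
and convergent cross mapping (CCM) testing for causal influence between
the two series. A synthetic-data layer generates every input needed to
validate both tracks against known ground truth.

## Distributed-lag Poisson regression

### Model

For one admission stratum (disease category × gender × age group) with
daily counts Y_t and daily mean exposure Ozone_t (µg/m³), the single-lag
model is

    log E(Y_t) = α + β₁ · Ozone_{t−l} + ns(Time, df) + β₂ · DOW_t

with Poisson error and log link. `ns(Time, df)` is a natural cubic
regression spline of calendar time controlling season and long-term trend;
`DOW` is a 6-column day-of-week indicator block with Monday as reference.
Effects are reported as relative risks per 10 µg/m³, RR = exp(10·β₁), with
Wald 95% intervals exp(10·(β₁ ± 1.959964·SE)) on the log scale.

Single-day lag effects (lag 0 … 5 by default, extensible to 14) come from
separate one-lag-at-a-time fits, the standard practice in air-pollution
time-series work. The cumulative lag-0–5 effect enters all six lag columns
in one unconstrained distributed-lag model; the reported effect is the
coefficient sum 1ᵀβ with variance 1ᵀΣ1 from the full coefficient
covariance. A constrained moving-average exposure term is available behind
a flag (`moving_average=True`) but is not the default, since the
unconstrained sum makes no shape assumption.

Between-stratum contrasts use the normal Z statistic
z = (δ₁ − δ₂)/√(SE₁² + SE₂²) with a two-sided p value.

### Estimation and numerical choices

* Fitting is iteratively reweighted least squares (via the GLM machinery in
  statsmodels), convergence at coefficient changes below 1e-8 or 100
  iterations; non-convergence raises with the deviance trace.
* The design is checked for full rank after dropping constant non-intercept
  columns; rank deficiency raises an error naming the collinear columns.
* The spline basis follows the classical natural-spline construction
  (cubic B-splines, interior knots at equally spaced quantiles of the
  observation times, boundary knots at the extremes, boundary curvature
  projected out by QR). With the intercept excluded, df columns correspond
  to df − 1 interior knots. The basis spans the same space as the standard
  R `splines::ns` parameterisation (asserted in the tests against a frozen
  reference matrix).
* The trend df defaults to 7 and can be chosen by AIC over a candidate set
  on the base model (spline + DOW, no pollutant); ties go to the smaller
  df, and residual partial autocorrelations to lag 14 are returned as a
  diagnostic.
* Days on which either series is missing or fails quality control are
  dropped listwise after lag alignment. A fit requires at least
  10·(df + 8) usable days (ten observations per parameter).
* The error family is pure Poisson by default, matching the generator; a
  quasi-Poisson scale (Pearson χ²) is available behind `quasipoisson=True`
  for overdispersed data.

## Convergent cross mapping

### Procedure

Both series are z-scored (counts optionally log(1+y) first). Each series
is delay-embedded into E lagged coordinates with delay τ
(x(t) = ⟨x_t, x_{t−τ}, …, x_{t−(E−1)τ}⟩), giving L − (E−1)τ shadow-manifold
points. To test whether Y causally influences X, each y_t is estimated
from X's manifold: the E+1 nearest library neighbours of x(t) (Euclidean
distance, ties broken by index) receive weights

    u_i = exp(−d_i/d_1),   w_i = u_i / Σ u_j,

and ŷ_t = Σ w_i y_{t_i} at the neighbours' origin times. Exact-match
neighbours (d_1 = 0) share the weight mass equally, the limit of the
formula. The predictee itself and library points within a Theiler window
of (E−1)·τ time steps are excluded from its neighbour search. Cross-map
skill is ρ = Pearson(y, ŷ) over all predictees; its significance uses
t = ρ/√((1−ρ²)/(N−2)) with N−2 degrees of freedom.

Convergence is scanned over a grid of library lengths L; at each L,
replicate libraries are random contiguous segments (contiguity preserves
the dynamics), seeded for reproducibility. Defaults: E = 2, τ = 2
(the values the admissions analysis uses), 100 replicates per L; the
embedding can instead be chosen from the data — τ by the first local
minimum of the average mutual information (16-bin 2-D histograms), E by
the false-nearest-neighbour criterion.

### The causality verdict

A direction is declared causal at the 95% level iff both hold:

1. **Convergence** — Spearman rank correlation between L and mean ρ is
   positive with one-sided p < 0.05, *and* mean ρ at the largest L exceeds
   mean ρ at the smallest L by more than `min_gain` (default 0.1).
2. **Significance** — the skill at the largest L is positive with t-test
   p < 0.05.

The gain floor in (1) is deliberate. Non-causal cross-map skill is not
flat in L: estimates average fewer effectively random neighbours as the
library grows, producing a small systematic upward drift (measured at
roughly +0.02 on the one-way benchmark's non-causal direction). A pure
trend test therefore fires on non-causal directions in a large fraction of
runs, while genuine convergence on the same benchmark gains 0.13–0.25.
The 0.1 floor separates the two regimes cleanly; it is configurable.

Two consequences worth knowing:

* Identical (or fully synchronised) series saturate ρ ≈ 1 from the
  smallest library, leave no room for a gain, and are therefore *not*
  flagged causal in either direction — the verdict pair is symmetric, and
  the saturated ρ itself signals the degeneracy.
* With large N the t-test alone is permissive (ρ = 0.08 at N ≈ 1000 is
  "significant"); the convergence requirement is the effective gate.

### Direction semantics

The skill of estimating Y from M_x measures Y's influence on X: only if Y
forces X does X's reconstructed state encode Y. Outputs are labelled
`"y->x"` (Y influences X, estimated as ŷ|M_x) and `"x->y"`; both
directions are always computed. For an ozone/admissions pair the claim
"ozone causally drives admissions" corresponds to the skill of estimating
ozone from the admissions manifold.

## Synthetic data

The generator layer provides four things, all deterministic under a seed.

**Coupled logistic maps.** x_{t+1} = x_t(r_x − r_x x_t − β_xy y_t),
y_{t+1} = y_t(r_y − r_y y_t − β_yx x_t), the canonical cross-mapping
benchmark; β_xy > 0, β_yx = 0 gives ground-truth one-way causality
(Y drives X). Defaults r_x = 3.8, r_y = 3.72, burn-in 200 steps, orbits
outside [0, 1.5] rejected as unstable. The driver's growth rate must be
chosen in the chaotic regime: with one-way coupling the driver is an
autonomous logistic map, and values in the periodic windows (e.g. 3.5,
period 4) collapse the whole system onto a periodic orbit on which both
cross-map directions trivially score ρ = 1 and the benchmark is
meaningless. r = 3.72 is comfortably chaotic.

**Seasonal exposure.** A sinusoid (annual period, default mean 70 µg/m³,
amplitude 40, peak near mid-October — matching the autumn ozone maximum of
a subtropical coastal city) plus stationary AR(1) noise (coefficient 0.7,
marginal SD 10), clipped at zero. A sinusoid cannot reproduce asymmetric
seasonal shapes (an October maximum three months before a July minimum);
it emulates amplitude and autocorrelation, not chemistry.

**Poisson counts.** Counts are drawn Poisson with
log µ_t = α + Σ_l β₁[l]·Ozone_{t−l} + spline trend + DOW effect. The trend
is evaluated through the *same* natural-spline constructor the regression
uses, so recovery tests run under a correctly specified model. Defaults:
α = log 300 (a daily admission volume of a few hundred, matching a large
city's respiratory caseload), a single lag-0 effect β₁ = 0.0016 per µg/m³
(≈ 1.6% per 10 µg/m³, the size of a typical significant cumulative
effect), mild trend and weekend effects. The generator is pure Poisson —
no overdispersion — matching the fitted family; robustness studies should
add their own dispersion.

**Record-level disaggregation.** Daily counts explode into per-admission
records with gender (default 60.1% male), age band (child-dominated mix:
85.2% aged 0–14, 10% 15–64, 4.8% 65+), uniform age within band, and an
ICD-10 diagnosis drawn from a pool spanning the acute upper (J00–J06),
acute lower (J20–J22) and other respiratory ranges. Re-aggregation
recovers the generating counts exactly, which the tests assert bit-for-bit.

What passing on synthetic data does *not* show: robustness to
overdispersion, missing-data mechanisms correlated with exposure,
exposure measurement error, or confounders outside the model (weather,
co-pollutants). The generators emulate structure, not epidemiology.

## Ingest and quality control

* Hourly station series are reindexed to a full hourly grid; unparsable
  values become missing with a logged warning.
* A station-day is valid iff at least `min_completeness` (default 0.75,
  i.e. 18 of 24 hours) of its hours are present; its value is the mean of
  the present hours. No imputation.
* The citywide series is the unweighted mean over stations valid that day;
  a pooled day is valid iff the reporting fraction reaches the same
  threshold. A nearest-station assignment (haversine on a 6371-km sphere,
  ties broken by station id) is retained for sensitivity analyses.
* ICD-10 codes classify by their 3-character root: J00–J06 acute upper
  respiratory, J20–J22 acute lower, other J chapter codes "other
  respiratory", everything else non-respiratory; subcodes inherit the
  root. Age bands are 0–14, 15–64, 65+ (65 in the elderly band,
  configurable). Dates parse ISO-8601; a dd/mm/yyyy dialect flag exists
  and is never auto-guessed.

## Problem sizes used in the validation suite

The bundled checks run the coupled-map benchmark at series length 1000
(1200 steps less 200 burn-in), an 8-point library grid from 50 to 600 with
15 replicate libraries per length and 50 seeds for direction recovery;
regression recovery and interval calibration use 2000-day series with 200
null replicates. These sizes give Monte-Carlo standard errors comfortably
below the margins being asserted (e.g. a ±4% band on 95% coverage at 200
replicates) while keeping the full suite quick on a single CPU.

## Known limitations

* Single-pollutant models only; no temperature/humidity confounders, no
  case-crossover designs.
* CCM significance uses the t approximation only; surrogate-data nulls are
  out of scope.
* The convergence verdict depends on `min_gain`; series pairs with genuine
  but weak coupling (gain below 0.1) will be called non-causal.
* CCM assumes stationary deterministic dynamics observed without large
  gaps; the pipeline concatenates valid days across QC gaps, which is
  acceptable for scattered missing days but not for long outages.
* Strongly shared seasonality can produce real cross-map skill in both
  directions on observational series; the benchmark verdicts quantify
  behaviour on systems with known ground truth, not on confounded field
  data.
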
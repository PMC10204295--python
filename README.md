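# aircausal

Lag-effect regression and convergent cross mapping for air-pollution
health time series.

Short-term links between a daily pollutant exposure series (such as ozone,
µg/m³) and daily hospital-admission counts are usually quantified with a
log-linear Poisson time-series regression — but regression measures
association, not causation, and correlation between two strongly seasonal
series is often a mirage. `aircausal` implements both sides of that
problem for epidemiologists and air-quality researchers:

* **`DistributedLagPoisson`** fits the standard model

  ```
  log E(Y_t) = α + β₁·Ozone_{t−l} + ns(Time, df) + β₂·DOW
  ```

  (natural cubic spline of calendar time for season/trend control,
  day-of-week indicators, Poisson error, log link) and reports single-day
  (lag 0–5) and cumulative (lag 0–5 distributed-lag) effects as relative
  risks per 10 µg/m³, RR = exp(10·β₁), with Wald 95% intervals, plus the
  between-group Z test z = (δ₁−δ₂)/√(SE₁²+SE₂²).

* **`CCM`** tests causal influence with convergent cross mapping: each
  series is delay-embedded (dimension E, delay τ) into its shadow
  manifold; y_t is estimated from the E+1 nearest neighbours of x(t) with
  exponential weights u_i = exp(−d_i/d₁); skill ρ = Pearson(y, ŷ) must
  *converge* (rise with library length L) and be significant
  (t = ρ/√((1−ρ²)/(N−2))) for a causal verdict at the 95% level. Both
  directions are always computed.

Supporting layers generate fully synthetic benchmark inputs (coupled
chaotic maps with known one-way causality, seasonal AR(1) exposure,
model-faithful Poisson counts, record-level admission files), ingest and
quality-control raw hourly monitoring and ICD-10 admission CSVs, and
orchestrate end-to-end reproducible runs from one YAML config.

## Worked example

```python
from aircausal import CCM, DistributedLagPoisson
from aircausal.simulate import (CoupledMapConfig, HealthSimConfig,
                                simulate_coupled_maps, simulate_counts,
                                simulate_exposure)

# two years of synthetic exposure and admissions with a known lag-0
# effect of 0.0016 per unit (~1.6% per 10 ug/m3)
exposure = simulate_exposure(735, seed=1)
counts = simulate_counts(exposure,
                         HealthSimConfig(n_days=730, beta1=(0.0016,), seed=2))
print(DistributedLagPoisson(counts, exposure, df=7).fit().summary())
```

```
Distributed-lag Poisson regression
  stratum: TOTAL_RESP/all/all
  spline df: 7   increment: 10 ug/m3
  lag          RR              95% CI        p
  Lag0      1.017      (1.012, 1.021)    0.000
  Lag1      1.011      (1.007, 1.015)    0.000
  Lag2      1.004      (1.000, 1.009)    0.040
  Lag3      1.002      (0.998, 1.006)    0.299
  Lag4      0.999      (0.995, 1.003)    0.651
  Lag5      0.999      (0.994, 1.003)    0.486
  Lag05     1.013      (1.007, 1.019)    0.000 *
```

The lag-0 RR of 1.017 per 10 µg/m³ brackets the generating truth
(exp(10·0.0016) = 1.016); the starred cumulative row flags a 95% interval
that excludes RR = 1. The apparent lag-1 effect is the generating lag-0
effect leaking through the exposure's day-to-day autocorrelation — exactly
the behaviour real single-lag models show.

```python
# ground-truth causality benchmark: Y drives X, never the reverse
x, y = simulate_coupled_maps(CoupledMapConfig(beta_xy=0.32, n=1200,
                                              burn_in=200, seed=3))
res = CCM(x, y, E=2, tau=2).fit(L_grid=[50, 100, 200, 400, 600],
                                n_reps=20, seed=4)
print(res.summary())
```

```
Convergent cross mapping
  E=2  tau=2  level=95%
  direction        rho(maxL)  converges  signif  causal
  y->x                 0.839       True    True    True
  x->y                 0.093      False    True   False
```

The true direction (y→x: skill of estimating y from x's manifold)
converges to ρ = 0.84 and is declared causal; the reverse direction hovers
near ρ = 0.09 without converging and is rejected — note that with ~1000
predictees even ρ = 0.09 is "significant", which is why the convergence
requirement, not the t-test, is the decisive gate.

The CLI mirrors the library: `aircausal simulate|ingest|gam|ccm|run|report`
(see `aircausal --help`); `aircausal run -c config.yaml -o out/` executes
the whole pipeline and writes RR tables, cross-map curves, verdicts,
descriptive statistics and a manifest, byte-identical under a fixed seed.

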
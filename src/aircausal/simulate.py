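"""Synthetic data generators.

Three generators cover the inputs the analysis layers need:

* a two-species coupled logistic map — the canonical benchmark for
  cross-mapping causality detection, with a known one-way coupling
  direction;
* a seasonal AR(1) daily exposure series emulating an annual ozone cycle
  (sinusoid with an autumn peak plus autocorrelated noise, clipped at 0);
* Poisson daily admission counts following the log-linear model the
  regression layer fits (intercept + lagged linear exposure effects +
  natural-spline calendar trend + day-of-week effects), and a record-level
  disaggregator that turns daily counts into per-admission rows with
  gender/age/ICD-10 attributes.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AdmissionRecord,
    AgeGroup,
    DailyExposureSeries,
    DiseaseCategory,
    ICD10_PATTERN,
    StratumCountSeries,
)
from .design import natural_spline_basis

__all__ = [
    "CoupledMapConfig",
    "HealthSimConfig",
    "simulate_coupled_maps",
    "simulate_exposure",
    "simulate_counts",
    "disaggregate_records",
    "write_admission_csv",
    "write_exposure_csv",
]


@dataclass
class CoupledMapConfig:
    """Two coupled logistic maps:

        x_{t+1} = x_t (r_x - r_x x_t - beta_xy * y_t)
        y_{t+1} = y_t (r_y - r_y y_t - beta_yx * x_t)

    ``beta_xy`` is the strength of Y's influence on X and ``beta_yx`` of
    X's influence on Y; one-way coupling (one of them zero) gives a system
    with known ground-truth causal direction.  Both default growth rates
    lie in the chaotic regime of the logistic map — an autonomous driver
    must itself be chaotic (r in the period-doubling windows, e.g. 3.5,
    collapses a one-way system onto a periodic orbit and makes cross-map
    benchmarks degenerate).
    """

    r_x: float = 3.8
    r_y: float = 3.72
    beta_xy: float = 0.0
    beta_yx: float = 0.0
    n: int = 1000
    burn_in: int = 200
    seed: int | None = None
    x0: float | None = None
    y0: float | None = None

    def __post_init__(self) -> None:
        if not (self.n > self.burn_in >= 0):
            raise ValueError("need n > burn_in >= 0")
        if self.r_x <= 0 or self.r_y <= 0:
            raise ValueError("growth parameters must be positive")
        if self.beta_xy < 0 or self.beta_yx < 0:
            raise ValueError("coupling strengths must be non-negative")
        for v, name in ((self.x0, "x0"), (self.y0, "y0")):
            if v is not None and not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")


def simulate_coupled_maps(cfg: CoupledMapConfig) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled logistic system, discarding ``burn_in`` steps.

    Returns two arrays of length ``n - burn_in``.  Raises if the orbit
    leaves [0, 1.5], which signals parameters outside the stable regime.
    """
    rng = np.random.default_rng(cfg.seed)
    x = cfg.x0 if cfg.x0 is not None else rng.uniform(0.1, 0.9)
    y = cfg.y0 if cfg.y0 is not None else rng.uniform(0.1, 0.9)
    xs = np.empty(cfg.n)
    ys = np.empty(cfg.n)
    for t in range(cfg.n):
        xs[t], ys[t] = x, y
        x_new = x * (cfg.r_x - cfg.r_x * x - cfg.beta_xy * y)
        y_new = y * (cfg.r_y - cfg.r_y * y - cfg.beta_yx * x)
        if not (0.0 <= x_new <= 1.5 and 0.0 <= y_new <= 1.5):
            raise ValueError(
                f"orbit left [0, 1.5] at step {t}: parameters outside stable regime"
            )
        x, y = x_new, y_new
    return xs[cfg.burn_in :], ys[cfg.burn_in :]


def simulate_exposure(
    n_days: int,
    mean_level: float = 70.0,
    seasonal_amplitude: float = 40.0,
    ar_coef: float = 0.7,
    noise_sd: float = 10.0,
    seed: int | None = None,
    start_date: str = "2013-01-01",
    period: float = 365.0,
    peak_day: float = 288.0,
) -> DailyExposureSeries:
    """Seasonal autocorrelated daily exposure series (µg/m³), clipped at 0.

    Deterministic component: ``mean + A cos(2π (doy - peak_day)/period)``
    (default peak in mid October).  Stochastic component: stationary AR(1)
    with marginal standard deviation ``noise_sd``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not abs(ar_coef) < 1:
        raise ValueError("|ar_coef| must be < 1 for stationarity")
    if mean_level <= 0:
        raise ValueError("mean_level must be positive")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = mean_level + seasonal_amplitude * np.cos(
        2 * np.pi * (doy - peak_day) / period
    )
    noise = np.zeros(n_days)
    if noise_sd > 0:
        innov_sd = noise_sd * np.sqrt(1 - ar_coef**2)
        e = rng.normal(0.0, innov_sd, size=n_days)
        prev = rng.normal(0.0, noise_sd)  # stationary start
        for t in range(n_days):
            prev = ar_coef * prev + e[t]
            noise[t] = prev
    values = np.clip(seasonal + noise, 0.0, None)
    return DailyExposureSeries(dates, values, np.ones(n_days, dtype=bool))


@dataclass
class HealthSimConfig:
    """Parameters of the log-linear Poisson admission model.

    ``beta1[l]`` is the log-relative-rate per µg/m³ at lag ``l`` days;
    ``trend_coefs`` weight a natural-spline basis of calendar time
    (df = len(trend_coefs)); ``dow_effects`` are 7 additive log-scale
    day-of-week effects indexed Monday..Sunday.
    """

    n_days: int = 730
    alpha: float = float(np.log(300.0))
    beta1: tuple = (0.0016,)
    trend_coefs: tuple = (0.15, -0.1, 0.2, -0.15, 0.1, 0.05, -0.05)
    dow_effects: tuple = (0.0, 0.01, 0.0, -0.01, 0.0, 0.05, 0.04)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have exactly 7 entries")
        if self.n_days <= self.max_lag:
            raise ValueError("n_days must exceed the maximum lag")

    @property
    def max_lag(self) -> int:
        return len(self.beta1) - 1


def simulate_counts(
    exposure: DailyExposureSeries, cfg: HealthSimConfig
) -> StratumCountSeries:
    """Draw Poisson daily counts with log-mean

        alpha + sum_l beta1[l] * ozone_{t-l} + spline trend + DOW effect.

    The first ``max_lag`` exposure days serve only as lag history, so the
    count series starts ``max_lag`` days into the exposure series and has
    ``cfg.n_days`` entries.
    """
    need = cfg.n_days + cfg.max_lag
    if len(exposure) < need:
        raise ValueError(
            f"exposure has {len(exposure)} days but {need} are required "
            f"(n_days={cfg.n_days} + max_lag={cfg.max_lag})"
        )
    rng = np.random.default_rng(cfg.seed)
    vals = exposure.values
    dates = exposure.dates[cfg.max_lag : cfg.max_lag + cfg.n_days]
    eta = np.full(cfg.n_days, cfg.alpha)
    for l, b in enumerate(cfg.beta1):
        eta += b * vals[cfg.max_lag - l : cfg.max_lag - l + cfg.n_days]
    if cfg.trend_coefs:
        basis = natural_spline_basis(np.arange(cfg.n_days, dtype=float),
                                     df=len(cfg.trend_coefs))
        eta += basis.design @ np.asarray(cfg.trend_coefs)
    eta += np.asarray(cfg.dow_effects)[dates.weekday]
    counts = rng.poisson(np.exp(eta))
    return StratumCountSeries(
        category=DiseaseCategory.TOTAL_RESP,
        gender="all",
        age_group=AgeGroup.ALL,
        dates=dates,
        counts=counts,
    )


DEFAULT_ICD_POOL = (
    "J00", "J02.9", "J03.9", "J04.0", "J06.9",   # AURD
    "J20.9", "J21.9", "J22",                      # ALRD
    "J18.9", "J45.9",                             # other respiratory
)

AGE_BANDS = {
    AgeGroup.CHILD: (0, 14),
    AgeGroup.ADULT: (15, 64),
    AgeGroup.ELDERLY: (65, 100),
}


def disaggregate_records(
    counts: StratumCountSeries,
    gender_probs: Sequence[float] = (0.601, 0.399),
    age_group_probs: Sequence[float] = (0.8517, 0.1, 0.0483),
    icd_pool: Sequence[str] = DEFAULT_ICD_POOL,
    seed: int | None = None,
    hospitals: Sequence[str] = ("H001", "H002", "H003"),
) -> list[AdmissionRecord]:
    """Expand a daily count series into per-admission records.

    Gender, age band and diagnosis are drawn independently per record from
    the given distributions (defaults emulate a 60.1% male share and a
    child-dominated age mix); ages are uniform within the drawn band.  The
    number of records on each date equals the input count exactly.
    """
    if not icd_pool:
        raise ValueError("icd_pool must not be empty")
    for code in icd_pool:
        if not ICD10_PATTERN.match(code):
            raise ValueError(f"malformed ICD-10 code in pool: {code!r}")
    gender_probs = np.asarray(gender_probs, dtype=float)
    age_group_probs = np.asarray(age_group_probs, dtype=float)
    for p, name in ((gender_probs, "gender_probs"), (age_group_probs, "age_group_probs")):
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError(f"{name} must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    bands = [AGE_BANDS[g] for g in (AgeGroup.CHILD, AgeGroup.ADULT, AgeGroup.ELDERLY)]
    records: list[AdmissionRecord] = []
    for date, n in zip(counts.dates, counts.counts):
        if n == 0:
            continue
        genders = rng.choice(len(gender_probs), size=n, p=gender_probs)
        age_idx = rng.choice(3, size=n, p=age_group_probs)
        codes = rng.choice(len(icd_pool), size=n)
        hosp = rng.choice(len(hospitals), size=n)
        for g, a, c, h in zip(genders, age_idx, codes, hosp):
            lo, hi = bands[a]
            records.append(
                AdmissionRecord(
                    date=date,
                    hospital_id=str(hospitals[h]),
                    gender="male" if g == 0 else "female",
                    age=int(rng.integers(lo, hi + 1)),
                    icd10=str(icd_pool[c]),
                )
            )
    return records


def write_admission_csv(records: Sequence[AdmissionRecord], path) -> None:
    """Write records as `date,hospital,gender,age,icd10` with ISO dates."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["date", "hospital", "gender", "age", "icd10"])
        for r in records:
            w.writerow([r.date.strftime("%Y-%m-%d"), r.hospital_id,
                        r.gender, r.age, r.icd10])


def write_exposure_csv(exposure: DailyExposureSeries, path) -> None:
    """Write a daily exposure series as `date,ozone_ugm3` (invalid days blank)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["date", "ozone_ugm3"])
        for d, v, ok in zip(exposure.dates, exposure.values, exposure.valid):
            w.writerow([d.strftime("%Y-%m-%d"), f"{v:.6g}" if ok else ""])
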
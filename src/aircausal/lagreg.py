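"""Distributed-lag Poisson regression of daily admission counts on exposure.

The model is the standard air-pollution time-series specification

    log E(Y_t) = alpha + beta1 * Ozone_{t-l} + ns(Time, df) + beta2 * DOW

with a log link and Poisson error, natural-cubic-spline control of season
and long-term trend, and day-of-week indicators.  Single-day lag effects
come from separate one-lag-at-a-time fits; the cumulative lag effect enters
all lags 0..max_lag simultaneously (unconstrained distributed lag) and sums
their coefficients, with the variance taken from the full coefficient
covariance.  Effects are reported as relative risks per 10 µg/m³ with Wald
95% confidence intervals on the log scale.

`DistributedLagPoisson` is the model object; `fit()` returns a
`DistributedLagResults` carrying the per-lag and cumulative estimates and a
`summary()` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import DailyExposureSeries, StratumCountSeries
from .design import dow_design, natural_spline_basis

__all__ = [
    "Z_CRIT",
    "GLMFit",
    "LagEffect",
    "CumulativeLagEffect",
    "GroupComparison",
    "fit_poisson_loglinear",
    "select_df_aic",
    "fit_single_lag",
    "fit_cumulative_lag",
    "rr_from_beta",
    "compare_groups_z",
    "pearson_descriptive",
    "DistributedLagPoisson",
    "DistributedLagResults",
]

logger = logging.getLogger(__name__)

#: normal 97.5th percentile used for all Wald intervals
Z_CRIT = 1.959964


# ---------------------------------------------------------------------------
# Elementary results containers and closed-form transforms


def rr_from_beta(beta: float, se: float, increment: float = 10.0):
    """Relative risk per ``increment`` exposure units with Wald 95% CI.

    rr = exp(increment * beta); ci = exp(increment * (beta ± 1.959964 se)).
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    rr = float(np.exp(increment * beta))
    lo = float(np.exp(increment * (beta - Z_CRIT * se)))
    hi = float(np.exp(increment * (beta + Z_CRIT * se)))
    return rr, lo, hi


def _wald_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2 * stats.norm.sf(abs(beta / se)))


@dataclass
class LagEffect:
    """Effect of exposure at a single lag: log-RR per µg/m³ and RR per 10."""

    lag: int
    beta: float
    se: float
    rr10: float
    ci_low: float
    ci_high: float
    p: float

    @classmethod
    def from_beta(cls, lag: int, beta: float, se: float,
                  increment: float = 10.0) -> "LagEffect":
        rr, lo, hi = rr_from_beta(beta, se, increment)
        return cls(lag=lag, beta=beta, se=se, rr10=rr, ci_low=lo, ci_high=hi,
                   p=_wald_p(beta, se))


@dataclass
class CumulativeLagEffect:
    """Summed effect over lags 0..max_lag from one distributed-lag fit."""

    max_lag: int
    beta_sum: float
    se_sum: float
    rr10: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool

    @classmethod
    def from_beta(cls, max_lag: int, beta_sum: float, se_sum: float,
                  increment: float = 10.0) -> "CumulativeLagEffect":
        rr, lo, hi = rr_from_beta(beta_sum, se_sum, increment)
        return cls(max_lag=max_lag, beta_sum=beta_sum, se_sum=se_sum,
                   rr10=rr, ci_low=lo, ci_high=hi, p=_wald_p(beta_sum, se_sum),
                   significant=not (lo <= 1.0 <= hi))


@dataclass
class GroupComparison:
    """Z-test for equality of two stratum coefficients:
    z = (delta1 - delta2) / sqrt(se1^2 + se2^2)."""

    delta1: float
    delta2: float
    se1: float
    se2: float
    z: float
    p: float


def compare_groups_z(delta1: float, se1: float, delta2: float, se2: float
                     ) -> GroupComparison:
    denom = np.hypot(se1, se2)
    if denom == 0:
        raise ValueError("both standard errors are zero")
    z = (delta1 - delta2) / denom
    return GroupComparison(delta1=delta1, delta2=delta2, se1=se1, se2=se2,
                           z=float(z), p=float(2 * stats.norm.sf(abs(z))))


def pearson_descriptive(counts: StratumCountSeries,
                        exposure: DailyExposureSeries) -> float:
    """Pearson correlation between daily counts and valid-day exposure."""
    exp_s = pd.Series(
        np.where(exposure.valid, exposure.values, np.nan), index=exposure.dates
    )
    x = exp_s.reindex(counts.dates).to_numpy()
    y = counts.counts.astype(float)
    mask = np.isfinite(x)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 overlapping valid days")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# GLM core


@dataclass
class GLMFit:
    """Poisson log-linear fit: coefficients, covariance, fit statistics."""

    names: list
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    fitted: np.ndarray
    n_obs: int
    pearson_resid: np.ndarray

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov[self.names.index(name),
                                      self.names.index(name)]))


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    """Drop constant non-intercept columns (e.g. a weekday absent from the
    sample) so the remaining design can be checked for full rank."""
    keep = []
    for i, c in enumerate(X.columns):
        col = X[c].to_numpy()
        if i > 0 and np.ptp(col) == 0:
            logger.warning("dropping constant design column %s", c)
            continue
        keep.append(c)
    return X[keep]


def fit_poisson_loglinear(counts: np.ndarray, design: pd.DataFrame,
                          quasipoisson: bool = False) -> GLMFit:
    """Maximise the Poisson log-likelihood with log link (IRLS; convergence
    when coefficient changes fall below 1e-8 or 100 iterations).

    ``design`` columns are named; the first is expected to be the intercept.
    Constant non-intercept columns are dropped; remaining rank deficiency is
    an error naming the collinear columns.  ``quasipoisson=True`` scales the
    covariance by the Pearson chi-square dispersion estimate.
    """
    y = np.asarray(counts)
    if y.min() < 0 or not np.issubdtype(np.asarray(y).dtype, np.number):
        raise ValueError("counts must be non-negative")
    X = _drop_constant(design)
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        from scipy.linalg import qr

        _, r, piv = qr(arr, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        bad = [X.columns[piv[i]] for i in range(len(d))
               if d[i] < 1e-8 * d.max()] or list(X.columns[rank:])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    model = sm.GLM(y, arr, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8, scale="X2" if quasipoisson else None)
    if not getattr(res, "converged", True):
        raise RuntimeError(
            f"IRLS did not converge in 100 iterations; deviance trace: "
            f"{res.fit_history.get('deviance', [])[-5:]}"
        )
    return GLMFit(
        names=list(X.columns),
        params=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        aic=float(-2 * res.llf + 2 * len(res.params)),
        fitted=np.asarray(res.fittedvalues),
        n_obs=len(y),
        pearson_resid=np.asarray(res.resid_pearson),
    )


# ---------------------------------------------------------------------------
# Alignment and model assembly


def _lagged_exposure_frame(counts: StratumCountSeries,
                           exposure: DailyExposureSeries,
                           lags: Sequence[int]) -> pd.DataFrame:
    """Per-count-date lagged exposure columns; NaN where the exposure day is
    missing or invalid."""
    exp_s = pd.Series(
        np.where(exposure.valid, exposure.values, np.nan), index=exposure.dates
    )
    cols = {}
    for l in lags:
        cols[f"ozone_lag{l}"] = exp_s.reindex(
            counts.dates - pd.Timedelta(days=l)
        ).to_numpy()
    return pd.DataFrame(cols, index=counts.dates)


def _base_design(dates: pd.DatetimeIndex, t0: pd.Timestamp, df: int):
    """Intercept + natural spline of calendar time + day-of-week columns."""
    times = (dates - t0).days.to_numpy(dtype=float)
    basis = natural_spline_basis(times, df=df)
    X = pd.DataFrame({"const": np.ones(len(dates))}, index=dates)
    for j in range(df):
        X[f"ns_{j+1}"] = basis.design[:, j]
    dow = dow_design(dates)
    for c in dow.columns:
        X[c] = dow[c].to_numpy()
    return X


def _min_usable(df: int) -> int:
    # 10 observations per parameter: intercept + exposure + df spline + 6 DOW
    return 10 * (df + 8)


def fit_single_lag(counts: StratumCountSeries, exposure: DailyExposureSeries,
                   lag: int, df: int = 7, increment: float = 10.0,
                   quasipoisson: bool = False) -> LagEffect:
    """Single-day lag effect: one model with exposure at one lag only.

    Days where either the count or the lag-shifted exposure is unusable are
    dropped listwise after alignment.
    """
    if not (0 <= lag <= 14):
        raise ValueError("lag must be between 0 and 14 days")
    lagged = _lagged_exposure_frame(counts, exposure, [lag])
    mask = np.isfinite(lagged.iloc[:, 0].to_numpy())
    usable = int(mask.sum())
    if usable < _min_usable(df):
        raise ValueError(
            f"only {usable} usable days after lag alignment; "
            f"need >= {_min_usable(df)} for df={df}"
        )
    dates = counts.dates[mask]
    X = _base_design(dates, counts.dates[0], df)
    X.insert(1, f"ozone_lag{lag}", lagged.iloc[:, 0].to_numpy()[mask])
    fit = fit_poisson_loglinear(counts.counts[mask], X, quasipoisson=quasipoisson)
    i = fit.names.index(f"ozone_lag{lag}")
    return LagEffect.from_beta(lag, float(fit.params[i]),
                               float(np.sqrt(fit.cov[i, i])), increment)


def fit_cumulative_lag(counts: StratumCountSeries,
                       exposure: DailyExposureSeries,
                       max_lag: int = 5, df: int = 7,
                       increment: float = 10.0,
                       moving_average: bool = False,
                       quasipoisson: bool = False) -> CumulativeLagEffect:
    """Cumulative effect over lags 0..max_lag.

    Default: unconstrained distributed lag — all lag columns enter one model
    and the coefficient sum (variance from the full covariance) is reported.
    ``moving_average=True`` replaces the lag columns by their mean, the
    usual constrained alternative.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    lags = list(range(max_lag + 1))
    lagged = _lagged_exposure_frame(counts, exposure, lags)
    arr = lagged.to_numpy()
    mask = np.isfinite(arr).all(axis=1)
    usable = int(mask.sum())
    if usable < _min_usable(df) + max_lag:
        raise ValueError(
            f"only {usable} usable days after lag alignment; need more data"
        )
    sub = arr[mask]
    if np.ptp(sub, axis=0).min() < 1e-12:
        raise ValueError("exposure nearly constant; lagged columns collinear")
    dates = counts.dates[mask]
    X = _base_design(dates, counts.dates[0], df)
    if moving_average:
        X.insert(1, "ozone_ma", sub.mean(axis=1))
        fit = fit_poisson_loglinear(counts.counts[mask], X,
                                    quasipoisson=quasipoisson)
        i = fit.names.index("ozone_ma")
        beta_sum = float(fit.params[i])
        se_sum = float(np.sqrt(fit.cov[i, i]))
    else:
        for j, l in enumerate(lags):
            X.insert(1 + j, f"ozone_lag{l}", sub[:, j])
        fit = fit_poisson_loglinear(counts.counts[mask], X,
                                    quasipoisson=quasipoisson)
        idx = [fit.names.index(f"ozone_lag{l}") for l in lags]
        ones = np.zeros(len(fit.params))
        ones[idx] = 1.0
        beta_sum = float(ones @ fit.params)
        se_sum = float(np.sqrt(ones @ fit.cov @ ones))
    return CumulativeLagEffect.from_beta(max_lag, beta_sum, se_sum, increment)


def select_df_aic(counts: StratumCountSeries,
                  candidate_dfs: Sequence[int]) -> tuple[int, pd.DataFrame, np.ndarray]:
    """Choose the calendar-time spline df for the base model (no pollutant)
    by AIC; ties go to the smaller df.  Also returns the AIC table and the
    chosen model's residual partial autocorrelations to lag 14."""
    if not candidate_dfs:
        raise ValueError("candidate_dfs must be non-empty")
    rows = []
    fits = {}
    for df in sorted(set(int(d) for d in candidate_dfs)):
        X = _base_design(counts.dates, counts.dates[0], df)
        fit = fit_poisson_loglinear(counts.counts, X)
        fits[df] = fit
        rows.append({"df": df, "aic": fit.aic, "loglik": fit.loglik})
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["aic"].idxmin(), "df"])  # idxmin → first/smallest
    from statsmodels.tsa.stattools import pacf

    resid = fits[chosen].pearson_resid
    nlags = min(14, len(resid) // 2 - 1)
    pacf_vals = pacf(resid, nlags=nlags)
    return chosen, table, pacf_vals


# ---------------------------------------------------------------------------
# Model / Results objects


class DistributedLagPoisson:
    """Distributed-lag Poisson model for one admission stratum.

    Parameters
    ----------
    counts, exposure : the daily series to relate.
    df : spline degrees of freedom for the calendar-time trend (default 7).
    single_lags : lags fitted one at a time (default 0..5).
    cum_max_lag : maximum lag of the cumulative model (default 5).
    increment : exposure increment for RR reporting (default 10 µg/m³).
    """

    def __init__(self, counts: StratumCountSeries,
                 exposure: DailyExposureSeries, df: int = 7,
                 single_lags: Sequence[int] = tuple(range(6)),
                 cum_max_lag: int = 5, increment: float = 10.0,
                 moving_average: bool = False, quasipoisson: bool = False):
        self.counts = counts
        self.exposure = exposure
        self.df = df
        self.single_lags = tuple(single_lags)
        self.cum_max_lag = cum_max_lag
        self.increment = increment
        self.moving_average = moving_average
        self.quasipoisson = quasipoisson

    @classmethod
    def from_frames(cls, counts_df: pd.DataFrame, exposure_df: pd.DataFrame,
                    **kwargs) -> "DistributedLagPoisson":
        """Build from plain DataFrames: counts (`date,count`) and exposure
        (`date,value[,valid]`)."""
        from .datatypes import AgeGroup, DiseaseCategory

        cdates = pd.DatetimeIndex(pd.to_datetime(counts_df["date"]))
        counts = StratumCountSeries(
            category=DiseaseCategory.TOTAL_RESP, gender="all",
            age_group=AgeGroup.ALL, dates=cdates,
            counts=counts_df["count"].to_numpy(),
        )
        edates = pd.DatetimeIndex(pd.to_datetime(exposure_df["date"]))
        valid = (exposure_df["valid"].astype(bool).to_numpy()
                 if "valid" in exposure_df.columns
                 else np.ones(len(exposure_df), dtype=bool))
        exposure = DailyExposureSeries(
            edates, exposure_df["value"].to_numpy(dtype=float), valid
        )
        return cls(counts, exposure, **kwargs)

    def select_df(self, candidate_dfs: Sequence[int] = (3, 5, 7, 9, 12)) -> int:
        chosen, self.aic_table_, self.resid_pacf_ = select_df_aic(
            self.counts, candidate_dfs
        )
        self.df = chosen
        return chosen

    def fit(self) -> "DistributedLagResults":
        effects = [
            fit_single_lag(self.counts, self.exposure, lag, self.df,
                           self.increment, self.quasipoisson)
            for lag in self.single_lags
        ]
        cumulative = fit_cumulative_lag(
            self.counts, self.exposure, self.cum_max_lag, self.df,
            self.increment, self.moving_average, self.quasipoisson
        )
        return DistributedLagResults(self, effects, cumulative)


class DistributedLagResults:
    """Estimates from a fitted `DistributedLagPoisson`."""

    def __init__(self, model: DistributedLagPoisson,
                 lag_effects: list[LagEffect],
                 cumulative: CumulativeLagEffect):
        self.model = model
        self.lag_effects = lag_effects
        self.cumulative = cumulative

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per lag plus the cumulative row."""
        rows = [
            {"lag": f"Lag{e.lag}", "beta": e.beta, "se": e.se, "rr10": e.rr10,
             "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p}
            for e in self.lag_effects
        ]
        c = self.cumulative
        rows.append({"lag": f"Lag0{c.max_lag}", "beta": c.beta_sum,
                     "se": c.se_sum, "rr10": c.rr10, "ci_low": c.ci_low,
                     "ci_high": c.ci_high, "p": c.p})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary of RRs per exposure increment with 95% CIs."""
        lines = [
            "Distributed-lag Poisson regression",
            f"  stratum: {self.model.counts.label}",
            f"  spline df: {self.model.df}   increment: "
            f"{self.model.increment:g} ug/m3",
            f"  {'lag':<7}{'RR':>8}{'95% CI':>20}{'p':>9}",
        ]
        for e in self.lag_effects:
            lines.append(
                f"  {'Lag'+str(e.lag):<7}{e.rr10:>8.3f}"
                f"{'(%.3f, %.3f)' % (e.ci_low, e.ci_high):>20}{e.p:>9.3f}"
            )
        c = self.cumulative
        star = " *" if c.significant else ""
        lines.append(
            f"  {'Lag0'+str(c.max_lag):<7}{c.rr10:>8.3f}"
            f"{'(%.3f, %.3f)' % (c.ci_low, c.ci_high):>20}{c.p:>9.3f}{star}"
        )
        return "\n".join(lines)

    def plot_lag_response(self, ax=None):
        """RR per increment vs lag with CI whiskers (optional convenience)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lags = [e.lag for e in self.lag_effects]
        rr = [e.rr10 for e in self.lag_effects]
        lo = [e.ci_low for e in self.lag_effects]
        hi = [e.ci_high for e in self.lag_effects]
        ax.errorbar(lags, rr,
                    yerr=[np.subtract(rr, lo), np.subtract(hi, rr)],
                    fmt="o", capsize=3)
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("lag (days)")
        ax.set_ylabel(f"RR per {self.model.increment:g} ug/m3")
        return ax
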
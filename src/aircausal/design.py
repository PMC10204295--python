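"""Design-matrix builders for the Poisson time-series regression.

`natural_spline_basis` reproduces the classical natural cubic regression
spline parameterisation used throughout air-pollution epidemiology: a cubic
B-spline basis with interior knots at equally spaced quantiles of the
observation times, constrained to be linear beyond the boundary knots
(second derivative zero there).  With the intercept excluded, ``df`` basis
columns correspond to ``df - 1`` interior knots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "natural_spline_basis", "dow_design", "DOW_LEVELS"]


@dataclass
class SplineBasis:
    """Evaluated natural cubic spline basis.

    Attributes
    ----------
    df : number of basis columns (intercept excluded).
    interior_knots, boundary_knots : knot positions on the time axis.
    design : (n, df) array of basis values.
    """

    df: int
    interior_knots: np.ndarray
    boundary_knots: np.ndarray
    design: np.ndarray

    # The QR-derived constraint transform, kept so that the identical basis
    # can be evaluated at new time points (needed when a simulator and a
    # fitter must share one trend surface).
    _aug_knots: np.ndarray = None
    _transform: np.ndarray = None

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        b = _bspline_design(self._aug_knots, times)
        return b[:, 1:] @ self._transform


def _bspline_design(aug_knots: np.ndarray, x: np.ndarray, nu: int = 0) -> np.ndarray:
    """Cubic B-spline design matrix (derivative order nu) with clamped ends;
    points beyond the boundary knots are handled by cubic extrapolation of
    each basis function, matching the usual regression-spline convention."""
    n_basis = len(aug_knots) - 4
    cols = []
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        spl = BSpline(aug_knots, c, 3, extrapolate=True)
        if nu:
            spl = spl.derivative(nu)
        cols.append(spl(x))
    return np.column_stack(cols)


def natural_spline_basis(times, df: int) -> SplineBasis:
    """Natural cubic spline basis of calendar time with ``df`` columns.

    Interior knots sit at the ``df - 1`` equally spaced quantiles of
    ``times``; boundary knots at min/max.  The natural constraint (zero
    second derivative at both boundaries) is imposed by projecting the
    cubic B-spline basis onto the null space of the boundary-curvature
    functionals, after dropping the intercept direction.
    """
    times = np.asarray(times, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    n_distinct = len(np.unique(times))
    if df >= n_distinct:
        raise ValueError(f"df={df} must be < number of distinct times ({n_distinct})")

    boundary = np.array([times[0], times[-1]])
    n_interior = df - 1
    if n_interior > 0:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(times, probs)
    else:
        interior = np.array([])
    aug = np.sort(np.concatenate([np.repeat(boundary, 4), interior]))

    basis = _bspline_design(aug, times)
    const = _bspline_design(aug, boundary, nu=2)  # curvature at the boundaries
    # Drop the intercept column, then remove the two constrained directions.
    basis = basis[:, 1:]
    const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    transform = q[:, 2:]
    design = basis @ transform
    if design.shape[1] != df:
        raise AssertionError("natural spline construction yielded wrong df")
    return SplineBasis(
        df=df,
        interior_knots=interior,
        boundary_knots=boundary,
        design=design,
        _aug_knots=aug,
        _transform=transform,
    )


DOW_LEVELS = ("Tue", "Wed", "Thu", "Fri", "Sat", "Sun")  # Monday = reference


def dow_design(dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Day-of-week indicator columns, Monday as the reference level.

    Returns a (n, 6) 0/1 DataFrame; each row sums to at most 1 (zero on
    Mondays).
    """
    dates = pd.DatetimeIndex(dates)
    wd = dates.weekday  # Monday=0 .. Sunday=6
    out = {}
    for k, name in enumerate(DOW_LEVELS, start=1):
        out[f"dow_{name}"] = (wd == k).astype(float)
    return pd.DataFrame(out, index=dates)
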
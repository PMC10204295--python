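"""Convergent cross mapping (CCM) for pairwise causality detection.

CCM tests whether variable Y causally influences variable X by asking
whether X's delay-coordinate reconstruction (its shadow manifold, Takens'
theorem) encodes Y: nearby points on M_x should index times at which Y was
also similar.  Concretely, each target value y_t is estimated as an
exponentially weighted mean of y at the origin times of the E+1 nearest
library neighbours of x(t) on M_x,

    u_i = exp(-d[x(t), x(t_i)] / d[x(t), x(t_1)]),   w_i = u_i / sum_j u_j,
    y_hat_t | M_x = sum_{i=1}^{E+1} w_i * y_{t_i},

and the cross-map skill is the Pearson correlation rho between y and
y_hat.  The distinguishing signature of causality — as opposed to mirage
correlation — is convergence: skill must increase as the library length L
grows.  Significance of a single skill value uses the t statistic
t = rho / sqrt((1 - rho^2)/(N - 2)) with N - 2 degrees of freedom.

Embedding hyper-parameters can be chosen from the data: the delay tau by
the first minimum of the average mutual information, and the dimension E by
the false-nearest-neighbour criterion.

`CCM` is the model object (two series plus embedding settings); `fit()`
runs the convergence scan in both directions and returns a `CCMResults`
with per-direction curves and causality verdicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "DelayEmbedding",
    "CrossMapResult",
    "ConvergenceCurve",
    "CausalityVerdict",
    "delay_embed",
    "neighbor_weights",
    "cross_map",
    "skill_significance",
    "convergence_scan",
    "select_tau_ami",
    "select_E_fnn",
    "detect_causality",
    "CCM",
    "CCMResults",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# State-space reconstruction


@dataclass
class DelayEmbedding:
    """Delay-coordinate reconstruction of one series.

    ``vectors[i]`` is ⟨x_t, x_{t-tau}, ..., x_{t-(E-1)tau}⟩ with
    ``t = t_index[i]`` (0-based position in the source series).
    """

    E: int
    tau: int
    vectors: np.ndarray
    t_index: np.ndarray

    def __len__(self) -> int:
        return len(self.vectors)


def delay_embed(series: np.ndarray, E: int, tau: int) -> DelayEmbedding:
    """Embed a series into E lagged coordinates with delay tau.

    Produces ``L - (E-1)*tau`` vectors for a series of length L; coordinate
    k (0-based) of the vector at time t is ``series[t - k*tau]``.
    """
    series = np.asarray(series, dtype=float)
    if E < 1 or tau < 1:
        raise ValueError("need E >= 1 and tau >= 1")
    L = len(series)
    min_len = (E - 1) * tau + 1
    if L < min_len:
        raise ValueError(f"series length {L} < minimum {min_len} for E={E}, tau={tau}")
    t = np.arange((E - 1) * tau, L)
    cols = [series[t - k * tau] for k in range(E)]
    return DelayEmbedding(E=E, tau=tau, vectors=np.column_stack(cols), t_index=t)


def neighbor_weights(distances: np.ndarray) -> np.ndarray:
    """Exponential neighbour weights from sorted ascending distances.

    u_i = exp(-d_i/d_1), w_i = u_i / sum(u).  When the nearest distance is
    zero the weight mass is split equally over all zero-distance neighbours
    (the limit of the formula for exact matches).
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if np.any(np.diff(d) < 0):
        raise ValueError("distances must be sorted ascending")
    if d[0] == 0:
        w = (d == 0).astype(float)
        return w / w.sum()
    u = np.exp(-d / d[0])
    return u / u.sum()


# ---------------------------------------------------------------------------
# Cross-map estimation


@dataclass
class CrossMapResult:
    """Skill of estimating the target series from one manifold."""

    direction: str
    L: int
    rho: float
    t_stat: float
    p: float
    n_pred: int
    estimates: np.ndarray = field(repr=False)


def skill_significance(rho: float, N: int) -> tuple[float, float]:
    """t statistic and two-sided p for a cross-map skill rho over N pairs:
    t = rho / sqrt((1 - rho^2)/(N - 2)), Student t with N-2 df."""
    if N < 3:
        raise ValueError("need N >= 3")
    if abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")
    if abs(rho) == 1.0:
        logger.info("perfect skill |rho|=1: s_rho = 0, reporting p = 0")
        return float(np.inf) * np.sign(rho), 0.0
    s_rho = np.sqrt((1 - rho**2) / (N - 2))
    t = rho / s_rho
    return float(t), float(2 * stats.t.sf(abs(t), df=N - 2))


def _cross_map_dists(
    D: np.ndarray,
    t_pred: np.ndarray,
    t_lib: np.ndarray,
    y: np.ndarray,
    E: int,
    theiler: int,
) -> np.ndarray:
    """Cross-map estimates given a (n_pred, n_lib) distance matrix.

    Library points within ``theiler`` time steps of the predictee (the
    point itself included) are excluded from its neighbour search.
    """
    D = np.where(
        np.abs(t_pred[:, None] - t_lib[None, :]) <= theiler, np.inf, D
    )
    k = E + 1
    n_ok = np.isfinite(D).sum(axis=1)
    if n_ok.min() < k:
        raise ValueError(
            f"library smaller than E+2 after exclusions "
            f"(need {k} neighbours, worst predictee has {int(n_ok.min())})"
        )
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    d = np.take_along_axis(D, order, axis=1)
    d1 = d[:, :1]
    zero_first = d1[:, 0] == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.exp(-d / np.where(d1 > 0, d1, 1.0))
    w = np.where(zero_first[:, None], (d == 0.0).astype(float), u)
    w /= w.sum(axis=1, keepdims=True)
    neighbor_y = y[t_lib[order]]
    return (w * neighbor_y).sum(axis=1)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(b) == 0:
        logger.info("constant cross-map estimates: reporting rho = 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cross_map(
    manifold: DelayEmbedding,
    target: np.ndarray,
    library: np.ndarray | None = None,
    predictee: np.ndarray | None = None,
    theiler: int | None = None,
    direction: str = "y_hat|M_x",
) -> CrossMapResult:
    """Estimate the target series from a manifold and score the skill.

    ``library`` and ``predictee`` are index sets into ``manifold.vectors``
    (default: all vectors).  For each predictee the E+1 nearest library
    vectors (Euclidean distance; ties broken by index) outside the temporal
    exclusion window supply a weighted-mean estimate of the target at the
    predictee's origin time; skill is Pearson rho over all predictees.
    """
    target = np.asarray(target, dtype=float)
    if target.ndim != 1 or len(target) <= manifold.t_index.max():
        raise ValueError("target must cover the manifold's origin times")
    n = len(manifold)
    library = np.arange(n) if library is None else np.asarray(library, dtype=int)
    predictee = np.arange(n) if predictee is None else np.asarray(predictee, dtype=int)
    if library.size < manifold.E + 2:
        raise ValueError(f"library must contain at least E+2={manifold.E + 2} points")
    if theiler is None:
        theiler = (manifold.E - 1) * manifold.tau
    t_pred = manifold.t_index[predictee]
    t_lib = manifold.t_index[library]
    y_true = target[t_pred]
    if np.ptp(y_true) == 0:
        raise ValueError("zero variance in target over the predictee set")
    D = cdist(manifold.vectors[predictee], manifold.vectors[library])
    estimates = _cross_map_dists(D, t_pred, t_lib, target, manifold.E, theiler)
    rho = _safe_pearson(y_true, estimates)
    t_stat, p = skill_significance(rho, len(predictee))
    return CrossMapResult(direction=direction, L=int(library.size), rho=rho,
                          t_stat=t_stat, p=p, n_pred=int(predictee.size),
                          estimates=estimates)


# ---------------------------------------------------------------------------
# Convergence over library length


@dataclass
class ConvergenceCurve:
    """Cross-map skill as a function of library length.

    ``rho_reps[i, j]`` is the skill of replicate j at ``L_grid[i]``;
    replicates draw random contiguous library segments.
    """

    direction: str
    L_grid: np.ndarray
    rho_mean: np.ndarray
    rho_reps: np.ndarray
    n_reps: int
    seed: int | None
    n_pred: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, L in enumerate(self.L_grid):
            for j in range(self.n_reps):
                rows.append({"direction": self.direction, "L": int(L),
                             "rep": j, "rho": self.rho_reps[i, j]})
        return pd.DataFrame(rows)


def convergence_scan(
    x: np.ndarray,
    y: np.ndarray,
    E: int = 2,
    tau: int = 2,
    L_grid=None,
    n_reps: int = 100,
    seed: int | None = None,
    theiler: int | None = None,
    direction: str = "y_hat|M_x",
) -> ConvergenceCurve:
    """Scan cross-map skill of estimating y from M_x over library lengths.

    For each L, ``n_reps`` random contiguous library segments of length L
    are drawn (seeded) and the skill over all predictees recorded.  A
    single replicate at full length reduces exactly to `cross_map` on the
    full library.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    emb = delay_embed(x, E, tau)
    n_vec = len(emb)
    if L_grid is None:
        L_min = max(5 * (E + 2), 20)
        L_grid = np.unique(np.linspace(L_min, n_vec, 8).astype(int))
    L_grid = np.asarray(sorted(int(L) for L in L_grid))
    if np.any(np.diff(L_grid) <= 0):
        raise ValueError("L_grid must be strictly increasing")
    if L_grid[0] < E + 2:
        raise ValueError(f"smallest L={L_grid[0]} below minimum library size {E + 2}")
    if L_grid[-1] > n_vec:
        raise ValueError(f"largest L={L_grid[-1]} exceeds {n_vec} usable vectors")
    if theiler is None:
        theiler = (E - 1) * tau
    t_all = emb.t_index
    y_true = y[t_all]
    if np.ptp(y_true) == 0:
        raise ValueError("zero variance in target over the predictee set")
    # One full pairwise distance matrix, sliced per library segment.
    D_full = cdist(emb.vectors, emb.vectors)
    rng = np.random.default_rng(seed)
    rho_reps = np.empty((len(L_grid), n_reps))
    for i, L in enumerate(L_grid):
        for j in range(n_reps):
            start = int(rng.integers(0, n_vec - L + 1))
            lib = np.arange(start, start + L)
            est = _cross_map_dists(D_full[:, lib], t_all, t_all[lib], y,
                                   E, theiler)
            rho_reps[i, j] = _safe_pearson(y_true, est)
    return ConvergenceCurve(direction=direction, L_grid=L_grid,
                            rho_mean=rho_reps.mean(axis=1), rho_reps=rho_reps,
                            n_reps=n_reps, seed=seed, n_pred=n_vec)


# ---------------------------------------------------------------------------
# Embedding parameter selection


def select_tau_ami(series: np.ndarray, max_lag: int = 10, n_bins: int = 16) -> int:
    """Delay selection by average mutual information (AMI).

    Computes I(lag) from the 2-D equal-width histogram of (x_t, x_{t+lag})
    and returns the first local minimum over lag = 1..max_lag; if the curve
    has no local minimum the argmin is returned (logged).
    """
    series = np.asarray(series, dtype=float)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if np.ptp(series) == 0:
        raise ValueError("constant series has no mutual-information structure")
    ami = np.empty(max_lag + 1)
    for lag in range(1, max_lag + 1):
        a, b = series[:-lag], series[lag:]
        joint, _, _ = np.histogram2d(a, b, bins=n_bins)
        pxy = joint / joint.sum()
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        nz = pxy > 0
        ami[lag] = float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())
    for lag in range(1, max_lag):
        left_ok = lag == 1 or ami[lag] < ami[lag - 1]
        if left_ok and ami[lag] < ami[lag + 1]:
            return lag
    tau = int(np.argmin(ami[1:]) + 1)
    logger.info("no local AMI minimum up to lag %d; falling back to argmin %d",
                max_lag, tau)
    return tau


def select_E_fnn(series: np.ndarray, tau: int = 2, E_max: int = 8,
                 r_tol: float = 10.0, threshold: float = 0.05) -> int:
    """Embedding-dimension selection by false nearest neighbours.

    For each E the nearest neighbour of every point in the E-dimensional
    reconstruction is declared false when adding the (E+1)-th coordinate
    stretches the pair by more than ``r_tol`` relative to their E-dim
    distance.  Returns the smallest E whose false-neighbour fraction drops
    below ``threshold``; if none does, E_max with a warning.
    """
    series = np.asarray(series, dtype=float)
    if E_max < 2:
        raise ValueError("E_max must be >= 2")
    if len(series) <= E_max * tau + 1:
        raise ValueError(
            f"series length {len(series)} too short for E_max={E_max}, tau={tau}"
        )
    for E in range(1, E_max + 1):
        emb = delay_embed(series, E, tau)
        # Added coordinate when unfolding to E+1 is the next value x_{t+tau}
        # (deterministic dynamics keep it close for true neighbours; lagged
        # past values would not, since maps need not be invertible).
        keep = emb.t_index + tau < len(series)
        pts = emb.vectors[keep]
        extra = series[emb.t_index[keep] + tau]
        D = cdist(pts, pts)
        np.fill_diagonal(D, np.inf)
        nn = np.argmin(D, axis=1)
        d_e = D[np.arange(len(pts)), nn]
        stretch = np.abs(extra - extra[nn])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_e > 0, stretch / d_e,
                             np.where(stretch > 0, np.inf, 0.0))
        frac = float(np.mean(ratio > r_tol))
        if frac < threshold:
            return E
    logger.warning("FNN fraction never fell below %.0f%% up to E_max=%d",
                   100 * threshold, E_max)
    return E_max


# ---------------------------------------------------------------------------
# Verdicts and the Model/Results pair


@dataclass
class CausalityVerdict:
    """Causality decision for one direction at the 95% level.

    ``causal`` requires both convergence of skill with library length
    (positive Spearman trend of mean rho over L with one-sided p < alpha,
    and a net rise from the smallest to the largest L exceeding
    ``min_gain``) and significance of the skill at the largest L (t-test
    p < alpha with positive rho).  The gain floor separates genuine
    convergence from the small systematic drift that non-causal cross-map
    skill shows as libraries grow.
    """

    direction: str
    causal: bool
    rho_at_max_L: float
    convergence_pass: bool
    significance_pass: bool
    p_at_max_L: float
    spearman_rho: float
    spearman_p: float
    gain: float


def _verdict_from_curve(curve: ConvergenceCurve, alpha: float = 0.05,
                        min_gain: float = 0.1) -> CausalityVerdict:
    rho_max_L = float(curve.rho_mean[-1])
    gain = rho_max_L - float(curve.rho_mean[0])
    if len(curve.L_grid) >= 3:
        sp = stats.spearmanr(curve.L_grid, curve.rho_mean, alternative="greater")
        sp_rho, sp_p = float(sp.statistic), float(sp.pvalue)
    else:
        sp_rho, sp_p = np.nan, 1.0
    convergence = (sp_p < alpha) and (gain > min_gain)
    _, p = skill_significance(np.clip(rho_max_L, -1.0, 1.0), curve.n_pred)
    significance = (p < alpha) and (rho_max_L > 0)
    return CausalityVerdict(
        direction=curve.direction,
        causal=bool(convergence and significance),
        rho_at_max_L=rho_max_L,
        convergence_pass=bool(convergence),
        significance_pass=bool(significance),
        p_at_max_L=float(p),
        spearman_rho=sp_rho,
        spearman_p=sp_p,
        gain=gain,
    )


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"series {name!r} cannot be z-scored (zero variance)")
    return (v - v.mean()) / sd


class CCM:
    """Convergent-cross-mapping model for one pair of series.

    Parameters
    ----------
    x, y : equal-length series (e.g. daily exposure and daily counts).
    E, tau : embedding dimension and delay (defaults 2 and 2; use
        `select_embedding` to choose them from the data instead).
    theiler : temporal exclusion radius for neighbour searches; default
        (E-1)*tau.
    normalize : z-score both series before embedding (default True).
    log1p_y : apply log(1+y) to the y series before normalising, useful for
        counts (default False).
    """

    def __init__(self, x, y, E: int = 2, tau: int = 2,
                 theiler: int | None = None, normalize: bool = True,
                 log1p_y: bool = False, x_name: str = "x", y_name: str = "y"):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("series must have equal length")
        if log1p_y:
            y = np.log1p(y)
        self.x = _zscore(x, x_name) if normalize else x
        self.y = _zscore(y, y_name) if normalize else y
        self.E = E
        self.tau = tau
        self.theiler = theiler
        self.x_name = x_name
        self.y_name = y_name

    def select_embedding(self, max_lag: int = 10, n_bins: int = 16,
                         E_max: int = 8, r_tol: float = 10.0) -> tuple[int, int]:
        """Choose (E, tau) from the x series: tau by the first AMI minimum,
        E by the false-nearest-neighbour criterion at that tau."""
        self.tau = select_tau_ami(self.x, max_lag=max_lag, n_bins=n_bins)
        self.E = select_E_fnn(self.x, tau=self.tau, E_max=E_max, r_tol=r_tol)
        return self.E, self.tau

    def fit(self, L_grid=None, n_reps: int = 100, seed: int | None = None,
            alpha: float = 0.05, min_gain: float = 0.1) -> "CCMResults":
        """Run the convergence scan in both directions and judge causality.

        Direction semantics: the skill of estimating y from M_x measures
        y's causal influence on x (x's dynamics encode y only if y forces
        x), and symmetrically for x from M_y.
        """
        dir_yx = f"{self.y_name}->{self.x_name}"
        dir_xy = f"{self.x_name}->{self.y_name}"
        curve_yx = convergence_scan(self.x, self.y, self.E, self.tau, L_grid,
                                    n_reps, seed, self.theiler, dir_yx)
        curve_xy = convergence_scan(self.y, self.x, self.E, self.tau, L_grid,
                                    n_reps, None if seed is None else seed + 1,
                                    self.theiler, dir_xy)
        curves = {dir_yx: curve_yx, dir_xy: curve_xy}
        verdicts = {d: _verdict_from_curve(c, alpha, min_gain)
                    for d, c in curves.items()}
        return CCMResults(self, curves, verdicts, alpha)


class CCMResults:
    """Curves and verdicts from a fitted `CCM`."""

    def __init__(self, model: CCM, curves: dict, verdicts: dict, alpha: float):
        self.model = model
        self.curves = curves
        self.verdicts = verdicts
        self.alpha = alpha

    def to_frame(self) -> pd.DataFrame:
        """Long-format replicate table: direction, L, rep, rho."""
        return pd.concat([c.to_frame() for c in self.curves.values()],
                         ignore_index=True)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Convergent cross mapping",
            f"  E={m.E}  tau={m.tau}  level={1 - self.alpha:.0%}",
            f"  {'direction':<16}{'rho(maxL)':>10}{'converges':>11}"
            f"{'signif':>8}{'causal':>8}",
        ]
        for d, v in self.verdicts.items():
            lines.append(
                f"  {d:<16}{v.rho_at_max_L:>10.3f}"
                f"{str(v.convergence_pass):>11}{str(v.significance_pass):>8}"
                f"{str(v.causal):>8}"
            )
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Mean skill vs library length for both directions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for d, c in self.curves.items():
            ax.plot(c.L_grid, c.rho_mean, marker="o", label=d)
        ax.set_xlabel("library length L")
        ax.set_ylabel(r"cross-map skill $\rho$")
        ax.legend()
        return ax


def detect_causality(
    x, y, E: int = 2, tau: int = 2, auto_select: bool = False,
    L_grid=None, n_reps: int = 20, seed: int | None = None,
    theiler: int | None = None, alpha: float = 0.05, min_gain: float = 0.1,
    log1p_y: bool = False, x_name: str = "x", y_name: str = "y",
) -> dict[str, CausalityVerdict]:
    """Convenience wrapper: z-score, (optionally) auto-select (E, tau), scan
    both directions, and return verdicts keyed "y->x" style
    ("{y_name}->{x_name}" = y causally influences x)."""
    model = CCM(x, y, E=E, tau=tau, theiler=theiler, log1p_y=log1p_y,
                x_name=x_name, y_name=y_name)
    if auto_select:
        model.select_embedding()
    return model.fit(L_grid=L_grid, n_reps=n_reps, seed=seed,
                     alpha=alpha, min_gain=min_gain).verdicts
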
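"""Distribution standardization and scaling analyses.

Single-cell scalar distributions (fluorescence or growth rate) measured at
different times often differ only by an affine rescaling: subtracting each
snapshot's mean and dividing by its standard deviation collapses them onto a
single shape. This module quantifies that collapse, fits the accompanying
variance-versus-mean law (a quadratic in the mean), and provides fluctuation
statistics (windowed coefficient of variation, autocorrelation time) for
slowly varying population time series such as chemostat density.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDistributionError, FitError

__all__ = [
    "ScalarDistributionSnapshot",
    "QuadraticLaw",
    "VarianceMeanFit",
    "CollapseResult",
    "CorrelationTime",
    "standardize",
    "collapse_distance",
    "fit_variance_mean",
    "windowed_cv",
    "autocorrelation_time",
]


@dataclass(frozen=True)
class ScalarDistributionSnapshot:
    """One time point's single-cell scalar values.

    Values are in arbitrary units (fluorescence) or 1/hour (growth rate).
    Moments are recomputed from the values on demand, so they can never
    drift out of sync with the data. Population conventions (``ddof=0``)
    are used throughout.
    """

    time_label: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("snapshot values must be a non-empty 1-D array")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))

    @property
    def variance(self) -> float:
        return float(np.var(self.values))


@dataclass(frozen=True)
class QuadraticLaw:
    """variance = a + b * mean + c * mean**2.

    ``a`` carries units², ``b`` units, ``c`` is dimensionless.
    """

    a: float
    b: float
    c: float = 0.0

    def __call__(self, mean):
        m = np.asarray(mean, dtype=float)
        out = self.a + self.b * m + self.c * m * m
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class VarianceMeanFit:
    """OLS fit of snapshot variance on (1, mean, mean²)."""

    law: QuadraticLaw
    means: np.ndarray
    variances: np.ndarray
    residuals: np.ndarray
    rsq: float


@dataclass(frozen=True)
class CollapseResult:
    """Pairwise distances between standardized snapshots."""

    labels: tuple
    matrix: np.ndarray
    metric: str

    @property
    def max_distance(self) -> float:
        return float(np.max(self.matrix))


def standardize(snapshot) -> np.ndarray:
    """Subtract the mean and divide by the standard deviation.

    Accepts a :class:`ScalarDistributionSnapshot` or a plain array. The
    output has mean 0 and (population) SD 1 to floating-point tolerance.

    Raises
    ------
    DegenerateDistributionError
        If the sample SD is zero.
    """
    values = snapshot.values if isinstance(snapshot, ScalarDistributionSnapshot) else np.asarray(snapshot, float)
    sd = np.std(values)
    if sd == 0:
        raise DegenerateDistributionError("cannot standardize a zero-variance sample")
    return (values - np.mean(values)) / sd


def collapse_distance(snapshots, metric: str = "ks") -> CollapseResult:
    """Pairwise two-sample distances between standardized snapshots.

    ``metric`` is ``"ks"`` (Kolmogorov–Smirnov statistic; default, with a
    distribution-free null) or ``"cvm"`` (Cramér–von Mises statistic). The
    summary is the maximum pairwise value: small means all snapshots share
    one shape up to affine rescaling.
    """
    snapshots = list(snapshots)
    if len(snapshots) < 2:
        raise ValueError("collapse_distance needs at least two snapshots")
    std = [standardize(s) for s in snapshots]
    labels = tuple(
        s.time_label if isinstance(s, ScalarDistributionSnapshot) else str(i)
        for i, s in enumerate(snapshots)
    )
    n = len(std)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if metric == "ks":
            d = stats.ks_2samp(std[i], std[j], method="asymp").statistic
        elif metric == "cvm":
            d = stats.cramervonmises_2samp(std[i], std[j]).statistic
        else:
            raise ValueError(f"unknown collapse metric: {metric!r}")
        mat[i, j] = mat[j, i] = d
    return CollapseResult(labels=labels, matrix=mat, metric=metric)


def _extract_points(snapshots, variances):
    if variances is not None:
        return np.asarray(snapshots, float), np.asarray(variances, float)
    snaps = list(snapshots)
    means = np.array([s.mean for s in snaps])
    var = np.array([s.variance for s in snaps])
    return means, var


def fit_variance_mean(snapshots, variances=None, *, constrain_linear: bool = False) -> VarianceMeanFit:
    """Ordinary least squares of variance on (1, mean, mean²).

    Call either with a sequence of snapshots, or with arrays
    ``fit_variance_mean(means, variances)``. With ``constrain_linear`` the
    quadratic coefficient is pinned to zero (for model comparison). The fit
    is unweighted; points generated exactly on a quadratic are recovered to
    solver precision.
    """
    means, var = _extract_points(snapshots, variances)
    n_par = 2 if constrain_linear else 3
    if means.size < n_par + 1:
        raise FitError(f"need at least {n_par + 1} snapshots, got {means.size}")
    cols = [np.ones_like(means), means] + ([] if constrain_linear else [means**2])
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < n_par:
        raise FitError("degenerate design: snapshot means are not distinct")
    coef, *_ = np.linalg.lstsq(design, var, rcond=None)
    law = QuadraticLaw(float(coef[0]), float(coef[1]), 0.0 if constrain_linear else float(coef[2]))
    resid = var - law(means)
    ss_tot = float(np.sum((var - var.mean()) ** 2))
    rsq = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    return VarianceMeanFit(law=law, means=means, variances=var, residuals=resid, rsq=rsq)


def windowed_cv(values, window: float, dt: float = 1.0) -> pd.DataFrame:
    """Per-window coefficient of variation σ/μ of a uniformly sampled series.

    ``window`` and ``dt`` share units (hours by convention). Windows are
    non-overlapping and only complete windows are reported. Used to compare
    background fluctuation magnitude against adapted-phase fluctuations.
    """
    vals = np.asarray(values, dtype=float)
    if np.any(vals <= 0):
        raise ValueError("windowed_cv requires positive values")
    width = int(round(window / dt))
    if width < 2:
        raise ValueError("window must cover at least two samples")
    if width > vals.size:
        raise ValueError("window longer than the series span")
    n_win = vals.size // width
    starts, cvs = [], []
    for k in range(n_win):
        chunk = vals[k * width : (k + 1) * width]
        starts.append(k * width * dt)
        cvs.append(float(np.std(chunk) / np.mean(chunk)))
    return pd.DataFrame({"t_start": starts, "cv": cvs})


@dataclass(frozen=True)
class CorrelationTime:
    """Autocorrelation time, in sampling units and (optionally) generations."""

    time: float
    generations: float | None = None


def autocorrelation_time(values, dt: float = 1.0, generation_time: float | None = None) -> CorrelationTime:
    """First lag at which the autocorrelation drops below 1/e.

    The series is mean-removed; the crossing lag is linearly interpolated.
    Requires at least 50 uniformly spaced samples. A correlation time of
    many generations distinguishes slow collective fluctuations from
    division-timescale noise.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 50:
        raise ValueError("autocorrelation_time needs at least 50 samples")
    x = vals - vals.mean()
    var = float(x @ x)
    if var == 0:
        raise DegenerateDistributionError("autocorrelation time undefined for a constant series")
    target = 1.0 / np.e
    acf_prev = 1.0
    for lag in range(1, vals.size):
        acf = float(x[lag:] @ x[:-lag]) / var
        if acf < target:
            frac = (acf_prev - target) / (acf_prev - acf)
            tau = (lag - 1 + frac) * dt
            gens = tau / generation_time if generation_time else None
            return CorrelationTime(time=tau, generations=gens)
        acf_prev = acf
    raise ValueError("autocorrelation never dropped below 1/e within the series")
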
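"""Pearson correlation over experiment subsets, correlation significance,
and the A/B correlation sets that drive experiment selection.

The correlation between two genes over a subset of experiments is the sample
Pearson correlation of their profiles over the *concatenated* arrays of the
member experiments.  Significance of a single correlation uses the classical
t-transform ``t = r*sqrt((n-2)/(1-r^2))`` with ``n-2`` degrees of freedom;
confidence bounds use the Fisher z transform ``atanh(r)`` with approximate
variance ``1/(n-3)``.

Missing values are handled pairwise-complete: a gene pair contributes a
correlation only where both measurements are present, and pairs with fewer
than :data:`MIN_COMPLETE` complete positions (or zero variance) are counted
as *dropped* rather than imputed.

The module also provides :func:`log_t_sf`, a Student-t upper-tail log
probability that stays finite far below double underflow.  Selection
compares one-sided t-test p-values that routinely underflow ``float64``
(t-statistics in the hundreds with thousands of degrees of freedom), so the
tail is evaluated directly in log space via the regularized incomplete-beta
continued fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .io import ExpressionCollection, ExpressionMatrix, GenePartition

__all__ = [
    "MIN_COMPLETE",
    "CorrelationSets",
    "pearson",
    "correlation_pvalue",
    "fisher_bounds",
    "log_t_sf",
    "concatenate_profiles",
    "build_correlation_sets",
    "filter_significant",
]

#: minimum pairwise-complete positions for a correlation to be defined
MIN_COMPLETE = 3


# ---------------------------------------------------------------------------
# log-space Student-t tail
# ---------------------------------------------------------------------------

def _betacf(a: float, b: float, x: float, max_iter: int = 500, eps: float = 3e-16) -> float:
    """Continued fraction for the regularized incomplete beta (Lentz)."""
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < 1e-300:
        d = 1e-300
    d = 1.0 / d
    h = d
    for m in range(1, max_iter):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < 1e-300:
            d = 1e-300
        c = 1.0 + aa / c
        if abs(c) < 1e-300:
            c = 1e-300
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            break
    return h


def _log_betainc(a: float, b: float, x: float) -> float:
    """log of the regularized incomplete beta I_x(a, b), stable for tiny I."""
    if x <= 0.0:
        return -math.inf
    if x >= 1.0:
        return 0.0
    lfront = (
        a * math.log(x)
        + b * math.log1p(-x)
        - math.log(a)
        - special.betaln(a, b)
    )
    if x < (a + 1.0) / (a + b + 2.0):
        return lfront + math.log(_betacf(a, b, x))
    lcomp = (
        b * math.log1p(-x)
        + a * math.log(x)
        - math.log(b)
        - special.betaln(a, b)
        + math.log(_betacf(b, a, 1.0 - x))
    )
    return math.log1p(-math.exp(min(lcomp, 0.0)))


def log_t_sf(t: float, df: float) -> float:
    """``log P(T > t)`` for Student t with ``df`` degrees of freedom.

    Finite (not ``-inf``) even when the tail probability underflows a
    ``float64``, so p-values of wildly different magnitudes remain ordered.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    t = float(t)
    if not math.isfinite(t):
        return -math.inf if t > 0 else 0.0
    if t <= 0:
        # tail >= 1/2; no underflow possible
        return math.log(special.stdtr(df, -t))
    x = df / (df + t * t)
    return math.log(0.5) + _log_betainc(df / 2.0, 0.5, x)


# ---------------------------------------------------------------------------
# pairwise correlation kernels
# ---------------------------------------------------------------------------

def _standardize_rows(X: np.ndarray):
    """Center and unit-normalize rows; returns (Z, defined) where rows with
    zero variance are flagged undefined (Z row zeroed)."""
    Z = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1)
    defined = norms > 0
    Z[defined] /= norms[defined, None]
    Z[~defined] = 0.0
    return Z, defined


def _corr_complete(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-by-row correlation matrix for complete (NaN-free) data."""
    Zx, okx = _standardize_rows(np.array(X, dtype=float))
    Zy, oky = _standardize_rows(np.array(Y, dtype=float))
    R = Zx @ Zy.T
    R[~okx, :] = np.nan
    R[:, ~oky] = np.nan
    return np.clip(R, -1.0, 1.0, out=R)


def _corr_pairwise(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise-complete correlation matrix; NaN marks undefined pairs
    (< MIN_COMPLETE shared positions or zero variance)."""
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    Mx = np.isfinite(X).astype(float)
    My = np.isfinite(Y).astype(float)
    Xf = np.where(np.isfinite(X), X, 0.0)
    Yf = np.where(np.isfinite(Y), Y, 0.0)
    n = Mx @ My.T
    sx = Xf @ My.T
    sy = Mx @ Yf.T
    sxx = (Xf * Xf) @ My.T
    syy = Mx @ (Yf * Yf).T
    sxy = Xf @ Yf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        R = cov / np.sqrt(vx * vy)
    eps = 1e-12
    bad = (n < MIN_COMPLETE) | (vx <= eps * np.maximum(sxx * n, 1.0)) | (
        vy <= eps * np.maximum(syy * n, 1.0)
    )
    R[bad] = np.nan
    return np.clip(R, -1.0, 1.0, out=R)


def _cross_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if np.isnan(X).any() or np.isnan(Y).any():
        return _corr_pairwise(X, Y)
    return _corr_complete(X, Y)


def pearson(x, y) -> float:
    """Sample Pearson correlation on pairwise-complete positions.

    Returns ``NaN`` (the "undefined correlation" signal) when fewer than
    :data:`MIN_COMPLETE` complete positions remain or either vector is
    constant on them; callers count such pairs as dropped.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < MIN_COMPLETE:
        return float("nan")
    xs, ys = x[ok], y[ok]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    nx, ny = np.linalg.norm(xs), np.linalg.norm(ys)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(np.clip(xs @ ys / (nx * ny), -1.0, 1.0))


def correlation_pvalue(r, n_arrays: int):
    """Two-sided p-value of a Pearson correlation via the t-transform.

    ``t = r*sqrt((n-2)/(1-r^2))`` follows Student t with ``n-2`` degrees of
    freedom under the bivariate-normal null; ``|r| = 1`` maps to p = 0.
    Accepts scalars or arrays.
    """
    if n_arrays < 3:
        raise ValueError("n_arrays must be >= 3")
    r_arr = np.asarray(r, dtype=float)
    if np.nanmax(np.abs(r_arr), initial=0.0) > 1.0 + 1e-12:
        raise ValueError("|r| must be <= 1")
    r_c = np.clip(r_arr, -1.0, 1.0)
    df = n_arrays - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r_c) * np.sqrt(df / (1.0 - r_c * r_c))
    p = np.where(np.abs(r_c) >= 1.0, 0.0, 2.0 * special.stdtr(df, -t))
    p = np.where(np.isnan(r_c), np.nan, p)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(p)
    return p


def fisher_bounds(r: float, n_arrays: int, confidence: float = 0.95):
    """Confidence interval for a correlation via the Fisher z transform.

    ``z = atanh(r)`` is approximately normal with variance ``1/(n-3)``; the
    interval is mapped back through ``tanh``.
    """
    if n_arrays < 4:
        raise ValueError("n_arrays must be >= 4 for Fisher bounds")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    z = math.atanh(r)
    q = special.ndtri(0.5 + confidence / 2.0)
    half = q / math.sqrt(n_arrays - 3)
    return math.tanh(z - half), math.tanh(z + half)


# ---------------------------------------------------------------------------
# A/B correlation sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationSets:
    """Within-category (A) and category-vs-background (B) correlations.

    A holds the upper triangle of the category-category correlation matrix
    (diagonal excluded); B holds every category x background pair.
    Background-background pairs are never used.  ``dropped_pairs`` counts
    pairs whose correlation was undefined on the subset.
    """

    a_values: np.ndarray
    b_values: np.ndarray
    n_arrays: int
    dropped_pairs: int = 0

    def __post_init__(self):
        object.__setattr__(self, "a_values", np.asarray(self.a_values, dtype=float))
        object.__setattr__(self, "b_values", np.asarray(self.b_values, dtype=float))


def concatenate_profiles(collection: ExpressionCollection, experiment_subset) -> ExpressionMatrix:
    """Restrict the matrix to the subset's arrays (manifest order preserved)."""
    cols = collection.column_indices(experiment_subset)
    m = collection.matrix
    return ExpressionMatrix(
        m.values[:, cols],
        m.gene_ids,
        tuple(m.array_ids[j] for j in cols),
    )


def build_correlation_sets(collection: ExpressionCollection, experiment_subset,
                           partition: GenePartition) -> CorrelationSets:
    """Compute the A and B correlation sets over an experiment subset."""
    cols = collection.column_indices(experiment_subset)
    if len(cols) < MIN_COMPLETE:
        raise ValueError(
            f"experiment subset spans {len(cols)} arrays; >= {MIN_COMPLETE} required"
        )
    m = collection.matrix
    X = m.values[np.ix_(m.gene_indices(partition.category), cols)]
    Y = m.values[np.ix_(m.gene_indices(partition.background), cols)]
    Rcc = _cross_correlations(X, X)
    Rcb = _cross_correlations(X, Y)
    iu = np.triu_indices(X.shape[0], k=1)
    a_all = Rcc[iu]
    b_all = Rcb.ravel()
    a_values = a_all[np.isfinite(a_all)]
    b_values = b_all[np.isfinite(b_all)]
    dropped = int(np.isnan(a_all).sum() + np.isnan(b_all).sum())
    if a_values.size == 0 and b_values.size == 0:
        raise ValueError("all gene pairs have undefined correlation on this subset")
    return CorrelationSets(a_values, b_values, int(len(cols)), dropped)


def filter_significant(values, n_arrays: int, alpha: float = 0.05) -> np.ndarray:
    """Keep only correlations significant at ``alpha`` (two-sided t-transform).

    This is the length-bias control: shorter profile vectors need larger
    correlations to survive, so distributions computed over subsets of
    different sizes stay comparable.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    p = correlation_pvalue(values, n_arrays)
    return values[np.asarray(p) < alpha]
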
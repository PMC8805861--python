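"""Connectivity estimators: lagged, antisymmetric, symmetric, zero-lag, Granger.

The directed methods exploit temporal precedence: region j is taken to drive
region k when the activation of j correlates with a *later* copy of the
activation of k.  For a lag d the lagged correlation matrix L holds, at entry
(j, k), the Pearson correlation between the first N-d samples of x_j and the
last N-d samples of x_k,

    rho_{j->k}(d) = 1/(N-d-1) * sum_i z(x_j')_i * z(x_k')_i,

with per-segment means and standard deviations.  L is generally asymmetric and
decomposes uniquely into an antisymmetric part A = L - L^T (net directed
influence; a single positive entry per region pair after clipping) and a
symmetric part S = L + L^T (undirected connectivity at that lag).  Negative
entries and self-connections are excluded from all network analyses by setting
them to zero, after the decomposition.

All estimators follow the scikit-learn transformer protocol and map an array
of per-subject time series, shape (n_subjects, n_regions, n_timepoints) or a
list of (n_regions, n_timepoints) arrays, to a stack of connectivity matrices
of shape (n_subjects, n_regions, n_regions).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ConnectivityMatrix, RegionTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "LaggedCorrelation",
    "AntisymmetricCorrelation",
    "SymmetricCorrelation",
    "ZeroLagCorrelation",
    "GrangerCausality",
    "lagged_correlation",
    "antisymmetric_part",
    "symmetric_part",
    "zero_lag_correlation",
    "granger_matrix",
    "group_average_matrix",
    "weight_histogram",
    "clip_connections",
]


def clip_connections(weights: np.ndarray) -> np.ndarray:
    """Zero negative entries and the diagonal (exclude anti-correlations and
    self-connections from the network analyses)."""
    w = np.array(weights, dtype=float, copy=True)
    w[w < 0] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def _ts_data(ts) -> np.ndarray:
    if isinstance(ts, RegionTimeSeries):
        return ts.data
    x = np.asarray(ts, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D region x time array")
    return x


def _ts_meta(ts) -> dict:
    if isinstance(ts, RegionTimeSeries):
        return {"region_labels": ts.region_labels, "subject_id": ts.subject_id}
    return {}


class _BaseConnectivity(BaseEstimator, TransformerMixin):
    """Shared multi-subject plumbing; subclasses implement ``_single``."""

    def _iter_subjects(self, X):
        if isinstance(X, (RegionTimeSeries, np.ndarray)) and (
            isinstance(X, RegionTimeSeries) or X.ndim == 2
        ):
            raise ValueError(
                "X must be a collection of subjects; wrap a single subject in a list"
            )
        return [_ts_data(x) for x in X]

    def fit(self, X, y=None):
        data = self._iter_subjects(X)
        if not data:
            raise ValueError("X is empty")
        self.n_regions_ = data[0].shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        data = self._iter_subjects(X)
        return np.stack([self._single(x) for x in data])

    def _single(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _zscore_segments(seg: np.ndarray) -> np.ndarray:
    """Row-wise z-scoring with sample SD (ddof=1); constant rows -> zeros."""
    mu = seg.mean(axis=1, keepdims=True)
    sd = seg.std(axis=1, ddof=1, keepdims=True)
    bad = (sd <= 0).ravel()
    if bad.any():
        logger.warning(
            "zero-variance segment for %d region(s); their connections set to 0",
            int(bad.sum()),
        )
    sd[sd <= 0] = 1.0
    z = (seg - mu) / sd
    z[bad, :] = 0.0
    return z


class LaggedCorrelation(_BaseConnectivity):
    """Lagged Pearson correlation matrix L at a fixed temporal lag.

    Parameters
    ----------
    lag : int
        Number of sampling steps by which the target series is shifted.
        ``lag=0`` reproduces the classical Pearson correlation matrix.
    clip : bool
        Zero negatives and the diagonal after computing L.  Off by default:
        the antisymmetric/symmetric decomposition consumes the signed matrix.
    """

    def __init__(self, lag: int = 1, clip: bool = False):
        self.lag = lag
        self.clip = clip

    def _single(self, x: np.ndarray) -> np.ndarray:
        n_t = x.shape[1]
        d = int(self.lag)
        if d < 0:
            raise ValueError("lag must be nonnegative")
        if d >= n_t - 2:
            raise ValueError(f"lag {d} too large for {n_t} time points (need d < N-2)")
        early = _zscore_segments(x[:, : n_t - d])  # x_j' : first N-d samples
        late = _zscore_segments(x[:, d:])  # x_k' : last N-d samples
        L = early @ late.T / (n_t - d - 1)
        over = np.abs(L) > 1.0 + 1e-12
        if over.any():
            logger.warning("clamped %d lagged-correlation entries to [-1, 1]", int(over.sum()))
        np.clip(L, -1.0, 1.0, out=L)
        return clip_connections(L) if self.clip else L


class AntisymmetricCorrelation(_BaseConnectivity):
    """Antisymmetric part A = L - L^T of the lagged correlation matrix.

    The clipped A keeps, for each region pair, a single nonnegative entry whose
    position encodes the net direction of influence and whose value its
    magnitude.
    """

    def __init__(self, lag: int = 1, clip: bool = True):
        self.lag = lag
        self.clip = clip

    def _single(self, x: np.ndarray) -> np.ndarray:
        L = LaggedCorrelation(lag=self.lag, clip=False)._single(x)
        A = L - L.T
        return clip_connections(A) if self.clip else A


class SymmetricCorrelation(_BaseConnectivity):
    """Symmetric part S = L + L^T: undirected connectivity at the given lag."""

    def __init__(self, lag: int = 1, clip: bool = True):
        self.lag = lag
        self.clip = clip

    def _single(self, x: np.ndarray) -> np.ndarray:
        L = LaggedCorrelation(lag=self.lag, clip=False)._single(x)
        S = L + L.T
        return clip_connections(S) if self.clip else S


class ZeroLagCorrelation(_BaseConnectivity):
    """Classical zero-lag Pearson correlation, rho_jk = cov(x_j,x_k)/(s_j s_k)."""

    def __init__(self, clip: bool = True):
        self.clip = clip

    def _single(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] < 3:
            raise ValueError("need at least 3 time points")
        # same z-scoring path as the lagged estimator, so the lag-0 and
        # symmetric(d=0) identities hold bit-for-bit, not just to tolerance
        z = _zscore_segments(x)
        C = z @ z.T / (x.shape[1] - 1)
        np.clip(C, -1.0, 1.0, out=C)
        return clip_connections(C) if self.clip else C


#: Floor for residual variances in the Granger log-ratio; caps F instead of
#: letting a noiseless deterministic coupling overflow to infinity.
EPS_VAR = 1e-12


def _lag_design(series: np.ndarray, p: int) -> np.ndarray:
    """Columns series(t-1..t-p) for t = p..T-1."""
    return np.column_stack([series[p - j : len(series) - j] for j in range(1, p + 1)])


def _granger_pair(target: np.ndarray, source: np.ndarray, p: int) -> float:
    """F_{source->target} = ln(var(eps_R)/var(eps_U)) from bivariate AR(p) fits."""
    y = target[p:]
    own = _lag_design(target, p)
    other = _lag_design(source, p)
    ones = np.ones((len(y), 1))
    x_r = np.hstack([ones, own])
    x_u = np.hstack([ones, own, other])
    if np.linalg.matrix_rank(x_u) < x_u.shape[1]:
        logger.warning("singular Granger design; returning F=0 for this pair")
        return 0.0
    rss_r = np.sum((y - x_r @ np.linalg.lstsq(x_r, y, rcond=None)[0]) ** 2)
    rss_u = np.sum((y - x_u @ np.linalg.lstsq(x_u, y, rcond=None)[0]) ** 2)
    var_r = max(rss_r / len(y), EPS_VAR)
    var_u = max(rss_u / len(y), EPS_VAR)
    return float(np.log(var_r / var_u))


class GrangerCausality(_BaseConnectivity):
    """Pairwise bivariate Granger causality network.

    Every ordered region pair (j, k) is fitted to a bivariate autoregressive
    model of order p by ordinary least squares; the entry (j, k) is
    F_{j->k} = ln(var(eps_R)/var(eps_U)), the log-ratio of the residual
    variance of the target's own-history model to that of the model augmented
    with the source's history.  Series are demeaned and linearly detrended
    first; if a series still looks non-stationary (lag-1 autocorrelation
    > 0.99) all series are first-differenced, preserving alignment.
    """

    def __init__(self, order: int = 1, clip: bool = True, stationarity_check: bool = True):
        self.order = order
        self.clip = clip
        self.stationarity_check = stationarity_check

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = signal.detrend(x, axis=1, type="linear")
        if self.stationarity_check:
            a = x[:, :-1]
            b = x[:, 1:]
            sd = x.std(axis=1)
            ok = sd > 0
            ac1 = np.zeros(x.shape[0])
            if ok.any():
                ac1[ok] = np.array(
                    [np.corrcoef(a[i], b[i])[0, 1] for i in np.nonzero(ok)[0]]
                )
            if (np.abs(ac1) > 0.99).any():
                logger.warning(
                    "unit-root heuristic failed for %d series; first-differencing all",
                    int((np.abs(ac1) > 0.99).sum()),
                )
                x = np.diff(x, axis=1)
        return x

    def _single(self, x: np.ndarray) -> np.ndarray:
        p = int(self.order)
        if p < 1:
            raise ValueError("order must be >= 1")
        if p >= x.shape[1] / 4:
            raise ValueError(f"order {p} too large for {x.shape[1]} time points")
        x = self._prepare(x)
        n = x.shape[0]
        F = np.zeros((n, n))
        for j in range(n):
            for k in range(n):
                if j != k:
                    F[j, k] = _granger_pair(x[k], x[j], p)
        return clip_connections(F) if self.clip else F


# ---------------------------------------------------------------------------
# Functional wrappers operating on a single subject
# ---------------------------------------------------------------------------


def _wrap(ts, weights, method, lag, clipped) -> ConnectivityMatrix:
    return ConnectivityMatrix(weights=weights, method=method, lag=lag, clipped=clipped, **_ts_meta(ts))


def lagged_correlation(ts, d: int) -> ConnectivityMatrix:
    """Unclipped lagged correlation matrix L at lag ``d`` for one subject."""
    return _wrap(ts, LaggedCorrelation(lag=d)._single(_ts_data(ts)), "lagged", d, False)


def antisymmetric_part(L: ConnectivityMatrix, clip: bool = True) -> ConnectivityMatrix:
    """A = L - L^T from an unclipped lagged matrix; clipped by default."""
    if L.method != "lagged" or L.clipped:
        raise ValueError("antisymmetric_part expects an unclipped lagged matrix")
    A = L.weights - L.weights.T
    if clip:
        A = clip_connections(A)
    return ConnectivityMatrix(A, "antisymmetric", L.lag, clip, L.region_labels, L.subject_id)


def symmetric_part(L: ConnectivityMatrix, clip: bool = True) -> ConnectivityMatrix:
    """S = L + L^T from an unclipped lagged matrix; clipped by default."""
    if L.method != "lagged" or L.clipped:
        raise ValueError("symmetric_part expects an unclipped lagged matrix")
    S = L.weights + L.weights.T
    if clip:
        S = clip_connections(S)
    return ConnectivityMatrix(S, "symmetric", L.lag, clip, L.region_labels, L.subject_id)


def zero_lag_correlation(ts, clip: bool = True) -> ConnectivityMatrix:
    return _wrap(ts, ZeroLagCorrelation(clip=clip)._single(_ts_data(ts)), "zerolag", 0, clip)


def granger_matrix(ts, order: int = 1, clip: bool = True) -> ConnectivityMatrix:
    return _wrap(
        ts, GrangerCausality(order=order, clip=clip)._single(_ts_data(ts)), "granger", order, clip
    )


def group_average_matrix(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of participant-specific matrices (group-representative
    adjacency)."""
    if not mats:
        raise ValueError("empty matrix list")
    first = mats[0]
    for m in mats:
        if m.weights.shape != first.weights.shape:
            raise ValueError("matrices must share a common shape")
        if m.method != first.method or m.lag != first.lag:
            raise ValueError("cannot average matrices with mixed method or lag")
    mean = np.mean([m.weights for m in mats], axis=0)
    return ConnectivityMatrix(
        mean, first.method, first.lag, first.clipped, first.region_labels, "group-average"
    )


def weight_histogram(
    mat: ConnectivityMatrix | np.ndarray,
    n_bins: int = 50,
    include_zeros: bool = False,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin_edges) of off-diagonal connection strengths.

    Exact zeros (clipped connections) are excluded by default so the histogram
    describes the strengths of present connections.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    w = mat.weights if isinstance(mat, ConnectivityMatrix) else np.asarray(mat, dtype=float)
    off = w[~np.eye(w.shape[0], dtype=bool)]
    if not include_zeros:
        off = off[off != 0]
    counts, edges = np.histogram(off, bins=n_bins, range=value_range)
    return counts, edges
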
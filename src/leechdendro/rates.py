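"""Binned firing rates and the time-varying unbiased cross-covariance.

The average firing rate (AFR) of a unit or nerve is the spike count per
fixed-width bin divided by the bin width (Hz).  For a pair of rate series
f1, f2 the covariance is computed in a sliding window of N samples
(default 100, i.e. 50 s at the 0.5 s bin): within each window the means
are removed and

    rho_12(m) = 1/(N-|m|) * sum_{n=0}^{N-|m|-1} (f1(n+m) - f1bar)(f2(n) - f2bar)

for m >= 0, with rho_12(m) = rho_21(-m) for m < 0 (unbiased 1/(N-|m|)
normalization).  A scalar per window is the mean of rho_12(m) over lags
m in [-max_lag, max_lag]; it is assigned to the center of the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .containers import SpikeTrain

DEFAULT_BINWIDTH = 0.5  # s
DEFAULT_WINDOW_SAMPLES = 100  # N: 50 s at the default bin
DEFAULT_MAX_LAG = 5  # bins


@dataclass
class RateSeries:
    """Binned average firing rate on half-open bins [t0+i*w, t0+(i+1)*w)."""

    t0: float
    binwidth: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.binwidth <= 0:
            raise ValueError("binwidth must be > 0")

    @property
    def centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.values.size) + 0.5) * self.binwidth

    def same_grid(self, other: "RateSeries") -> bool:
        return (
            abs(self.t0 - other.t0) < 1e-9
            and abs(self.binwidth - other.binwidth) < 1e-12
            and self.values.size == other.values.size
        )


@dataclass
class CovarianceSeries:
    """Lag-averaged windowed covariance (Hz^2), one value per window center."""

    t_centers: np.ndarray
    values: np.ndarray
    window_length: float  # s
    max_lag: int  # bins


def bin_rate(
    spikes: SpikeTrain | np.ndarray,
    binwidth: float = DEFAULT_BINWIDTH,
    span: tuple[float, float] | None = None,
) -> RateSeries:
    """Count spikes on half-open bins and divide by the bin width."""
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if binwidth <= 0:
        raise ValueError("binwidth must be > 0")
    if span is None:
        if times.size == 0:
            raise ValueError("span is required for an empty spike train")
        span = (0.0, float(times[-1]) + binwidth)
    t0, t1 = span
    n_bins = max(1, int(np.ceil((t1 - t0) / binwidth - 1e-9)))
    edges = t0 + np.arange(n_bins + 1) * binwidth
    counts, _ = np.histogram(times, bins=edges)
    # np.histogram closes the last bin; drop a spike exactly at t1 to keep
    # bins half-open
    if times.size and np.any(times == edges[-1]):
        counts[-1] -= np.count_nonzero(times == edges[-1])
    return RateSeries(t0=t0, binwidth=binwidth, values=counts / binwidth)


def mean_afr(rate_list: list[RateSeries]) -> RateSeries:
    """Pointwise mean <AFR_i> of several series on one grid."""
    if not rate_list:
        raise ValueError("need at least one rate series")
    first = rate_list[0]
    for r in rate_list[1:]:
        if not first.same_grid(r):
            raise ValueError("rate series grids do not match")
    stacked = np.vstack([r.values for r in rate_list])
    return RateSeries(t0=first.t0, binwidth=first.binwidth, values=stacked.mean(axis=0))


def cross_covariance_lags(
    f1: np.ndarray, f2: np.ndarray, max_lag: int
) -> np.ndarray:
    """rho_12(m) for m in [-max_lag, max_lag] on one window (means removed
    within the window).  Returns an array of length 2*max_lag + 1 indexed
    m = -max_lag ... +max_lag."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    N = f1.size
    if f2.size != N:
        raise ValueError("windows must have equal length")
    if N - max_lag <= 1:
        raise ValueError("window too short for the requested lag range")
    a = f1 - f1.mean()
    b = f2 - f2.mean()
    out = np.empty(2 * max_lag + 1)
    for m in range(max_lag + 1):
        out[max_lag + m] = np.dot(a[m:N], b[: N - m]) / (N - m)
        out[max_lag - m] = np.dot(b[m:N], a[: N - m]) / (N - m)
    return out


def windowed_cross_covariance(
    f1: RateSeries,
    f2: RateSeries,
    N: int = DEFAULT_WINDOW_SAMPLES,
    max_lag: int = DEFAULT_MAX_LAG,
    window_step: int = 1,
) -> CovarianceSeries:
    """Lag-averaged covariance in sliding windows of N samples.

    ``window_step`` is in bins (default 1).  Windows with fewer than N
    samples at the record edge are dropped, not padded.
    """
    if not f1.same_grid(f2):
        raise ValueError("rate series grids do not match")
    if N - max_lag <= 1:
        raise ValueError("N - max_lag must exceed 1")
    if N > f1.values.size:
        raise ValueError("N exceeds the series length")
    scal = _pair_scalars(f1.values[None, :], f2.values[None, :], N, max_lag, window_step)[0]
    centers = _window_centers(f1, N, window_step)
    return CovarianceSeries(
        t_centers=centers, values=scal, window_length=N * f1.binwidth, max_lag=max_lag
    )


def _window_centers(f: RateSeries, N: int, step: int) -> np.ndarray:
    n_win = (f.values.size - N) // step + 1
    starts = np.arange(n_win) * step
    return f.t0 + (starts + N / 2.0) * f.binwidth


def _pair_scalars(
    X: np.ndarray, Y: np.ndarray, N: int, max_lag: int, step: int
) -> np.ndarray:
    """Lag-averaged windowed covariance for each row pair (X[i], Y[i]).

    X, Y: (n_pairs, n_bins).  Returns (n_pairs, n_windows).
    """
    W1 = sliding_window_view(X, N, axis=1)[:, ::step, :]  # (p, w, N)
    W2 = sliding_window_view(Y, N, axis=1)[:, ::step, :]
    A = W1 - W1.mean(axis=2, keepdims=True)
    B = W2 - W2.mean(axis=2, keepdims=True)
    acc = np.einsum("pwn,pwn->pw", A, B) / N  # m = 0 term
    for m in range(1, max_lag + 1):
        acc = acc + np.einsum("pwn,pwn->pw", A[:, :, m:], B[:, :, : N - m]) / (N - m)
        acc = acc + np.einsum("pwn,pwn->pw", B[:, :, m:], A[:, :, : N - m]) / (N - m)
    return acc / (2 * max_lag + 1)


def covariance_matrix_series(
    rate_list: list[RateSeries],
    N: int = DEFAULT_WINDOW_SAMPLES,
    max_lag: int = DEFAULT_MAX_LAG,
    window_step: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Time series of M x M symmetric lag-averaged covariance matrices.

    Returns (window centers, matrices of shape (n_windows, M, M)); the
    diagonal holds the windowed auto-covariance.
    """
    M = len(rate_list)
    if M < 2:
        raise ValueError("need at least two series")
    first = rate_list[0]
    for r in rate_list[1:]:
        if not first.same_grid(r):
            raise ValueError("rate series grids do not match")
    V = np.vstack([r.values for r in rate_list])
    centers = _window_centers(first, N, window_step)
    mats = np.empty((centers.size, M, M))
    rows_i, rows_j = np.triu_indices(M)
    scal = _pair_scalars(V[rows_i], V[rows_j], N, max_lag, window_step)
    for k, (i, j) in enumerate(zip(rows_i, rows_j)):
        mats[:, i, j] = scal[k]
        mats[:, j, i] = scal[k]
    return centers, mats


def mean_covariance(
    centers: np.ndarray, mats: np.ndarray, window_length: float, max_lag: int
) -> CovarianceSeries:
    """<rho_ij>: per-window mean over all off-diagonal pairs i < j."""
    M = mats.shape[1]
    if M < 2:
        raise ValueError("need at least two units")
    iu = np.triu_indices(M, k=1)
    vals = mats[:, iu[0], iu[1]].mean(axis=1)
    return CovarianceSeries(
        t_centers=np.asarray(centers), values=vals,
        window_length=window_length, max_lag=max_lag,
    )


def nerve_rates(
    spikes: dict[str, SpikeTrain],
    binwidth: float = DEFAULT_BINWIDTH,
    span: tuple[float, float] | None = None,
) -> dict[str, RateSeries]:
    """Pool the spikes of all units on each nerve/electrode into nerve AFRs."""
    groups: dict[str, list[np.ndarray]] = {}
    for st in spikes.values():
        groups.setdefault(st.unit.nerve_id, []).append(st.times)
    if span is None:
        t_max = max((float(ts[-1]) for ts in
                     (np.concatenate(g) for g in groups.values()) if ts.size), default=0.0)
        span = (0.0, t_max + binwidth)
    return {
        nerve: bin_rate(np.sort(np.concatenate(times)), binwidth, span)
        for nerve, times in groups.items()
    }


def unit_rates(
    spikes: dict[str, SpikeTrain],
    binwidth: float = DEFAULT_BINWIDTH,
    span: tuple[float, float] | None = None,
) -> dict[str, RateSeries]:
    """Per-unit AFR series on a common grid."""
    if span is None:
        t_max = max((float(st.times[-1]) for st in spikes.values() if len(st)), default=0.0)
        span = (0.0, t_max + binwidth)
    return {uid: bin_rate(st, binwidth, span) for uid, st in spikes.items()}
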
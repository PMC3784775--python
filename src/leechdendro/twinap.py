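"""Twin action potentials traveling between the two connectives.

A spike propagating between ganglia appears on both the rostral (RC) and
caudal (CC) connective electrodes with a fixed 4-6 ms lag; the lag sign
gives the travel direction.  Detection pairs spikes greedily (earliest
candidate pair first, each spike used at most once) and keeps pairs whose
absolute lag lies in the configured band.
"""

from __future__ import annotations

import numpy as np

from .containers import TwinEvent
from .kinematics import _gaussian_kernel, _smooth
from .rates import RateSeries

DEFAULT_BAND_MS = (4.0, 6.0)
DEFAULT_TWIN_BINWIDTH = 1.0  # s
DEFAULT_PERI_HALF_WINDOW = 30.0  # s


def detect_twins(
    rostral: np.ndarray,
    caudal: np.ndarray,
    delay_band_ms: tuple[float, float] = DEFAULT_BAND_MS,
) -> list[TwinEvent]:
    """Pair RC/CC spikes with |lag| inside the band.

    Candidate pairs are processed by earliest spike time (ties by smaller
    |lag|); a spike enters at most one pair.  Output sorted by the earlier
    spike of each pair.
    """
    lo, hi = delay_band_ms
    if not 0.0 < lo < hi:
        raise ValueError("delay band must satisfy 0 < lo < hi")
    r = np.sort(np.asarray(rostral, dtype=float))
    c = np.sort(np.asarray(caudal, dtype=float))
    if r.size == 0 or c.size == 0:
        return []
    # band edges padded by 1 us so a lag exactly at the edge is kept
    # regardless of float rounding
    lo_s, hi_s = lo / 1000.0 - 1e-6, hi / 1000.0 + 1e-6

    # enumerate candidate pairs within the band (each caudal spike can
    # only match rostral spikes within hi_s on either side)
    cand = []
    j0 = 0
    for i, tr in enumerate(r):
        while j0 < c.size and c[j0] < tr - hi_s:
            j0 += 1
        j = j0
        while j < c.size and c[j] <= tr + hi_s:
            lag = abs(c[j] - tr)
            if lo_s <= lag <= hi_s:
                cand.append((min(tr, c[j]), lag, i, j))
            j += 1
    cand.sort()
    used_r: set[int] = set()
    used_c: set[int] = set()
    events = []
    for _, _, i, j in cand:
        if i in used_r or j in used_c:
            continue
        used_r.add(i)
        used_c.add(j)
        events.append(TwinEvent(t_rostral=float(r[i]), t_caudal=float(c[j])))
    events.sort(key=lambda e: min(e.t_rostral, e.t_caudal))
    return events


def twin_rate(
    events: list[TwinEvent],
    binwidth: float = DEFAULT_TWIN_BINWIDTH,
    smoothing_sd: float = 2.0,
    span: tuple[float, float] | None = None,
) -> RateSeries:
    """Binned, Gaussian-smoothed rate of twin events (events/s)."""
    if binwidth <= 0:
        raise ValueError("binwidth must be > 0")
    times = np.array([min(e.t_rostral, e.t_caudal) for e in events])
    if span is None:
        span = (0.0, float(times.max()) + binwidth) if times.size else (0.0, binwidth)
    t0, t1 = span
    n_bins = max(1, int(np.ceil((t1 - t0) / binwidth - 1e-9)))
    counts, _ = np.histogram(times, bins=t0 + np.arange(n_bins + 1) * binwidth)
    values = counts / binwidth
    if smoothing_sd > 0 and values.size > 1:
        values = _smooth(values, _gaussian_kernel(smoothing_sd, binwidth))
    return RateSeries(t0=t0, binwidth=binwidth, values=values)


def peri_event_average(
    rate: RateSeries,
    event_times,
    half_window: float = DEFAULT_PERI_HALF_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean rate trace aligned on events (t = 0 at the event).

    Only events whose full +/- half_window lies inside the record are
    used; returns (relative time axis, averaged trace).
    """
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    n_half = int(round(half_window / rate.binwidth))
    if n_half < 1:
        raise ValueError("half_window must cover at least one bin")
    centers = rate.centers
    snippets = []
    for te in event_times:
        idx = int(np.round((te - rate.t0) / rate.binwidth - 0.5))
        if idx - n_half < 0 or idx + n_half + 1 > rate.values.size:
            continue
        snippets.append(rate.values[idx - n_half : idx + n_half + 1])
    if not snippets:
        raise ValueError("no event has a complete window inside the record")
    rel_t = (np.arange(-n_half, n_half + 1)) * rate.binwidth
    return rel_t, np.vstack(snippets).mean(axis=0)


def direction_counts(events: list[TwinEvent]) -> dict[str, int]:
    """Number of detected twins traveling each way."""
    out = {"head_to_tail": 0, "tail_to_head": 0}
    for e in events:
        out[e.direction] += 1
    return out
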
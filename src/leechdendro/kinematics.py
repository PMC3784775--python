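"""Behavior quantification from bead coordinates and sucker traces.

Velocities are Gaussian-smoothed central differences; elongation is the
distance of each bead from the reference point M at the dissected
ganglion (total elongation = head + tail components).  An epoch is
stationary when both head and tail speed stay below ``factor * sigma``
(defaults 3 x 2.5 pix/s) continuously for longer than 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BehaviorInterval, KinematicsTrace, SuckerTrace

#: Defaults of the stationary rule.
DEFAULT_SIGMA = 2.5  # pix/s
DEFAULT_FACTOR = 3.0
DEFAULT_MIN_DURATION = 10.0  # s, strict inequality
# Velocity smoothing kernel sd (s), truncated at +/- 4 sd.  Chosen below
# half the swim period: a wider kernel (e.g. 0.5 s) attenuates a 1.5 Hz
# oscillation by ~5 orders of magnitude and swimming would read as rest.
DEFAULT_KERNEL_SD = 0.2


@dataclass
class ElongationSeries:
    t: np.ndarray
    head_elongation: np.ndarray
    tail_elongation: np.ndarray

    @property
    def total_elongation(self) -> np.ndarray:
        return self.head_elongation + self.tail_elongation


def _gaussian_kernel(kernel_sd: float, dt: float) -> np.ndarray:
    half = max(1, int(np.ceil(4.0 * kernel_sd / dt)))
    x = np.arange(-half, half + 1) * dt
    k = np.exp(-0.5 * (x / kernel_sd) ** 2)
    return k / k.sum()


def _smooth(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve with truncated-kernel renormalization at the edges."""
    half = kernel.size // 2
    sl = slice(half, half + values.size)
    num = np.convolve(values, kernel, mode="full")[sl]
    den = np.convolve(np.ones_like(values), kernel, mode="full")[sl]
    return num / den


def gaussian_velocity(
    trace: KinematicsTrace, kernel_sd: float = DEFAULT_KERNEL_SD
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample head and tail speeds (pix/s).

    Speed is the Euclidean norm of the Gaussian-smoothed central-difference
    derivative of each bead position, on the same grid as the input.
    """
    if trace.t.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be > 0")
    dt = trace.dt
    kernel = _gaussian_kernel(kernel_sd, dt)
    speeds = []
    for xy in (trace.head_xy, trace.tail_xy):
        vx = _smooth(np.gradient(xy[:, 0], dt), kernel)
        vy = _smooth(np.gradient(xy[:, 1], dt), kernel)
        speeds.append(np.hypot(vx, vy))
    return speeds[0], speeds[1]


def elongation(trace: KinematicsTrace) -> ElongationSeries:
    """Distances of the head and tail beads from the reference point M."""
    if trace.ref_point_M is None:
        raise ValueError("reference point M is not set on this trace")
    M = np.asarray(trace.ref_point_M, dtype=float)
    return ElongationSeries(
        t=trace.t,
        head_elongation=np.linalg.norm(trace.head_xy - M, axis=1),
        tail_elongation=np.linalg.norm(trace.tail_xy - M, axis=1),
    )


def detect_stationary(
    head_speed: np.ndarray,
    tail_speed: np.ndarray,
    t: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    factor: float = DEFAULT_FACTOR,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> list[BehaviorInterval]:
    """Maximal intervals where both speeds stay below factor*sigma for
    longer than ``min_duration`` (strict)."""
    head_speed = np.asarray(head_speed, dtype=float)
    tail_speed = np.asarray(tail_speed, dtype=float)
    t = np.asarray(t, dtype=float)
    if head_speed.size == 0:
        raise ValueError("empty speed series")
    if factor <= 0 or min_duration <= 0:
        raise ValueError("factor and min_duration must be > 0")
    below = (head_speed < factor * sigma) & (tail_speed < factor * sigma)

    intervals: list[BehaviorInterval] = []
    edges = np.diff(below.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(below.size)
    dt = float(t[1] - t[0]) if t.size > 1 else 0.0
    for i0, i1 in zip(starts, ends):
        t0 = t[i0]
        t1 = t[i1 - 1] + dt
        if t1 - t0 > min_duration:
            intervals.append(BehaviorInterval(t0, t1, "stationary"))
    return intervals


def estimate_sigma(head_speed: np.ndarray, tail_speed: np.ndarray) -> float:
    """Estimate the quiescent speed scale from the data (robust MAD of the
    pooled speeds), for experiments where sigma is not given."""
    pooled = np.concatenate([np.asarray(head_speed), np.asarray(tail_speed)])
    med = np.median(pooled)
    return float(1.4826 * np.median(np.abs(pooled - med)) + med)


def sucker_states(suckers: SuckerTrace) -> tuple[np.ndarray, list[tuple[float, int, int]]]:
    """Per-sample joint state 0-3 and the list of transitions (time, from, to)."""
    state = suckers.state
    change = np.flatnonzero(np.diff(state) != 0) + 1
    transitions = [
        (float(suckers.t[i]), int(state[i - 1]), int(state[i])) for i in change
    ]
    return state, transitions


def occupancy_fractions(states: np.ndarray) -> np.ndarray:
    """Fraction of samples spent in states 0-3 (sums to 1)."""
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty state sequence")
    counts = np.bincount(states.astype(int), minlength=4)[:4]
    return counts / states.size
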
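"""Synthetic semi-intact session generator.

Emulates the statistical structure of multi-unit motoneuron recordings from
a behaving semi-intact leech: behavior-dependent per-cell firing rates
(anti-phase contractors vs. elongators during crawling, fast oscillations
during swimming/pseudo-swimming, low uncorrelated activity at rest),
25 Hz bead kinematics with matching sucker attach/detach traces, and twin
action potentials on the two connective channels around head-sucker
detachments.

Spike trains are inhomogeneous Poisson processes sampled by Lewis-Shedler
thinning; every unit draws from its own substream of the master seed so
adding units never perturbs existing trains.  Within oscillatory behaviors
rate profiles are half-wave rectified sinusoids (the simplest form that
produces the anti-phase contractor/elongator structure); elsewhere they are
piecewise constant.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (
    BehaviorInterval,
    CellIdentity,
    KinematicsTrace,
    SpikeTrain,
    SuckerTrace,
    SyntheticSession,
    TwinEvent,
)


class SchedulingError(ValueError):
    """Raised when a requested behavior mix cannot be laid out in the session."""


class RateTableError(KeyError):
    """Raised when no firing-rate profile exists for a (cell, behavior) pair."""


# --------------------------------------------------------------------------
# Rosters
# --------------------------------------------------------------------------

#: Per-phase mean rates (Hz) of the canonical cells during the contraction
#: and elongation phases.  Cell 3 rises to 5.72 Hz in contraction and is
#: silent in elongation; CV goes from 0.18 to 1.56 Hz, 109 from 0.20 to
#: 2.12 Hz.  102 mirrors CV (no measured value); the inhibitor 119 follows
#: the elongators.
CONTRACTION_RATES = {"3": 5.72, "L": 0.71, "CV": 0.18, "102": 0.10, "109": 0.20, "119": 0.05}
ELONGATION_RATES = {"3": 0.0, "L": 0.0, "CV": 1.56, "102": 1.40, "109": 2.12, "119": 1.00}

#: Intermediate units fire at 50% of their class maximum in both phases.
INTERMEDIATE_RATES = {"110": 0.5 * 5.72, "10": 0.5 * 2.12}

_CLASS_OF = {
    "3": "contractor",
    "L": "contractor",
    "CV": "elongator",
    "102": "elongator",
    "109": "elongator",
    "119": "inhibitor",
    "110": "intermediate",
    "10": "intermediate",
}
_NERVE_OF = {
    "3": "DP",
    "L": "DP",
    "110": "DP",
    "CV": "MA",
    "102": "MA",
    "109": "MA",
    "119": "MA",
    "10": "MA",
}

#: The six most reliably identified cells, used for cross-experiment
#: average dendrograms.
CANONICAL_CELLS = ("CV", "L", "3", "109", "102", "119")


def default_roster() -> list[CellIdentity]:
    """24 units: the 6 canonical cell types on both sides of both exposed
    ganglia (8 electrodes: left/right DP and MA of ganglia 1 and 2)."""
    return _make_roster(CANONICAL_CELLS)


def extended_roster() -> list[CellIdentity]:
    """Default roster plus intermediate units (cells 110 on DP, 10 on MA)."""
    return _make_roster(CANONICAL_CELLS + ("110", "10"))


def _make_roster(cell_types) -> list[CellIdentity]:
    roster = []
    for ganglion in (1, 2):
        for side in ("left", "right"):
            for ct in cell_types:
                roster.append(
                    CellIdentity(
                        cell_type=ct,
                        side=side,
                        ganglion=ganglion,
                        nerve=_NERVE_OF[ct],
                        functional_class=_CLASS_OF[ct],
                    )
                )
    return roster


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatorConfig:
    """Knobs of the session generator.

    Defaults encode the study conditions: crawling elongation cycles of
    ~40 s, swimming oscillations at 1.5 Hz (admissible 0.5-2 Hz for
    pseudo-swimming), peristalsis at ~0.03 Hz, kinematics sampled at
    25 Hz with position noise giving sigma ~2.5 pix/s, and twin APs
    separated by 4-6 ms whose rate rises ~8 s before head detachment.
    """

    session_duration: float = 600.0
    kinematics_rate: float = 25.0
    crawl_period: float = 40.0
    swim_freq: float = 1.5
    pseudo_swim_freq: float = 1.0  # admissible 0.5-2 Hz
    peristalsis_freq: float = 0.03
    stationary_base_rate: float = 1.0
    # Doubly-stochastic structure: during movement all units share one
    # slow lognormal "vigor" envelope (plus a small common tonic drive),
    # producing the elevated pairwise covariance that movement shows;
    # at rest each unit follows its own independent slow envelope, so
    # rest firing is irregular but uncorrelated across units.  Set the
    # sds to 0 for plain (homogeneous-within-behavior) Poisson trains.
    movement_envelope_sd: float = 0.5  # log-scale sd
    movement_envelope_tau: float = 10.0  # s
    movement_tonic_rate: float = 0.75  # Hz, common drive during movement
    rest_envelope_sd: float = 0.5
    rest_envelope_tau: float = 8.0
    # Population-wide excitability drift at rest: much slower than the
    # 50 s covariance window, so it moves the resting <AFR> around
    # without creating within-window covariance between units.
    rest_drift_sd: float = 0.5
    rest_drift_tau: float = 120.0
    twin_delay_ms: float = 6.0  # admissible 4-6 ms
    twin_pre_lead: float = 8.0
    twin_clutter_rate: float = 1.0  # independent background per connective
    velocity_noise_sd: float = 2.5  # pix/s
    seed: int = 0
    contraction_rates: dict = field(default_factory=lambda: dict(CONTRACTION_RATES))
    elongation_rates: dict = field(default_factory=lambda: dict(ELONGATION_RATES))
    intermediate_rates: dict = field(default_factory=lambda: dict(INTERMEDIATE_RATES))

    def __post_init__(self) -> None:
        if self.session_duration <= 0:
            raise ValueError("session_duration must be > 0")
        for name in ("kinematics_rate", "crawl_period", "swim_freq",
                     "pseudo_swim_freq", "peristalsis_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.5 <= self.pseudo_swim_freq <= 2.0:
            raise ValueError("pseudo_swim_freq must lie in [0.5, 2] Hz")
        if not 4.0 <= self.twin_delay_ms <= 6.0:
            raise ValueError("twin_delay_ms must lie in [4, 6] ms by default policy")
        if self.stationary_base_rate < 0 or self.twin_clutter_rate < 0:
            raise ValueError("rates must be >= 0")
        for table in (self.contraction_rates, self.elongation_rates, self.intermediate_rates):
            if any(v < 0 for v in table.values()):
                raise ValueError("all rates must be >= 0")

    def with_seed(self, seed: int) -> "SimulatorConfig":
        return replace(self, seed=int(seed))


def _substream(config: SimulatorConfig, tag: str) -> np.random.Generator:
    """Independent, reproducible substream of the master seed."""
    return np.random.default_rng([int(config.seed) % 2**31, zlib.crc32(tag.encode())])


# --------------------------------------------------------------------------
# Behavior schedule
# --------------------------------------------------------------------------

#: Minimum single-episode duration per behavior (s).
MIN_EPISODE = {
    "crawling": None,  # one crawl period, filled from the config
    "swimming": 20.0,
    "pseudo_swimming": 20.0,
    "exploring": 30.0,
    "peristalsis": 60.0,
    "contraction": 20.0,
    "elongation": 20.0,
}

#: Preferred single-episode duration per behavior (s); targets are split
#: into episodes of roughly this length.
TYPICAL_EPISODE = {
    "crawling": 160.0,
    "swimming": 60.0,
    "pseudo_swimming": 60.0,
    "exploring": 60.0,
    "peristalsis": 90.0,
    "contraction": 30.0,
    "elongation": 30.0,
}


def make_behavior_schedule(
    config: SimulatorConfig, mix: dict[str, float]
) -> list[BehaviorInterval]:
    """Lay out behavior episodes covering [0, session_duration].

    ``mix`` maps labels to target time fractions (nonnegative, summing to
    at most 1); remaining time becomes stationary, distributed between the
    episodes.  Crawling episodes are integer multiples of the crawl
    period.  Episode order is randomized by the seed.
    """
    T = config.session_duration
    mix = {k: float(v) for k, v in mix.items() if v > 0}
    if any(v < 0 for v in mix.values()):
        raise SchedulingError("mix fractions must be nonnegative")
    if sum(mix.values()) > 1.0 + 1e-9:
        raise SchedulingError(f"mix fractions sum to {sum(mix.values()):.3f} > 1")
    for label in mix:
        if label not in MIN_EPISODE and label != "stationary":
            raise SchedulingError(f"unknown behavior label {label!r}")

    rng = _substream(config, "schedule")
    episodes: list[tuple[str, float]] = []
    for label, frac in mix.items():
        if label == "stationary":
            continue  # stationary is the remainder by construction
        target = frac * T
        min_ep = MIN_EPISODE[label] or config.crawl_period
        if min_ep > T:
            raise SchedulingError(
                f"{label} episode minimum {min_ep:.0f} s exceeds session duration {T:.0f} s"
            )
        if label == "crawling":
            P = config.crawl_period
            n_periods = max(1, int(round(target / P)))
            n_ep = max(1, int(round(n_periods * P / TYPICAL_EPISODE["crawling"])))
            base, extra = divmod(n_periods, n_ep)
            lengths = [P * (base + (1 if i < extra else 0)) for i in range(n_ep)]
            lengths = [ln for ln in lengths if ln > 0]
        else:
            n_ep = max(1, int(round(target / TYPICAL_EPISODE[label])))
            lengths = [max(min_ep, target / n_ep)] * n_ep
        episodes.extend((label, ln) for ln in lengths)

    busy = sum(ln for _, ln in episodes)
    if busy > T + 1e-9:
        raise SchedulingError(
            f"scheduled episodes need {busy:.0f} s but the session lasts only {T:.0f} s"
        )

    order = rng.permutation(len(episodes))
    episodes = [episodes[i] for i in order]

    # Distribute the stationary remainder into the gaps between episodes.
    n_gaps = len(episodes) + 1
    remainder = T - busy
    gaps = rng.dirichlet(np.ones(n_gaps)) * remainder if remainder > 1e-9 else np.zeros(n_gaps)

    schedule: list[BehaviorInterval] = []
    t = 0.0

    def _push(label: str, dur: float) -> None:
        nonlocal t
        if dur <= 1e-9:
            return
        if schedule and schedule[-1].label == label:
            prev = schedule.pop()
            schedule.append(BehaviorInterval(prev.t_start, t + dur, label))
        else:
            schedule.append(BehaviorInterval(t, t + dur, label))
        t += dur

    for i, (label, ln) in enumerate(episodes):
        _push("stationary", gaps[i])
        _push(label, ln)
    _push("stationary", gaps[-1])

    # Force exact coverage of [0, T] against float accumulation.
    if schedule and abs(schedule[-1].t_end - T) > 1e-9:
        last = schedule.pop()
        schedule.append(BehaviorInterval(last.t_start, T, last.label))
    if not schedule:
        schedule.append(BehaviorInterval(0.0, T, "stationary"))
    return schedule


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------

_M = (320.0, 240.0)  # reference point: center of the dissected ganglion (pix)
_REST_HALF = 110.0  # rest distance of each bead from M (pix)
_CRAWL_AMP = 200.0  # per-bead crawl displacement (pix)
_SWIM_AMP = 20.0  # bead oscillation amplitude during (pseudo-)swimming (pix)
_PERI_AMP = 40.0  # peristalsis displacement (pix); slow, sub-threshold motion


def _velocity_noise_gain(dt: float) -> float:
    """White-position-noise -> smoothed-velocity gain of the standard
    velocity pipeline (central difference + Gaussian smoothing)."""
    from .kinematics import DEFAULT_KERNEL_SD, _gaussian_kernel, _smooth

    imp = np.zeros(max(801, int(16 * DEFAULT_KERNEL_SD / dt) | 1))
    imp[imp.size // 2] = 1.0
    resp = _smooth(np.gradient(imp, dt), _gaussian_kernel(DEFAULT_KERNEL_SD, dt))
    return float(np.sqrt((resp**2).sum()))


def _envelope(tloc: np.ndarray, duration: float, ramp: float = 1.0) -> np.ndarray:
    """Half-cosine on/off ramp keeping positions continuous across episodes."""
    env = np.ones_like(tloc)
    ramp = min(ramp, duration / 2)
    rising = tloc < ramp
    falling = tloc > duration - ramp
    env[rising] = 0.5 * (1 - np.cos(np.pi * tloc[rising] / ramp))
    env[falling] = 0.5 * (1 - np.cos(np.pi * (duration - tloc[falling]) / ramp))
    return env


def simulate_kinematics(
    schedule: list[BehaviorInterval], config: SimulatorConfig
) -> tuple[KinematicsTrace, SuckerTrace]:
    """Bead positions and sucker attachment flags consistent with the schedule.

    Stationary epochs are constant positions plus Gaussian noise of sd
    ``velocity_noise_sd * dt``; crawling modulates the head-tail distance
    with the crawl period; swimming oscillates both bead ordinates at the
    swim frequency; pseudo-swimming oscillates only the head while the
    tail sucker stays attached.
    """
    if config.kinematics_rate <= 2 * max(config.swim_freq, config.pseudo_swim_freq):
        raise ValueError("kinematics_rate must exceed twice the fastest oscillation")
    T = schedule[-1].t_end
    dt = 1.0 / config.kinematics_rate
    t = np.arange(0.0, T - dt / 2, dt)
    n = t.size

    head = np.tile(np.array([_M[0] + _REST_HALF, _M[1]]), (n, 1))
    tail = np.tile(np.array([_M[0] - _REST_HALF, _M[1]]), (n, 1))
    head_att = np.ones(n, dtype=bool)
    tail_att = np.ones(n, dtype=bool)

    for iv in schedule:
        sl = (t >= iv.t_start - dt / 4) & (t < iv.t_end - dt / 4)
        tloc = t[sl] - iv.t_start
        if iv.label == "crawling":
            # out-and-back elongation cycle; head sucker detaches while the
            # body elongates (second half of each cycle) to reach forward
            d = _CRAWL_AMP * 0.5 * (1 - np.cos(2 * np.pi * tloc / config.crawl_period))
            head[sl, 0] += d
            tail[sl, 0] -= d
            # body elongates over the first half-cycle (head sucker released
            # to reach forward) and contracts over the second
            phase = np.mod(tloc / config.crawl_period, 1.0)
            head_att[sl] = phase >= 0.5
        elif iv.label == "swimming":
            env = _envelope(tloc, iv.duration)
            osc = _SWIM_AMP * np.sin(2 * np.pi * config.swim_freq * tloc) * env
            head[sl, 1] += osc
            tail[sl, 1] -= osc
            head_att[sl] = False
            tail_att[sl] = False
        elif iv.label == "pseudo_swimming":
            env = _envelope(tloc, iv.duration)
            head[sl, 1] += _SWIM_AMP * np.sin(2 * np.pi * config.pseudo_swim_freq * tloc) * env
            head_att[sl] = False
        elif iv.label == "exploring":
            env = _envelope(tloc, iv.duration)
            head[sl, 1] += (30.0 * np.sin(2 * np.pi * 0.10 * tloc)
                            + 15.0 * np.sin(2 * np.pi * 0.23 * tloc)) * env
            head_att[sl] = False
        elif iv.label == "peristalsis":
            d = _PERI_AMP * 0.5 * (1 - np.cos(2 * np.pi * config.peristalsis_freq * tloc))
            head[sl, 0] -= d
            tail[sl, 0] += d
        elif iv.label == "contraction":
            env = _envelope(tloc, iv.duration, ramp=2.0)
            head[sl, 0] -= 60.0 * env
            tail[sl, 0] += 60.0 * env
        elif iv.label == "elongation":
            env = _envelope(tloc, iv.duration, ramp=2.0)
            head[sl, 0] += 60.0 * env
            tail[sl, 0] -= 60.0 * env
        # stationary: rest positions, both suckers attached

    if config.velocity_noise_sd > 0:
        rng = _substream(config, "kinematics")
        # position noise calibrated so the standard smoothed-velocity
        # pipeline sees a speed RMS of velocity_noise_sd at rest (the
        # sigma that the 3-sigma stationary rule assumes)
        noise_sd = (config.velocity_noise_sd / np.sqrt(2.0)) / _velocity_noise_gain(dt)
        head = head + rng.normal(0.0, noise_sd, size=head.shape)
        tail = tail + rng.normal(0.0, noise_sd, size=tail.shape)

    trace = KinematicsTrace(t=t, head_xy=head, tail_xy=tail, ref_point_M=_M)
    suckers = SuckerTrace(t=t, head_attached=head_att, tail_attached=tail_att)
    return trace, suckers


# --------------------------------------------------------------------------
# Spike trains
# --------------------------------------------------------------------------


def _halfwave(theta: np.ndarray, sign: float) -> np.ndarray:
    """Half-wave rectified sine; active where sign*sin(theta) > 0."""
    return np.maximum(0.0, sign * np.sin(theta))


def rate_profile(
    unit: CellIdentity, interval: BehaviorInterval, config: SimulatorConfig
):
    """Return (rate_fn, lambda_max) for one unit in one behavior interval.

    ``rate_fn`` maps absolute times (s, array) to instantaneous rate (Hz).
    Raises RateTableError when no profile is defined for the pair.
    """
    ct, fc, label = unit.cell_type, unit.functional_class, interval.label
    t0 = interval.t_start

    def const(r):
        return (lambda s: np.full(np.shape(s), float(r))), float(r)

    if label == "stationary":
        return const(config.stationary_base_rate)

    if fc == "intermediate":
        try:
            r = config.intermediate_rates[ct]
        except KeyError:
            raise RateTableError(f"no intermediate rate for cell {ct} during {label}")
        if label in ("crawling", "contraction", "elongation", "peristalsis"):
            return const(r)
        return const(1.0)  # placeholder: no measured intermediate rate here

    try:
        r_con = config.contraction_rates[ct]
        r_el = config.elongation_rates[ct]
    except KeyError:
        raise RateTableError(f"no rate entry for cell {ct} during {label}")

    if label in ("crawling", "peristalsis"):
        period = config.crawl_period if label == "crawling" else 1.0 / config.peristalsis_freq
        # elongation phase = first half-cycle (matching the kinematics),
        # contraction the second; contractors and elongators are in
        # anti-phase.  Peak scaled by pi/2 so the mean over the active
        # phase equals the tabulated rate.
        if fc == "contractor":
            on, off, sign = r_con, r_el, -1.0
        else:
            on, off, sign = r_el, r_con, +1.0
        amp = (on - off) * (np.pi / 2.0)

        def fn(s, t0=t0, period=period, off=off, amp=amp, sign=sign):
            theta = 2 * np.pi * (np.asarray(s) - t0) / period
            return off + amp * _halfwave(theta, sign)

        return fn, off + max(amp, 0.0)

    if label == "contraction":
        return const(r_con)
    if label == "elongation":
        return const(r_el)

    if label == "swimming":
        # cell 3 oscillates up to ~10 Hz; 102 in phase with it, 109 and the
        # inhibitor 119 in anti-phase; L and CV fire below 0.5 Hz.
        peaks = {"3": (10.0, +1.0), "102": (3.0, +1.0), "109": (3.0, -1.0), "119": (3.0, -1.0)}
        if ct in peaks:
            peak, sign = peaks[ct]

            def fn(s, t0=t0, f=config.swim_freq, peak=peak, sign=sign):
                theta = 2 * np.pi * f * (np.asarray(s) - t0)
                return peak * _halfwave(theta, sign)

            return fn, peak
        return const(0.3)

    if label == "pseudo_swimming":
        # cells 3, 102, 109 oscillate between 1 and 3 Hz; 119 joins the
        # cell-3 arm, 102 drifts out of phase; L and CV stay below 0.5 Hz.
        phases = {"3": 0.0, "119": 0.0, "109": np.pi, "102": np.pi / 2}
        if ct in phases:
            phi = phases[ct]

            def fn(s, t0=t0, f=config.pseudo_swim_freq, phi=phi):
                return 2.0 + np.sin(2 * np.pi * f * (np.asarray(s) - t0) + phi)

            return fn, 3.0
        return const(0.3)

    if label == "exploring":
        # placeholder rates: no measured per-cell values for exploring
        return const(1.5 if fc in ("elongator", "inhibitor") else 1.0)

    raise RateTableError(f"no rate entry for cell {ct} during {label}")


def _lognormal_envelope(
    rng: np.random.Generator, T: float, sd: float, tau: float, dt: float = 0.5
):
    """Smooth lognormal envelope with mean 1, log-sd ``sd`` and correlation
    time ``tau``; returns a callable on absolute time."""
    if sd <= 0:
        return lambda s: np.ones(np.shape(s)), 1.0
    from .kinematics import _gaussian_kernel, _smooth

    grid = np.arange(0.0, T + dt, dt)
    g = _smooth(rng.normal(size=grid.size), _gaussian_kernel(tau, dt))
    if g.std() > 0:
        g = (g - g.mean()) / g.std() * sd
    E = np.exp(g - sd**2 / 2.0)

    def fn(s):
        return np.interp(np.asarray(s, dtype=float), grid, E)

    return fn, float(E.max())


def _sample_inhomogeneous(
    rate_fn, lam_max: float, t0: float, t1: float, rng: np.random.Generator
) -> np.ndarray:
    """Lewis-Shedler thinning on [t0, t1)."""
    if lam_max <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(lam_max * (t1 - t0))
    if n == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t1, size=n))
    accept = rng.uniform(0.0, lam_max, size=n) < rate_fn(cand)
    return cand[accept]


def simulate_spike_trains(
    schedule: list[BehaviorInterval],
    config: SimulatorConfig,
    roster: list[CellIdentity] | None = None,
) -> dict[str, SpikeTrain]:
    """Inhomogeneous-Poisson spike trains for every unit in the roster.

    Each unit uses a substream keyed by its id, so rosters can grow
    without perturbing existing trains.
    """
    roster = default_roster() if roster is None else roster
    T = schedule[-1].t_end
    move_env, move_env_max = _lognormal_envelope(
        _substream(config, "envelope"), T,
        config.movement_envelope_sd, config.movement_envelope_tau,
    )
    drift_env, drift_env_max = _lognormal_envelope(
        _substream(config, "rest_drift"), T,
        config.rest_drift_sd, config.rest_drift_tau, dt=2.0,
    )
    trains: dict[str, SpikeTrain] = {}
    for unit in roster:
        rng = _substream(config, f"spikes/{unit.unit_id}")
        rest_env, rest_env_max = _lognormal_envelope(
            _substream(config, f"rest/{unit.unit_id}"), T,
            config.rest_envelope_sd, config.rest_envelope_tau,
        )
        pieces = []
        for iv in schedule:
            fn, lam_max = rate_profile(unit, iv, config)
            if iv.label == "stationary":
                total = (lambda s, fn=fn, env=rest_env, drift=drift_env:
                         fn(s) * env(s) * drift(s))
                total_max = lam_max * rest_env_max * drift_env_max
            else:
                tonic = config.movement_tonic_rate
                total = (lambda s, fn=fn, env=move_env, tonic=tonic:
                         env(s) * (tonic + fn(s)))
                total_max = move_env_max * (tonic + lam_max)
            pieces.append(_sample_inhomogeneous(total, total_max, iv.t_start, iv.t_end, rng))
        times = np.concatenate(pieces) if pieces else np.empty(0)
        # thinning within non-overlapping intervals keeps order; dedupe to
        # enforce strict ascent against pathological float coincidences
        times = np.unique(times)
        trains[unit.unit_id] = SpikeTrain(unit=unit, times=times)
    return trains


# --------------------------------------------------------------------------
# Twin APs on the connectives
# --------------------------------------------------------------------------


def inject_twin_aps(
    connectives: dict[str, np.ndarray],
    detach_times,
    config: SimulatorConfig,
    session_duration: float | None = None,
) -> tuple[dict[str, np.ndarray], list[TwinEvent]]:
    """Insert paired spikes on RC and CC around each head-detachment time.

    Pair rate ramps up from ``twin_pre_lead`` seconds before each
    detachment and bursts at the detachment itself.  Injected pairs travel
    tail → head (caudal electrode leads) with lag ``twin_delay_ms``.
    Returns the augmented channels and the ground-truth event list.
    """
    detach_times = np.atleast_1d(np.asarray(detach_times, dtype=float))
    T = session_duration if session_duration is not None else config.session_duration
    if detach_times.size and (detach_times.min() < 0 or detach_times.max() > T):
        raise ValueError("detach time outside the session")

    rng = _substream(config, "twins")
    delay = config.twin_delay_ms / 1000.0
    events: list[TwinEvent] = []
    for td in detach_times:
        lead = config.twin_pre_lead
        ramp_fn = lambda s, td=td, lead=lead: 2.0 * np.clip((np.asarray(s) - (td - lead)) / lead, 0.0, 1.0)
        t_ramp = _sample_inhomogeneous(ramp_fn, 2.0, max(0.0, td - lead), td, rng)
        n_burst = rng.poisson(8.0)
        t_burst = np.sort(rng.uniform(td, min(td + 1.0, T), size=n_burst))
        for tc in np.concatenate([t_ramp, t_burst]):
            events.append(TwinEvent(t_rostral=tc + delay, t_caudal=tc))

    events.sort(key=lambda e: min(e.t_rostral, e.t_caudal))
    out = {
        "RC": np.sort(np.concatenate([connectives.get("RC", np.empty(0)),
                                      [e.t_rostral for e in events]])),
        "CC": np.sort(np.concatenate([connectives.get("CC", np.empty(0)),
                                      [e.t_caudal for e in events]])),
    }
    return out, events


def head_detach_times(suckers: SuckerTrace) -> np.ndarray:
    """Times at which the head sucker goes from attached to detached."""
    h = suckers.head_attached
    idx = np.flatnonzero(h[:-1] & ~h[1:]) + 1
    return suckers.t[idx]


# --------------------------------------------------------------------------
# Orchestrator
# --------------------------------------------------------------------------


def simulate_session(
    config: SimulatorConfig,
    mix: dict[str, float],
    roster: list[CellIdentity] | None = None,
) -> SyntheticSession:
    """Generate a complete ground-truth-labeled session (deterministic per seed)."""
    schedule = make_behavior_schedule(config, mix)
    kinematics, suckers = simulate_kinematics(schedule, config)
    spikes = simulate_spike_trains(schedule, config, roster)

    rng = _substream(config, "connectives")
    T = config.session_duration
    clutter = {
        ch: np.sort(rng.uniform(0.0, T, size=rng.poisson(config.twin_clutter_rate * T)))
        for ch in ("RC", "CC")
    }
    detaches = head_detach_times(suckers)
    connectives, truth = inject_twin_aps(clutter, detaches, config, T)

    session = SyntheticSession(
        schedule=schedule,
        kinematics=kinematics,
        suckers=suckers,
        spikes=spikes,
        connectives=connectives,
        truth_twins=truth,
        config=config,
    )
    session.validate()
    return session
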
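"""Synthetic-session generator: schedules, rates, kinematics, twins."""

import numpy as np
import pytest

from leechdendro.containers import BehaviorInterval
from leechdendro.synth import (
    RateTableError,
    SchedulingError,
    SimulatorConfig,
    default_roster,
    extended_roster,
    head_detach_times,
    inject_twin_aps,
    make_behavior_schedule,
    rate_profile,
    simulate_kinematics,
    simulate_session,
    simulate_spike_trains,
)

from conftest import replace_config


class TestSchedule:
    def test_degenerate_mix_single_stationary_interval(self):
        cfg = SimulatorConfig(session_duration=300.0, seed=0)
        sched = make_behavior_schedule(cfg, {"stationary": 1.0})
        assert len(sched) == 1
        assert sched[0] == BehaviorInterval(0.0, 300.0, "stationary")

    def test_crawling_time_in_whole_periods_near_target(self):
        cfg = SimulatorConfig(session_duration=400.0, seed=2)
        sched = make_behavior_schedule(cfg, {"crawling": 0.5, "swimming": 0.25})
        crawl = sum(iv.duration for iv in sched if iv.label == "crawling")
        assert abs(crawl - 200.0) <= 20.0
        for iv in sched:
            if iv.label == "crawling":
                assert abs(iv.duration / cfg.crawl_period
                           - round(iv.duration / cfg.crawl_period)) < 1e-6

    def test_covers_session_without_gaps(self):
        cfg = SimulatorConfig(session_duration=977.0, seed=5)
        sched = make_behavior_schedule(
            cfg, {"crawling": 0.3, "swimming": 0.2, "pseudo_swimming": 0.1}
        )
        assert sched[0].t_start == 0.0
        assert sched[-1].t_end == pytest.approx(977.0)
        for a, b in zip(sched, sched[1:]):
            assert a.t_end == pytest.approx(b.t_start)

    def test_targets_met_within_ten_percent(self):
        cfg = SimulatorConfig(session_duration=1200.0, seed=9)
        mix = {"crawling": 0.4, "swimming": 0.25}
        sched = make_behavior_schedule(cfg, mix)
        totals = {}
        for iv in sched:
            totals[iv.label] = totals.get(iv.label, 0.0) + iv.duration
        for label, frac in mix.items():
            assert totals[label] == pytest.approx(frac * 1200.0, rel=0.10)

    def test_infeasible_mix_raises(self):
        cfg = SimulatorConfig(session_duration=30.0, seed=0)
        with pytest.raises(SchedulingError):
            make_behavior_schedule(cfg, {"crawling": 0.9})  # < one crawl period
        with pytest.raises(SchedulingError):
            make_behavior_schedule(
                SimulatorConfig(session_duration=100.0),
                {"crawling": 0.8, "swimming": 0.5},
            )

    def test_episode_order_depends_on_seed(self):
        mix = {"crawling": 0.3, "swimming": 0.3}
        s1 = make_behavior_schedule(SimulatorConfig(session_duration=1200, seed=1), mix)
        s2 = make_behavior_schedule(SimulatorConfig(session_duration=1200, seed=2), mix)
        assert [iv.label for iv in s1] != [iv.label for iv in s2]


class TestKinematics:
    def test_zero_noise_stationary_velocities_exactly_zero(self):
        cfg = SimulatorConfig(session_duration=60.0, velocity_noise_sd=0.0)
        sched = [BehaviorInterval(0.0, 60.0, "stationary")]
        trace, _ = simulate_kinematics(sched, cfg)
        assert np.all(np.diff(trace.head_xy, axis=0) == 0)
        assert np.all(np.diff(trace.tail_xy, axis=0) == 0)

    def test_default_grid_is_25_hz(self):
        cfg = SimulatorConfig(session_duration=10.0)
        trace, _ = simulate_kinematics([BehaviorInterval(0, 10, "stationary")], cfg)
        assert trace.rate == pytest.approx(25.0)

    def test_rest_speed_scale_matches_sigma(self):
        """Smoothed speed RMS at rest ~ velocity_noise_sd, over 10 seeds."""
        from leechdendro.kinematics import gaussian_velocity

        rms = []
        for seed in range(10):
            cfg = SimulatorConfig(session_duration=120.0, seed=seed)
            trace, _ = simulate_kinematics(
                [BehaviorInterval(0, 120, "stationary")], cfg
            )
            hs, _ = gaussian_velocity(trace)
            rms.append(np.sqrt(np.mean(hs[20:-20] ** 2)))
        assert np.mean(rms) == pytest.approx(2.5, rel=0.15)

    def test_sucker_flags_follow_labels(self):
        cfg = SimulatorConfig(session_duration=120.0, seed=1)
        sched = [
            BehaviorInterval(0, 40, "stationary"),
            BehaviorInterval(40, 80, "pseudo_swimming"),
            BehaviorInterval(80, 120, "swimming"),
        ]
        _, suck = simulate_kinematics(sched, cfg)
        t = suck.t
        stat = (t >= 0) & (t < 40)
        pseudo = (t >= 40) & (t < 80)
        swim = (t >= 80) & (t < 120)
        assert suck.head_attached[stat].all() and suck.tail_attached[stat].all()
        assert (~suck.head_attached[pseudo]).all() and suck.tail_attached[pseudo].all()
        assert (~suck.head_attached[swim]).all() and (~suck.tail_attached[swim]).all()

    def test_crawling_elongation_oscillates_at_crawl_period(self):
        from leechdendro.kinematics import elongation

        cfg = SimulatorConfig(session_duration=400.0, seed=3)
        sched = [BehaviorInterval(0, 400, "crawling")]
        trace, _ = simulate_kinematics(sched, cfg)
        elo = elongation(trace).total_elongation
        elo = elo - elo.mean()
        freqs = np.fft.rfftfreq(elo.size, d=trace.dt)
        power = np.abs(np.fft.rfft(elo)) ** 2
        peak = freqs[1:][np.argmax(power[1:])]
        assert peak == pytest.approx(1.0 / cfg.crawl_period, rel=0.1)


class TestSpikes:
    def test_all_rates_zero_no_spikes(self):
        cfg = SimulatorConfig(
            session_duration=100.0,
            stationary_base_rate=0.0,
            rest_envelope_sd=0.0,
            rest_drift_sd=0.0,
        )
        sched = [BehaviorInterval(0, 100, "stationary")]
        trains = simulate_spike_trains(sched, cfg)
        assert all(len(st) == 0 for st in trains.values())

    def test_missing_rate_entry_names_cell_and_behavior(self):
        cfg = SimulatorConfig(contraction_rates={}, elongation_rates={})
        unit = next(u for u in default_roster() if u.cell_type == "3")
        with pytest.raises(RateTableError, match=r"3.*crawling"):
            rate_profile(unit, BehaviorInterval(0, 40, "crawling"), cfg)

    def test_rate_recovery_within_three_standard_errors(self, plain_config):
        """Empirical per-behavior mean rates match the configured table
        (600 s episodes, envelopes off)."""
        cfg = replace_config(plain_config, session_duration=600.0)
        for behavior, table in (
            ("contraction", cfg.contraction_rates),
            ("elongation", cfg.elongation_rates),
        ):
            sched = [BehaviorInterval(0, 600, behavior)]
            trains = simulate_spike_trains(sched, cfg)
            for uid, st in trains.items():
                expect = table[st.unit.cell_type]
                se = np.sqrt(max(expect, 1e-12) / 600.0)
                assert abs(len(st) / 600.0 - expect) <= max(3 * se, 0.01), uid

    def test_poisson_dispersion_across_seeds(self, plain_config):
        """Counts in a homogeneous segment are Poisson-dispersed."""
        counts = []
        for seed in range(100):
            cfg = replace_config(plain_config, session_duration=30.0, seed=seed)
            trains = simulate_spike_trains(
                [BehaviorInterval(0, 30, "contraction")], cfg
            )
            counts.append(len(trains["3_DP_1L"]))
        counts = np.asarray(counts, float)
        assert 0.8 <= counts.var(ddof=1) / counts.mean() <= 1.25

    def test_adding_units_does_not_perturb_existing_trains(self, plain_config):
        sched = [BehaviorInterval(0, 600, "crawling")]
        small = simulate_spike_trains(sched, plain_config, default_roster())
        big = simulate_spike_trains(sched, plain_config, extended_roster())
        for uid, st in small.items():
            assert np.array_equal(st.times, big[uid].times)

    def test_contractors_silent_in_elongation_phase(self, plain_crawl_session):
        s = plain_crawl_session
        crawl = [iv for iv in s.schedule if iv.label == "crawling"][0]
        t = s.spikes["3_DP_1L"].times
        t = t[(t >= crawl.t_start) & (t < crawl.t_end)] - crawl.t_start
        phase = np.mod(t / 40.0, 1.0)
        # elongation = first half-cycle; cell 3 has rate 0 there
        assert (phase >= 0.5).all()


class TestTwins:
    def test_no_detach_events_is_identity(self):
        cfg = SimulatorConfig(session_duration=100.0)
        conn = {"RC": np.array([1.0, 2.0]), "CC": np.array([3.0])}
        out, truth = inject_twin_aps(conn, [], cfg)
        assert truth == []
        assert np.array_equal(out["RC"], conn["RC"])
        assert np.array_equal(out["CC"], conn["CC"])

    def test_injected_delay_is_exact(self):
        cfg = SimulatorConfig(session_duration=100.0, twin_delay_ms=6.0, seed=4)
        out, truth = inject_twin_aps({"RC": np.empty(0), "CC": np.empty(0)}, [50.0], cfg)
        assert len(truth) > 0
        for e in truth:
            assert abs(e.t_rostral - e.t_caudal) == pytest.approx(6e-3, abs=1e-12)
            assert e.direction == "tail_to_head"

    def test_pair_rate_rises_before_detachment(self):
        cfg = SimulatorConfig(session_duration=200.0, seed=8)
        counts_pre = counts_far = 0
        for seed in range(20):
            _, truth = inject_twin_aps(
                {"RC": np.empty(0), "CC": np.empty(0)}, [100.0],
                replace_config(cfg, seed=seed),
            )
            tt = np.array([e.t_caudal for e in truth])
            counts_pre += ((tt >= 96) & (tt < 100)).sum()
            counts_far += ((tt >= 92) & (tt < 96)).sum()
        assert counts_pre > counts_far  # ramp toward the detachment

    def test_detach_outside_session_rejected(self):
        cfg = SimulatorConfig(session_duration=100.0)
        with pytest.raises(ValueError):
            inject_twin_aps({"RC": np.empty(0), "CC": np.empty(0)}, [150.0], cfg)


class TestSession:
    def test_deterministic_given_seed(self, tmp_path):
        from leechdendro.io import write_session

        mix = {"crawling": 0.4, "stationary": 0.6}
        cfg = SimulatorConfig(session_duration=200.0, seed=13)
        d1 = write_session(simulate_session(cfg, mix), tmp_path / "a")
        d2 = write_session(simulate_session(cfg, mix), tmp_path / "b")
        for name in ("spikes.csv", "kinematics.csv", "suckers.csv",
                     "connectives.csv", "schedule.csv", "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_all_requested_labels_present(self):
        cfg = SimulatorConfig(session_duration=1200.0, seed=21)
        mix = {"crawling": 0.2, "swimming": 0.15, "pseudo_swimming": 0.1,
               "exploring": 0.1, "peristalsis": 0.1, "stationary": 0.35}
        s = simulate_session(cfg, mix)
        labels = {iv.label for iv in s.schedule}
        assert labels >= set(mix)

    def test_invariants_hold(self, repertoire_session):
        repertoire_session.validate()
        T = repertoire_session.duration
        for st in repertoire_session.spikes.values():
            if len(st):
                assert st.times[0] >= 0 and st.times[-1] <= T
                assert (np.diff(st.times) > 0).all()

    def test_sucker_trace_consistent_with_schedule(self, repertoire_session):
        s = repertoire_session
        detaches = head_detach_times(s.suckers)
        # head detachments only occur entering crawling cycles or swim
        # episodes; a detachment sample may sit one kinematics sample
        # before the episode's nominal start, hence the small offset
        for td in detaches:
            label = next(iv.label for iv in s.schedule
                         if iv.t_start <= td + 0.05 < iv.t_end)
            assert label in ("crawling", "swimming")
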
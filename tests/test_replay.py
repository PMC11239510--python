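"""Replay decoding, detection and statistics on constructed fixtures."""

import numpy as np
import pandas as pd
import pytest

from replan import maze as mz
from replan.replay import (Decoder, ReplayEvent, SessionData,
                           consecutive_overrepresentation, decode_ml,
                           decode_stationary, detect_replays, fit_decoder,
                           follow_probability, goal_passage_stat,
                           nonidentical_transforms, permutation_test,
                           replay_successful, transform_walls,
                           wall_crossing_stat, wells, _direction)


def make_session(decoded_len=4000, maze_obj=None, trials=None,
                 spikes=None, n_neurons=5, stationary=True):
    """Minimal synthetic session scaffold for detection-level tests."""
    if maze_obj is None:
        maze_obj = mz.Maze(side=5, periodic=False, walls=frozenset())
    n_bins = decoded_len
    if spikes is None:
        spikes = np.zeros((n_neurons, n_bins), dtype=int)
    speed = np.zeros(n_bins) if stationary else np.full(n_bins, 10.0)
    positions = pd.DataFrame({
        "time_ms": np.arange(n_bins) * 5.0,
        "x_cm": np.full(n_bins, 30.0), "y_cm": np.full(n_bins, 30.0),
        "speed_cms": speed})
    if trials is None:
        trials = pd.DataFrame([
            dict(trial=1, type="home", goal_well=6, prev_well=12,
                 t_start=9000.0, t_end=10000.0, t_arrive=0.0, t_depart=9000.0),
            dict(trial=2, type="home", goal_well=6, prev_well=12,
                 t_start=19000.0, t_end=20000.0, t_arrive=10000.0,
                 t_depart=19000.0)])
    return SessionData(spikes=spikes, positions=positions, maze=maze_obj,
                       trials=trials)


def put(decoded, t_ms, states, dwell_bins=8):
    """Write a state sequence into a decoded array starting at t_ms."""
    b = int(t_ms // 5)
    for s in states:
        decoded[b:b + dwell_bins] = s
        b += dwell_bins
    return decoded


class TestDecodeML:
    def test_matches_bruteforce_likelihood(self, rng):
        """Sliding-window ML decoding equals brute-force evaluation of the
        Poisson log-likelihood over all states."""
        n_neurons, n_bins, n_states = 8, 400, 25
        spikes = rng.poisson(0.5, size=(n_neurons, n_bins))
        rates = rng.uniform(0.01, 20.0, size=(n_neurons, n_states))
        dec = Decoder(rates=rates, included=np.ones(n_neurons, dtype=bool))
        sess = make_session(decoded_len=n_bins, spikes=spikes)
        got = decode_ml(dec, sess, np.ones(n_bins, dtype=bool))
        W = 0.075
        half = 7
        for i in rng.choice(np.arange(half, n_bins - half), 50, replace=False):
            counts = spikes[:, i - half:i + half + 1].sum(axis=1)
            ll = [counts @ np.log(rates[:, s] * W) - rates[:, s].sum() * W
                  for s in range(n_states)]
            assert got[i] == int(np.argmax(ll))

    def test_zero_spikes_prefer_smallest_total_rate(self, rng):
        n_neurons, n_bins = 4, 100
        rates = rng.uniform(0.1, 5.0, size=(n_neurons, 25))
        dec = Decoder(rates=rates, included=np.ones(n_neurons, dtype=bool))
        sess = make_session(decoded_len=n_bins,
                            spikes=np.zeros((n_neurons, n_bins), dtype=int))
        got = decode_ml(dec, sess, np.ones(n_bins, dtype=bool))
        assert (got[7:-7] == int(np.argmin(rates.sum(axis=0)))).all()

    def test_point_field_neuron_wins(self):
        rates = np.full((1, 25), 0.01)
        rates[0, 13] = 50.0
        dec = Decoder(rates=rates, included=np.ones(1, dtype=bool))
        spikes = np.ones((1, 100), dtype=int)
        sess = make_session(decoded_len=100, spikes=spikes)
        got = decode_ml(dec, sess, np.ones(100, dtype=bool))
        assert (got[7:-7] == 13).all()


class TestFitDecoder:
    def test_low_rate_neurons_excluded_and_floor(self, rng):
        n_bins = 40_000  # 200 s
        spikes = np.zeros((2, n_bins), dtype=int)
        spikes[0, ::100] = 1          # 2 Hz -> included
        spikes[1, ::5000] = 1         # 0.04 Hz -> excluded
        speed = np.full(n_bins, 10.0)
        positions = pd.DataFrame({"time_ms": np.arange(n_bins) * 5.0,
                                  "x_cm": 30.0, "y_cm": 30.0,
                                  "speed_cms": speed})
        sess = SessionData(spikes=spikes, positions=positions,
                           maze=mz.Maze(side=5, periodic=False),
                           trials=pd.DataFrame())
        dec = fit_decoder(sess)
        assert dec.included.tolist() == [True, False]
        # unvisited states floored
        assert dec.rates.min() == pytest.approx(0.01)

    def test_requires_movement(self):
        sess = make_session(stationary=True)
        with pytest.raises(ValueError):
            fit_decoder(sess)


class TestDetectReplays:
    def test_constant_sequence_yields_no_events(self):
        sess = make_session()
        decoded = np.full(sess.n_bins, 12)
        assert detect_replays(decoded, sess, drop_first_home=False) == []

    def test_scripted_three_state_sweep(self):
        sess = make_session()
        decoded = np.full(sess.n_bins, 12)
        put(decoded, 4000.0, [12, 13, 14])  # adjacent sweep from the well
        events = detect_replays(decoded, sess, drop_first_home=False)
        assert len(events) == 1
        assert events[0].states == [12, 13, 14]
        assert events[0].trial == 1
        assert events[0].first_action == mz.RIGHT

    def test_first_home_trial_dropped_and_long_trials_skipped(self):
        trials = pd.DataFrame([
            dict(trial=1, type="home", goal_well=6, prev_well=12,
                 t_start=9000.0, t_end=10000.0, t_arrive=0.0, t_depart=9000.0),
            dict(trial=2, type="away", goal_well=7, prev_well=12,
                 t_start=19000.0, t_end=60000.0, t_arrive=10000.0,
                 t_depart=19000.0)])
        sess = make_session(trials=trials, decoded_len=12000)
        decoded = np.full(sess.n_bins, 12)
        put(decoded, 4000.0, [12, 13, 14])    # in trial 1 (first home: drop)
        put(decoded, 15000.0, [12, 13, 14])   # in trial 2 (> 40 s: skip)
        assert detect_replays(decoded, sess) == []

    def test_origin_must_match_animal_location(self):
        sess = make_session()
        decoded = np.full(sess.n_bins, 12)
        put(decoded, 4000.0, [13, 14, 15])  # starts away from the well
        # the preceding 12-run is not adjacent to 13's run start? 12 and 13
        # are adjacent, so the sweep attaches to the ambient run and the
        # event origin is the well: [12, 13, 14, 15] qualifies.
        events = detect_replays(decoded, sess, drop_first_home=False)
        assert len(events) == 1 and events[0].states[0] == 12

    def test_lapse_bridged_and_reported(self):
        sess = make_session()
        decoded = np.full(sess.n_bins, 12)
        b = int(4000 // 5)
        for s, d in [(12, 8), (13, 4), (24, 3), (13, 4), (14, 8)]:
            decoded[b:b + d] = s
            b += d
        events = detect_replays(decoded, sess, drop_first_home=False)
        assert len(events) == 1
        assert events[0].states == [12, 13, 14]
        assert len(events[0].lapses) == 1

    def test_long_lapse_not_bridged(self):
        sess = make_session()
        decoded = np.full(sess.n_bins, 12)
        b = int(4000 // 5)
        for s, d in [(12, 8), (13, 4), (24, 9), (13, 4), (14, 8)]:
            decoded[b:b + d] = s
            b += d
        events = detect_replays(decoded, sess, drop_first_home=False)
        # the 45-ms excursion breaks the sweep; no 3-distinct-state event
        # remains on either side of it
        assert all(ev.states != [12, 13, 14] for ev in events)

    def test_invariants_on_random_decodings(self, rng):
        """Random decoded sequences: every event satisfies the contract."""
        sess = make_session()
        for _ in range(20):
            decoded = rng.integers(0, 25, size=sess.n_bins)
            for ev in detect_replays(decoded, sess, drop_first_home=False):
                assert len(set(ev.states)) >= 3
                assert ev.states[0] == ev.origin == 12
                for a, b in ev.transitions():
                    assert _direction(a, b, 5) >= 0


class TestWallStats:
    def test_crossing_fraction_example(self):
        maze_obj = mz.Maze(side=5, periodic=False,
                           walls=frozenset({(12, mz.AXIS_RIGHT)}))
        ev = ReplayEvent(trial=2, t_start_ms=0, t_end_ms=100,
                         states=[12, 13, 14, 19, 18], origin=12)
        true_frac, ctrl = wall_crossing_stat([ev], maze_obj)
        assert true_frac == pytest.approx(0.25)

    def test_symmetric_wall_set_excludes_identical_transforms(self):
        # fully symmetric wall set: the four walls around the center cell
        walls = frozenset({(12, mz.AXIS_RIGHT), (12, mz.AXIS_DOWN),
                           (11, mz.AXIS_RIGHT), (7, mz.AXIS_DOWN)})
        maze_obj = mz.Maze(side=5, periodic=False, walls=walls)
        assert nonidentical_transforms(maze_obj) == []

    def test_transforms_preserve_wall_count(self, rng):
        from replan.synth import gen_arena
        maze_obj = gen_arena(rng)
        for w in nonidentical_transforms(maze_obj):
            assert len(w) == len(maze_obj.walls)


class TestGoalStats:
    def make_events(self, paths, origin=12):
        return [ReplayEvent(trial=2, t_start_ms=0, t_end_ms=1,
                            states=p, origin=origin) for p in paths]

    def test_all_through_goal(self):
        evs = self.make_events([[12, 13, 18], [12, 7, 18, 13]])
        true_frac, ctrl = goal_passage_stat(evs, goal=18)
        assert true_frac == 1.0
        assert 0 <= ctrl < 1

    def test_goal_unbiased_replays_match_control(self, rng):
        """Replays that wander randomly show no goal enrichment once the
        goal is, as in the task, equally often each candidate well."""
        evs = []
        for _ in range(400):
            path = [12]
            while len(path) < 6:
                opts = [n for a in range(4)
                        if (n := mz._neighbor(path[-1], a, 5, False)) >= 0]
                path.append(int(rng.choice(opts)))
            evs.append(ReplayEvent(trial=2, t_start_ms=0, t_end_ms=1,
                                   states=path, origin=12))
        diffs = []
        for goal in wells(5):
            if goal == 12:
                continue
            true_frac, ctrl = goal_passage_stat(evs, goal=goal)
            diffs.append(true_frac - ctrl)
        # averaged over all candidate goals the enrichment must vanish
        assert abs(np.mean(diffs)) < 0.02


class TestReplaySuccess:
    def test_goal_behind_wall_not_successful(self):
        maze_obj = mz.Maze(side=5, periodic=False,
                           walls=frozenset({(12, mz.AXIS_RIGHT)}))
        ev = ReplayEvent(trial=2, t_start_ms=0, t_end_ms=1,
                         states=[12, 13, 14], origin=12)
        assert replay_successful(ev, 13, maze_obj.walls) is False
        assert replay_successful(ev, 13, frozenset()) is True
        assert replay_successful(ev, 24, frozenset()) is False


class TestFollowProbability:
    def test_scripted_following(self):
        maze_obj = mz.Maze(side=5, periodic=False)
        evs = [ReplayEvent(trial=2, t_start_ms=0, t_end_ms=1,
                           states=[12, 13, 18], origin=12)
               for _ in range(10)]
        # behavior always follows the replayed first action (RIGHT)
        res = follow_probability(evs, [mz.RIGHT] * 10, goal=18,
                                 maze_obj=maze_obj)
        assert res["p_success"] == 1.0

    def test_independent_behavior_near_chance(self, rng):
        maze_obj = mz.Maze(side=5, periodic=False)
        evs, acts = [], []
        for _ in range(800):
            path = [12]
            while len(path) < 5:
                opts = [n for a in range(4)
                        if (n := mz._neighbor(path[-1], a, 5, False)) >= 0]
                path.append(int(rng.choice(opts)))
            evs.append(ReplayEvent(trial=2, t_start_ms=0, t_end_ms=1,
                                   states=path, origin=12))
            acts.append(int(rng.integers(4)))
        res = follow_probability(evs, acts, goal=7, maze_obj=maze_obj)
        assert res["p_success"] == pytest.approx(0.25, abs=0.12)
        assert res["p_unsuccess"] == pytest.approx(0.25, abs=0.12)


class TestConsecutive:
    def make_session_with_trials(self, n_trials=30):
        rows = []
        t = 0.0
        for i in range(n_trials):
            rows.append(dict(trial=i + 1, type="home", goal_well=6,
                             prev_well=12, t_start=t + 10_000,
                             t_end=t + 12_000, t_arrive=t,
                             t_depart=t + 10_000))
            t += 12_000
        return make_session(trials=pd.DataFrame(rows), decoded_len=10)

    def events_for(self, sess, success_by_index, rng):
        """3 replays per trial at random times; replay i succeeds with
        probability success_by_index[i].  Onsets are randomized so replay
        index is not collinear with time in the epoch (as in real data)."""
        evs = []
        tinfo = sess.trials.set_index("trial")
        for trial in sess.trials["trial"]:
            arrive = tinfo.loc[trial, "t_arrive"]
            onsets = np.sort(rng.uniform(500, 9500, size=3))
            for i in range(3):
                if rng.random() < success_by_index[i]:
                    states = [12, 7, 6]            # reaches goal 6
                else:
                    states = [12, 13, 14]          # misses goal 6
                evs.append(ReplayEvent(trial=int(trial),
                                       t_start_ms=arrive + onsets[i],
                                       t_end_ms=arrive + onsets[i] + 120,
                                       states=states, origin=12))
        return evs

    def test_flat_null(self, rng):
        sess = self.make_session_with_trials(60)
        evs = self.events_for(sess, [0.4, 0.4, 0.4], rng)
        res = consecutive_overrepresentation(evs, sess)
        over = res["overrep"]
        assert np.all(np.isfinite(over))
        assert np.ptp(over) < 0.35 * over.mean()

    def test_scripted_increase_detected(self, rng):
        sess = self.make_session_with_trials(60)
        evs = self.events_for(sess, [0.2, 0.5, 0.8], rng)
        res = consecutive_overrepresentation(evs, sess, n_perm=500, rng=rng)
        over = res["overrep"]
        assert over[2] > over[1] > over[0]
        assert res["p_values"][-1] < 0.05

    def test_time_confound_flattened(self, rng):
        """Success depending only on time-to-departure is removed by the
        regression: the index curve stays flat."""
        sess = self.make_session_with_trials(80)
        evs = []
        tinfo = sess.trials.set_index("trial")
        for trial in sess.trials["trial"]:
            arrive = tinfo.loc[trial, "t_arrive"]
            depart = tinfo.loc[trial, "t_depart"]
            for i in range(3):
                t0 = arrive + 1000 + i * 2500
                p = 0.8 * (depart - t0) / 10_000  # decays with time in epoch
                succ = rng.random() < p
                states = [12, 7, 6] if succ else [12, 13, 14]
                evs.append(ReplayEvent(trial=int(trial), t_start_ms=t0,
                                       t_end_ms=t0 + 200, states=states,
                                       origin=12))
        res = consecutive_overrepresentation(evs, sess)
        over = res["overrep"]
        assert np.ptp(over) < 0.35 * np.mean(over)

    def test_too_few_replays_raises(self):
        sess = self.make_session_with_trials(5)
        evs = [ReplayEvent(trial=1, t_start_ms=1000, t_end_ms=1200,
                           states=[12, 7, 6], origin=12)]
        with pytest.raises(ValueError):
            consecutive_overrepresentation(evs, sess)


class TestPermutationTest:
    def test_identical_values_give_p_one(self, rng):
        vals = rng.normal(size=10)
        assert permutation_test(vals, vals, n_perm=500, rng=rng) == 1.0

    def test_separated_distributions_give_small_p(self, rng):
        t = np.full(12, 1.0)
        c = np.zeros(12)
        p = permutation_test(t, c, n_perm=2000, rng=rng)
        assert p <= 1 / 2000 + 1e-12

    def test_matches_exhaustive_enumeration(self, rng):
        t = rng.normal(0.3, 1.0, size=5)
        c = rng.normal(0.0, 1.0, size=5)
        exact = permutation_test(t, c, exact=True)
        mc = permutation_test(t, c, n_perm=40_000,
                              rng=np.random.default_rng(0))
        assert mc == pytest.approx(exact, abs=0.02)

    def test_bad_arguments(self, rng):
        with pytest.raises(ValueError):
            permutation_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            permutation_test([1.0, 2.0], [0.0, 1.0], n_perm=0)
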
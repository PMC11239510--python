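"""Model-analysis machinery on constructed and lightly trained agents."""

import numpy as np
import pandas as pd
import pytest

from replan import maze as mz
from replan import analyses
from replan.agent import AgentConfig, AgentParams, physical_policy
from replan.simulate import BatchSim, collect_episodes, sample_envs


@pytest.fixture
def small_params(rng):
    return AgentParams.init(AgentConfig(hidden_units=12), rng)


class TestTaskSpace:
    def test_degenerate_generator_gives_sixteen(self, rng):
        fixed = mz.generate_maze(np.random.default_rng(0))
        res = analyses.estimate_task_space(rng, n=200, reps=3,
                                           generator=lambda r: fixed)
        assert res["mean"] == pytest.approx(16.0)

    def test_uniform_toy_support_recovered(self, rng):
        """Uniform over 100 known layouts -> about 1,600 tasks."""
        layouts = [mz.generate_maze(np.random.default_rng(s))
                   for s in range(200)]
        layouts = list({m.walls: m for m in layouts}.values())[:100]
        assert len(layouts) == 100

        def gen(r):
            return layouts[r.integers(100)]

        res = analyses.estimate_task_space(rng, n=3000, reps=5, generator=gen)
        assert res["mean"] == pytest.approx(1600.0, rel=0.06)

    def test_no_duplicates_reports_lower_bound(self, rng):
        counter = [0]

        def gen(r):
            counter[0] += 1
            m = mz.Maze(4, True, frozenset({(counter[0] % 1000, 0)}))
            return mz.Maze(4, True, frozenset({(counter[0], 0)}))

        res = analyses.estimate_task_space(rng, n=50, reps=1, generator=gen)
        assert res["mean"] == float("inf") and "lower_bound" in res


class TestPairedAblation:
    def test_agent_without_rollouts_unaffected(self, rng):
        """If the policy never selects the rollout action, forbidding it
        changes nothing statistically (same environments, same dynamics)."""
        cfg = AgentConfig(hidden_units=8)
        p = AgentParams.zeros(cfg)
        p.tensors["bp"][mz.ROLLOUT] = -50.0  # never roll out
        res = analyses.ablate_rollouts(p, n_episodes=30,
                                       rng=np.random.default_rng(0))
        assert res["mean_default"] == pytest.approx(res["mean_ablated"],
                                                    abs=0.6)

    def test_shuffle_preserves_rollout_count(self, small_params):
        res = analyses.shuffle_rollout_times(small_params, n_episodes=40,
                                             rng=np.random.default_rng(1))
        # counts preserved up to collisions dropped at episode end
        d = res["rollouts_default"].sum()
        s = res["rollouts_shuffled"].sum()
        assert abs(d - s) <= res["dropped"] + 0.1 * d

    def test_shuffle_noop_for_rollout_free_agent(self, rng):
        cfg = AgentConfig(hidden_units=8)
        p = AgentParams.zeros(cfg)
        p.tensors["bp"][mz.ROLLOUT] = -50.0
        res = analyses.shuffle_rollout_times(p, n_episodes=20,
                                             rng=np.random.default_rng(2))
        assert res["rollouts_shuffled"].sum() == 0
        assert res["mean_shuffled"] == pytest.approx(res["mean_default"],
                                                     abs=0.7)


class TestForcedRollouts:
    def test_runs_and_reports_shapes(self, small_params):
        res = analyses.forced_rollout_curve(small_params, n_list=(0, 2),
                                            n_mazes=40,
                                            rng=np.random.default_rng(0))
        assert len(res.mean_steps) == 2 == len(res.mean_steps_ctrl)
        assert res.optimal > 0
        assert (res.mean_steps >= res.optimal - 1e-9).all()

    def test_nan_params_rejected(self, small_params):
        bad = small_params.copy()
        bad.tensors["Wp"][0, 0] = np.nan
        with pytest.raises(ValueError):
            analyses.forced_rollout_curve(bad, n_list=(0,), n_mazes=5)

    def test_entropy_of_uniform_policy_is_ln4(self, rng):
        cfg = AgentConfig(hidden_units=8)
        p = AgentParams.zeros(cfg)
        ent = analyses.entropy_after_rollouts(p, n_list=(0, 1), n_mazes=30,
                                              rng=np.random.default_rng(0))
        assert np.allclose(ent, np.log(4), atol=1e-6)


class TestSuccessEffect:
    def test_identity_recurrence_with_zero_feedback_weights(self, rng):
        """If the recurrent update ignores its input (update gate saturated
        closed) the policy after the rollout equals the policy before."""
        cfg = AgentConfig(hidden_units=8)
        p = AgentParams.zeros(cfg)
        p.tensors["bz"][:] = 30.0           # z ~ 1 -> h' = h exactly
        p.tensors["bp"][:4] = 0.0
        res = analyses.success_effect(p, n_mazes=15, max_attempts=50,
                                      rng=np.random.default_rng(0))
        if len(res.pre_success):
            assert np.allclose(res.pre_success, res.post_success, atol=1e-9)
        if len(res.pre_unsuccess):
            assert np.allclose(res.pre_unsuccess, res.post_unsuccess,
                               atol=1e-9)

    def test_matched_pairs_per_episode(self, small_params):
        res = analyses.success_effect(small_params, n_mazes=30,
                                      max_attempts=60,
                                      rng=np.random.default_rng(1))
        assert len(res.pre_success) == len(res.pre_unsuccess)
        for arr in (res.pre_success, res.post_success, res.pre_unsuccess,
                    res.post_unsuccess):
            assert ((arr >= 0) & (arr <= 1)).all()


class TestResidualCorrelation:
    def test_identity_gives_unit_correlation(self, rng):
        x = rng.normal(size=300)
        d = rng.integers(1, 5, size=300)
        r_raw, _, _ = analyses.residual_correlation(x, x, d)
        assert r_raw == pytest.approx(1.0)

    def test_distance_only_variables_have_no_residual_correlation(self):
        rng = np.random.default_rng(0)
        d = rng.integers(1, 6, size=4000)
        tt = 100.0 * d + rng.normal(0, 5, size=4000)
        pr = 0.05 * d + rng.normal(0, 0.01, size=4000)
        r_raw, r_dist, r_res = analyses.residual_correlation(tt, pr, d)
        assert r_raw > 0.5 and r_dist > 0.9
        assert abs(r_res) < 3 / np.sqrt(4000 - 3)

    def test_shuffled_control_near_zero(self):
        rng = np.random.default_rng(1)
        d = rng.integers(1, 6, size=2000)
        tt = 100.0 * d + rng.normal(0, 20, size=2000)
        pr = 0.05 * d + rng.normal(0, 0.02, size=2000)
        r_raw, _, _ = analyses.residual_correlation(
            rng.permutation(tt), pr, d)
        assert abs(r_raw) < 0.08

    def test_single_distance_rejected(self):
        with pytest.raises(ValueError):
            analyses.residual_correlation([1, 2], [1, 2], [3, 3])


class TestClampedPiRollout:
    def make_human_episode(self, rng, maze_obj, goal, n_trials=2):
        """A legal trajectory that walks shortest paths to the goal."""
        rows = []
        tab = maze_obj.transitions()
        state = int(rng.integers(16))
        while state == goal:
            state = int(rng.integers(16))
        for trial in range(1, n_trials + 1):
            step = 0
            while state != goal:
                dists = mz.shortest_path_lengths_from(maze_obj, goal)
                opts = [(a, int(tab[state, a])) for a in range(4)
                        if int(tab[state, a]) != state]
                a, nxt = min(opts, key=lambda t: dists[t[1]])
                rows.append(dict(trial=trial, step=step, state=state,
                                 action=a))
                state = nxt
                step += 1
            state = int(rng.integers(16))
            while state == goal:
                state = int(rng.integers(16))
        return pd.DataFrame(rows)

    def test_constant_policy_gives_constant_pi(self, rng):
        cfg = AgentConfig(hidden_units=8)
        p = AgentParams.zeros(cfg)  # uniform policy: pi(rollout) = 0.2
        maze_obj = mz.generate_maze(rng)
        goal = 5
        steps = self.make_human_episode(rng, maze_obj, goal)
        out = analyses.clamped_pi_rollout(p, steps, maze_obj, goal,
                                          np.random.default_rng(0), n_reps=2)
        assert np.allclose(out, 0.2, atol=1e-9)

    def test_illegal_human_action_raises(self, rng):
        cfg = AgentConfig(hidden_units=8)
        p = AgentParams.zeros(cfg)
        maze_obj = mz.Maze(4, True, frozenset({(0, mz.AXIS_RIGHT)}))
        steps = pd.DataFrame([dict(trial=1, step=0, state=0,
                                   action=mz.RIGHT),
                              dict(trial=1, step=1, state=1, action=mz.UP)])
        with pytest.raises(ValueError):
            analyses.clamped_pi_rollout(p, steps, maze_obj, 9,
                                        np.random.default_rng(0), n_reps=1)

    def test_averaging_reduces_variance(self, small_params, rng):
        maze_obj = mz.generate_maze(rng)
        goal = 7
        steps = self.make_human_episode(rng, maze_obj, goal)
        runs1 = [analyses.clamped_pi_rollout(small_params, steps, maze_obj,
                                             goal, np.random.default_rng(s),
                                             n_reps=1)
                 for s in range(8)]
        runs20 = [analyses.clamped_pi_rollout(small_params, steps, maze_obj,
                                              goal, np.random.default_rng(s),
                                              n_reps=20)
                  for s in range(8)]
        v1 = np.var([r.mean() for r in runs1])
        v20 = np.var([r.mean() for r in runs20])
        assert v20 <= v1 + 1e-12


class TestValueError:
    def test_constant_control_zero_mean(self, small_params):
        res = analyses.value_error(small_params, n_episodes=30,
                                   rng=np.random.default_rng(0))
        assert res["error_const"].mean() == pytest.approx(0.0, abs=1e-9)
        assert np.isfinite(res["error"]).all()


class TestConsecutiveAgent:
    def test_untrained_agent_flat_near_one(self, rng):
        """Cross-validated success by rollout index: an untrained agent has
        no mechanism to improve successive rollouts, so the curve is flat."""
        p = AgentParams.init(AgentConfig(hidden_units=10),
                             np.random.default_rng(3))
        res = analyses.agent_consecutive_overrepresentation(
            p, n_episodes=150, rng=np.random.default_rng(4))
        if res["n_sequences"] >= 20:
            over = res["overrep"]
            assert np.isfinite(over).all()
            assert np.ptp(over) < 0.8 * max(over.mean(), 1e-9)


class TestStepsByTrial:
    def test_reports_physical_steps(self, small_params):
        res = analyses.steps_by_trial(small_params, n_episodes=60,
                                      rng=np.random.default_rng(0))
        assert set(res) == {1, 2, 3, 4}
        assert res[1] > 0
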
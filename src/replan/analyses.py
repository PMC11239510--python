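"""Model analyses: what rollouts do to performance and policy.

These reproduce, on any trained agent, the evaluation battery used to
characterize planning behavior: forced-rollout performance curves and their
feedback-zeroed control, policy entropy after rollouts, rollout ablation and
shuffled rollout timing, the causal effect of rollout success on the policy,
task-space size estimation, trajectory-clamped rollout probabilities with
residual correlations, value-function error, and the cross-validated
success-by-rollout-index curve.

Paired comparisons always evaluate both arms on identical environments.
Physical steps (not network iterations) quantify navigation performance.
During simulation-based analyses actions are sampled from the policy, which
is robust for partially trained agents (greedy selection can cycle); the
policy probabilities that the analyses report are sampling-free quantities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import maze as mz
from .agent import (AgentParams, gru_forward, physical_policy, policy_value,
                    run_rollout)
from .simulate import BatchSim, collect_episodes, returns, sample_envs


# ---------------------------------------------------------------------------
# snapshots at the start of trial 2

def snapshot_trial2(params: AgentParams, n_mazes: int,
                    rng: np.random.Generator) -> tuple[BatchSim, np.ndarray]:
    """Simulate until each episode's first teleport; freeze at trial-2 start.

    Returns the frozen simulation and a boolean mask of episodes that did
    reach trial 2 within the episode time budget.
    """
    envs = sample_envs(rng, n_mazes, params.config)
    sim = BatchSim(params, envs, rng, record=False)
    while sim.alive.any():
        sim.iterate()
        sim.frozen |= (sim.trial >= 2) & ~sim.teleport_flag
    valid = (sim.trial >= 2) & ~sim.teleport_flag
    return sim, valid


def _force_n_rollouts(sim: BatchSim, n: int, zero_feedback: bool) -> None:
    allmask = np.ones(sim.B, dtype=bool)
    for _ in range(n):
        sim.iterate(force_rollout=allmask, zero_feedback=zero_feedback)


@dataclass
class ForcedRolloutResult:
    n_list: list
    mean_steps: np.ndarray        # intact feedback
    mean_steps_ctrl: np.ndarray   # feedback zeroed
    optimal: float
    n_episodes: int


def forced_rollout_curve(params: AgentParams, n_list=tuple(range(16)),
                         n_mazes: int = 1000,
                         rng: np.random.Generator | None = None,
                         max_release_iters: int = 100) -> ForcedRolloutResult:
    """Trial-2 steps to goal after a forced number of rollouts.

    After the agent first finds the goal and is teleported, `n` rollouts are
    enforced; the agent is then released with rollouts prohibited (policy
    renormalized over physical actions) and the physical steps to the goal
    are counted (capped at `max_release_iters`).  The control arm repeats
    this with the rollout feedback channels zeroed.  The optimal reference
    is the mean shortest path from the trial-2 start locations.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if not np.all(np.isfinite(params.to_vector())):
        raise ValueError("agent parameters contain non-finite values")
    sim0, valid = snapshot_trial2(params, n_mazes, rng)
    if not valid.any():
        raise RuntimeError("no episode reached trial 2")
    opt = np.mean([mz.shortest_path_length(sim0.mazes[b], int(sim0.pos[b]),
                                           int(sim0.goal[b]))
                   for b in np.flatnonzero(valid)])
    child_seeds = rng.integers(0, 2**31 - 1, size=2 * len(n_list))
    results = {}
    for arm, zero_fb in (("intact", False), ("ctrl", True)):
        means = []
        for i, n in enumerate(n_list):
            arm_rng = np.random.default_rng(
                child_seeds[i + (0 if arm == "intact" else len(n_list))])
            sim = sim0.clone(rng=arm_rng)
            sim.time_limit = False
            sim.frozen = ~valid
            _force_n_rollouts(sim, n, zero_feedback=zero_fb)
            steps = np.zeros(sim.B)
            reached = ~valid
            for _ in range(max_release_iters):
                if reached.all():
                    break
                info = sim.iterate(forbid_rollout=True)
                steps += info["is_physical"] & ~reached
                reached |= info["reward"] > 0
                sim.frozen |= reached
            steps[~reached & valid] = max_release_iters
            means.append(float(steps[valid].mean()))
        results[arm] = np.array(means)
    return ForcedRolloutResult(n_list=list(n_list),
                               mean_steps=results["intact"],
                               mean_steps_ctrl=results["ctrl"],
                               optimal=float(opt),
                               n_episodes=int(valid.sum()))


def entropy_after_rollouts(params: AgentParams, n_list=tuple(range(16)),
                           n_mazes: int = 1000,
                           rng: np.random.Generator | None = None
                           ) -> np.ndarray:
    """Mean policy entropy over the 4 physical actions after n rollouts."""
    rng = rng if rng is not None else np.random.default_rng(0)
    sim0, valid = snapshot_trial2(params, n_mazes, rng)
    out = []
    for n in n_list:
        sim = sim0.clone(rng=np.random.default_rng(rng.integers(2**31 - 1)))
        sim.time_limit = False
        sim.frozen = ~valid
        _force_n_rollouts(sim, n, zero_feedback=False)
        sim.network_step()
        phys = physical_policy(sim.pi)
        ent = -(phys * np.log(np.maximum(phys, 1e-30))).sum(axis=1)
        out.append(float(ent[valid].mean()))
    return np.array(out)


# ---------------------------------------------------------------------------
# ablations

def ablate_rollouts(params: AgentParams, n_episodes: int = 500,
                    rng: np.random.Generator | None = None) -> dict:
    """Mean reward with and without the rollout action, paired environments."""
    rng = rng if rng is not None else np.random.default_rng(0)
    envs = sample_envs(rng, n_episodes, params.config)
    r1, r2 = [np.random.default_rng(s) for s in rng.integers(2**31 - 1, size=2)]
    default = collect_episodes(params, r1, n_episodes, envs=envs)
    ablated = collect_episodes(params, r2, n_episodes, envs=envs,
                               forbid_rollout=True)
    rew_d = np.array([t.total_reward for t in default])
    rew_a = np.array([t.total_reward for t in ablated])
    return {"mean_default": float(rew_d.mean()),
            "mean_ablated": float(rew_a.mean()),
            "rewards_default": rew_d, "rewards_ablated": rew_a}


def shuffle_rollout_times(params: AgentParams, n_episodes: int = 500,
                          rng: np.random.Generator | None = None) -> dict:
    """Mean reward with rollout timing resampled, count preserved per episode.

    Rollouts are enforced at uniformly resampled network iterations (matched
    in number to the default run in the same environment) and prohibited
    elsewhere.  A rollout scheduled on a goal/teleport iteration is resampled
    from the remaining iterations of that episode.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    envs = sample_envs(rng, n_episodes, params.config)
    r1, r2, r3 = [np.random.default_rng(s)
                  for s in rng.integers(2**31 - 1, size=3)]
    default = collect_episodes(params, r1, n_episodes, envs=envs)
    n_iters = [t.n_iterations for t in default]
    n_roll = [int(t.is_rollout.sum()) for t in default]
    schedules = [set(r2.choice(k, size=min(m, k), replace=False).tolist())
                 for k, m in zip(n_iters, n_roll)]
    dropped = 0
    sim = BatchSim(params, envs, r3, record=True)
    k = 0
    while sim.alive.any():
        sim.network_step()
        force = np.array([k in schedules[b] for b in range(sim.B)])
        info = sim.act(force_rollout=force, forbid_rollout=True)
        collided = force & info["is_teleport"]
        for b in np.flatnonzero(collided):
            free = [j for j in range(k + 1, n_iters[b])
                    if j not in schedules[b]]
            if free:
                schedules[b].add(int(r2.choice(free)))
            else:
                dropped += 1
        k += 1
    shuffled = sim.traces()
    rew_d = np.array([t.total_reward for t in default])
    rew_s = np.array([t.total_reward for t in shuffled])
    return {"mean_default": float(rew_d.mean()),
            "mean_shuffled": float(rew_s.mean()),
            "rewards_default": rew_d, "rewards_shuffled": rew_s,
            "rollouts_default": np.array(n_roll),
            "rollouts_shuffled": np.array([int(t.is_rollout.sum())
                                           for t in shuffled]),
            "dropped": dropped}


# ---------------------------------------------------------------------------
# effect of rollout success on the policy

@dataclass
class SuccessEffectResult:
    pre_success: np.ndarray
    post_success: np.ndarray
    pre_unsuccess: np.ndarray
    post_unsuccess: np.ndarray
    n_discarded: int


def success_effect(params: AgentParams, n_mazes: int = 1000,
                   max_attempts: int = 100,
                   rng: np.random.Generator | None = None
                   ) -> SuccessEffectResult:
    """pi(a1_hat) before and after a rollout, split by rollout success.

    At the first iteration of trial 2, rollouts are rejection-sampled from
    the identical (maze, location, hidden state) until one successful and
    one unsuccessful rollout are obtained; episodes where `max_attempts`
    samples fail to produce both are discarded.  Probabilities are
    renormalized over the physical actions.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    cfg = params.config
    sim0, valid = snapshot_trial2(params, n_mazes, rng)
    sim = sim0.clone()
    sim.network_step()  # first iteration of trial 2: h incorporates new state
    res = {k: [] for k in ("pre_s", "post_s", "pre_u", "post_u")}
    discarded = 0
    for b in np.flatnonzero(valid):
        st = mz.EnvState(maze=sim.mazes[b], goal=int(sim.goal[b]),
                         agent=int(sim.pos[b]), t=float(sim.t[b]),
                         trial=int(sim.trial[b]), T=float(sim.T[b]))
        h1 = sim.h[b]
        pi_pre = physical_policy(sim.pi[b])
        succ = unsucc = None
        for _ in range(max_attempts):
            ro = run_rollout(params, h1, st, rng)
            if ro.success and succ is None:
                succ = ro
            elif not ro.success and unsucc is None:
                unsucc = ro
            if succ is not None and unsucc is not None:
                break
        if succ is None or unsucc is None:
            discarded += 1
            continue
        for ro, pre_key, post_key in ((succ, "pre_s", "post_s"),
                                      (unsucc, "pre_u", "post_u")):
            st2 = st.copy()
            st2.t += cfg.rollout_ms
            x = mz.observe(st2, prev_action=mz.ROLLOUT, prev_reward=0.0,
                           rollout_feedback=ro.feedback,
                           feedback_len=cfg.feedback_len)
            h2, _ = gru_forward(params, h1, x)
            pi_post = physical_policy(policy_value(params, h2)[0])
            a1 = ro.actions[0]
            res[pre_key].append(pi_pre[a1])
            res[post_key].append(pi_post[a1])
    return SuccessEffectResult(
        pre_success=np.array(res["pre_s"]),
        post_success=np.array(res["post_s"]),
        pre_unsuccess=np.array(res["pre_u"]),
        post_unsuccess=np.array(res["post_u"]),
        n_discarded=discarded)


# ---------------------------------------------------------------------------
# task space size

def estimate_task_space(rng: np.random.Generator, n: int = 50_000,
                        reps: int = 10, side: int = 4, periodic: bool = True,
                        generator=None) -> dict:
    """Estimate the number of distinct tasks (wall layouts x goals).

    Samples `n` wall configurations, computes the fraction of the n(n-1)/2
    pairwise comparisons that are identical (by exact layout hashing, which
    is equivalent to all-pairs comparison) and returns 16/f per repetition,
    where the factor accounts for the goal locations.
    """
    gen = generator or (lambda r: mz.generate_maze(r, side=side,
                                                   periodic=periodic))
    n_goals = side * side
    values = []
    for _ in range(reps):
        counts = Counter()
        for _ in range(n):
            counts[gen(rng).walls] += 1
        ident = sum(c * (c - 1) // 2 for c in counts.values())
        pairs = n * (n - 1) // 2
        if ident == 0:
            values.append(float("inf"))
            continue
        f = ident / pairs
        values.append(n_goals / f)
    values = np.array(values)
    finite = np.isfinite(values)
    if not finite.all():
        return {"mean": float("inf"), "sem": float("nan"), "values": values,
                "lower_bound": n_goals * n * (n - 1) / 2}
    return {"mean": float(values.mean()),
            "sem": float(values.std(ddof=1) / np.sqrt(reps)),
            "values": values}


# ---------------------------------------------------------------------------
# trajectory clamping to human behavior

def clamped_pi_rollout(params: AgentParams, steps: pd.DataFrame,
                       maze_obj: mz.Maze, goal: int,
                       rng: np.random.Generator, n_reps: int = 20
                       ) -> np.ndarray:
    """pi(rollout) at the first iteration in each state of a clamped episode.

    Physical actions are forced to the human's; between them the agent still
    samples rollouts with probability pi(rollout).  `steps` holds one
    episode's rows ordered by (trial, step) with columns (trial, step,
    state, action).  Returns the mean over `n_reps` repetitions of
    pi(rollout) recorded at the first iteration in each new state.
    """
    cfg = params.config
    trans = maze_obj.transitions()
    rows = steps.reset_index(drop=True)
    # validate the human trajectory against the maze
    for i in range(len(rows)):
        s, a = int(rows.loc[i, "state"]), int(rows.loc[i, "action"])
        nxt = int(trans[s, a])
        if i + 1 < len(rows) and rows.loc[i + 1, "trial"] == rows.loc[i, "trial"]:
            if nxt != int(rows.loc[i + 1, "state"]):
                raise ValueError(f"human action at row {i} is inconsistent "
                                 "with the maze")
            if nxt == s:
                raise ValueError(f"human action at row {i} is blocked by a wall")
    out = np.zeros((n_reps, len(rows)))
    for rep in range(n_reps):
        h = np.zeros(cfg.hidden_units)
        st = mz.EnvState(maze=maze_obj, goal=goal, agent=int(rows.loc[0, "state"]),
                         t=0.0, trial=1, T=cfg.episode_ms)
        prev_a, prev_r, fb = None, 0.0, None
        for i in range(len(rows)):
            st.agent = int(rows.loc[i, "state"])
            x = mz.observe(st, prev_a, prev_r, rollout_feedback=fb,
                           feedback_len=cfg.feedback_len)
            h, _ = gru_forward(params, h, x)
            pi, _ = policy_value(params, h)
            out[rep, i] = pi[mz.ROLLOUT]
            fb = None
            # keep rolling out with probability pi(rollout), then act
            while rng.random() < pi[mz.ROLLOUT]:
                ro = run_rollout(params, h, st, rng)
                st.t = min(st.t + cfg.rollout_ms, st.T)
                x = mz.observe(st, mz.ROLLOUT, 0.0, rollout_feedback=ro.feedback,
                               feedback_len=cfg.feedback_len)
                h, _ = gru_forward(params, h, x)
                pi, _ = policy_value(params, h)
            a = int(rows.loc[i, "action"])
            nxt = int(trans[st.agent, a])
            st.t = min(st.t + cfg.action_ms, st.T)
            if nxt == goal:
                # goal observation, then the human's next start state
                st.agent = goal
                x = mz.observe(st, a, 1.0, feedback_len=cfg.feedback_len)
                h, _ = gru_forward(params, h, x)
                st.t = min(st.t + cfg.action_ms, st.T)
                st.trial += 1
                prev_a, prev_r, fb = None, 0.0, None
            else:
                prev_a, prev_r = a, 0.0
    return out.mean(axis=0)


def residual_correlation(thinking_times, pi_rollout, distance_to_goal
                         ) -> tuple[float, float, float]:
    """Correlations of thinking time with pi(rollout), raw and residual.

    Residuals subtract, from both variables, their mean over all actions at
    the same momentary distance to goal.  Returns (r_raw, r_distance,
    r_residual) for one participant.
    """
    tt = np.asarray(thinking_times, dtype=float)
    pr = np.asarray(pi_rollout, dtype=float)
    d = np.asarray(distance_to_goal)
    if len(np.unique(d)) < 2:
        raise ValueError("need at least 2 distinct distances for residuals")
    r_raw = stats.pearsonr(tt, pr).statistic
    r_dist = stats.pearsonr(tt, d.astype(float)).statistic
    tt_res, pr_res = tt.copy(), pr.copy()
    for dv in np.unique(d):
        m = d == dv
        tt_res[m] -= tt[m].mean()
        pr_res[m] -= pr[m].mean()
    r_res = stats.pearsonr(tt_res, pr_res).statistic
    return float(r_raw), float(r_dist), float(r_res)


# ---------------------------------------------------------------------------
# value function quality

def value_error(params: AgentParams, n_episodes: int = 200,
                rng: np.random.Generator | None = None) -> dict:
    """V_k - R_k against the constant control Rbar - R_k."""
    rng = rng if rng is not None else np.random.default_rng(0)
    traces = collect_episodes(params, rng, n_episodes)
    errs, rs = [], []
    for tr in traces:
        R = returns(tr)
        errs.append(tr.value - R)
        rs.append(R)
    err = np.concatenate(errs)
    R_all = np.concatenate(rs)
    err_const = R_all.mean() - R_all
    return {"error": err, "error_const": err_const,
            "mean_abs": float(np.abs(err).mean()),
            "mean_abs_const": float(np.abs(err_const).mean())}


# ---------------------------------------------------------------------------
# steps per trial and rollout usage

def steps_by_trial(params: AgentParams, n_episodes: int = 1000,
                   rng: np.random.Generator | None = None,
                   max_trial: int = 4) -> dict:
    """Mean physical steps to goal by trial number (completed trials only)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    traces = collect_episodes(params, rng, n_episodes)
    per_trial = {k: [] for k in range(1, max_trial + 1)}
    for tr in traces:
        # trial number at each iteration: starts at 1, +1 after each reward
        trial_no = 1 + np.concatenate([[0], np.cumsum(tr.reward)[:-1]]).astype(int)
        completed = int(tr.reward.sum())
        for k in range(1, max_trial + 1):
            if completed >= k:
                per_trial[k].append(int((tr.is_physical
                                         & (trial_no == k)).sum()))
    return {k: (float(np.mean(v)) if v else float("nan"))
            for k, v in per_trial.items()}


def rollout_fraction(params: AgentParams, n_episodes: int = 500,
                     rng: np.random.Generator | None = None) -> float:
    """Fraction of action iterations on which the agent chose to roll out."""
    rng = rng if rng is not None else np.random.default_rng(0)
    traces = collect_episodes(params, rng, n_episodes)
    n_roll = sum(int(t.is_rollout.sum()) for t in traces)
    n_act = sum(int(t.is_action.sum()) for t in traces)
    return n_roll / n_act if n_act else float("nan")


# ---------------------------------------------------------------------------
# cross-validated success by rollout index

def agent_consecutive_overrepresentation(params: AgentParams,
                                         n_episodes: int = 500,
                                         rng: np.random.Generator | None = None,
                                         max_index: int = 3) -> dict:
    """Goal over-representation by rollout index within consecutive sequences.

    Every time the agent rolls out, a second, independent sample is drawn
    from the rollout process; the agent never sees it.  The shadow sample's
    trajectory is scored for passing through the true goal (vs the 14
    control locations that are neither the goal nor the current location),
    which decouples rollout choice from success assessment.  Sequences of at
    least `max_index` consecutive rollouts contribute.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    envs = sample_envs(rng, n_episodes, params.config)
    sim = BatchSim(params, envs, rng, record=False)
    n = params.config.n_cells
    streak_idx = np.zeros(sim.B, dtype=int)
    open_events: dict[int, list] = {b: [] for b in range(sim.B)}
    sequences: list[list] = []

    def close(b):
        if len(open_events[b]) >= max_index:
            sequences.append(list(open_events[b]))
        open_events[b] = []
        streak_idx[b] = 0

    while sim.alive.any():
        info = sim.iterate(double_rollout_sample=True)
        shadow = sim.last_shadow
        ro_rows = set(shadow["rows"].tolist()) if shadow else set()
        for b in range(sim.B):
            if not info["alive"][b]:
                continue
            if b in ro_rows:
                i = list(shadow["rows"]).index(b)
                states = shadow["states"][i]
                states = states[states >= 0]
                hit_goal = bool(np.isin(sim.goal[b], states))
                pos_b, goal_b = int(sim.pos[b]), int(sim.goal[b])
                controls = [c for c in range(n) if c != pos_b and c != goal_b]
                hit_ctrl = float(np.isin(controls, states).mean())
                streak_idx[b] += 1
                open_events[b].append((streak_idx[b], hit_goal, hit_ctrl))
            elif info["is_physical"][b] or info["is_teleport"][b]:
                close(b)
        for b in np.flatnonzero(~sim.alive):
            if open_events[b]:
                close(b)
    for b in range(sim.B):
        close(b)
    if not sequences:
        return {"overrep": np.full(max_index, np.nan), "n_sequences": 0}
    flat = [ev for seq in sequences for ev in seq]
    ctrl_mean = float(np.mean([ev[2] for ev in flat]))
    overrep = np.empty(max_index)
    for idx in range(1, max_index + 1):
        hits = [ev[1] for seq in sequences for ev in seq if ev[0] == idx]
        overrep[idx - 1] = (np.mean(hits) / ctrl_mean) if ctrl_mean > 0 \
            else np.nan
    return {"overrep": overrep, "n_sequences": len(sequences),
            "control_rate": ctrl_mean}
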
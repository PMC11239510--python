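"""Vectorized episode simulation for training and analyses.

`BatchSim` advances a batch of episodes in lockstep.  One *iteration* of the
network dynamics is `network_step()` (a batched GRU update plus heads)
followed by `act()` (action selection, environment transition, rollout
execution, clock accounting).  Episodes whose clock has expired are frozen.

Conventions mirror the single-episode API in :mod:`replan.agent`:

- reaching the goal triggers a reward-1 input at the goal cell on the next
  iteration, whose policy output is ignored (`is_teleport`), after which the
  agent continues from a uniformly random non-goal cell with a blank
  previous-action block;
- a rollout leaves the location unchanged, consumes rollout time, and its
  feedback vector is appended to the next iteration's input;
- gradients never flow through rollout-internal network updates, so those
  updates are not cached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import maze as mz
from .agent import (AgentConfig, AgentParams, GRUCache, gru_forward,
                    physical_policy, policy_value, softmax, advance_clock,
                    feedback_vector)


@dataclass
class EpisodeTrace:
    """Per-iteration record of one completed (or truncated) episode."""

    x: np.ndarray          # (K, X) network inputs
    action: np.ndarray     # (K,) sampled action, -1 at teleport iterations
    reward: np.ndarray     # (K,) instantaneous reward
    value: np.ndarray      # (K,) V_k
    is_action: np.ndarray  # (K,) bool: an action was sampled here
    is_physical: np.ndarray
    is_rollout: np.ndarray
    is_teleport: np.ndarray
    wm_next: np.ndarray    # (K,) true next cell for physical iterations else -1
    clock: np.ndarray      # (K,) t at the start of each iteration (ms)
    goal: int
    maze: mz.Maze

    @property
    def n_iterations(self) -> int:
        return len(self.action)

    @property
    def total_reward(self) -> float:
        return float(self.reward.sum())


def returns(trace: EpisodeTrace) -> np.ndarray:
    """Empirical cumulative future reward R_k from iteration k onward."""
    return np.cumsum(trace.reward[::-1])[::-1].copy()


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Categorical sample per row of a (B, A) probability matrix."""
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    return np.minimum((u[:, None] > cdf).sum(axis=1), probs.shape[1] - 1)


class BatchSim:
    """A batch of episodes advanced in lockstep under one parameter set."""

    def __init__(self, params: AgentParams, envs: list[mz.EnvState],
                 rng: np.random.Generator, greedy: bool = False,
                 record: bool = True, time_limit: bool = True):
        cfg = params.config
        self.params = params
        self.cfg = cfg
        self.rng = rng
        self.greedy = greedy
        self.record = record
        self.time_limit = time_limit
        B, n = len(envs), cfg.n_cells
        self.B = B
        self.mazes = [e.maze for e in envs]
        self.goal = np.array([e.goal for e in envs])
        self.pos = np.array([e.agent for e in envs])
        self.t = np.array([e.t for e in envs], dtype=float)
        self.T = np.array([e.T for e in envs], dtype=float)
        self.trial = np.array([e.trial for e in envs])
        self.trans = np.stack([e.maze.transitions() for e in envs])
        self.wallvec = np.stack([e.maze.wall_vector() for e in envs])
        self.h = np.zeros((B, cfg.hidden_units))
        self.frozen = np.zeros(B, dtype=bool)  # externally stopped episodes
        # pending-observation fields
        self.obs_loc = self.pos.copy()
        self.obs_prev_a = np.full(B, -1)
        self.obs_prev_r = np.zeros(B)
        self.obs_feedback = np.zeros((B, cfg.feedback_len))
        self.teleport_flag = np.zeros(B, dtype=bool)
        # iteration products
        self.pi = np.full((B, mz.N_ACTIONS), 1.0 / mz.N_ACTIONS)
        self.value = np.zeros(B)
        self.n_rollouts = np.zeros(B, dtype=int)
        self.iter_index = np.zeros(B, dtype=int)
        self._records: list[list[dict]] = [[] for _ in range(B)]

    # ------------------------------------------------------------------
    @property
    def alive(self) -> np.ndarray:
        ok = ~self.frozen
        if self.time_limit:
            ok = ok & (self.t < self.T)
        return ok

    def build_obs(self) -> np.ndarray:
        cfg, n = self.cfg, self.cfg.n_cells
        x = np.zeros((self.B, cfg.obs_len))
        rows = np.arange(self.B)
        x[rows, self.obs_loc] = 1.0
        has_a = self.obs_prev_a >= 0
        x[rows[has_a], n + self.obs_prev_a[has_a]] = 1.0
        x[:, n + mz.N_ACTIONS] = self.obs_prev_r
        x[:, n + mz.N_ACTIONS + 1:n + mz.N_ACTIONS + 1 + 2 * n] = self.wallvec
        # the scaled clock saturates at 1 for analyses that run past T
        x[:, n + mz.N_ACTIONS + 1 + 2 * n] = np.minimum(self.t / self.T, 1.0)
        x[:, -cfg.feedback_len:] = self.obs_feedback
        return x

    def clone(self, rng: np.random.Generator | None = None) -> "BatchSim":
        """Deep copy of the simulation state (parameters shared)."""
        new = object.__new__(BatchSim)
        new.params, new.cfg = self.params, self.cfg
        new.rng = rng if rng is not None else self.rng
        new.greedy, new.record = self.greedy, self.record
        new.time_limit = self.time_limit
        new.B, new.mazes = self.B, self.mazes
        new.trans, new.wallvec = self.trans, self.wallvec
        for name in ("goal", "pos", "t", "T", "trial", "h", "frozen",
                     "obs_loc", "obs_prev_a", "obs_prev_r", "obs_feedback",
                     "teleport_flag", "pi", "value", "n_rollouts",
                     "iter_index"):
            setattr(new, name, getattr(self, name).copy())
        new._records = [list(r) for r in self._records]
        return new

    def network_step(self) -> tuple[np.ndarray, GRUCache]:
        """One batched GRU update; frozen/dead episodes keep their state."""
        alive = self.alive
        x = self.build_obs()
        h_new, cache = gru_forward(self.params, self.h, x)
        self.h = np.where(alive[:, None], h_new, self.h)
        pi, v = policy_value(self.params, self.h)
        self.pi = pi
        self.value = v
        self._last_x = x
        self._last_alive = alive
        return x, cache

    # ------------------------------------------------------------------
    def _run_rollouts(self, rows: np.ndarray, zero_feedback: bool = False
                      ) -> dict:
        """Sample one rollout per row.

        Returns a dict with feedback (m, F), lengths (m,), success (m,),
        imagined goal (m,) and imagined state sequences (m, horizon; -1 pad).
        """
        cfg = self.cfg
        m = len(rows)
        h_im = self.h[rows].copy()
        g_im = np.full(m, -1)
        done = np.zeros(m, dtype=bool)
        success = np.zeros(m, dtype=bool)
        fb = np.zeros((m, cfg.feedback_len))
        lengths = np.zeros(m, dtype=int)
        states = np.full((m, cfg.planning_horizon), -1)
        first_action = np.full(m, -1)
        s_im = self.pos[rows].copy()
        n = cfg.n_cells
        p = self.params.tensors
        for j in range(cfg.planning_horizon):
            act_rows = ~done
            if not act_rows.any():
                break
            pi, _ = policy_value(self.params, h_im)
            phys = physical_policy(pi)
            a_im = _sample_rows(phys, self.rng)
            # world model on all rows (cheap), applied to active ones
            a_onehot = np.zeros((m, mz.N_ACTIONS))
            a_onehot[np.arange(m), a_im] = 1.0
            u = np.concatenate([h_im, a_onehot], axis=1)
            mm = np.maximum(u @ p["Wm1"].T + p["bm1"], 0.0)
            logits = mm @ p["Wm2"].T + p["bm2"]
            s_next = np.argmax(logits[:, :n], axis=1)
            if j == 0:
                g_im = np.argmax(logits[:, n:], axis=1)
            upd = act_rows
            fb[upd, 4 * j + a_im[upd]] = 1.0
            lengths[upd] += 1
            states[upd, j] = s_next[upd]
            if j == 0:
                first_action[upd] = a_im[upd]
            reached = upd & (s_next == g_im)
            success |= reached
            done |= reached
            s_im = np.where(upd, s_next, s_im)
            still = upd & ~reached
            if j < cfg.planning_horizon - 1 and still.any():
                x_im = np.zeros((m, cfg.obs_len))
                rr = np.arange(m)
                x_im[rr, s_im] = 1.0
                x_im[rr, n + a_im] = 1.0
                x_im[:, n + mz.N_ACTIONS + 1:n + mz.N_ACTIONS + 1 + 2 * n] = \
                    self.wallvec[rows]
                x_im[:, n + mz.N_ACTIONS + 1 + 2 * n] = \
                    self.t[rows] / self.T[rows]
                h_next, _ = gru_forward(self.params, h_im, x_im)
                h_im = np.where(still[:, None], h_next, h_im)
        fb[:, -1] = success.astype(float)
        if zero_feedback:
            fb = np.zeros_like(fb)
        return dict(feedback=fb, lengths=lengths, success=success,
                    imagined_goal=g_im, states=states,
                    first_action=first_action)

    # ------------------------------------------------------------------
    def act(self, force_rollout: np.ndarray | None = None,
            forbid_rollout: bool = False,
            zero_feedback: bool = False,
            double_rollout_sample: bool = False) -> dict:
        """Select and execute actions for all alive episodes.

        `force_rollout`: boolean (B,) mask forcing the rollout action at this
        iteration (ignored at teleport iterations).  `forbid_rollout`
        renormalizes the policy over physical actions before selection.
        Returns a dict of per-episode arrays for this iteration.
        """
        cfg = self.cfg
        alive = self._last_alive
        rows = np.arange(self.B)
        action = np.full(self.B, -1)
        reward = np.zeros(self.B)
        is_tel = alive & self.teleport_flag
        is_act = alive & ~self.teleport_flag
        wm_next = np.full(self.B, -1)
        clock_before = self.t.copy()
        self.last_rollout = None
        self.last_shadow = None

        # -- teleport iterations: policy ignored, agent relocated
        if is_tel.any():
            tl = rows[is_tel]
            offs = self.rng.integers(0, cfg.n_cells - 1, size=len(tl))
            newpos = np.where(offs >= self.goal[tl], offs + 1, offs)
            self.pos[tl] = newpos
            self.t[tl] += cfg.action_ms
            self.obs_loc[tl] = newpos
            self.obs_prev_a[tl] = -1
            self.obs_prev_r[tl] = 0.0
            self.obs_feedback[tl] = 0.0
            self.teleport_flag[tl] = False

        # -- action selection
        if is_act.any():
            pol = self.pi.copy()
            if forbid_rollout:
                pol[:, :4] = physical_policy(pol)
                pol[:, 4] = 0.0
            if self.greedy:
                chosen = np.argmax(pol, axis=1)
            else:
                chosen = _sample_rows(pol, self.rng)
            if force_rollout is not None:
                chosen = np.where(force_rollout & is_act, mz.ROLLOUT, chosen)
            chosen = np.where(is_act, chosen, -1)

            # rollouts
            ro = is_act & (chosen == mz.ROLLOUT)
            if ro.any():
                ro_rows = rows[ro]
                detail = self._run_rollouts(ro_rows,
                                            zero_feedback=zero_feedback)
                if double_rollout_sample:
                    # an independent second sample, unseen by the agent, for
                    # cross-validated assessment of the momentary policy
                    self.last_shadow = dict(self._run_rollouts(ro_rows),
                                            rows=ro_rows)
                self.last_rollout = dict(detail, rows=ro_rows)
                self.obs_feedback[ro_rows] = detail["feedback"]
                self.obs_prev_a[ro_rows] = mz.ROLLOUT
                self.obs_prev_r[ro_rows] = 0.0
                self.obs_loc[ro_rows] = self.pos[ro_rows]
                cost = np.array([advance_clock("rollout", int(l), cfg)
                                 for l in detail["lengths"]])
                self.t[ro_rows] += cost
                self.n_rollouts[ro_rows] += 1

            # physical moves
            ph = is_act & (chosen >= 0) & (chosen < 4)
            if ph.any():
                pr = rows[ph]
                nxt = self.trans[pr, self.pos[pr], chosen[ph]]
                hit = nxt == self.goal[pr]
                wm_next[pr] = nxt
                reward[pr[hit]] = 1.0
                # goal-reaching: observe the goal cell, teleport next iteration
                self.pos[pr] = nxt
                self.trial[pr[hit]] += 1
                self.teleport_flag[pr[hit]] = True
                self.obs_loc[pr] = nxt
                self.obs_prev_a[pr] = chosen[ph]
                self.obs_prev_r[pr] = reward[pr]
                self.obs_feedback[pr] = 0.0
                self.t[pr] += cfg.action_ms
            action = chosen

        info = {
            "alive": alive.copy(),
            "action": action,
            "reward": reward,
            "value": self.value.copy(),
            "pi": self.pi.copy(),
            "is_action": is_act,
            "is_physical": alive & (action >= 0) & (action < 4),
            "is_rollout": alive & (action == mz.ROLLOUT),
            "is_teleport": is_tel,
            "wm_next": wm_next,
            "clock": clock_before,
            "x": self._last_x,
        }
        if self.record:
            for b in rows[alive]:
                self._records[b].append({k: v[b] for k, v in info.items()
                                         if k != "alive"})
        self.iter_index[alive] += 1
        return info

    def iterate(self, **act_kwargs) -> dict:
        self.network_step()
        return self.act(**act_kwargs)

    def run(self, max_iters: int = 100_000, **act_kwargs) -> None:
        it = 0
        while self.alive.any():
            self.iterate(**act_kwargs)
            it += 1
            if it > max_iters:
                raise RuntimeError("simulation exceeded max_iters")

    # ------------------------------------------------------------------
    def traces(self) -> list[EpisodeTrace]:
        out = []
        for b in range(self.B):
            recs = self._records[b]
            K = len(recs)
            get = lambda k, dtype=float: np.array([r[k] for r in recs],
                                                  dtype=dtype)
            out.append(EpisodeTrace(
                x=np.stack([r["x"] for r in recs]) if K else
                np.zeros((0, self.cfg.obs_len)),
                action=get("action", int) if K else np.zeros(0, int),
                reward=get("reward") if K else np.zeros(0),
                value=get("value") if K else np.zeros(0),
                is_action=get("is_action", bool) if K else np.zeros(0, bool),
                is_physical=get("is_physical", bool) if K else np.zeros(0, bool),
                is_rollout=get("is_rollout", bool) if K else np.zeros(0, bool),
                is_teleport=get("is_teleport", bool) if K else np.zeros(0, bool),
                wm_next=get("wm_next", int) if K else np.zeros(0, int),
                clock=get("clock") if K else np.zeros(0),
                goal=int(self.goal[b]),
                maze=self.mazes[b],
            ))
        return out


def sample_envs(rng: np.random.Generator, n: int,
                cfg: AgentConfig) -> list[mz.EnvState]:
    return [mz.init_episode(rng, T=cfg.episode_ms, side=cfg.side,
                            periodic=cfg.periodic) for _ in range(n)]


def collect_episodes(params: AgentParams, rng: np.random.Generator,
                     n_episodes: int, greedy: bool = False,
                     envs: list[mz.EnvState] | None = None,
                     forbid_rollout: bool = False) -> list[EpisodeTrace]:
    """Run complete episodes and return their traces."""
    if envs is None:
        envs = sample_envs(rng, n_episodes, params.config)
    sim = BatchSim(params, envs, rng, greedy=greedy)
    sim.run(forbid_rollout=forbid_rollout)
    return sim.traces()
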
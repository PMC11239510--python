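"""Synthetic-data generators with known ground truth.

Everything the analysis modules consume can be generated here: response-time
tables with known thinking times, rodent-style recording sessions with
scripted replays and Poisson place-cell spiking, and small trained agent
checkpoints.  All generators are pure functions of (rng, config).

The spiking model is deliberately simple — Gaussian place fields with an
additive baseline, Poisson counts in 5-ms bins, and replay content injected
by evaluating the fields along a scripted trajectory at a compressed speed
(40 ms per state by default).  It emulates the statistical structure the
replay pipeline relies on (position-tuned rates, time-compressed sequences
during stillness) and none of the biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maze as mz
from .agent import AgentConfig, AgentParams
from .replay import SessionData, wells
from .thinking import FIRST_OF_TRIAL, OTHER


# ---------------------------------------------------------------------------
# response-time tables

DEFAULT_DELAY_PRIORS = {
    OTHER: dict(mu=5.6, sigma=0.4, delta_ms=150.0),
    FIRST_OF_TRIAL: dict(mu=5.9, sigma=0.35, delta_ms=200.0),
}


def _shifted_lognormal(rng, mu, sigma, delta_ms, size):
    return delta_ms + np.exp(rng.normal(mu, sigma, size=size))


def gen_rt_dataset(rng: np.random.Generator, n_participants: int = 20,
                   prior_params: dict | None = None,
                   tt_model=None,
                   n_guided: int = 150, n_nonguided: int = 300
                   ) -> pd.DataFrame:
    """Response-time table with per-row ground-truth thinking times.

    Guided rows have t_t = 0 (their response time is a pure perception-
    action delay drawn from the per-class shifted log-normal); nonguided
    rows add a thinking time drawn from `tt_model` (a callable
    (rng, n, distance) -> ms, or None for a distance-dependent exponential
    with mean 100 + 150 * distance ms).  Columns follow the behavior-table
    schema plus `thinking_time_true_ms`.
    """
    priors = prior_params or DEFAULT_DELAY_PRIORS
    for cls in (OTHER, FIRST_OF_TRIAL):
        if cls not in priors or priors[cls]["sigma"] <= 0:
            raise ValueError(f"invalid prior parameters for class {cls!r}")
    if tt_model is None:
        def tt_model(r, n, distance):
            return r.exponential(100.0 + 150.0 * distance, size=n)
    frames = []
    for pid in range(n_participants):
        for guided, n_rows in ((True, n_guided), (False, n_nonguided)):
            first = np.zeros(n_rows, dtype=bool)
            # roughly one action in four starts a trial
            first[rng.random(n_rows) < 0.25] = True
            distance = rng.integers(1, 5, size=n_rows)
            tt = np.zeros(n_rows)
            if not guided:
                tt = np.asarray(tt_model(rng, n_rows, distance), dtype=float)
            td = np.empty(n_rows)
            for cls, m in ((FIRST_OF_TRIAL, first), (OTHER, ~first)):
                pp = priors[cls]
                td[m] = _shifted_lognormal(rng, pp["mu"], pp["sigma"],
                                           pp["delta_ms"], int(m.sum()))
            frames.append(pd.DataFrame({
                "participant": pid,
                "episode": np.arange(n_rows) // 10,
                "trial": 1 + (np.arange(n_rows) // 4) % 4,
                "step": np.arange(n_rows) % 4,
                "state": rng.integers(0, 16, size=n_rows),
                "action": rng.integers(0, 4, size=n_rows),
                "response_time_ms": tt + td,
                "guided": guided,
                "first_action": first,
                "distance_to_goal": distance,
                "thinking_time_true_ms": tt,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# rodent-style sessions

@dataclass
class PlaceCellModel:
    """Gaussian place fields: rate = baseline + peak * exp(-d^2 / 2 width^2)."""

    centers_cm: np.ndarray   # (N, 2) x, y
    width_cm: np.ndarray     # (N,)
    peak_hz: np.ndarray      # (N,)
    baseline_hz: np.ndarray  # (N,)

    def __post_init__(self):
        if np.any(self.peak_hz < 0) or np.any(self.baseline_hz < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_neurons(self) -> int:
        return len(self.peak_hz)

    def rates_at(self, xy: np.ndarray) -> np.ndarray:
        """(N, T) firing rates at positions xy (T, 2)."""
        d2 = ((xy[None, :, :] - self.centers_cm[:, None, :]) ** 2).sum(-1)
        return (self.baseline_hz[:, None]
                + self.peak_hz[:, None]
                * np.exp(-d2 / (2 * self.width_cm[:, None] ** 2)))


def default_place_cells(rng: np.random.Generator, side: int = 5,
                        cell_cm: float = 20.0, fields_per_cell: int = 8,
                        peak_hz: float = 25.0, width_cm: float = 8.0,
                        baseline_hz: float = 0.5) -> PlaceCellModel:
    """Place fields centered on the grid cells, slightly jittered.

    The default of 8 fields per cell (200 neurons on the 5x5 arena) matches
    the order of simultaneously recorded units in the tetrode sessions this
    generator emulates (roughly 190-330 per session).
    """
    centers = []
    for r in range(side):
        for c in range(side):
            for _ in range(fields_per_cell):
                centers.append([(c + 0.5) * cell_cm + rng.normal(0, 1.0),
                                (r + 0.5) * cell_cm + rng.normal(0, 1.0)])
    n = len(centers)
    return PlaceCellModel(centers_cm=np.array(centers),
                          width_cm=np.full(n, width_cm),
                          peak_hz=np.full(n, peak_hz),
                          baseline_hz=np.full(n, baseline_hz))


def gen_arena(rng: np.random.Generator, side: int = 5,
              n_walls: int = 6) -> mz.Maze:
    """A bounded arena with `n_walls` random walls keeping it connected."""
    edges = mz.potential_edges(side, periodic=False)
    while True:
        pick = rng.choice(len(edges), size=n_walls, replace=False)
        maze_obj = mz.Maze(side=side, periodic=False,
                           walls=frozenset(edges[i] for i in pick))
        if mz.is_connected(maze_obj):
            return maze_obj


@dataclass
class ReplayScript:
    """A scripted replay trajectory inside one pre-trial stationary period."""

    trial: int
    offset_ms: float          # relative to the stationary period start
    path: list                # grid cells, first = the occupied well
    compression_ms: float = 40.0
    wall_respecting: bool = True
    goal_biased: bool = False
    hold_last_ms: float = 40.0  # extra dwell on the final state (replays
                                # linger at their end point)

    @property
    def duration_ms(self) -> float:
        return len(self.path) * self.compression_ms + self.hold_last_ms


def _bfs_path(maze_obj: mz.Maze, a: int, b: int) -> list[int]:
    tab = maze_obj.transitions()
    prev = {a: None}
    frontier = [a]
    while frontier and b not in prev:
        nxt = []
        for c in frontier:
            for nb in tab[c]:
                if int(nb) not in prev:
                    prev[int(nb)] = c
                    nxt.append(int(nb))
        frontier = nxt
    path = [b]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return path[::-1]


def _random_walk(rng, maze_obj: mz.Maze, start: int, length: int,
                 respect_walls: bool = True) -> list[int]:
    path = [start]
    cur = start
    tab = maze_obj.transitions()
    for _ in range(length):
        if respect_walls:
            opts = [int(n) for n in tab[cur] if int(n) != cur]
        else:
            opts = [n for a in range(4)
                    if (n := mz._neighbor(cur, a, maze_obj.side, False)) >= 0]
        if len(path) > 1:
            opts = [o for o in opts if o != path[-2]] or opts
        cur = int(opts[rng.integers(len(opts))])
        path.append(cur)
    return path


def gen_trial_plan(rng: np.random.Generator, n_trials: int = 24,
                   side: int = 5) -> pd.DataFrame:
    """Alternating home/away trial plan over the 3x3 wells."""
    ws = wells(side)
    home = int(rng.choice(ws))
    rows = []
    prev = int(rng.choice([w for w in ws if w != home]))
    for i in range(n_trials):
        is_home = i % 2 == 0
        goal = home if is_home else \
            int(rng.choice([w for w in ws if w not in (home, prev)]))
        rows.append(dict(trial=i + 1, type="home" if is_home else "away",
                         goal_well=goal, prev_well=prev))
        prev = goal
    return pd.DataFrame(rows)


def gen_replay_scripts(rng: np.random.Generator, plan: pd.DataFrame,
                       maze_obj: mz.Maze, n_per_trial: int = 2,
                       goal_biased: bool = True,
                       wall_respecting: bool = True,
                       compression_ms: float = 40.0,
                       min_gap_ms: float = 300.0,
                       min_len: int = 6) -> list[ReplayScript]:
    """Scripted replays starting at the occupied well.

    Goal-biased scripts follow a shortest wall-respecting path to the
    trial's goal well, extended with further legal steps to at least
    `min_len` states (so the goal sits inside the trajectory, as in forward
    replays that sweep through the reward); unbiased scripts are random
    walks.  Offsets are spaced by at least `min_gap_ms` so scripts never
    overlap.
    """
    scripts = []
    for _, tr in plan.iterrows():
        t_off = 500.0
        for _ in range(n_per_trial):
            if goal_biased:
                path = _bfs_path(maze_obj, int(tr["prev_well"]),
                                 int(tr["goal_well"]))
            else:
                path = _random_walk(rng, maze_obj, int(tr["prev_well"]),
                                    rng.integers(3, 6),
                                    respect_walls=wall_respecting)
            tries = 0
            while len(path) < min_len:
                step = _random_walk(rng, maze_obj, path[-1], 1,
                                    respect_walls=wall_respecting)[1]
                tries += 1
                if len(path) > 1 and step == path[-2] and tries < 10:
                    continue  # avoid immediate backtracking (dead ends allowed)
                path.append(step)
            sc = ReplayScript(trial=int(tr["trial"]), offset_ms=t_off,
                              path=path, compression_ms=compression_ms,
                              wall_respecting=wall_respecting,
                              goal_biased=goal_biased)
            if wall_respecting:
                tab = maze_obj.transitions()
                for a, b in zip(path[:-1], path[1:]):
                    if b not in tab[a]:
                        raise ValueError("script path blocked by a wall")
            scripts.append(sc)
            t_off += sc.duration_ms + min_gap_ms
    return scripts


def simulate_session(rng: np.random.Generator, maze_obj: mz.Maze | None = None,
                     plan: pd.DataFrame | None = None,
                     scripts: list[ReplayScript] | None = None,
                     place_cells: PlaceCellModel | None = None,
                     bin_ms: float = 5.0, cell_cm: float = 20.0,
                     speed_cms: float = 25.0,
                     stationary_s: tuple = (5.0, 15.0),
                     n_trials: int = 24,
                     replay_gain: float = 3.0) -> SessionData:
    """Simulate one home/away session with Poisson place-cell spiking.

    The animal waits at the previously rewarded well for 5-15 s (the
    pre-trial stationary period containing any scripted replays), then runs
    a wall-respecting shortest path to the next well at `speed_cms`.  Spike
    rates follow the place fields evaluated at the animal's position —
    except during a scripted replay, when they are evaluated along the
    script's path at its compressed speed and multiplied by `replay_gain`
    (the population burst that accompanies sharp-wave-ripple reactivation).
    """
    side = 5
    if maze_obj is None:
        maze_obj = gen_arena(rng, side=side)
    if maze_obj.periodic or maze_obj.side != side:
        raise ValueError("sessions use a bounded 5x5 arena")
    if plan is None:
        plan = gen_trial_plan(rng, n_trials=n_trials, side=side)
    if place_cells is None:
        place_cells = default_place_cells(rng, side=side, cell_cm=cell_cm)
    if scripts is None:
        scripts = gen_replay_scripts(rng, plan, maze_obj)

    def center(cell):
        r, c = divmod(int(cell), side)
        return np.array([(c + 0.5) * cell_cm, (r + 0.5) * cell_cm])

    bin_s = bin_ms / 1000.0
    pos_chunks, rate_pos_chunks, gain_chunks = [], [], []
    trial_rows = []
    visits = np.zeros(side * side)
    t = 0.0

    def n_bins_of(dur_ms):
        return int(round(dur_ms / bin_ms))

    tab = maze_obj.transitions()
    scripts_by_trial: dict[int, list[ReplayScript]] = {}
    for sc in scripts:
        if sc.wall_respecting:
            for a, b in zip(sc.path[:-1], sc.path[1:]):
                if b not in tab[a]:
                    raise ValueError(
                        f"script path {sc.path} is blocked by a wall")
        scripts_by_trial.setdefault(sc.trial, []).append(sc)

    for _, tr in plan.iterrows():
        stat_dur = rng.uniform(*stationary_s) * 1000.0
        t_arrive = t
        nb = n_bins_of(stat_dur)
        well_xy = center(tr["prev_well"])
        chunk = np.tile(well_xy, (nb, 1))
        rate_chunk = chunk.copy()
        gain_chunk = np.ones(nb)
        for sc in scripts_by_trial.get(int(tr["trial"]), []):
            if sc.offset_ms + sc.duration_ms > stat_dur:
                continue
            b0 = n_bins_of(sc.offset_ms)
            per_state = n_bins_of(sc.compression_ms)
            for si, cell in enumerate(sc.path):
                hold = n_bins_of(sc.hold_last_ms) if si == len(sc.path) - 1 \
                    else 0
                sl = slice(b0 + si * per_state,
                           b0 + (si + 1) * per_state + hold)
                rate_chunk[sl] = center(cell)
                gain_chunk[sl] = replay_gain
        pos_chunks.append(chunk)
        rate_pos_chunks.append(rate_chunk)
        gain_chunks.append(gain_chunk)
        t_depart = t_arrive + nb * bin_ms

        # run to the goal well, detouring via the least-visited cell so the
        # session's movement epochs cover the whole arena (needed for the
        # decoder's rate maps, as in real foraging behavior)
        waypoint = int(np.argmin(visits))
        leg1 = _bfs_path(maze_obj, int(tr["prev_well"]), waypoint)
        leg2 = _bfs_path(maze_obj, waypoint, int(tr["goal_well"]))
        path = leg1 + leg2[1:]
        for c in path:
            visits[c] += 1
        run_ms = (len(path) - 1) * cell_cm / speed_cms * 1000.0
        nb_run = max(n_bins_of(run_ms), 1)
        pts = np.array([center(c) for c in path])
        frac = np.linspace(0, 1, nb_run, endpoint=False) * (len(path) - 1)
        seg = np.minimum(frac.astype(int), len(path) - 2)
        w = frac - seg
        run_xy = pts[seg] * (1 - w[:, None]) + pts[seg + 1] * w[:, None]
        pos_chunks.append(run_xy)
        rate_pos_chunks.append(run_xy)
        gain_chunks.append(np.ones(nb_run))
        t_end = t_depart + nb_run * bin_ms
        trial_rows.append(dict(trial=int(tr["trial"]), type=tr["type"],
                               goal_well=int(tr["goal_well"]),
                               prev_well=int(tr["prev_well"]),
                               t_start=t_depart, t_end=t_end,
                               t_arrive=t_arrive, t_depart=t_depart))
        t = t_end

    xy = np.concatenate(pos_chunks)
    rate_xy = np.concatenate(rate_pos_chunks)
    n_bins = len(xy)
    speed = np.zeros(n_bins)
    speed[1:] = np.linalg.norm(np.diff(xy, axis=0), axis=1) / bin_s
    positions = pd.DataFrame({"time_ms": np.arange(n_bins) * bin_ms,
                              "x_cm": xy[:, 0], "y_cm": xy[:, 1],
                              "speed_cms": speed})
    gain = np.concatenate(gain_chunks)
    rates = place_cells.rates_at(rate_xy) * gain   # (N, n_bins)
    spikes = rng.poisson(rates * bin_s)
    return SessionData(spikes=spikes, positions=positions, maze=maze_obj,
                       trials=pd.DataFrame(trial_rows), bin_ms=bin_ms,
                       cell_cm=cell_cm)


# ---------------------------------------------------------------------------
# trained-agent fixture

def gen_agent_fixture(seed: int = 0, hidden_units: int = 48,
                      batches: int = 1500, learning_rate: float = 1e-3,
                      baseline_factor: float = 2.0,
                      cache_path: str | None = None) -> AgentParams:
    """A small trained checkpoint for analysis tests.

    Runs a deterministic short training run and checks that the resulting
    agent collects at least `baseline_factor` times the reward of a
    uniform-policy agent on fresh environments; raises if not (an invalid
    fixture).  If `cache_path` is given and exists, it is loaded instead.
    """
    import os

    from .training import TrainConfig, train, random_policy_baseline

    if cache_path and os.path.exists(cache_path):
        return AgentParams.load(cache_path)
    cfg = AgentConfig(hidden_units=hidden_units)
    tc = TrainConfig(batches=batches, seed=seed,
                     learning_rate=learning_rate, log_every=max(batches // 10, 1))
    params, _curve = train(cfg, tc)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    base = random_policy_baseline(cfg, rng, n_episodes=100)
    from .simulate import collect_episodes
    traces = collect_episodes(params, np.random.default_rng(
        np.random.SeedSequence([seed, 2])), 100)
    reward = float(np.mean([t.total_reward for t in traces]))
    if reward < baseline_factor * base:
        raise RuntimeError(
            f"fixture training failed its baseline: reward {reward:.2f} < "
            f"{baseline_factor} x {base:.2f}")
    if cache_path:
        params.save(cache_path)
    return params
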
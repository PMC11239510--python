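"""Hippocampal replay pipeline: decoding, detection and enrichment statistics.

Works on sessions from a home/away maze task on a bounded 5x5 grid arena:
spike counts in 5-ms bins, a position trace, the session's wall set and a
trial table.  A Poisson Bayesian decoder is fitted on movement epochs
(speed > 2 cm/s) and applied during stationary epochs at the previously
rewarded well; forward replays are contiguous sequences of three or more
lattice-adjacent decoded states originating at the animal's location, with
brief decoding lapses (<= 20 ms) bridged.  Four statistics compare replay
content against matched controls: wall avoidance (vs rotated/reflected wall
sets), goal passage (vs non-goal wells), the probability of behaviorally
following a replay (successful vs unsuccessful replays), and goal
over-representation by replay index within trials, each with a permutation
test across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from . import maze as mz

SPEED_THRESH_CMS = 2.0
WINDOW_MS = 75.0
BIN_MS = 5.0
MIN_RATE_HZ = 0.1
RATE_FLOOR_HZ = 0.01
LAPSE_MS = 20.0


@dataclass
class SessionData:
    """One recording session on the 5x5 arena.

    `spikes` is (n_neurons, n_bins) counts in uniform `bin_ms` bins;
    `positions` has one row per bin with columns (time_ms, x_cm, y_cm,
    speed_cms); `trials` has columns (trial, type, goal_well, prev_well,
    t_start, t_end, t_arrive, t_depart), where [t_arrive, t_depart] is the
    stationary period at the previous well ahead of the trial's run.
    """

    spikes: np.ndarray
    positions: pd.DataFrame
    maze: mz.Maze
    trials: pd.DataFrame
    bin_ms: float = BIN_MS
    cell_cm: float = 20.0

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    def cells(self) -> np.ndarray:
        """Grid cell per bin (row-major, row 0 at top)."""
        side = self.maze.side
        col = np.clip((self.positions["x_cm"].to_numpy() // self.cell_cm)
                      .astype(int), 0, side - 1)
        row = np.clip((self.positions["y_cm"].to_numpy() // self.cell_cm)
                      .astype(int), 0, side - 1)
        return row * side + col


def save_session(session: SessionData, directory: str) -> None:
    """Write a session as plain-text files (spikes/positions/trials/walls)."""
    import os
    os.makedirs(directory, exist_ok=True)
    n, b = np.nonzero(session.spikes)
    pd.DataFrame({"neuron": n, "bin_index": b,
                  "count": session.spikes[n, b]}).to_csv(
        os.path.join(directory, "spikes.csv"), index=False)
    session.positions.to_csv(os.path.join(directory, "positions.csv"),
                             index=False)
    session.trials.to_csv(os.path.join(directory, "trials.csv"), index=False)
    with open(os.path.join(directory, "walls.json"), "w") as f:
        f.write(session.maze.to_json())
    with open(os.path.join(directory, "meta.json"), "w") as f:
        import json
        json.dump({"n_neurons": int(session.spikes.shape[0]),
                   "n_bins": int(session.n_bins),
                   "bin_ms": session.bin_ms,
                   "cell_cm": session.cell_cm}, f)


def load_session(directory: str) -> SessionData:
    import json
    import os
    with open(os.path.join(directory, "meta.json")) as f:
        meta = json.load(f)
    long = pd.read_csv(os.path.join(directory, "spikes.csv"))
    spikes = np.zeros((meta["n_neurons"], meta["n_bins"]), dtype=int)
    spikes[long["neuron"], long["bin_index"]] = long["count"]
    with open(os.path.join(directory, "walls.json")) as f:
        maze_obj = mz.Maze.from_json(f.read())
    return SessionData(
        spikes=spikes,
        positions=pd.read_csv(os.path.join(directory, "positions.csv")),
        maze=maze_obj,
        trials=pd.read_csv(os.path.join(directory, "trials.csv")),
        bin_ms=meta["bin_ms"], cell_cm=meta["cell_cm"])


def wells(side: int = 5) -> list[int]:
    """The 3x3 grid of candidate reward locations (inner cells)."""
    return [r * side + c for r in range(1, side - 1)
            for c in range(1, side - 1)]


@dataclass
class Decoder:
    """Per-neuron mean rate (Hz) per grid state, with inclusion mask."""

    rates: np.ndarray            # (n_neurons, n_states), floored
    included: np.ndarray         # (n_neurons,) bool
    window_ms: float = WINDOW_MS
    bin_ms: float = BIN_MS


def fit_decoder(session: SessionData, speed_thresh: float = SPEED_THRESH_CMS,
                min_rate: float = MIN_RATE_HZ,
                floor: float = RATE_FLOOR_HZ,
                exclude_bins: np.ndarray | None = None) -> Decoder:
    """Fit Poisson rate maps from movement epochs.

    Neurons with a session-average rate below `min_rate` Hz are excluded;
    rate maps are floored at `floor` Hz so silent (neuron, state) pairs keep
    finite log-likelihoods.  `exclude_bins` masks bins out of the fit (for
    held-out evaluation).
    """
    speed = session.positions["speed_cms"].to_numpy()
    moving = speed > speed_thresh
    if exclude_bins is not None:
        moving = moving & ~exclude_bins
    if not moving.any():
        raise ValueError("no movement epochs to fit the decoder on")
    n_states = session.maze.n_cells
    cells = session.cells()
    bin_s = session.bin_ms / 1000.0
    onehot = np.zeros((moving.sum(), n_states))
    onehot[np.arange(moving.sum()), cells[moving]] = 1.0
    occupancy = onehot.sum(axis=0) * bin_s
    counts = session.spikes[:, moving] @ onehot
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occupancy > 0, counts / np.maximum(occupancy, 1e-12),
                         floor)
    rates = np.maximum(rates, floor)
    total_s = session.n_bins * bin_s
    avg_rate = session.spikes.sum(axis=1) / total_s
    return Decoder(rates=rates, included=avg_rate >= min_rate)


def decode_ml(decoder: Decoder, session: SessionData,
              bins_mask: np.ndarray) -> np.ndarray:
    """Maximum-likelihood state per bin under the Poisson decoder.

    Uses a centered rolling window of `window_ms` of spikes from the
    included neurons; bins whose window is truncated by the session edges or
    that are outside `bins_mask` decode to -1.  Ties break to the lowest
    state index.
    """
    n_bins = session.n_bins
    half = int(round(decoder.window_ms / session.bin_ms)) // 2
    spk = session.spikes[decoder.included].astype(float)
    cs = np.concatenate([np.zeros((spk.shape[0], 1)), np.cumsum(spk, axis=1)],
                        axis=1)
    out = np.full(n_bins, -1, dtype=int)
    idx = np.flatnonzero(bins_mask)
    idx = idx[(idx >= half) & (idx < n_bins - half)]
    if idx.size == 0:
        return out
    counts = cs[:, idx + half + 1] - cs[:, idx - half]        # (N, M)
    lam = decoder.rates[decoder.included] * (decoder.window_ms / 1000.0)
    loglik = counts.T @ np.log(lam) - lam.sum(axis=0)          # (M, S)
    out[idx] = np.argmax(loglik, axis=1)
    return out


def decode_stationary(decoder: Decoder, session: SessionData,
                      speed_thresh: float = SPEED_THRESH_CMS) -> np.ndarray:
    """Decoded state per 5-ms step during stationary epochs (else -1)."""
    speed = session.positions["speed_cms"].to_numpy()
    return decode_ml(decoder, session, speed < speed_thresh)


# ---------------------------------------------------------------------------
# replay detection

def _direction(a: int, b: int, side: int) -> int:
    """Cardinal action index moving a -> b on the bounded grid, else -1."""
    ra, ca = divmod(a, side)
    rb, cb = divmod(b, side)
    for act, (dr, dc) in enumerate(((-1, 0), (1, 0), (0, -1), (0, 1))):
        if (rb - ra, cb - ca) == (dr, dc):
            return act
    return -1


def _adjacent(a: int, b: int, side: int) -> bool:
    return _direction(a, b, side) >= 0


@dataclass
class ReplayEvent:
    """A decoded forward replay trajectory during a stationary epoch."""

    trial: int
    t_start_ms: float
    t_end_ms: float
    states: list
    origin: int
    lapses: list = field(default_factory=list)  # (start_ms, end_ms) excluded

    @property
    def first_action(self) -> int:
        return _direction(self.states[0], self.states[1], 5)

    def transitions(self) -> list[tuple[int, int]]:
        return list(zip(self.states[:-1], self.states[1:]))


def _runs(seq: np.ndarray) -> list[list]:
    """Run-length encode a sequence into [state, start, length] items."""
    runs = []
    for i, s in enumerate(seq):
        if runs and runs[-1][0] == s:
            runs[-1][2] += 1
        else:
            runs.append([int(s), i, 1])
    return runs


def _bridge_lapses(runs: list[list], side: int, max_bins: int
                   ) -> tuple[list[list], list[tuple[int, int]]]:
    """Remove lapse runs: short excursions away from a state and back.

    A run of duration <= `max_bins`, flanked by two runs of one same state,
    is excised and its neighbors merged — whether the excursion was to a
    distant cell or a neighboring one, since a state decoded for only a few
    5-ms steps under a 75-ms window is noise either way.  Applied
    repeatedly, so consecutive short lapses are each tolerated.
    """
    lapses = []
    changed = True
    while changed:
        changed = False
        for j in range(1, len(runs) - 1):
            prev, cur, nxt = runs[j - 1], runs[j], runs[j + 1]
            if (cur[2] <= max_bins and prev[0] == nxt[0]
                    and cur[0] != prev[0]):
                lapses.append((cur[1], cur[1] + cur[2]))
                prev[2] += nxt[2]
                del runs[j:j + 2]
                changed = True
                break
    return runs, lapses


def detect_replays(decoded: np.ndarray, session: SessionData,
                   lapse_ms: float = LAPSE_MS,
                   max_trial_s: float = 40.0,
                   drop_first_home: bool = True,
                   min_states: int = 3,
                   edge_margin_ms: float = WINDOW_MS,
                   max_dwell_ms: float = 150.0) -> list[ReplayEvent]:
    """Detect forward replays in the pre-trial stationary epochs.

    Considers, for each eligible trial (duration < `max_trial_s`; the first
    home trial of the session dropped), the decoded sequence during
    [t_arrive, t_depart] at the previous well.  Events are maximal sequences
    of consecutively lattice-adjacent states, covering >= `min_states`
    distinct cells, whose first state is the animal's current cell.  Short
    lapses are bridged and reported on the event.  `edge_margin_ms` is
    trimmed from both ends of each epoch so that decoding windows straddling
    the arrival or departure run cannot masquerade as replays.  A decoded
    state holding for longer than `max_dwell_ms` is ambient activity rather
    than part of a time-compressed sweep: it terminates any event in
    progress (and may anchor the start of the next one).
    """
    side = session.maze.side
    bin_ms = session.bin_ms
    max_lapse_bins = int(lapse_ms // bin_ms)
    events = []
    first_home_seen = False
    for _, tr in session.trials.iterrows():
        is_home = str(tr["type"]) == "home"
        if is_home and not first_home_seen:
            first_home_seen = True
            if drop_first_home:
                continue
        if (tr["t_end"] - tr["t_start"]) / 1000.0 >= max_trial_s:
            continue
        b0 = int((tr["t_arrive"] + edge_margin_ms) // bin_ms)
        b1 = int((tr["t_depart"] - edge_margin_ms) // bin_ms)
        seq = decoded[b0:b1]
        ok = seq >= 0
        if not ok.any():
            continue
        animal_cell = int(tr["prev_well"])
        # split on undecoded bins
        max_dwell_bins = int(max_dwell_ms // bin_ms)
        for chunk_start, chunk in _split_chunks(seq):
            runs = _runs(chunk)
            runs, lapse_spans = _bridge_lapses(runs, side, max_lapse_bins)
            # long dwells separate compressed sweeps; the dwell state itself
            # can anchor the start of the following sweep
            blocks, cur = [], []
            for run in runs:
                if run[2] > max_dwell_bins and cur:
                    blocks.append(cur)
                    cur = [run]
                else:
                    cur.append(run)
            if cur:
                blocks.append(cur)
            for block in blocks:
                i = 0
                while i < len(block) - (min_states - 1):
                    j = i
                    while (j + 1 < len(block)
                           and _adjacent(block[j][0], block[j + 1][0], side)):
                        j += 1
                    states = [block[k][0] for k in range(i, j + 1)]
                    if (j - i + 1 >= min_states and block[i][0] == animal_cell
                            and len(set(states)) >= min_states):
                        start_bin = b0 + chunk_start + block[i][1]
                        end_bin = b0 + chunk_start + block[j][1] + block[j][2]
                        ev_lapses = [((b0 + chunk_start + a) * bin_ms,
                                      (b0 + chunk_start + b) * bin_ms)
                                     for a, b in lapse_spans
                                     if block[i][1] <= a
                                     <= block[j][1] + block[j][2]]
                        events.append(ReplayEvent(
                            trial=int(tr["trial"]),
                            t_start_ms=start_bin * bin_ms,
                            t_end_ms=end_bin * bin_ms,
                            states=states, origin=animal_cell,
                            lapses=ev_lapses))
                    i = max(j, i + 1)
    return events


def _split_chunks(seq: np.ndarray):
    """Yield (start_offset, contiguous decoded sub-sequences) of `seq`."""
    ok = seq >= 0
    i = 0
    n = len(seq)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        yield i, seq[i:j]
        i = j


# ---------------------------------------------------------------------------
# wall transforms (dihedral group of the square arena)

def _transform_cell(cell: int, side: int, kind: str) -> int:
    r, c = divmod(cell, side)
    s = side - 1
    mapping = {
        "rot90": (c, s - r), "rot180": (s - r, s - c), "rot270": (s - c, r),
        "flip_h": (r, s - c), "flip_v": (s - r, c),
        "flip_d": (c, r), "flip_a": (s - c, s - r),
    }
    nr, nc = mapping[kind]
    return nr * side + nc


def transform_walls(maze_obj: mz.Maze, kind: str) -> frozenset:
    """Image of the wall set under a rotation/reflection of the arena."""
    side = maze_obj.side
    out = set()
    for cell, axis in maze_obj.walls:
        a = cell
        b = mz._neighbor(cell, mz.DOWN if axis == mz.AXIS_DOWN else mz.RIGHT,
                         side, maze_obj.periodic)
        ta, tb = _transform_cell(a, side, kind), _transform_cell(b, side, kind)
        for act in range(4):
            if mz._neighbor(ta, act, side, maze_obj.periodic) == tb:
                out.add(mz._edge_for_move(ta, act, side))
                break
    return frozenset(out)


def nonidentical_transforms(maze_obj: mz.Maze) -> list[frozenset]:
    """The wall-set images under the 7 non-identity symmetries, minus any
    that coincide with the original walls."""
    kinds = ("rot90", "rot180", "rot270", "flip_h", "flip_v",
             "flip_d", "flip_a")
    out = []
    for kind in kinds:
        w = transform_walls(maze_obj, kind)
        if w != maze_obj.walls:
            out.append(w)
    return out


def _crossing_fraction(replays: list[ReplayEvent], walls: frozenset,
                       side: int) -> float:
    cross = total = 0
    for ev in replays:
        for a, b in ev.transitions():
            d = _direction(a, b, side)
            total += 1
            if mz._edge_for_move(a, d, side) in walls:
                cross += 1
    return cross / total if total else float("nan")


def wall_crossing_stat(replays: list[ReplayEvent], maze_obj: mz.Maze
                       ) -> tuple[float, float]:
    """Fraction of replay transitions through a wall, vs transformed walls."""
    true_frac = _crossing_fraction(replays, maze_obj.walls, maze_obj.side)
    ctrl_sets = nonidentical_transforms(maze_obj)
    ctrl = float(np.mean([_crossing_fraction(replays, w, maze_obj.side)
                          for w in ctrl_sets])) if ctrl_sets else float("nan")
    return true_frac, ctrl


# ---------------------------------------------------------------------------
# goal passage and success

def goal_passage_stat(replays: list[ReplayEvent], goal: int,
                      side: int = 5) -> tuple[float, float]:
    """Fraction of replays passing through the goal well vs control wells.

    Controls are, per replay, the wells that are neither the goal nor the
    replay's origin.
    """
    if not replays:
        return float("nan"), float("nan")
    ws = wells(side)
    true_hits, ctrl_hits = [], []
    for ev in replays:
        body = set(ev.states)
        true_hits.append(goal in body)
        ctrl = [w for w in ws if w != goal and w != ev.origin]
        ctrl_hits.append(np.mean([w in body for w in ctrl]))
    return float(np.mean(true_hits)), float(np.mean(ctrl_hits))


def replay_successful(ev: ReplayEvent, goal: int, walls: frozenset,
                      side: int = 5) -> bool:
    """A replay is successful if it reaches `goal` without crossing a wall
    on the way there."""
    for i, (a, b) in enumerate(ev.transitions()):
        d = _direction(a, b, side)
        if mz._edge_for_move(a, d, side) in walls:
            return False
        if b == goal:
            return True
    return False


def follow_probability(replays: list[ReplayEvent],
                       subsequent_actions: list[int], goal: int,
                       maze_obj: mz.Maze,
                       disjoint: bool = True) -> dict:
    """P(first physical action == first replayed action) by success class.

    Successful replays reach the goal without crossing a wall.  The
    unsuccessful class pools, over the control wells (neither goal nor
    origin), the replays successful toward that well — excluding, when
    `disjoint`, replays successful for the true goal.
    """
    side = maze_obj.side
    walls = maze_obj.walls
    ws = wells(side)
    succ_match, ctrl_fracs = [], []
    succ_mask = [replay_successful(ev, goal, walls, side) for ev in replays]
    for ev, a_next, s in zip(replays, subsequent_actions, succ_mask):
        if s:
            succ_match.append(ev.first_action == a_next)
    for c in ws:
        matches = []
        for ev, a_next, s in zip(replays, subsequent_actions, succ_mask):
            if c == goal or c == ev.origin:
                continue
            if disjoint and s:
                continue
            if replay_successful(ev, c, walls, side):
                matches.append(ev.first_action == a_next)
        if matches:
            ctrl_fracs.append(np.mean(matches))
    return {
        "p_success": float(np.mean(succ_match)) if succ_match else float("nan"),
        "p_unsuccess": float(np.mean(ctrl_fracs)) if ctrl_fracs else float("nan"),
        "n_success": len(succ_match),
        "n_unsuccess": len(ctrl_fracs),
    }


# ---------------------------------------------------------------------------
# consecutive replays

def _time_corrected(success: np.ndarray, ts: np.ndarray, td: np.ndarray
                    ) -> np.ndarray:
    """Subtract the time-predicted component, keeping the overall mean."""
    X = np.column_stack([np.ones_like(ts), ts, td])
    coef, *_ = np.linalg.lstsq(X, success.astype(float), rcond=None)
    pred = X @ coef
    return success - pred + success.mean()

def consecutive_overrepresentation(replays: list[ReplayEvent],
                                   session: SessionData,
                                   max_index: int = 3,
                                   cap_s: float = 15.0,
                                   n_perm: int = 0,
                                   rng: np.random.Generator | None = None
                                   ) -> dict:
    """Goal over-representation by replay index in trials with >= 3 replays.

    Success (reaching the trial's goal well without wall crossing) is
    residualized against the time since arriving at the well and the time
    until departing (both capped at `cap_s`); the per-index mean is divided
    by the analogous all-index control-well baseline with its own time
    correction.  Optional permutation test shuffles replay order within
    trials (after the time correction) and reports, for each index > 1, the
    fraction of permutations in which the increase over index 1 is at least
    the observed one.
    """
    side = session.maze.side
    walls = session.maze.walls
    ws = wells(side)
    tinfo = session.trials.set_index("trial")
    rows = []
    by_trial: dict[int, list[ReplayEvent]] = {}
    for ev in replays:
        by_trial.setdefault(ev.trial, []).append(ev)
    for trial, evs in by_trial.items():
        if len(evs) < max_index:
            continue
        evs = sorted(evs, key=lambda e: e.t_start_ms)
        goal = int(tinfo.loc[trial, "goal_well"])
        arrive = float(tinfo.loc[trial, "t_arrive"])
        depart = float(tinfo.loc[trial, "t_depart"])
        for idx, ev in enumerate(evs, start=1):
            ctrl = [w for w in ws if w != goal and w != ev.origin]
            rows.append(dict(
                trial=trial, index=idx,
                success=replay_successful(ev, goal, walls, side),
                ctrl_success=np.mean([replay_successful(ev, c, walls, side)
                                      for c in ctrl]),
                ts=min((ev.t_start_ms - arrive) / 1000.0, cap_s),
                td=min((depart - ev.t_end_ms) / 1000.0, cap_s)))
    if not rows:
        raise ValueError("no trial has the required number of replays")
    df = pd.DataFrame(rows)
    corr_true = _time_corrected(df["success"].to_numpy(),
                                df["ts"].to_numpy(), df["td"].to_numpy())
    corr_ctrl = _time_corrected(df["ctrl_success"].to_numpy(),
                                df["ts"].to_numpy(), df["td"].to_numpy())
    baseline = corr_ctrl.mean()
    idx_arr = df["index"].to_numpy()
    trial_arr = df["trial"].to_numpy()

    def curve(corrected, order_idx):
        return np.array([corrected[order_idx == i].mean() / baseline
                         for i in range(1, max_index + 1)])

    overrep = curve(corr_true, idx_arr)
    out = {"overrep": overrep, "n_trials": int(df["trial"].nunique()),
           "baseline": float(baseline)}
    if n_perm > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        obs = overrep - overrep[0]
        hits = np.zeros(max_index)
        for _ in range(n_perm):
            perm_idx = idx_arr.copy()
            for trial in np.unique(trial_arr):
                m = trial_arr == trial
                perm_idx[m] = rng.permutation(perm_idx[m])
            oc = curve(corr_true, perm_idx)
            hits += (oc - oc[0]) >= obs - 1e-12
        out["p_values"] = hits[1:] / n_perm
    return out


# ---------------------------------------------------------------------------
# permutation test

def permutation_test(true_vals, control_vals, n_perm: int = 10_000,
                     rng: np.random.Generator | None = None,
                     exact: bool = False) -> float:
    """Paired label-swap permutation test across sessions.

    The statistic is the mean of (true - control); the p-value is the
    fraction of permutations (independent label swaps per session) whose
    statistic is at least the observed one.  With `exact`, all 2^S swap
    patterns are enumerated instead.
    """
    t = np.asarray(true_vals, dtype=float)
    c = np.asarray(control_vals, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("true and control must be 1-D arrays of equal length")
    if not exact and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    diff = t - c
    obs = diff.mean()
    S = len(diff)
    if exact:
        if S > 20:
            raise ValueError("exact enumeration limited to 20 sessions")
        count = 0
        for signs in product((1.0, -1.0), repeat=S):
            if (diff * signs).mean() >= obs - 1e-12:
                count += 1
        return count / 2 ** S
    rng = rng if rng is not None else np.random.default_rng(0)
    signs = rng.choice((1.0, -1.0), size=(n_perm, S))
    stats_perm = (signs * diff).mean(axis=1)
    return float(np.mean(stats_perm >= obs - 1e-12))
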
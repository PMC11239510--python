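"""Gridworld maze environment with periodic or bounded boundaries.

The arena is a ``side x side`` lattice of cells, indexed row-major with cell 0
in the top-left corner.  Physical actions are ordered ``(up, down, left,
right)`` = ``(0, 1, 2, 3)`` with *up* decreasing the row index; action 4 is
reserved for the agent's rollout (planning) action.  Walls live on undirected
edges between lattice-adjacent cells; on a periodic arena adjacency wraps
across the boundary.

Mazes are generated by carving a perfect maze (a uniformly-rooted randomized
depth-first spanning tree) and then deleting a few extra walls, which yields
connected mazes with loops whose shortest-path statistics are comparable
between the periodic and bounded variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

# physical actions
UP, DOWN, LEFT, RIGHT = 0, 1, 2, 3
ROLLOUT = 4
N_ACTIONS = 5

# wall-edge axes: an edge id is (cell, axis) where axis 0 joins `cell` to the
# cell below it (row + 1) and axis 1 joins it to the cell on its right.
AXIS_DOWN, AXIS_RIGHT = 0, 1

#: wall-clock defaults (ms)
ACTION_MS = 400
ROLLOUT_MS = 120
EPISODE_MS = 20_000


def _neighbor(cell: int, action: int, side: int, periodic: bool) -> int:
    """Adjacent cell in the direction of `action`, or -1 if off a bounded edge."""
    r, c = divmod(cell, side)
    if action == UP:
        r -= 1
    elif action == DOWN:
        r += 1
    elif action == LEFT:
        c -= 1
    elif action == RIGHT:
        c += 1
    else:
        raise ValueError(f"invalid physical action {action}")
    if periodic:
        return (r % side) * side + (c % side)
    if 0 <= r < side and 0 <= c < side:
        return r * side + c
    return -1


def _edge_for_move(cell: int, action: int, side: int) -> tuple[int, int]:
    """Canonical (cell, axis) edge id crossed when moving from `cell`."""
    nxt = _neighbor(cell, action, side, periodic=True)
    if action == DOWN:
        return (cell, AXIS_DOWN)
    if action == RIGHT:
        return (cell, AXIS_RIGHT)
    if action == UP:
        return (nxt, AXIS_DOWN)
    return (nxt, AXIS_RIGHT)


def potential_edges(side: int, periodic: bool) -> list[tuple[int, int]]:
    """All edge ids present under the boundary convention."""
    edges = []
    for cell in range(side * side):
        r, c = divmod(cell, side)
        if periodic or r < side - 1:
            edges.append((cell, AXIS_DOWN))
        if periodic or c < side - 1:
            edges.append((cell, AXIS_RIGHT))
    return edges


@dataclass(frozen=True)
class Maze:
    """A wall configuration over the lattice.

    `walls` is a frozenset of (cell, axis) edge ids.  The open-passage graph
    is guaranteed connected for generator output; arbitrary wall sets can be
    constructed and checked with :func:`is_connected`.
    """

    side: int = 4
    periodic: bool = True
    walls: frozenset = frozenset()

    @property
    def n_cells(self) -> int:
        return self.side * self.side

    def transitions(self) -> np.ndarray:
        """(n_cells, 4) table of next cells; blocked or off-grid moves stay put."""
        cached = getattr(self, "_transitions", None)
        if cached is not None:
            return cached
        tab = np.empty((self.n_cells, 4), dtype=np.int64)
        for cell in range(self.n_cells):
            for a in range(4):
                nxt = _neighbor(cell, a, self.side, self.periodic)
                if nxt < 0 or _edge_for_move(cell, a, self.side) in self.walls:
                    nxt = cell
                tab[cell, a] = nxt
        object.__setattr__(self, "_transitions", tab)
        return tab

    def wall_vector(self) -> np.ndarray:
        """Binary wall indicator of length 2*side^2 indexed by cell*2 + axis."""
        v = np.zeros(2 * self.n_cells)
        for cell, axis in self.walls:
            v[2 * cell + axis] = 1.0
        return v

    # -- JSON round trip (walls as cell pairs, the external interchange format)
    def to_json(self) -> str:
        pairs = []
        for cell, axis in sorted(self.walls):
            a = DOWN if axis == AXIS_DOWN else RIGHT
            pairs.append([cell, _neighbor(cell, a, self.side, self.periodic)])
        return json.dumps(
            {"side": self.side, "periodic": self.periodic, "walls": pairs}
        )

    @classmethod
    def from_json(cls, text: str) -> "Maze":
        obj = json.loads(text)
        side, periodic = int(obj["side"]), bool(obj["periodic"])
        walls = set()
        for a_cell, b_cell in obj["walls"]:
            edge = None
            for act in range(4):
                if _neighbor(a_cell, act, side, periodic) == b_cell:
                    edge = _edge_for_move(a_cell, act, side)
                    break
            if edge is None:
                raise ValueError(f"wall pair {a_cell}-{b_cell} is not adjacent")
            walls.add(edge)
        return cls(side=side, periodic=periodic, walls=frozenset(walls))


def is_connected(maze: Maze) -> bool:
    tab = maze.transitions()
    seen = np.zeros(maze.n_cells, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        c = stack.pop()
        for n in tab[c]:
            if not seen[n]:
                seen[n] = True
                stack.append(n)
    return bool(seen.all())


def generate_maze(rng: np.random.Generator, side: int = 4, periodic: bool = True) -> Maze:
    """Sample a maze: DFS-carve a perfect maze, then knock out extra walls.

    The carving step produces a spanning tree of open passages (all other
    potential edges are walls).  In the last step, 3 of the remaining walls
    (periodic) or 4 (bounded) are removed uniformly at random, which
    approximately matches the shortest-path distributions of the two variants.
    """
    if side < 2:
        raise ValueError("side must be >= 2")
    n = side * side
    walls = set(potential_edges(side, periodic))
    visited = np.zeros(n, dtype=bool)
    start = int(rng.integers(n))
    visited[start] = True
    stack = [start]
    while stack:
        cell = stack[-1]
        nbrs = []
        for a in range(4):
            nxt = _neighbor(cell, a, side, periodic)
            if nxt >= 0 and not visited[nxt]:
                nbrs.append((a, nxt))
        if not nbrs:
            stack.pop()
            continue
        a, nxt = nbrs[rng.integers(len(nbrs))]
        walls.discard(_edge_for_move(cell, a, side))
        visited[nxt] = True
        stack.append(nxt)
    n_extra = 3 if periodic else 4
    remaining = sorted(walls)
    for i in rng.choice(len(remaining), size=n_extra, replace=False):
        walls.discard(remaining[i])
    return Maze(side=side, periodic=periodic, walls=frozenset(walls))


@dataclass
class EnvState:
    """Mutable episode state: maze + hidden goal + agent position + clock."""

    maze: Maze
    goal: int
    agent: int
    t: float = 0.0
    trial: int = 1
    T: float = EPISODE_MS

    def copy(self) -> "EnvState":
        return replace(self)


def init_episode(rng: np.random.Generator, maze: Maze | None = None,
                 T: float = EPISODE_MS, side: int = 4,
                 periodic: bool = True) -> EnvState:
    """Sample a fresh episode: maze, hidden goal and start location."""
    if maze is None:
        maze = generate_maze(rng, side=side, periodic=periodic)
    n = maze.n_cells
    goal = int(rng.integers(n))
    # the initial location is never the goal itself (a zero-length trial)
    agent = int(rng.integers(n - 1))
    if agent >= goal:
        agent += 1
    return EnvState(maze=maze, goal=goal, agent=agent, T=T)


def step(state: EnvState, action: int, rng: np.random.Generator,
         action_ms: float = ACTION_MS) -> tuple[EnvState, float, bool]:
    """Execute one physical action.

    Moving into a wall leaves the agent in place with no reward.  Reaching the
    goal yields reward 1 and the agent is relocated uniformly at random over
    the other cells (`teleported=True`); the caller is responsible for feeding
    the goal-cell observation at the teleport iteration and ignoring the
    policy output there.  The clock advances by one physical-action duration.
    """
    if not 0 <= action < 4:
        raise ValueError(f"invalid physical action {action}")
    if state.t >= state.T:
        raise RuntimeError("episode is over (t >= T)")
    new = state.copy()
    new.t = state.t + action_ms
    nxt = int(state.maze.transitions()[state.agent, action])
    if nxt == state.goal:
        n = state.maze.n_cells
        tele = int(rng.integers(n - 1))
        if tele >= state.goal:
            tele += 1
        new.agent = tele
        new.trial = state.trial + 1
        return new, 1.0, True
    new.agent = nxt
    return new, 0.0, False


FEEDBACK_LEN = 33  # 8 slots x 4 one-hot imagined actions + 1 success bit


def observation_length(side: int = 4, feedback_len: int = FEEDBACK_LEN) -> int:
    n = side * side
    return n + N_ACTIONS + 1 + 2 * n + 1 + feedback_len


def observe(state: EnvState, prev_action: int | None, prev_reward: float,
            rollout_feedback: np.ndarray | None = None,
            loc: int | None = None,
            feedback_len: int = FEEDBACK_LEN) -> np.ndarray:
    """Encode the network input vector.

    Blocks: agent location (one-hot), previous action (one-hot, all-zero on
    the first step), previous reward, wall layout, elapsed time t/T, rollout
    feedback (zeros when the last action was physical).  The goal is never
    encoded.  `loc` overrides the encoded location (used for the goal-cell
    input at teleport iterations and for imagined states during rollouts).
    """
    n = state.maze.n_cells
    x = np.zeros(observation_length(state.maze.side, feedback_len))
    cell = state.agent if loc is None else loc
    x[cell] = 1.0
    if prev_action is not None:
        if not 0 <= prev_action < N_ACTIONS:
            raise ValueError(f"invalid previous action {prev_action}")
        x[n + prev_action] = 1.0
    x[n + N_ACTIONS] = prev_reward
    x[n + N_ACTIONS + 1:n + N_ACTIONS + 1 + 2 * n] = state.maze.wall_vector()
    x[n + N_ACTIONS + 1 + 2 * n] = state.t / state.T
    if rollout_feedback is not None:
        fb = np.asarray(rollout_feedback, dtype=float)
        if fb.shape != (feedback_len,):
            raise ValueError(f"rollout feedback must have length {feedback_len}")
        x[-feedback_len:] = fb
    return x


def shortest_path_length(maze: Maze, a: int, b: int) -> int:
    """Minimal number of legal moves between cells `a` and `b` (BFS)."""
    if not (0 <= a < maze.n_cells and 0 <= b < maze.n_cells):
        raise ValueError("invalid cell index")
    return int(shortest_path_lengths_from(maze, a)[b])


def shortest_path_lengths_from(maze: Maze, a: int) -> np.ndarray:
    """BFS distances from cell `a` to every cell."""
    tab = maze.transitions()
    dist = np.full(maze.n_cells, -1, dtype=np.int64)
    dist[a] = 0
    frontier = [a]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for c in frontier:
            for nb in tab[c]:
                if dist[nb] < 0:
                    dist[nb] = d
                    nxt.append(int(nb))
        frontier = nxt
    return dist


def optimal_exploration_steps(maze: Maze, start: int = 0,
                              max_states: int = 5_000_000) -> float:
    """Expected steps to first reward of the fastest full-coverage walk.

    Finds, by dynamic programming over (visited-set, cell) states, the
    shortest walk from `start` that visits every cell; among walks of minimal
    length it picks one minimizing the mean first-visit step index.  The
    returned value is that mean over all cells used as the goal (the start
    cell contributes index 0).
    """
    n = maze.n_cells
    tab = maze.transitions()
    full = (1 << n) - 1
    start_code = ((1 << start) << 5) | start  # mask << 5 | cell (n <= 25 fits)
    if n > 25:
        raise ValueError("exploration search supports up to 25 cells")
    # Dijkstra-by-layers: dist implicit in BFS layer; tie-break on summed
    # first-visit indices, which is exact because every prefix of a minimal
    # walk is itself minimal to its intermediate (mask, cell) state.
    best_sum: dict[int, int] = {start_code: 0}
    frontier: dict[int, int] = {start_code: 0}
    steps = 0
    while frontier:
        done = {code: s for code, s in frontier.items()
                if (code >> 5) == full}
        if done:
            return (min(done.values()) / n) if n else 0.0
        steps += 1
        if len(best_sum) > max_states:
            raise RuntimeError("exploration search budget exceeded")
        nxt: dict[int, int] = {}
        for code, ssum in frontier.items():
            mask, cell = code >> 5, code & 31
            for a in range(4):
                nb = int(tab[cell, a])
                nmask = mask | (1 << nb)
                ncode = (nmask << 5) | nb
                nsum = ssum + (steps if nmask != mask else 0)
                prev = best_sum.get(ncode)
                if prev is None or nsum < prev:
                    best_sum[ncode] = nsum
                    nxt[ncode] = nsum
        frontier = nxt
    raise RuntimeError("maze is not connected")


def mean_shortest_path(maze: Maze) -> float:
    """All-pairs mean shortest-path length (including zero self-distances)."""
    dists = [shortest_path_lengths_from(maze, a) for a in range(maze.n_cells)]
    return float(np.mean(dists))
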
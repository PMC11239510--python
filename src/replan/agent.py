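"""Recurrent planning agent: GRU core, policy/value/world-model heads, rollouts.

The agent is a gated recurrent unit (GRU) network.  Its input is the encoded
observation (see :mod:`replan.maze`); its outputs are a 5-way policy over
(up, down, left, right, rollout), a scalar state value, and a learned world
model that maps (hidden state, action) to distributions over the next cell
and the hidden goal cell.  Choosing the fifth action triggers a *rollout*: an
imagined trajectory sampled from the agent's own policy and propagated
through the world model, whose flattened action sequence plus a success bit
is fed back as input on the next iteration.  Rollouts never mutate the
caller's hidden state or location and carry no gradients.

All numerics are plain numpy; the update rule is

    z = sigmoid(Wz x + Uz h + bz)
    r = sigmoid(Wr x + Ur h + br)
    n = tanh(Wn x + r * (Un h) + bn)
    h' = (1 - z) * n + z * h

so that at zero weights the policy is uniform and the value is zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np

from . import maze as mz

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class AgentConfig:
    hidden_units: int = 100
    planning_horizon: int = 8
    action_ms: float = 400.0
    rollout_ms: float = 120.0
    per_step_rollout_ms: float = 24.0
    rollout_cost: str = "fixed"  # "fixed" (120 ms) or "per_step" (l * 24 ms)
    episode_ms: float = 20_000.0
    side: int = 4
    periodic: bool = True
    world_hidden: int = 33

    def __post_init__(self):
        if self.hidden_units < 1 or self.planning_horizon < 1:
            raise ValueError("hidden_units and planning_horizon must be >= 1")
        if self.rollout_cost not in ("fixed", "per_step"):
            raise ValueError("rollout_cost must be 'fixed' or 'per_step'")

    @property
    def n_cells(self) -> int:
        return self.side * self.side

    @property
    def feedback_len(self) -> int:
        return 4 * self.planning_horizon + 1

    @property
    def obs_len(self) -> int:
        n = self.n_cells
        return n + mz.N_ACTIONS + 1 + 2 * n + 1 + self.feedback_len


def advance_clock(kind: str, rollout_length: int = 0,
                  config: AgentConfig | None = None) -> float:
    """Wall-clock cost in ms of one network iteration."""
    cfg = config or AgentConfig()
    if kind == "physical":
        return cfg.action_ms
    if kind == "rollout":
        if cfg.rollout_cost == "per_step":
            return rollout_length * cfg.per_step_rollout_ms
        return cfg.rollout_ms
    raise ValueError(f"unknown iteration kind {kind!r}")


# parameter tensor names and their shape builders
def _param_shapes(cfg: AgentConfig) -> dict[str, tuple]:
    H, X, M = cfg.hidden_units, cfg.obs_len, cfg.world_hidden
    n = cfg.n_cells
    return {
        "Wz": (H, X), "Uz": (H, H), "bz": (H,),
        "Wr": (H, X), "Ur": (H, H), "br": (H,),
        "Wn": (H, X), "Un": (H, H), "bn": (H,),
        "Wp": (mz.N_ACTIONS, H), "bp": (mz.N_ACTIONS,),
        "wv": (H,), "bv": (),
        "Wm1": (M, H + mz.N_ACTIONS), "bm1": (M,),
        "Wm2": (2 * n, M), "bm2": (2 * n,),
    }


@dataclass
class AgentParams:
    """All trainable tensors plus the architecture config."""

    config: AgentConfig
    tensors: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, config: AgentConfig) -> "AgentParams":
        return cls(config, {k: np.zeros(s) for k, s in _param_shapes(config).items()})

    @classmethod
    def init(cls, config: AgentConfig, rng: np.random.Generator) -> "AgentParams":
        tensors = {}
        for name, shape in _param_shapes(config).items():
            if len(shape) < 2:
                tensors[name] = np.zeros(shape)
            else:
                fan_in = shape[1]
                tensors[name] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
        return cls(config, tensors)

    def copy(self) -> "AgentParams":
        return AgentParams(self.config, {k: v.copy() for k, v in self.tensors.items()})

    def __getattr__(self, name):
        tensors = object.__getattribute__(self, "tensors")
        if name in tensors:
            return tensors[name]
        raise AttributeError(name)

    # flat-vector view (optimizers, finite-difference tests)
    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.tensors[k].ravel()
                               for k in sorted(self.tensors)])

    def from_vector(self, vec: np.ndarray) -> "AgentParams":
        out, i = {}, 0
        for k in sorted(self.tensors):
            shape = self.tensors[k].shape
            size = int(np.prod(shape)) if shape else 1
            out[k] = np.asarray(vec[i:i + size]).reshape(shape)
            i += size
        return AgentParams(self.config, out)

    def save(self, path: str) -> None:
        payload = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "tensors": {k: v.tolist() for k, v in self.tensors.items()},
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def load(cls, path: str) -> "AgentParams":
        with open(path) as f:
            payload = json.load(f)
        if payload.get("version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        cfg = AgentConfig(**payload["config"])
        tensors = {k: np.asarray(v, dtype=float)
                   for k, v in payload["tensors"].items()}
        expected = _param_shapes(cfg)
        for k, shape in expected.items():
            if tensors[k].shape != shape:
                raise ValueError(f"tensor {k} has shape {tensors[k].shape}, "
                                 f"expected {shape}")
        return cls(cfg, tensors)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class GRUCache(NamedTuple):
    x: np.ndarray
    h_prev: np.ndarray
    z: np.ndarray
    r: np.ndarray
    n: np.ndarray
    hu: np.ndarray  # Un h_prev


def gru_forward(params: AgentParams, h: np.ndarray, x: np.ndarray
                ) -> tuple[np.ndarray, GRUCache]:
    """One GRU step.  `h` is (..., H), `x` is (..., X)."""
    p = params.tensors
    z = _sigmoid(x @ p["Wz"].T + h @ p["Uz"].T + p["bz"])
    r = _sigmoid(x @ p["Wr"].T + h @ p["Ur"].T + p["br"])
    hu = h @ p["Un"].T
    n = np.tanh(x @ p["Wn"].T + r * hu + p["bn"])
    h_new = (1.0 - z) * n + z * h
    return h_new, GRUCache(x, h, z, r, n, hu)


def gru_backward(params: AgentParams, cache: GRUCache, dh_new: np.ndarray,
                 grads: dict) -> np.ndarray:
    """Backprop one GRU step; accumulates into `grads`, returns dh_prev."""
    p = params.tensors
    x, h, z, r, n, hu = cache
    dz = dh_new * (h - n)
    dn = dh_new * (1.0 - z)
    dh = dh_new * z
    da_n = dn * (1.0 - n * n)
    dr = da_n * hu
    dhu = da_n * r
    da_z = dz * z * (1.0 - z)
    da_r = dr * r * (1.0 - r)
    grads["Wn"] += da_n.T @ x
    grads["Un"] += dhu.T @ h
    grads["bn"] += da_n.sum(axis=0)
    grads["Wz"] += da_z.T @ x
    grads["Uz"] += da_z.T @ h
    grads["bz"] += da_z.sum(axis=0)
    grads["Wr"] += da_r.T @ x
    grads["Ur"] += da_r.T @ h
    grads["br"] += da_r.sum(axis=0)
    dh += dhu @ p["Un"] + da_z @ p["Uz"] + da_r @ p["Ur"]
    return dh


def policy_value(params: AgentParams, h: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    p = params.tensors
    logits = h @ p["Wp"].T + p["bp"]
    return softmax(logits), h @ p["wv"] + p["bv"]


def agent_step(params: AgentParams, h: np.ndarray, x: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, GRUCache]:
    """One iteration of the network dynamics: h' = phi(x, h), heads of h'.

    Returns (h_new, policy, value, cache).  Deterministic given inputs.
    """
    h = np.asarray(h, dtype=float)
    x = np.asarray(x, dtype=float)
    H, X = params.config.hidden_units, params.config.obs_len
    if h.shape[-1] != H:
        raise ValueError(f"hidden state must have length {H}")
    if x.shape[-1] != X:
        raise ValueError(f"input must have length {X}")
    h_new, cache = gru_forward(params, h, x)
    pi, v = policy_value(params, h_new)
    return h_new, pi, v, cache


def predict_world(params: AgentParams, h: np.ndarray, a
                  ) -> tuple[np.ndarray, np.ndarray]:
    """World-model heads: distributions over next state and goal location."""
    n = params.config.n_cells
    p = params.tensors
    h = np.atleast_2d(np.asarray(h, dtype=float))
    a_idx = np.atleast_1d(np.asarray(a, dtype=int))
    if np.any((a_idx < 0) | (a_idx >= mz.N_ACTIONS)):
        raise ValueError("action index out of range")
    a_onehot = np.zeros((h.shape[0], mz.N_ACTIONS))
    a_onehot[np.arange(h.shape[0]), a_idx] = 1.0
    u = np.concatenate([h, a_onehot], axis=-1)
    m = np.maximum(u @ p["Wm1"].T + p["bm1"], 0.0)
    logits = m @ p["Wm2"].T + p["bm2"]
    sdist = softmax(logits[:, :n])
    gdist = softmax(logits[:, n:])
    if np.ndim(a) == 0 and np.asarray(h).ndim <= 2:
        return sdist[0] if sdist.shape[0] == 1 else sdist, \
               gdist[0] if gdist.shape[0] == 1 else gdist
    return sdist, gdist


def sample_action(policy: np.ndarray, rng: np.random.Generator | None = None,
                  greedy: bool = False) -> int:
    """Draw an action from a policy simplex; greedy = argmax (lowest index wins)."""
    policy = np.asarray(policy, dtype=float)
    if policy.ndim != 1 or not np.isclose(policy.sum(), 1.0, atol=1e-6) \
            or np.any(policy < -1e-12):
        raise ValueError("policy must be a probability vector")
    if greedy:
        return int(np.argmax(policy))
    if rng is None:
        raise ValueError("rng required for stochastic sampling")
    return int(rng.choice(len(policy), p=policy / policy.sum()))


@dataclass
class Rollout:
    """An imagined trajectory and the feedback vector derived from it."""

    actions: list
    imagined_states: list
    imagined_goal: int
    success: bool
    feedback: np.ndarray

    def __len__(self) -> int:
        return len(self.actions)


def feedback_vector(actions: list[int], success: bool, horizon: int) -> np.ndarray:
    """Flattened imagined-action array: horizon x 4 one-hots + success bit."""
    fb = np.zeros(4 * horizon + 1)
    for j, a in enumerate(actions):
        fb[4 * j + a] = 1.0
    fb[-1] = 1.0 if success else 0.0
    return fb


def decode_feedback(fb: np.ndarray) -> tuple[list[int], bool]:
    """Inverse of :func:`feedback_vector`."""
    fb = np.asarray(fb)
    slots = fb[:-1].reshape(-1, 4)
    actions = []
    for row in slots:
        if row.sum() == 0:
            break
        actions.append(int(np.argmax(row)))
    return actions, bool(fb[-1] > 0.5)


def physical_policy(policy: np.ndarray) -> np.ndarray:
    """Renormalize a 5-way policy over the four physical actions."""
    p = np.asarray(policy, dtype=float)[..., :4]
    s = p.sum(axis=-1, keepdims=True)
    out = np.where(s > 0, p / np.where(s > 0, s, 1.0), 0.25)
    return out


def run_rollout(params: AgentParams, h: np.ndarray, state: mz.EnvState,
                rng: np.random.Generator, at_teleport: bool = False) -> Rollout:
    """Sample one imagined rollout from (h, state) through the world model.

    The imagined goal is the argmax of the goal prediction at rollout start.
    Imagined actions are drawn from the policy renormalized over the four
    physical actions; the imagined next state is the argmax of the predicted
    next-state distribution.  The loop stops at the planning horizon or as
    soon as the imagined state equals the imagined goal.  The caller's `h`
    and `state` are never modified and no gradient bookkeeping is performed.
    """
    if at_teleport:
        raise RuntimeError("rollouts are not possible at a teleport iteration")
    cfg = params.config
    h_im = np.array(h, dtype=float, copy=True)
    s_im = state.agent
    actions: list[int] = []
    states: list[int] = []
    goal_im = -1
    success = False
    for j in range(cfg.planning_horizon):
        pi, _ = policy_value(params, h_im)
        a_im = sample_action(physical_policy(pi), rng)
        sdist, gdist = predict_world(params, h_im, a_im)
        if j == 0:
            goal_im = int(np.argmax(gdist))
        s_next = int(np.argmax(sdist))
        actions.append(a_im)
        states.append(s_next)
        if s_next == goal_im:
            success = True
            break
        s_im = s_next
        x_im = mz.observe(state, prev_action=a_im, prev_reward=0.0, loc=s_im,
                          feedback_len=cfg.feedback_len)
        h_im, _ = gru_forward(params, h_im, x_im)
    fb = feedback_vector(actions, success, cfg.planning_horizon)
    return Rollout(actions=actions, imagined_states=states,
                   imagined_goal=goal_im, success=success, feedback=fb)
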
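"""On-policy actor-critic training with auxiliary world-model and entropy terms.

The parameter update implements a policy gradient with baseline,

    dtheta ~ sum_k [ (grad log pi_k(a_k) + beta_v grad V_k) * delta_k
                     - beta_e grad sum_a pi log pi - beta_p grad L_P ]

where delta_k = R_k - V_k is the advantage (treated as a constant in the
actor and critic multipliers), L_P is the cross-entropy of the world-model
predictions against the true next state and goal (applied at physical-action
iterations, where a real transition exists), and the entropy bonus runs over
the full 5-way policy.  Teleport iterations are masked out of all policy
terms.  Gradients are averaged over the episodes of a batch and applied with
Adam.  Backpropagation-through-time runs over the recorded outer iterations
only; rollout-internal updates are part of the environment and carry no
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maze as mz
from .agent import AgentConfig, AgentParams, gru_forward, gru_backward, softmax
from .simulate import BatchSim, EpisodeTrace, collect_episodes, returns, sample_envs


@dataclass
class TrainConfig:
    batches: int = 200_000
    episodes_per_batch: int = 40
    learning_rate: float = 1e-3
    beta_v: float = 0.05
    beta_e: float = 0.05
    beta_p: float = 0.5
    seed: int = 0
    adam_b1: float = 0.9
    adam_b2: float = 0.999
    adam_eps: float = 1e-8
    log_every: int = 10

    def __post_init__(self):
        if min(self.beta_v, self.beta_e, self.beta_p) < 0:
            raise ValueError("loss coefficients must be >= 0")


def losses(trace: EpisodeTrace, params: AgentParams,
           ) -> tuple[float, float, float, float]:
    """Per-episode (J, L_V, L_H, L_P) evaluated on a recorded trace.

    J is the episode return; L_V / L_H / L_P are means over the iterations
    where each term applies (action iterations for L_V and L_H, physical
    transitions for L_P).
    """
    loss, _, parts = trace_loss_and_grads(params, [trace],
                                          TrainConfig(), want_grads=False)
    return (trace.total_reward, parts["L_V"], parts["L_H"], parts["L_P"])


def _pad_traces(traces: list[EpisodeTrace], cfg: AgentConfig):
    B = len(traces)
    K = max(t.n_iterations for t in traces)
    X = cfg.obs_len
    x = np.zeros((K, B, X))
    valid = np.zeros((K, B), dtype=bool)
    action = np.zeros((K, B), dtype=int)
    reward = np.zeros((K, B))
    is_action = np.zeros((K, B), dtype=bool)
    is_phys = np.zeros((K, B), dtype=bool)
    wm_next = np.zeros((K, B), dtype=int)
    goal = np.array([t.goal for t in traces])
    delta = np.zeros((K, B))
    R = np.zeros((K, B))
    for b, tr in enumerate(traces):
        k = tr.n_iterations
        x[:k, b] = tr.x
        valid[:k, b] = True
        action[:k, b] = np.maximum(tr.action, 0)
        reward[:k, b] = tr.reward
        is_action[:k, b] = tr.is_action
        is_phys[:k, b] = tr.is_physical
        wm_next[:k, b] = np.maximum(tr.wm_next, 0)
        Rb = returns(tr)
        R[:k, b] = Rb
        delta[:k, b] = Rb - tr.value  # advantage frozen at collection values
    return dict(x=x, valid=valid, action=action, reward=reward,
                is_action=is_action, is_phys=is_phys, wm_next=wm_next,
                goal=goal, delta=delta, R=R, K=K, B=B)


def trace_loss_and_grads(params: AgentParams, traces: list[EpisodeTrace],
                         tc: TrainConfig, want_grads: bool = True):
    """Teacher-forced surrogate loss and its parameter gradients.

    Re-runs the recurrent forward pass over the recorded inputs and actions,
    with the advantage frozen at its collection-time value, so that the
    gradient of the returned scalar is exactly the training update and can be
    verified by finite differences.
    """
    cfg = params.config
    p = params.tensors
    n = cfg.n_cells
    d = _pad_traces(traces, cfg)
    K, B = d["K"], d["B"]
    H = cfg.hidden_units
    grads = {k: np.zeros_like(v) for k, v in p.items()} if want_grads else None

    h = np.zeros((B, H))
    caches, dh_heads = [], []
    total = 0.0
    sums = {"L_V": 0.0, "L_H": 0.0, "L_P": 0.0}
    counts = {"L_V": 0, "L_H": 0, "L_P": 0}
    rowsB = np.arange(B)
    for k in range(K):
        valid = d["valid"][k]
        h_new, cache = gru_forward(params, h, d["x"][k])
        h = np.where(valid[:, None], h_new, h)
        caches.append(cache)
        dh = np.zeros((B, H))

        m_act = (d["is_action"][k] & valid).astype(float)
        m_phys = (d["is_phys"][k] & valid).astype(float)

        logits = h @ p["Wp"].T + p["bp"]
        pi = softmax(logits)
        logpi = np.log(np.maximum(pi, 1e-30))
        V = h @ p["wv"] + p["bv"]
        a = d["action"][k]
        delta = d["delta"][k]
        neg_ent = (pi * logpi).sum(axis=1)

        # actor + entropy
        onehot = np.zeros((B, mz.N_ACTIONS))
        onehot[rowsB, a] = 1.0
        total += float((m_act * (-logpi[rowsB, a] * delta
                                 + tc.beta_e * neg_ent)).sum())
        sums["L_H"] += float((m_act * neg_ent).sum())
        counts["L_H"] += int(m_act.sum())
        # critic
        verr = V - d["R"][k]
        total += float((m_act * tc.beta_v * 0.5 * verr ** 2).sum())
        sums["L_V"] += float((m_act * 0.5 * verr ** 2).sum())
        counts["L_V"] += int(m_act.sum())

        if want_grads:
            dlogits = m_act[:, None] * (-delta[:, None] * (onehot - pi)
                                        + tc.beta_e * pi
                                        * (logpi - neg_ent[:, None]))
            dV = m_act * tc.beta_v * verr
            grads["Wp"] += dlogits.T @ h
            grads["bp"] += dlogits.sum(axis=0)
            grads["wv"] += dV @ h
            grads["bv"] += dV.sum()
            dh += dlogits @ p["Wp"] + dV[:, None] * p["wv"]

        # world model at physical transitions
        if m_phys.any():
            a_onehot = np.zeros((B, mz.N_ACTIONS))
            a_onehot[rowsB, a] = 1.0
            u = np.concatenate([h, a_onehot], axis=1)
            mmid = np.maximum(u @ p["Wm1"].T + p["bm1"], 0.0)
            wl = mmid @ p["Wm2"].T + p["bm2"]
            sdist = softmax(wl[:, :n])
            gdist = softmax(wl[:, n:])
            s_t = d["wm_next"][k]
            g_t = d["goal"]
            ce = (-np.log(np.maximum(sdist[rowsB, s_t], 1e-30))
                  - np.log(np.maximum(gdist[rowsB, g_t], 1e-30)))
            total += float((m_phys * tc.beta_p * ce).sum())
            sums["L_P"] += float((m_phys * ce).sum())
            counts["L_P"] += int(m_phys.sum())
            if want_grads:
                dwl = np.concatenate([sdist, gdist], axis=1)
                dwl[rowsB, s_t] -= 1.0
                dwl[rowsB, n + g_t] -= 1.0
                dwl *= (tc.beta_p * m_phys)[:, None]
                grads["Wm2"] += dwl.T @ mmid
                grads["bm2"] += dwl.sum(axis=0)
                dmid = (dwl @ p["Wm2"]) * (mmid > 0)
                grads["Wm1"] += dmid.T @ u
                grads["bm1"] += dmid.sum(axis=0)
                dh += dmid @ p["Wm1"][:, :H]
        dh_heads.append(dh)

    # backward through time
    if want_grads:
        dh_carry = np.zeros((B, H))
        for k in range(K - 1, -1, -1):
            valid = d["valid"][k][:, None]
            dh_total = (dh_heads[k] + dh_carry) * valid + dh_carry * 0.0
            dh_prev = gru_backward(params, caches[k], dh_total, grads)
            dh_carry = dh_prev * valid + dh_carry * (1.0 - valid)
        for k in grads:
            grads[k] /= B
    total /= B
    parts = {k: (sums[k] / counts[k] if counts[k] else 0.0) for k in sums}
    return total, grads, parts


@dataclass
class AdamState:
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    step: int = 0


def gradient_step(params: AgentParams, batch: list[EpisodeTrace],
                  tc: TrainConfig, opt: AdamState | None = None
                  ) -> tuple[AgentParams, AdamState, dict]:
    """One Adam update from a batch of completed traces."""
    loss, grads, parts = trace_loss_and_grads(params, batch, tc)
    for g in grads.values():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite gradient (loss={loss}, parts={parts})")
    opt = opt or AdamState()
    if not opt.m:
        opt.m = {k: np.zeros_like(v) for k, v in grads.items()}
        opt.v = {k: np.zeros_like(v) for k, v in grads.items()}
    opt.step += 1
    b1, b2, eps, lr = tc.adam_b1, tc.adam_b2, tc.adam_eps, tc.learning_rate
    new = params.copy()
    for k, g in grads.items():
        opt.m[k] = b1 * opt.m[k] + (1 - b1) * g
        opt.v[k] = b2 * opt.v[k] + (1 - b2) * g * g
        mhat = opt.m[k] / (1 - b1 ** opt.step)
        vhat = opt.v[k] / (1 - b2 ** opt.step)
        new.tensors[k] = new.tensors[k] - lr * mhat / (np.sqrt(vhat) + eps)
    parts = dict(parts, loss=loss)
    return new, opt, parts


def train(agent_config: AgentConfig, train_config: TrainConfig,
          progress: bool = False) -> tuple[AgentParams, pd.DataFrame]:
    """Full training loop; reproducible given `train_config.seed`.

    Returns the final parameters and a per-logged-batch learning curve with
    mean reward and loss components.  On numerical divergence the last good
    parameters are returned with the curve collected so far.
    """
    ss = np.random.SeedSequence(train_config.seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    params = AgentParams.init(agent_config, init_rng)
    opt = AdamState()
    rows = []
    batch_seeds = ss.spawn(train_config.batches)
    for i in range(train_config.batches):
        rng = np.random.default_rng(batch_seeds[i])
        traces = collect_episodes(params, rng,
                                  train_config.episodes_per_batch)
        mean_rew = float(np.mean([t.total_reward for t in traces]))
        try:
            params_new, opt, parts = gradient_step(params, traces,
                                                   train_config, opt)
        except FloatingPointError:
            break
        params = params_new
        if i % train_config.log_every == 0 or i == train_config.batches - 1:
            rows.append(dict(batch=i,
                             episodes=(i + 1) * train_config.episodes_per_batch,
                             mean_reward=mean_rew, **parts))
            if progress:
                print(f"batch {i}: reward {mean_rew:.2f} "
                      f"loss {parts['loss']:.3f}", flush=True)
    return params, pd.DataFrame(rows)


def random_policy_baseline(agent_config: AgentConfig, rng: np.random.Generator,
                           n_episodes: int = 200) -> float:
    """Mean episode reward of a uniform-policy (zero-weight) agent."""
    params = AgentParams.zeros(agent_config)
    traces = collect_episodes(params, rng, n_episodes)
    return float(np.mean([t.total_reward for t in traces]))
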
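# replan

Recurrent meta-reinforcement-learning agents that can *think*, and the
analysis pipelines for comparing their planning behavior with humans and
with rodent hippocampal replay.

## The problem

When navigating a novel maze, people pause and deliberate — and the time
they spend thinking varies lawfully with the situation (longer early in a
route, longer far from the goal).  `replan` implements a computational
account of this behavior: a recurrent network agent (GRU, hidden state
$h_k$) trained across millions of maze episodes whose action space includes,
besides the four moves, a fifth *rollout* action.  Choosing it makes the
agent simulate a trajectory $\hat\tau = (\hat a_1, \hat a_2, \dots)$ from
its own policy through a learned world model (predicted next state
$\hat s_{k+1}$ and predicted goal $\hat g_k$), and feeds the flattened
imagined action sequence plus a success bit back as input.  A physical
action costs 400 ms of the 20-s episode; a rollout only 120 ms.  Planning
is therefore a learned trade-off between time and policy improvement.

The package contains, as separately usable modules:

- `replan.maze` — the task: procedurally generated 4×4 mazes (periodic or
  bounded), episode dynamics with teleportation and wall-clock accounting,
  observation encoding, shortest-path and optimal-exploration baselines;
- `replan.agent` / `replan.training` — the GRU agent with policy, value and
  world-model heads, the rollout planner, and on-policy actor–critic
  training with auxiliary prediction and entropy losses
  ($\beta_p{=}0.5$, $\beta_v{=}0.05$, $\beta_e{=}0.05$), all in numpy with
  hand-written, finite-difference-verified backpropagation;
- `replan.analyses` — forced-rollout performance curves and their
  feedback-zeroed control, rollout ablation and shuffled-timing controls,
  the effect of rollout success on $\pi(\hat a_1)$, task-space estimation,
  trajectory-clamped $\pi(\mathrm{rollout})$ and residual correlations,
  value-function error;
- `replan.thinking` — Bayesian decomposition of response times
  $t_r = t_t + t_d$ with a shifted log-normal delay prior fitted on guided
  trials and a closed-form posterior-mean thinking time
  $\hat t_t = t_r - \delta - \mathbb E[x \mid x < t_r - \delta]$;
- `replan.replay` — hippocampal replay analysis: Poisson Bayesian position
  decoding (75-ms windows, 5-ms steps), forward-replay detection with lapse
  tolerance, wall-avoidance and goal-passage enrichment, follow-probability
  by replay success, consecutive-replay over-representation, permutation
  tests;
- `replan.synth` — generators for every input with known ground truth:
  response-time tables, rodent-style sessions with scripted replays and
  Poisson place-cell spiking, and small trained agent checkpoints.

## Worked example

Estimate the size of the task space the agent is trained on, by sampling
50,000 wall layouts and counting duplicate pairs:

```python
import numpy as np
from replan.analyses import estimate_task_space

res = estimate_task_space(np.random.default_rng(0), n=50_000, reps=10)
print(f"{res['mean']/1e6:.0f} +/- {res['sem']/1e6:.0f} million tasks")
```

```
304 +/- 7 million tasks
```

so 8 million training episodes cover about 2.9% of the space — at test
time the agent is almost always in a maze it has never seen.  Train a
scaled-down agent and inspect its behavior:

```python
from replan.agent import AgentConfig
from replan.training import TrainConfig, train
from replan.analyses import steps_by_trial

params, curve = train(AgentConfig(hidden_units=48),
                      TrainConfig(batches=1500, seed=0))
print({k: round(v, 1) for k, v in
       steps_by_trial(params, 400, np.random.default_rng(1)).items()})
```

```
{1: 17.7, 2: 11.7, 3: 10.5, 4: 7.9}
```

after finding the goal once (trial 1), the agent returns to it faster on
every subsequent trial of the episode — within-episode adaptation carried
entirely by the recurrent state, since the weights are fixed at test time.
(A short run like this demonstrates the mechanics; the planning-specific
effects — rollouts improving the policy — need far longer training, see
`docs/methods.md`.)

Decompose response times into thinking times:

```python
from replan.synth import gen_rt_dataset
from replan.thinking import fit_priors, estimate_thinking_times

table = gen_rt_dataset(np.random.default_rng(2), n_participants=5)
out = estimate_thinking_times(table, fit_priors(table))
print(out[["response_time_ms", "thinking_time_ms"]].head(3).round(0))
```

```
     response_time_ms  thinking_time_ms
150             339.0              37.0
151            1377.0             806.0
152            1071.0             635.0
```

The estimator subtracts, for each response, the expected perception–action
delay conditioned on the delay being shorter than the response; short
responses are attributed almost entirely to the delay, long ones mostly to
thinking.

A command-line interface wraps the same functionality
(`replan train|analyze|thinktime|replay|synth|taskspace|validate`).

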
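# Methods

This note documents the models and procedures implemented in `replan`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Task and maze generation

The arena is a 4×4 lattice, periodic by default (bounded as a variant),
with walls on undirected edges between adjacent cells.  Mazes are sampled
by carving a perfect maze — a randomized depth-first spanning tree over
the cells — and then deleting extra walls uniformly at random from the
remaining set: 3 on the torus, 4 on the bounded grid.  The extra deletion
on the bounded grid compensates for its missing wrap-around passages; the
all-pairs mean shortest-path lengths of the two variants agree to within
5% (checked over thousands of samples), so task difficulty is comparable
across boundary conditions.

Each episode lasts T = 20 s.  A hidden goal cell is drawn uniformly; the
start cell is drawn uniformly among the other cells.  Reaching the goal
pays reward 1: the agent first receives one observation at the goal cell
with the reward flag set (the policy output at this iteration is ignored),
then continues from a uniformly random non-goal cell.  Moving into a wall
leaves the agent in place and costs a full action; this is the standard
gridworld convention — the task never states a collision rule, and staying
in place preserves the time accounting.

Duplicate-sampling over 50,000 wall layouts (the fraction of identical
pairs, divided by 16 goals, repeated 10×) estimates an effective task
space of roughly 2.8–3.0×10⁸ tasks under this generator, so 8×10⁶
training episodes cover about 2.7–2.9% of it.

Cell indexing is row-major with row 0 at top; actions are ordered (up,
down, left, right, rollout); the replay module uses the same conventions
on its 5×5 arena.

## Agent

A GRU with H hidden units (100 by default; 48–60 in the scaled-down runs
here) receives, each iteration: agent location (one-hot, 16), previous
action (one-hot, 5; all-zero at episode start and after a teleport),
previous reward (1), wall layout (32 binary, one per potential torus
edge), elapsed time t/T (clamped at 1 for analyses that run past the
episode end), and the rollout feedback block (33).  Heads: a linear→softmax
5-way policy, a linear value, and a world model — a one-hidden-layer
(33 rectified-linear units) network from (h, one-hot action) to two
16-way softmaxes over the next state and the goal location.

Choosing action 5 triggers a rollout: the imagined goal is the argmax of
the goal head at rollout start; imagined actions are sampled from the
policy renormalized over the four moves (a rollout inside a rollout is
undefined); the imagined next state is the argmax of the next-state head
(sampling would add variance; ties break to the lowest cell index); the
imagined observation reuses the real input encoder with previous reward 0
and the elapsed time frozen at rollout start.  The loop stops at the
planning horizon (8) or when the imagined state equals the imagined goal.
The feedback vector is 8 slots × 4 one-hot action entries plus a success
bit (33 numbers); the caller's hidden state and location are never
modified, and no gradients flow through rollout-internal updates.  A
physical action or teleport step advances the clock 400 ms; a rollout
120 ms (or l·24 ms in the proportional-cost variant).

## Training

On-policy actor–critic with Adam on batches of 40 complete episodes.  The
surrogate loss per iteration (teleport iterations masked out of all policy
terms) is

    −log π(a_k)·δ̄_k + β_v·½(V_k−R_k)² + β_e·Σ_a π_a log π_a + β_p·CE_k

with R_k the undiscounted reward-to-go, δ̄_k = R_k − V_k frozen at its
collection value, β_v = β_e = 0.05, β_p = 0.5, and CE_k the cross-entropy
of the world-model heads against the true next state and goal, applied at
physical-action iterations (the only ones with a real transition).  The
entropy term runs over the full 5-way policy.  Gradients are averaged over
the batch and computed by backpropagation-through-time over the recorded
iterations; the implementation is verified against central finite
differences to ~1e-10 relative error on small instances.  The learning
rate (not a published quantity) defaults to 1e-3 with standard Adam
moments.  Rollout-internal network updates are part of the environment:
the feedback enters the next iteration as a constant input.

Seeding: one master seed spawns independent per-batch streams
(`numpy.random.SeedSequence`), so runs are exactly reproducible and
paired comparisons can reuse environment seeds across arms.

### What scaled-down training does and does not show

Full-scale training is 200,000 batches (8×10⁶ episodes).  Training this
implementation from scratch shows a long silent phase: through ~7×10⁵
episodes the world model becomes essentially perfect (>99% next-state and
goal accuracy) and the within-episode adaptation signature appears
(trial-2 steps < trial-1 steps), while reward stays near the uniform
baseline; reward then rises steadily (≈0.9 at 4×10⁵ episodes, ≈1.3 at
7×10⁵, ≈2.3 at 1.4×10⁶, ≈3.1 at 1.8×10⁶), and the planning-specific
effects switch on in sequence — forced rollouts improving the released
policy and the feedback-zeroed control falling behind by ~1.4×10⁶
episodes, the rollout-ablation and shuffled-timing costs by ~1.7×10⁶.

The test suite therefore ships a pretrained checkpoint (60 hidden units,
trained by `replan.training.train` with the default hyperparameters for
~2×10⁶ episodes; weights rounded to 3 significant digits and sharded into
small JSON files under `tests/fixtures/`, regenerable with
`scripts/train_fixture.py`), and the agent-side acceptance tests assert
the planning effects on it at the stated significance thresholds.  One
effect is asserted and currently fails: the success-dependent policy
shift (successful rollouts raising π(â₁)).  At this training scale the
policy at the start of trial 2 is already nearly deterministic
(π_pre(â₁) ≈ 0.99 versus ≈0.55 for the full-scale model), so there is no
headroom for an upward shift and any feedback slightly perturbs the
near-saturated policy downward; the red test documents this regime
difference rather than being weakened to pass.  The acceptance *script*
trains its agent from scratch at an honest in-budget scale (60 units,
10⁵ episodes, minutes of CPU) and reports whatever that run produces —
at that scale only the trial-structure effect is present.  Nothing about
the analysis machinery depends on the agent's strength; every analysis is
additionally unit-tested on constructed agents with known behavior.

Evaluation-side conventions: analyses sample actions from the policy
rather than taking the argmax (a weakly trained greedy policy can cycle
against a wall; sampled and greedy evaluation are otherwise equivalent for
the probability-level quantities the analyses report).  "Performance" in
the forced-rollout analysis counts physical steps only, and the release
phase caps at 100 iterations.

## Thinking-time decomposition

Response times decompose as t_r = t_t + t_d with a uniform prior for t_t
on [0, 7 s] (the task's response deadline) and a shifted log-normal delay
prior p_d(t_d; μ, σ, δ) fitted per participant on guided actions, where
t_t = 0 by design.  The fit profiles (μ, σ) in closed form (mean and s.d.
of log(t−δ)) over a 1-ms grid of δ ∈ [0, min(t)−1]; stopping the grid
1 ms below the smallest observation keeps every point at positive density.
Separate priors are fitted for the first action of a trial (extra
perceptual load after the teleport) and for all other actions.

The posterior mean is computed in closed form,
t̂ = t_r − δ − E[x | x < t_r−δ], with the truncated log-normal mean
evaluated via log-space normal CDF ratios (`scipy.special.log_ndtr`) for
numerical stability; responses at or below δ map to t̂ = 0.  The uniform
prior's upper bound never binds for t_r ≤ 7 s, so the closed form omits
upper truncation.  Alternative point estimates (posterior mode, constant
delay) are available behind a strategy flag for robustness checks.

Calibration: when thinking times are generated from the uniform prior and
responses respect the 7-s cap, the estimator recovers per-participant mean
thinking times without detectable bias (|bias| within 3 s.e. across 200
simulated participants).  Under a mismatched generative distribution
(e.g., exponential with mean ~0.5 s) the posterior mean carries a
systematic bias of a few tens of ms — inherent to Bayes point estimation
under prior mismatch, and worth remembering when interpreting absolute
(rather than relative) thinking times.

## Replay pipeline

Sessions are spike counts in 5-ms bins plus a position trace on a bounded
5×5 arena (20-cm cells) with 6 walls and a 3×3 grid of candidate reward
wells, organized in alternating home/away trials with a stationary period
at the previously rewarded well before each run.

*Decoder*: per-neuron mean rates per cell are fitted on movement epochs
(speed > 2 cm/s), excluding neurons averaging < 0.1 Hz over the session
and flooring rate maps at 0.01 Hz so silent (neuron, state) pairs keep
finite Poisson log-likelihoods.  Decoding maximizes the Poisson
log-likelihood of a centered 75-ms window of spikes, stepped every 5 ms;
ties break to the lowest state index; windows truncated by the session
edges are not decoded.

*Detection*: within each eligible pre-trial stationary period (trials
longer than 40 s and the session's first home trial are excluded; one
75-ms margin is trimmed at each end so windows straddling the arrival or
departure run cannot contribute), the decoded sequence is run-length
encoded; any run of ≤ 20 ms flanked by two runs of the same state is a
lapse — excised and reported; a run longer than 150 ms is ambient activity
and terminates any candidate sweep (while being allowed to anchor the next
one).  Forward replays are maximal sequences of consecutively
lattice-adjacent states covering at least three distinct cells and
starting at the animal's current cell.  Adjacency is 4-connected without
wrap and deliberately ignores walls — wall crossings are a measured
statistic, not a constraint.

*Statistics*: wall avoidance compares the fraction of replay transitions
crossing a wall against the mean over the nonidentical rotations and
reflections of the session's wall set (the dihedral group minus identity,
minus any transform fixing the walls).  Goal passage compares the fraction
of replays containing the home well against the mean over the wells that
are neither the goal nor the replay's origin.  A replay is *successful*
toward a location if it reaches it without crossing a wall on the way.
Follow probability is P(first physical action = first replayed action) for
successful replays versus replays successful toward control wells
(excluding, by default, replays successful for the true goal; the
non-disjoint variant is a flag).  Consecutive-replay over-representation
residualizes success against the times since arrival and until departure
(capped at ±15 s, preserving the mean) and divides per-index means by the
control-well baseline with its own time correction.  Session-level
significance uses label-swap permutation tests (10,000 permutations,
one-sided in the direction of each hypothesis; exact enumeration available
for ≤ 20 sessions), and the consecutive analysis permutes replay order
within trials.

For the agent-side analogue, every rollout draws a second, independent
sample from the rollout process that the agent never sees; scoring that
shadow sample decouples the choice to keep rolling out from the quality
assessment.

## Synthetic sessions

The generator emulates the statistical structure the pipeline needs and
nothing more: Gaussian place fields (8 per cell ≈ 200 neurons, matching
the order of simultaneously recorded units in the tetrode datasets this
emulates; peak 25 Hz, width 8 cm, baseline 0.5 Hz) with Poisson spiking;
movement at 25 cm/s along wall-respecting paths that detour through the
least-visited cell so rate maps cover the arena; stationary periods of
5–15 s; scripted replays as compressed trajectories (40 ms per state, the
final state held 40 ms longer, a 3× rate gain standing in for the
sharp-wave-ripple population burst) starting at the occupied well, either
goal-biased (shortest path through the home well, extended to ≥ 6 states)
or unbiased random walks.  With these settings the decoder reaches ~95%
held-out movement accuracy, ≥ 90% of scripts are recovered within edit
distance 1, and script-free sessions yield < 0.05 false events per
stationary period.  A 20-ms-per-state compression is *not* resolvable
under the 75-ms window (each window then spans ~4 states and interior
states are skipped), which is why the default sits at 40 ms.

What passing these benchmarks shows: the pipeline recovers known
time-compressed trajectories, and its enrichment statistics respond to
scripted structure and stay flat under nulls.  What it does not show:
robustness to real-data phenomena the generator omits — theta sequences,
remote/reverse replay, rate remapping, clusterless artifacts, or
behavioral idiosyncrasies of real animals.

## Known limitations

- Planning-specific agent effects require order-10⁶ training episodes;
  the success-dependent policy shift additionally requires the softer
  policy regime of full-scale training (see above).
- The thinking-time point estimate is prior-dependent (see calibration).
- The replay detector's dwell/lapse thresholds (150 ms, 20 ms) are tuned
  to the 75-ms/5-ms decoding geometry; very slow or very fast compressed
  sequences would need the thresholds revisited.
- The exploration baseline (`optimal_exploration_steps`) enumerates
  coverage walks exactly and is practical for 4×4 mazes but exponential in
  principle; it raises once its state budget is exceeded.
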
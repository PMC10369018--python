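# Methods

## Model

`steerevolve` simulates self-propelled agents in a closed square arena
`[0, L]^2` (default `L = 600` px). An agent is a point `(x, y)` with a
heading `theta`, moving a fixed distance `s` per time step (reference
`s = 50` px; slow condition `s = 5`). Its only control is the heading
change per step.

**Perception.** The agent senses two cues: the distance `d_w` to the
closest point on any wall and the signed angle `theta_w` between its
heading and the bearing to that point. Sign convention (fixed here, since
it determines what "turning away" means): `theta_w = wrap(heading -
bearing)`, so `theta_w = 0` means facing the wall orthogonally and
`theta_w > 0` means the wall lies to the agent's right; angles are
counterclockwise-positive and wrapped to `(-pi, pi]`. Both cues are
normalized to `[0, 1]` before entering the network: `d_w / (L/2)` (the
largest possible distance-to-nearest-wall inside the square) and
`(theta_w + pi) / (2*pi)`.

**Decision.** A multilayer perceptron with 2 inputs, one hidden layer of
`n_hidden` neurons (reference 3) and 1 output, logistic sigmoid at hidden
*and* output neurons (so the output `o1` lies in `(0, 1)`):

    o1 = sigma( b_out + sum_k v_k * sigma( b_k + w_k1 * d_norm + w_k2 * theta_norm ) )

The parameter count is `4*n_hidden + 1`; the reference 2-3-1 network has
13 weights and biases. The turn per step is `dphi = (o1 - 0.5) *
i_steering`, with the steering increment `i_steering in [0, 2*pi]`
(default `2*pi`, i.e. any turn up to a full U-turn).

**Movement.** The heading is updated first, then the position moves with
the *new* heading: `theta' = wrap(theta + dphi)`, `x' = x + s*cos
theta'`, `y' = y + s*sin theta'`. A step that lands outside the closed
square kills the agent; the killing step does not count toward the
survival score, and a point exactly on the boundary is alive. Death is
checked only at integer time steps (discrete-time model; no mid-step
collision detection).

## Objectives and scoring

A *round* runs one agent until death or `T_max` steps. Two objectives:

* **survive** — score is the number of steps completed while inside;
* **explore** — the arena is discretized into `g x g` equal cells
  (default `20 x 20 = 400` cells of 30 px); the score is the number of
  distinct cells entered at least once. The starting cell is credited at
  `t = 0`, and crediting uses the position at integer steps only — cells
  flown over mid-step (possible at `s = 50` with 30 px cells) are not
  credited. This discrete crediting shapes what trajectories are optimal
  and is deliberate; cell indices are row-major with half-open cells
  (interior edges belong to the higher-index cell).

An *evaluation* is four scored rounds from start positions drawn
uniformly in the arena with fixed initial headings `(0, -pi, -pi/2,
pi/2)` — assigned to rounds in that order, a choice the round protocol
leaves open — plus a fifth monitoring round from the centre with heading
0 whose score is logged for cross-generation comparison but never enters
fitness. Turning can be penalized: each step costs `p_t * dphi^2`
(reference `p_t = 0`; penalty condition 0.33), accrued on every step
including a killing one, and the penalized score is `S_p = S - C_t` over
the four scored rounds.

## Genetic algorithm

Each generation holds `n` agents. The initial population is a Latin
hypercube design over `[-50, 50]` per parameter; the maximin criterion is
approximated by drawing `k` candidate scrambled designs (default 20) and
keeping the one with the largest minimum pairwise distance (exact maximin
optimization is NP-hard and adds nothing at these sizes). Per
generation:

1. evaluate all agents (start positions redrawn per agent per
   generation; a config switch shares them across agents for variance
   reduction);
2. min–max interpolate penalized scores to `[0, 1]` and normalize to sum
   1 (`f_i = u_i / sum u_j`); an all-equal generation gets uniform
   fitness rather than 0/0;
3. sample `n` parents with replacement proportionally to fitness (no
   elitism — the best genome is archived but not protected);
4. mutate every copied parameter independently: with probability 0.33
   add `N(0, 0.5)` noise, with probability 0.01 add `N(0, 5)` noise
   (both may hit the same parameter). Values are not clipped;
   `[-50, 50]` is an initialization range, not a constraint.

All randomness derives from one master seed through named substreams
(`init`, `starts`, `selection`, `mutation`), so changing one stage's
draws does not perturb the others and runs are bit-reproducible.

The per-generation evaluation is vectorized with numpy across all
`5n` (agent, round) walkers; the scalar `run_round` loop is the readable
reference implementation and the two paths are written with identical
elementwise formulas so their scores agree exactly (tested).

## Empirical wall-avoidance rule and structure validation

Single rummy-nose tetra swimming in a tank avoid walls by turning away
from them at short range. A simplified closed form for the turn per step
is

    dphi = sin(theta_w) * exp(-(d_w / l_w)^2)

an odd function of the wall angle times a Gaussian decay in distance,
with interaction range `l_w`. The value of `l_w` behind the published
heatmaps is not reported; the default here is 60 px (one tenth of the
arena side, giving a near-wall interaction zone comparable to the 50 px
"near" regime) and it is configurable. Under the sign convention above
the rule turns the agent *away* from the wall (wall right → positive
`dphi` → left turn).

Networks of 1–6 hidden neurons are fitted to this rule on a regular
`(theta_w, d_w)` grid (36 angles × 30 distances), with targets expressed
in output space via the inverse steering map `o1* = dphi / i_steering +
0.5`, so the fitted object is directly a simulator-ready brain. The
fitting procedure is scipy Levenberg–Marquardt least squares on the MSE
with random restarts (default 8 restarts, 400 function evaluations each,
initial weights `N(0, 5)`), a budget at which the 3-neuron fit has
plateaued; budgets are matched across sizes when comparing structures.
The published claim that three hidden neurons suffice while more add
nothing material is qualitative (no fitting procedure or loss reported),
so the comparison is operationalized as diminishing returns: the RMSE
gain from 3→6 neurons must be smaller than the gain from 1→3. At the
default budget we measure RMSE ≈ 0.21 rad (1 neuron), 0.072 (3), 0.028
(6): one neuron cannot represent the sign change across `theta_w = 0`,
three reproduce the rule broadly, six halve an already small residual.

## Trajectory statistics

All angle averages use the circular mean `atan2(sum sin, sum cos)`;
a vanishing resultant (e.g. an antipodal pair) is flagged NaN, never
silently zero. Analyses consume the trajectory CSVs written by the
simulator; turning statistics use decision rows only.

* **Inferred rule heatmap** — per-(theta_w, d_w)-bin circular mean of
  the turns actually taken (default 36 × 30 bins; the published figures'
  resolution is not reported). Empty bins are NaN.
* **Presence density** — normalized occupancy histogram over the same
  bins.
* **Signed turn** `dphi_plus = dphi * sign(theta_w)` — positive means
  turning away from the wall; `sign(0) = 0`, so head-on steps drop out
  of the away/toward dichotomy. Near/far regimes are `d_w < 50` px and
  `d_w > 150` px.
* **Small-angle normality** — moment fit of a normal to far-regime turns
  below 60° in magnitude, reported with a Kolmogorov–Smirnov distance as
  a descriptive statistic (the underlying claim is visual, so no p-value
  verdict is asserted).
* **Segment length** — U-turns are decision steps with `|dphi| > pi/2`
  (chosen from the trimodal turn distribution: small angles / ~90° /
  U-turns; configurable); the estimate is the median distance between
  consecutive U-turn positions.
* **Wall-following fraction** — fraction of steps within a band
  (default 100 px) of the wall.

## Problem sizes used by the test suite

The published emergent behaviours come from populations of 20 000 evolved
for 150 generations with `T_max = 5000`, repeated in 60 trials. The test
suite and the acceptance script run a desk-scale version of the same
protocol: `n = 500`, 60 generations, `T_max = 1000`, three trial seeds,
everything else at reference values. At this scale:

* the **survive** objective reliably converges to the freezing strategy —
  the best agent of every trial survives the full lifespan by oscillating
  back and forth with per-step U-turns, giving a segment length of
  exactly 50 px (the per-step displacement);
* the **explore** objective reliably evolves near-wall avoidance
  (positive signed turn near the wall in every trial). Wall-following
  and the antisymmetric rule heatmap are population-level statements:
  they hold on trajectories pooled over the best agent of each of the
  last 20 generations across trials — the same across-generations-and-
  trials averaging used for the published rule heatmaps — but not
  necessarily for any single best agent, which typically keeps an
  idiosyncratic left- or right-turning style (individual strategies
  differing from the population average is itself an expected feature of
  this model class);
* the far-from-wall left/right **balance** (population circular mean of
  far-regime turns ≈ 0) does *not* emerge from three desk-scale trials:
  each lineage keeps a chirality, and with so few independent trials the
  chiralities do not cancel (we measure a pooled circular mean of about
  −0.6 rad). Reproducing the balance requires many independent trials;
  the corresponding test is left failing by design rather than weakened,
  and the moment-fit machinery it exercises is verified separately by
  parameter recovery on synthetic normal samples.

## What the synthetic conditions do and do not show

The generator of evolutionary runs *is* the model itself; no external
data is consumed. The closed-form wall rule stands in for the empirical
fish measurements, so agreement with it shows that the pipeline can
express and recover that behaviour class — not that real fish are fitted
well, and not that desk-scale populations reproduce every population-
level statistic of full-scale runs (see the balance caveat above).

## Numerical choices and degenerate inputs

* Heading wrap is `(-pi, pi]`; ties at the centre or corners for the
  closest wall are broken by the fixed order left, right, bottom, top
  (measure-zero events).
* An agent exactly on the boundary is alive (closed square).
* At `d_w = 0` the bearing to the wall is taken along the wall's outward
  normal.
* Sigmoid outputs saturate to exactly 0/1 in double precision for
  pre-activations beyond ~±37; this is expected with weights of order
  50 and is harmless to the dynamics.
* Degenerate statistics (empty bins, vanishing circular resultant,
  zero-variance samples, too few U-turns) are flagged (NaN / explicit
  flags), never silently defaulted.
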
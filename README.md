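# steerevolve

Neuroevolution of steering controllers for self-propelled agents in a
bounded arena.

Animals enclosed in a tank or cage must make movement decisions — where
to turn, when to avoid a wall — while moving at the same time, and the
interaction rules observed in such experiments (e.g. wall avoidance in
small fish) may be *emergent consequences* of simple goals rather than
hard-wired programs. `steerevolve` is a framework for studying this: an
agent moves at constant speed `s` in a closed square arena and its only
control is the heading change per time step,

    dphi = (o1 - 0.5) * i_steering,

where `o1` is the output of a tiny sigmoid multilayer perceptron (2
inputs, one hidden layer, 1 output; the reference 2-3-1 network has 13
parameters) reading the normalized distance `d_w` and signed angle
`theta_w` to the closest wall. A genetic algorithm — Latin hypercube
initialization in `U(-50, 50)`, fitness-proportional selection with
replacement, and two-scale Gaussian mutation (33% of parameters with
sd 0.5, 1% with sd 5) — evolves the weights toward one of two goals:
**survive** (stay inside as long as possible) or **explore** (visit as
many cells of a 20×20 discretization as possible), optionally under a
turning penalty `C_t = sum p_t |dphi|^2` or at reduced speed.

The package also ships the closed-form empirical wall-avoidance rule
measured in rummy-nose tetra,

    dphi = sin(theta_w) * exp(-(d_w / l_w)^2),

supervised fitting of networks to it (validating that three hidden
neurons suffice to express it, a proxy for the task's cognitive
difficulty), and trajectory statistics: inferred rule-of-interaction
heatmaps, presence densities, signed turn distributions `dphi_plus =
dphi * sign(theta_w)` (positive = turning away from the wall), Gaussian
small-angle fits, U-turn segment lengths and wall-following fractions.
It is aimed at movement ecologists and behavioural modellers who want to
test which interaction rules emerge from which objectives and
constraints.

See `docs/methods.md` for the full model description, conventions,
defaults and known limitations.

## Worked example

Evolve survival specialists at desk scale, replay the winner and measure
its trajectory:

    $ steerevolve evolve --seed 1 --out survive --objective survive \
          --n 200 --generations 20 --tmax 500
    best penalized score 2000.0 (generation 19)

    $ steerevolve replay --genome survive/best_genome.json --out replay \
          --objective survive --tmax 500
    score 500, 500 steps, ended by lifespan

    $ steerevolve analyze --trajectories "replay/*.csv" --what segments --out stats
    $ cat stats/segments.csv
    trajectory,segment_length_px,wall_following_fraction
    replay/trajectory.csv,50.0,0.0

A best penalized score of 2000 is the ceiling (4 scored rounds × 500
steps each): the winner never dies. The replay shows how: it "freezes",
oscillating back and forth with a U-turn every step, so the median
distance between consecutive U-turn positions equals the per-step
displacement of 50 px and it never goes near a wall (wall-following
fraction 0). Agents evolved to *explore* instead avoid walls when close
and spend most of their time following them.

Comparing how well different network sizes can express the empirical
fish rule:

    $ steerevolve compare-structures --sizes 1,3 --out structures
     n_hidden     rmse
            1 0.206085
            3 0.071610

One hidden neuron cannot represent the rule's sign change across
`theta_w = 0` (RMSE 0.21 rad); three neurons reproduce it broadly
(RMSE 0.07 rad).

Other subcommands: `steerevolve fit-rule` (fit one network to the rule
and export its response surface) and `steerevolve evolve --config FILE`
with a JSON config accepting the standard parameter-table names
(`goal`, `speed`, `turning_penalty`, `max_turning_angle`, `n_hidden`).
Everything is also available as a library (`steerevolve.run_evolution`,
`steerevolve.run_round`, `steerevolve.analysis`, ...).

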
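# Methods

This note documents the model as implemented, the choices made where
the design was genuinely open, and what the test suite does and does
not establish.

## Model and assumptions

The society consists of `S = n·G` agents in `G` groups of fixed size
`n`. Groups only matter as the arena for collective action, fights and
group selection; there is no between-group hierarchy, no spatial
structure, and generations (Q rounds each) are non-overlapping. Each
agent carries a binary action `x` (cooperate in the collective action
or not), an integer dominance score `r`, a heritable internalization
trait `η ∈ [0, 1]` fixed for the agent's lifetime, the payoff currently
held this round (`pi_round`), and the resources kept over the
generation (`pi_star`).

Round schedule (fixed): **collective action → fights → strategy
revision**. The tests include a regression check that permuting this
order changes trajectories on a fixed seed.

### Collective action

`π_CA = b·P(X) − c·x` with `P(X) = X/X̄`, `X` the group's total effort
and `X̄` the mean effort over all groups in the same round. `P` is a
relative production index: a group at the society average produces
`b` per member. If the entire society defects, `X̄ = 0` and `P` is
defined as 0 for every group (this avoids 0/0 in a transient,
measure-zero state; the first error-driven cooperator ends the state
immediately).

### Fights

Every agent initiates exactly one fight per round against a uniformly
chosen other member of her group, so participation per round averages
two fights (minimum 1, maximum `n`). Fights are resolved sequentially
in initiator order (group-major, agent-index order): the higher-scored
contestant wins with probability `p_win`, ties are a fair coin, the
winner absorbs the loser's current holding (`π_w ← π_w + π_l`,
`π_l ← 0`) and scores move ±1 through the active score rule. Because
resolution is sequential, payoffs captured early in a round are at
stake again later in the same round. After the stage, surviving
holdings are added to `pi_star`. Note that a cooperator in a
below-average group holds a negative `π_CA`; the transfer rule is
applied literally, so a winner can absorb a negative holding.

The win probability is score-rank based only; a pluggable
rank-difference-dependent win function is deliberately out of scope.

### Utility and revision

A revising agent (probability `μ` per round) errs with probability `e`
(uniform action); otherwise she plays
`argmax_x (1−η)·F(r)·π(x) + v·η·x`, with `F(r) = 1/(1+exp(−γr))` and
`π(x) = b·(X₋ᵢ + x)/X̄ − c·x`, where `X₋ᵢ` and `X̄` are the *current
round's realized* efforts of the others and society mean — a one-step
memory consistent with "everyone repeats what they just did". The score
in `F` is the post-fight score of the current round, matching the stage
order. Exact utility ties keep the current action (minimal-change
convention, isolated in `myopic_best_action` so it can be flipped).

### Score regimes

- *unconstrained*: `r ← r ± 1`.
- *exogenous*: `r ← min(n, max(0, r ± 1))`; scores start at the
  interval's lower bound 0.
- *endogenous*: decayed update `r ← round((1−λ)·r ± 1)` applied **at
  every fight outcome** (default). Rounding is half-away-from-zero,
  which is symmetric about 0 like the rest of the model. The
  alternative scope (`endogenous_decay_scope="round"`) applies the
  decay once per round to the start-of-round score plus the net
  win/loss tally. The per-fight default was chosen because it produces
  the collapsed score supports characteristic of strong decay (support
  {−1, +1} at λ = 0.75; the per-round scope leaves a support roughly
  ±7), which is the qualitative signature this regime exists to
  capture. With λ = 0 both scopes reduce bit-exactly to the
  unconstrained regime (tested).

### Fitness and reproduction

`w = 1 + π*/Q − c_opt(1−η) − c_int·η`, with `Q` the rounds per
generation. With `c_opt = c_int` the direct cost is independent of `η`
and selection on the trait acts only through behaviour. Reproduction:

1. `G` parent groups drawn with replacement, probability ∝ the group's
   total effort accumulated over the generation (uniform fallback if
   all efforts are zero);
2. within each parent group, `n` parents drawn with replacement,
   probability ∝ `max(w, 0)` (negative fitness carries zero weight —
   proportional sampling needs nonnegative weights; uniform fallback if
   all weights vanish);
3. offspring inherit `η` plus a `Normal(0, mutation_sigma)` deviate,
   clipped to `[0, 1]`; actions are fresh Bernoulli(½); scores,
   holdings and `pi_star` restart at zero (the "restart of the
   population" reading: a new cohort forms its hierarchy from scratch;
   the score-inheritance alternative was evaluated and produced runaway
   internalization, see Limitations);
4. dispersal: `floor(n/2)` offspring per group enter a global pool,
   are shuffled, and refill the vacated slots, so group sizes are
   exactly preserved and migrants may land back home. Sex is not
   modelled; dispersal moves an anonymous half.

## Parameters

| name | meaning | default | note |
|---|---|---|---|
| `n`, `G` | group size, group count | 8, 500 | `S = n·G` |
| `T`, `Q` | total rounds, rounds/generation | 10000, 40 | `T % Q = 0` |
| `b`, `c` | production multiplier, effort cost | 1, 1 | payoff units |
| `v` | value of norm-following | 1 | utility units |
| `gamma` | foresight steepness | 0.5 | per score unit |
| `e`, `mu` | revision error, revision rate | 0.1, 0.75 | probabilities |
| `c_opt`, `c_int` | fitness costs | 0.1, 0.1 | equal by default |
| `p_win` | higher score wins | 0.9 | ties: 0.5 |
| `lambda_decay` | endogenous decay rate | 0 | used by that regime only |
| `eta_init_max` | initial η upper bound | 0.05 | η ~ U(0, 0.05) |
| `mutation_sigma` | η mutation scale | 0.05 | Gaussian, clipped |

The per-generation mutation kernel is a free choice (only "a random
mutation" is specified by the model family); a clipped Gaussian with
σ = 0.05 keeps the trait responsive on the simulated horizon. Note that
clipping at 0 gives near-zero traits a small upward mutational bias.

## Randomness and reproducibility

One `numpy` PCG64 generator, seeded from `params.seed`, drives
everything in a fixed documented order: initialization draws actions
then traits; each round the fight stage draws an opponent-offset array
and a win-draw array (length S each), then the revision stage draws
revision, error and random-action arrays; reproduction draws parent
groups, per-group parents, mutation deviates, offspring actions, then
dispersal slots and the pool permutation. Replaying the same parameters
reproduces runs bit for bit (tested), and the run manifest stores
everything needed to do so.

## Reported aggregates

- cooperation fraction: mean of the actions *played in the round's
  collective action* (so the first round of a generation reflects the
  fresh Bernoulli draw);
- score histograms: raw integer scores (no binning), aggregated over
  all groups, split by the same played action;
- payoff–score relation: OLS of end-of-generation `pi_star` on the
  score over all agents (scipy `linregress`), with a flagged degenerate
  result when only one score is realized;
- rounds and generations are 0-based internally and 1-based in all
  written tables.

## Scale used in tests and the acceptance script

The characteristic regimes are checked at a reduced scale chosen to
keep the full suite fast on one CPU: 50 groups, 2,000 rounds, Q = 40,
three replicate seeds (the model's qualitative regimes are insensitive
to the group count well below 500; the horizon mainly limits how far
the internalization trait can travel). The acceptance script runs the
same conditions and finishes in under a minute.

## What the synthetic dynamics do and do not show

All inputs are generated by the model itself; there is no empirical
data anywhere. The simulations demonstrate the mechanisms — winner–loser
score feedback, robbery-mediated discipline, two-level selection on an
internalization trait — under the stated stylized assumptions (constant
group size, synchronized rounds, a single global production
normalization). They say nothing about real primate or human societies.

## Known limitations

- Under the literal transfer rule a robbed cooperator loses `π_CA =
  b·P − c`, i.e. part of her effort cost is effectively passed to the
  robber. This weakens within-group selection against cooperation and,
  over long horizons, group selection drives the internalization trait
  upward in *all three* score regimes (toward η ≈ 0.5 at 250
  generations), rather than only in the constrained ones. The
  alternative accounting (cost paid unconditionally from the
  accumulated stash) suppresses internalization everywhere, including
  the clipped regime where it should thrive, and was therefore
  rejected. As a consequence the unconstrained regime at long horizons
  shows more internalization and somewhat more cooperation than the
  hierarchy-frozen ideal.
- For large groups (`n = 24`) the myopic material margin
  `b/X̄ − c` is negative at any cooperation level above `1/n` of the
  society, so within-generation cooperation relaxes from its random
  ½ starting point toward the rank-driven level (~0.4–0.5) instead of
  transiently overshooting it; the revision-error floor (`e/2`) keeps
  `X̄` above the boom threshold `b/c`.
- Endogenous decay with λ = 0.75 confines scores to {−1, +1}; the
  decayed update cannot park an agent exactly at 0 because everyone
  fights at least once per round.
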
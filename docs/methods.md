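# Methods

## The model

A population of asexual agents lives in at most *G* social groups with a
global cap of *K* adults. Each agent carries one binary **play gene** and
passes through two developmental stages: a juvenile stage of *j* steps,
then adulthood until a pre-assigned lifespan runs out.

Each simulation step executes seven phases in a fixed order:

1. **Juvenile play.** Gene-carrying juveniles seek one play bout each
   with another willing (gene-carrying, not-yet-paired) juvenile in their
   group; a juvenile that finds no partner does not play and pays no
   cost. Both participants of a bout add one to their bout count and each
   independently dies with probability *c*.
2. **Maturation.** Juveniles that complete the stage become adults,
   processed in random order across the whole population; once the adult
   count reaches *K* the remainder die (density-dependent juvenile
   mortality, deliberately unbiased with respect to genotype).
   A maturing agent becomes **fair** iff fairness learning is enabled, it
   carries the gene, and it played at least *α* bouts.
3. **Foraging.** Each adult succeeds with probability *p*; a success
   yields *R* plus Gaussian noise with SD 0.1·*R*.
4. **Pooling.** Per group, fair adults pool the current step's gains and
   each receives pool/m; selfish adults keep their own gains. Pooling
   uses only the step's gains, never accumulated stock: that is what
   makes expected intake identical (pR) for both strategies while the
   within-pool variance of a step's intake is zero.
5. **Reproduction.** An adult with resources ≥ *T* whose last
   reproduction is at least *d* steps past produces exactly one
   offspring (surplus resources never yield a second), transfers the
   fraction *P* of its stock to it, and inherits its gene with symmetric
   mutation at rate *r*.
6. **Aging.** Ages increment (newborns included, so an offspring born at
   step *t* matures at step *t + j*); agents at the end of their lifespan
   die, and a dying adult removes its still-juvenile offspring with it
   (dependent young).
7. **Fission.** A group reaching *f* adults, while fewer than *G* groups
   exist, sends *g* uniformly sampled adults (plus their dependent
   juveniles) to a new group. Empty groups simply cease to exist.

Extinction is the loss of all adults; the run halts and is flagged. (A
population with zero adults can hold no juveniles either, since juveniles
die with their parents.)

The **dependent variable** is the gene birth frequency: the fraction of
agents born during the measurement window [burn_in, tau) — by default
steps 10,000–25,000, the post-equilibration window — that carry the gene
at birth. The realized **play mortality** is play deaths divided by the
number of juveniles that ever entered a bout (juveniles that never played
faced no risk; other denominators would mix in agents the cost cannot
touch).

## Parameters and defaults

| symbol | default | meaning |
|--------|---------|---------|
| K      | 1000    | adult population cap |
| G      | 50      | group cap |
| f, g   | 40, 20  | fission trigger size / offspring-group size (adults) |
| j      | 50      | juvenile stage length (steps) |
| α      | 5       | bouts required to learn fairness |
| P      | 0.5     | parental investment (fraction of parent stock) |
| T      | 100     | reproductive threshold (resource units) |
| d      | 15      | reproductive delay (steps) |
| r      | 0.01    | mutation rate per birth |
| l, SD_l | 150, 25 | lifespan mean / SD (steps) |
| R, p   | 40, 0.0875 | foraging reward / success probability (pR = 3.5) |
| c      | 0.003   | per-bout play mortality |
| F0     | 0.05    | initial play-gene frequency |
| τ, burn_in | 25000, 10000 | run length / start of measurement window |

Founders: 50 groups of 20 adults, resources uniform on [50, 150], ages
uniform integers on [50, 150] (≥ j, so all founders are adults). The
foraging noise SD is always derived as 0.1·R, and the expected payoff pR
is always derived from (p, R); neither is ever stored, so the paired
representations cannot drift apart. The default (R, p, d, c) is the
condition where the dynamics are sharpest — high-variance foraging with
the delay at the predicted selection peak and the harshest play cost —
which also makes it the most informative smoke test.

## Closed-form quantities

- `payoff_variance(R, p) = (1-p) p R²` — the idealized per-step intake
  variance among selfish foragers, treating exactly pm of m agents as
  successful. The simulated intake variance converges to it only in
  expectation, and carries a small extra term p·(0.1R)² from the reward
  noise (≈1% at the defaults).
- `prob_reach_threshold(d, p, k)` — binomial tail P(X ≥ k) via the
  regularized-beta survival function; `k` defaults to ⌈P·T/R⌉ (= 2 at the
  reference condition), the number of discrete wins a selfish adult needs
  to replace one investment.
- `predicted_peak_delay(P, T, p, R) = P·T/(pR)` — returns a real number;
  callers round to the nearest integer delay when comparing with sweep
  grids.

## Design choices where the rules were open

- **Founders' fairness.** Founders carrying the gene count as fair when
  learning is enabled, although they had no juvenile stage to learn in.
  With F0 = 0.05 this is a brief transient (founders die out within ~150
  steps); the choice avoids a dead start in which no adult could ever be
  fair before the first learned cohort matures.
- **First reproduction.** Founders and newly matured adults are not
  delay-gated: the delay constrains the interval *between* an agent's own
  reproductive events only.
- **Play pairing.** The invite-in-random-order process is equivalent in
  distribution to a uniform random matching among the group's willing
  juveniles, and is implemented that way (random permutation, pair
  adjacent group members). An agent that found no partner can still be
  found by a later initiator in the same step if it has not yet played;
  no juvenile plays more than one bout per step.
- **Bout accounting.** A bout counts toward α for both participants, and
  the mortality lottery applies independently to each.
- **Resource custody.** Offspring hold their endowment from birth and
  carry it into adulthood; juveniles never forage.
- **Lifespan clamp.** Drawn lifespans are clamped below at 1 step (not at
  j): a founder whose drawn lifespan falls below its initial age dies on
  the first aging pass. This is visible as the ~12% founder die-off in
  the first step of the example run; the population refills within a few
  hundred steps and the transient is long over before the measurement
  window.
- **Extinct runs in averages** are excluded from frequency means but
  counted and reported per cell; additionally, delay-averaged summaries
  at P = 0.1 use d ≤ 45 only, because very low investment plus delays
  beyond 45 routinely drives the population extinct.
- **Seeding.** Per-run seeds are base_seed + config_index·1024 +
  replicate (mod 2³¹), which is provably collision-free within any sweep
  of ≤1024 replicates. Nearby integer seeds are safe because every seed
  passes through numpy's SeedSequence mixing before initializing the
  PCG64 generator; a hashed scheme was rejected because it cannot
  guarantee injectivity over a large sweep.

## Numerical notes

- All randomness in a run flows from one `numpy.random.Generator`;
  identical (params, seed) reproduce results bit-for-bit, and sweep rows
  are independent of enumeration order.
- Foraging draws are clamped at 0 (a negative draw would need a −10σ
  deviate; the clamp is a guard, not a modeling choice).
- Pooling conserves resources exactly up to floating-point division;
  tests assert conservation at 1e-9 relative tolerance.
- The state is stored as numpy columns over living agents (compacted
  every step), which keeps a full 25,000-step, 1000-adult run in the
  tens of seconds on one CPU.

## What the tests do and do not show

The test suite verifies the mechanism on its own terms: invariants
(caps, conservation, one bout per step, determinism), closed-form worked
values, and the headline equilibria at the reference condition with 5
replicates per mortality setting — the evolved frequency stays above 80%
for c ≤ 0.00225 and above 70% at c = 0.003 (~10% realized play
mortality), while the neutral control sits near 50%. The published-scale
factorial (342,720 runs) is enumerable and runnable with `SweepSpec` but
is cluster-scale; the suite checks its design size exactly and spot-checks
reduced grids.

The model is deliberately generic, not a portrait of any species: equal
foraging ability, a single gene with symmetric mutation, fixed group
caps, mortality only from play, lifespan, and the juvenile cap. Passing
tests show the variance-reduction mechanism works under these idealized
conditions; they say nothing about taxa where sharing is ability- or
contribution-based, where group membership is fluid, or where play
benefits flow through other channels (exercise, motor skills). Cheating
and punishment among adults are out of scope.
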
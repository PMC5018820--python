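# Methods

## The model

Two cylindrical robots (7 cm diameter) forage in a 1 m x 1 m toroidal
arena containing two immobile food discs (5.4 cm).  Driving over a food
disc "eats" it — one fitness unit — and the disc immediately respawns at a
uniform random position.  Each mobile robot becomes *stuck* with
probability 5e-4 per 100 ms control step; a stuck robot cannot move or
eat, renders blue instead of green, and regains mobility with hazard 5e-4
per step, or five times that while its partner's edge-to-edge distance is
below 1 cm ("helping").  A release counts as helped — and as a helping
event given by the partner — exactly when the partner is inside that gap
at the step the release fires.

Each robot is driven by a three-layer logistic network: a constant bias
plus 17 sensory inputs (8 proximity sensors at 45-degree spacing that
detect only the other robot within 5 cm of the body, falling off linearly
with the edge-to-edge gap; and a 9-neuron RGB camera covering a 60-degree
forward cone split into three 20-degree sectors, each neuron reporting the
fraction of its sector covered by the nearest object of its color — food
is red, mobile robots green, stuck robots blue), 9 hidden units, and 2
output units scaled linearly onto wheel velocities in [-8.2, 8.2] cm/s.
Kinematics are differential-drive with the axle set to the body diameter,
Euler-integrated per step (translate along the old heading, then turn);
colliding discs are projected back to contact along the center line, with
the correction split between whichever robots are mobile, so bodies never
overlap but can always drive apart.

The optional *memory* input (18th sensor) reports the fraction of the
robot's completed stuck episodes so far that ended by partner help; it is
initialized at its maximum of 1 each evaluation, so a robot starts every
interaction "trusting" its partner.  Its 9 extra input-to-hidden weights
are appended after the base weight block, which keeps 182-weight genotypes
prefix-compatible with 191-weight ones.

Genotypes are bitstrings, 8 bits per connection weight, MSB first, mapped
linearly onto [-5, 5] via v/255 so both bounds are reachable.  The range
is a package choice (documented, configurable): it gives the logistic
units both a near-linear and a saturating regime.  Mutation flips each bit
independently (default 1e-2); there is no crossover.

## Evolution

A population of 100 robots evolves by Wright-Fisher sampling: each robot
is focal in 5 evaluations of 20,000 steps; its fecundity is the food it
gathered in those evaluations (partners' food is credited only in the
partners' own focal evaluations, so nothing is double-counted); the next
generation is sampled with replacement proportional to fecundity and
mutated.  If every fecundity is zero — possible at initialization —
parents are drawn uniformly, keeping the process defined.  Pairing
conditions control relatedness: clone partners (R=1), partners drawn
uniformly from the other N-1 robots (R=0), or a clone with probability 1/2
(R=1/2); a two-phase schedule (half-related then unrelated) supports the
kin-recognition scenario.  A reference genotype can be injected by
replacing each offspring with it at a small probability (1e-2 gives one
copy per generation on average at N=100).

Helping is assayed every 25 generations on the generation's
highest-fecundity individual plus a uniform sample of 10 (the sampling
scheme is a package default; full-population assays are configurable via
`assay_sample`).

## The helping-rate estimator

The assay places the focal 100 times for 1000 steps with a stuck partner
that cannot self-release, starting at least one body diameter apart, and
records which trials ended in a release and when.  Under a constant
per-step release probability h the release time is geometric and
unreleased trials are right-censored, so the recorded summaries
(proportion released, mean time to release) are the model's sufficient
statistics and the MLE is closed-form:

    h_hat = k / (sum(t_i) + (n - k) * T)

with k releases at steps t_i out of n trials of length T.  Profile-
likelihood intervals come from the chi-square cutoff on the same
likelihood.  Two conventions to note.  First, trials end at the release
(the quantities above are unaffected) and the focal cannot itself become
stuck during a trial.  Second, h_hat is a *release* rate and is therefore
bounded by the helped release hazard, help_multiplier x p_self_release =
2.5e-3 per step; the per-step probability of *being in helping position*
is h_hat divided by that hazard.  All comparisons in the package (related
vs. unrelated, visible vs. invisible partner, good vs. bad mood) are
invariant to this positive scaling, so the release-rate convention is used
throughout.  The chance-level assay removes the partner from the focal's
proximity and camera inputs — both channels, since "by chance" must mean
no sensory route to the partner — while leaving it physically present and
releasable.

## Artificial selection

The reciprocator regime clamps each robot's memory input, per evaluation,
to a fair-coin value and scores food + help_bonus x releases-given when
the clamp is 1 and food - help_bonus x releases-given when it is 0; only
conditional helpers score well on both coin outcomes.  help_bonus defaults
to 1 fitness unit per release (the scale of one food item), a package
choice.  The default engine is a steady-state GA (200 robots, 1500
cycles): each cycle scores everyone and replaces the worst decile with
mutated copies of uniformly drawn survivors — a minimal, documented
steady-state scheme.  Selfish is bred by plain foraging selection; Helper
adds the helping bonus unconditionally and must pass an assay threshold of
5x its own chance-level rate (if no individual passes, the best-rate
individual is returned flagged `threshold_met=False`).  The
similarity-penalized regime subtracts similarity_weight x locus-distance
to a reference genotype from the conditional-helping score, selecting for
reciprocators mutationally close to a given Selfish genotype.  Candidates
are ranked by the Moran fixation probability of a single copy among N-1
reference residents, with the 2x2 payoff matrix measured by simulation
(100 interactions per pair by default for tractability; 1000 matches the
full-scale protocol).

## Game dynamics

Payoff matrices hold row-player mean food per evaluation.  The packaged
reference matrix for the bred Selfish/Helper/Reciprocator strategies is

|              | Selfish | Helper | Reciprocator |
|--------------|---------|--------|--------------|
| Selfish      | 152     | 205    | 160          |
| Helper       | 132     | 198    | 175          |
| Reciprocator | 147     | 203    | 173          |

Invasion barriers solve the linear payoff-equality condition under random
pairing; the Reciprocator-vs-Selfish barrier is 5/18 = 0.2777…, which the
reference table prints as 0.27 (truncated at two decimals; the library
returns full precision and the CLI rounds per `--digits`).  The Moran
fixation probability uses self-excluded expected payoffs and the standard
product formula; fitness is 1 - w + w*payoff with w = 1 by default, i.e.
payoffs (positive food counts) act directly as fitness, mirroring
fecundity-proportional selection in the robot loop.  Strategy dynamics use
Wright-Fisher generations, matching the robot loop (the Moran process is
reserved for the fixation screen, where overlapping-generations invasion
of a single copy is the quantity of interest), with each offspring
mutating to one of the
other strategies with probability mu, split equally — the
one-mutation-apart assumption.  Defaults mu = 1e-2 at N = 100 and 1e-3 at
N = 1e4 are package choices.  Initial compositions are likewise package
choices: all-Selfish for the small-population scenario (drift plus
mutation repeatedly carries the population over the barrier and back,
producing the cycling regime) and equal thirds for the large-population
scenario.  The latter matters: at N = 1e4 a barrier at frequency 0.27
cannot be crossed by drift in any feasible time, so a Selfish-monomorphic
start would simply stay Selfish; from a mixed start the dynamics settle on
the Reciprocator/Helper edge mixture at 5/7 : 2/7, which Selfish cannot
invade (its payoff against the mixture, 1210/7, is below the residents'
1271/7) — the stable Reciprocator-majority polymorphism.

## Numerical and reproducibility choices

All stochastic simulation flows through one splitmix64 stream per
evaluation with a fixed draw order (respawn draws, then one stuck/release
uniform per robot per step); per-evaluation seeds are derived from the
experiment seed, the generation and the focal/round indices through
`numpy` SeedSequence, so results are independent of evaluation order and
identical runs are byte-identical.  The inner loops are numba-compiled;
the step-level API and the full-evaluation kernel share the same compiled
subroutines.  Camera coverage is computed exactly by breakpoint sweep over
interval endpoints with nearest-object occlusion (no ray sampling).
Placement draws uniform positions until the robots' edge gap is
non-negative (assays: at least one diameter), with a bounded retry count.
Ties in steady-state ranking are broken by stable sort order.

## What the scaled test runs do and do not show

The test suite exercises every mechanism at reduced scale: short
evaluations, small populations, tens of generations.  At these scales
selection on *foraging* is demonstrably effective, but the evolution of
*helping* in clone-paired populations — the full-scale headline contrast —
is largely beyond reach: with 2000-step evaluations a robot is stuck about
once per evaluation and the benefit of being released early is mostly
censored by the evaluation's end, so the selection differential on helping
is of the order of drift at N = 20, and assayed helping rates in both
pairing conditions remain near chance level.  The corresponding
acceptance-level check (relatedness ordering under a rank test at these
scaled conditions) is therefore expected to fail, and is retained
unchanged as a faithful record of that limit rather than weakened.
Full-scale campaigns (N = 100, 20,000-step evaluations, hundreds to
thousands of generations, and the 200 x 1500 breeding runs) are supported
by the same code paths but are multi-hour computations.

Other known limitations: the synthetic world has no physical-robot
counterpart (no sensor noise, no motor noise, perfect color segmentation);
proximity sensors see only the partner, not food; both robots may be stuck
simultaneously, each waiting on its own release process; stuck onset
leaves the robot in place (the alternative reading — relocation to a
random position on sticking — is not implemented).
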
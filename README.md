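# reciprobots

Embodied evolutionary simulations of helping and reciprocity in foraging
robot pairs, for researchers in social evolution and evolutionary
robotics.

The puzzle the package addresses: game theory predicts that reciprocal
cooperation should invade selfish populations, yet reciprocity is rare in
nature.  One proposed resolution is mechanistic: reciprocity must be
produced by an actual behavioral machine, and a machine that helps
*conditionally on its partner's past helping* takes many coordinated
mutations to build — so no directional selection can assemble it
gradually.  This package provides the full experimental platform to study
that question in simulation:

- **Embodied foraging world** — pairs of disc robots with logistic
  feed-forward controllers (1 bias + 17 sensors + 9 hidden + 2 wheel
  outputs; 182 connection weights, or 191 with a memory input) forage on a
  1 m torus; robots stochastically get stuck (hazard 5·10⁻⁴ per 100 ms
  step) and are released five times faster while their partner stays
  within 1 cm — helping, at a foraging cost.
- **Evolution** — bitstring genotypes (8 bits per weight), per-bit
  mutation 10⁻², Wright–Fisher selection on food gathered, with pairing
  conditions controlling genetic relatedness (clone partners R=1, random
  partners R=0, mixed R=1/2), optional genotype injection, and a memory
  input whose activation is the fraction of past stuck episodes ended by
  partner help.
- **Behavioral assays** — the helping rate h of a genotype is estimated by
  maximum likelihood from 100 trials with a stuck partner under a
  censored-geometric release model, ĥ = k / (Σtᵢ + (n−k)T), with
  profile-likelihood intervals, chance-level (invisible-partner) and
  mood-clamped variants, and pairwise payoff measurement.
- **Artificial selection** — breeding of reference strategies: Selfish,
  unconditional Helper, and Reciprocator (helping rewarded when the memory
  input is clamped to 1 and fined when clamped to 0), plus a
  similarity-penalized regime and a Moran fixation-probability screen.
- **Game dynamics** — on measured payoff matrices: 2×2 game
  classification (T > R > P > S → prisoner's dilemma), invasion barriers
  from the linear payoff-equality condition, frequency-dependent Moran
  fixation probabilities, and finite-population Wright–Fisher strategy
  dynamics over the simplex.

The inner simulation loops are numba-compiled (~1 µs per world step), so
scaled-down evolutionary experiments run in minutes on one core.

## Worked example

`examples/` contains one short script per capability.  Analyzing the
packaged payoff matrix of the three bred reference strategies
(`python examples/04_payoff_game_analysis.py`):

```
payoff matrix (row player):
       Selfish: [152. 205. 160.]
        Helper: [132. 198. 175.]
  Reciprocator: [147. 203. 173.]

Selfish vs Helper game: prisoners_dilemma
invasion barrier of Helper against Selfish: never favored
invasion barrier of Reciprocator against Selfish: 0.2778

Moran fixation probability of 1 Reciprocator among 99 Selfish: 0.01004 (neutral: 0.01000)
near-neutral overall: the mild payoff deficit below the barrier is offset by a strong advantage once reciprocators are common
```

Selfish/Helper is a prisoner's dilemma (205 > 198 > 152 > 132): helping is
mutually preferable but defection dominates.  Unconditional helpers are
never favored against selfish residents at any frequency, whereas
reciprocators become favored once their frequency exceeds 5/18 ≈ 0.28 —
the invasion barrier that makes reciprocity unable to bootstrap itself
from rarity.  Simulating the three strategies as one mutation apart
(`python examples/05_strategy_dynamics.py`):

```
small population (N=100, mu=1e-2, 20,000 generations, all-Selfish start):
  time with a Selfish majority:      0.20
  time with a Reciprocator majority: 0.58
large population (N=10,000, mu=1e-3, equal start) mean frequencies:
       Selfish: 0.011
        Helper: 0.284
  Reciprocator: 0.705
the large population sits at the uninvadable Reciprocator/Helper mixture; the small one keeps escaping it by drift
```

A small population cycles between selfish and reciprocator majorities;
a large one settles into a stable Reciprocator-majority polymorphism.
That contrast is the game-theoretic baseline: *if* reciprocity is one
mutation away, it thrives — the embodied simulations (examples 03 and 06)
let you study why it does not arise when it must instead be built by a
neural controller.

There is also a thin CLI exposing the same operations, e.g.

```sh
reciprobots dynamics --invader Reciprocator --resident Selfish --threshold
# 0.28
reciprobots evolve --condition related --generations 100 --pop-size 20 \
    --eval-steps 2000 --seed 1 --out runs/related1
```

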
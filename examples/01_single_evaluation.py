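"""Run a single foraging evaluation of a robot pair and inspect the events.

Two robots with a random genotype share a 1 m x 1 m toroidal arena with
two food items for 20,000 control steps.  The printed food counts are the
fitness units each robot earned; stuck episodes show when each robot was
immobilized, when it was released, and whether the release was caused by
its partner staying within the 1 cm helping gap.
"""

import numpy as np

from reciprobots.arena import ArenaConfig, run_evaluation
from reciprobots.controller import NetworkTopology
from reciprobots.genome import DecodingSpec, random_genome

rng = np.random.default_rng(9)
genome = random_genome(DecodingSpec(), rng)
result = run_evaluation(
    (genome, genome), NetworkTopology(), ArenaConfig(), seed=9
)

print(f"food eaten: robot0={result.food_counts[0]}, robot1={result.food_counts[1]}")
print(f"releases caused by partner: {result.helping_given}")
for r in range(2):
    print(f"robot {r} stuck episodes (start, end, helped):")
    for ep in result.stuck_episodes[r]:
        print(f"   {ep}")
    if result.censored[r] is not None:
        print(f"   (still stuck since step {result.censored[r]})")
print(f"memory activations at the end: "
      f"{[round(m.helps / m.opportunities, 3) if m.opportunities else 1.0 for m in result.memory]}")
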
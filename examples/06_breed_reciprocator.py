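"""Breed conditional helpers by artificial selection (scaled down).

Each robot's memory input is clamped to a fair-coin value for each
evaluation; helping pays when the clamp is 1 and costs when it is 0, so
only robots that help *conditionally* on the memory signal score well.
The mood assay then measures the bred genotype's helping rate with the
memory input clamped high ("good mood") and low ("bad mood"); a true
reciprocator helps far more in a good mood.  At this miniature scale
(16 robots, 30 cycles, 1500-step evaluations) selection usually only
begins to bend behavior, so the printed contrast is typically modest.
"""

from reciprobots.arena import ArenaConfig
from reciprobots.artificial_selection import BreedingConfig, breed_reciprocator
from reciprobots.assays import AssayConfig, mood_assay

arena = ArenaConfig(eval_steps=1500)
config = BreedingConfig(
    regime="reciprocator", population_size=16, generations=30,
    evaluations_per_robot=3, arena=arena,
    assay=AssayConfig(n_trials=50, arena=arena), seed=2,
)
candidates = breed_reciprocator(config)
best = candidates[0]

assay_cfg = AssayConfig(n_trials=50, arena=arena)
good = mood_assay(best, config.topology, 1, assay_cfg, seed=11)
bad = mood_assay(best, config.topology, 0, assay_cfg, seed=11)
print(f"best candidate, memory clamped to 1: rate {good.helping_rate:.2e} "
      f"({good.released}/{good.n_trials} released)")
print(f"best candidate, memory clamped to 0: rate {bad.helping_rate:.2e} "
      f"({bad.released}/{bad.n_trials} released)")
print("a full-scale breeding campaign (200 robots, 1500 cycles, 20,000-step "
      "evaluations) produces strongly conditional helpers")
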
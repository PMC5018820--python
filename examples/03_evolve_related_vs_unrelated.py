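"""Contrast evolution with clone partners (R=1) and random partners (R=0).

A scaled-down pair of runs: 10 robots, 40 generations, 1000-step
evaluations.  Each generation every robot forages in 5 paired evaluations;
fecundity is its own food total, and the next generation is Wright-Fisher
sampled.  Helping is costly to the helper, so it is expected to be favored
only when partners are genetically related -- although at this tiny scale
(and over so few generations) helping rates mostly reflect chance-level
contact with the partner; the full-scale contrast needs hundreds of
generations of 20,000-step evaluations.
"""

from reciprobots.arena import ArenaConfig
from reciprobots.assays import AssayConfig
from reciprobots.evolution import EvolutionConfig, run_experiment

arena = ArenaConfig(eval_steps=1000)
for condition in ("related", "unrelated"):
    cfg = EvolutionConfig(
        population_size=10, generations=40, pairing=condition,
        arena=arena, assay=AssayConfig(n_trials=30, arena=arena),
        assay_every=20, seed=4,
    )
    res = run_experiment(cfg)
    final = res.stats[-1]
    print(f"{condition:>9}: mean fecundity {final.mean_fecundity:5.1f}, "
          f"assayed helping rate {final.mean_helping_rate:.2e}")
print("(fecundity counts food items per 5 evaluations; the helping rate "
      "is the per-step release probability from the standardized assay)")
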
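import numpy as np
import pytest

from reciprobots.arena import ArenaConfig
from reciprobots.assays import AssayConfig
from reciprobots.evolution import (
    EvolutionConfig,
    Population,
    next_generation,
    pair_population,
    run_experiment,
)
from reciprobots.genome import DecodingSpec, Genome


TINY = DecodingSpec(n_weights=2)  # fast genomes for statistical tests


def tiny_population(n, seed=0):
    return Population.random(n, TINY, np.random.default_rng(seed))


def tiny_config(**kw):
    defaults = dict(population_size=10, generations=2,
                    arena=ArenaConfig(eval_steps=200),
                    assay=AssayConfig(n_trials=2, trial_steps=100,
                                      arena=ArenaConfig(eval_steps=200)),
                    assay_every=1000)
    defaults.update(kw)
    return EvolutionConfig(**defaults)


class TestPairing:
    def test_related_pairs_are_clones(self, rng):
        pop = tiny_population(20)
        for i, j in pair_population(pop, "related", 0, rng):
            assert i == j

    def test_unrelated_never_pairs_self_and_is_uniform(self):
        pop = tiny_population(10)
        rng = np.random.default_rng(1)
        counts = np.zeros((10, 10))
        for _ in range(1000):  # 10^4 focal draws
            for i, j in pair_population(pop, "unrelated", 0, rng):
                assert i != j
                counts[i, j] += 1
        # each of the 9 partners of a focal is drawn ~1000/9 times
        off_diag = counts[~np.eye(10, dtype=bool)]
        expected = 1000 / 9
        assert abs(off_diag.mean() - expected) < 1e-9  # row sums are exact
        se = np.sqrt(expected * (1 - 1 / 9))
        assert (np.abs(off_diag - expected) < 5 * se).all()

    def test_half_related_clone_fraction(self):
        pop = tiny_population(50)
        rng = np.random.default_rng(2)
        clones = total = 0
        for _ in range(200):  # 10^4 draws
            for i, j in pair_population(pop, "half_related", 0, rng):
                clones += i == j
                total += 1
        p = clones / total
        se = np.sqrt(0.25 / total)
        assert abs(p - 0.5) < 3 * se


class TestReproduction:
    def test_equal_fecundities_give_unit_expected_offspring(self):
        pop = tiny_population(50)
        cfg = tiny_config(population_size=50, per_bit_mutation=0.0)
        rng = np.random.default_rng(3)
        counts = np.zeros(50)
        reps = 2000
        for _ in range(reps):
            _, parents, _ = next_generation(pop, np.ones(50), cfg, rng,
                                            return_details=True)
            counts += np.bincount(parents, minlength=50)
        mean = counts / reps
        se = np.sqrt(1.0 * (1 - 1 / 50) / reps)
        assert (np.abs(mean - 1.0) < 4 * se).all()

    def test_sole_positive_fecundity_parent_takes_all(self):
        pop = tiny_population(8)
        cfg = tiny_config(population_size=8, per_bit_mutation=0.0)
        fec = np.zeros(8)
        fec[3] = 7.0
        child = next_generation(pop, fec, cfg, np.random.default_rng(4))
        assert (child.bits == pop.bits[3]).all()

    def test_offspring_are_parents_modulo_mutation(self):
        pop = tiny_population(12)
        cfg = tiny_config(population_size=12, per_bit_mutation=0.0)
        child = next_generation(pop, np.arange(12, dtype=float),
                                cfg, np.random.default_rng(5))
        parent_rows = {row.tobytes() for row in pop.bits}
        assert all(row.tobytes() in parent_rows for row in child.bits)

    def test_negative_fecundity_rejected(self):
        pop = tiny_population(4)
        cfg = tiny_config(population_size=4)
        with pytest.raises(ValueError):
            next_generation(pop, np.array([1.0, -1, 1, 1]), cfg,
                            np.random.default_rng(0))

    def test_injection_mean_one_per_generation(self):
        pop = tiny_population(100)
        inject = Genome(np.ones(TINY.n_bits, dtype=np.uint8), TINY)
        cfg = tiny_config(population_size=100, injection_genome=inject,
                          injection_prob=1e-2, per_bit_mutation=0.0)
        rng = np.random.default_rng(6)
        total = 0
        reps = 10_000
        for _ in range(reps):
            _, _, injected = next_generation(pop, np.ones(100), cfg, rng,
                                             return_details=True)
            total += injected.sum()
        se = np.sqrt(100 * 1e-2 * (1 - 1e-2) / reps)
        assert abs(total / reps - 1.0) < 3 * se

    def test_wright_fisher_neutrality(self):
        # constant fecundity: allele frequencies random-walk with zero drift
        cfg = tiny_config(population_size=40, per_bit_mutation=0.0)
        deltas = []
        for rep in range(300):
            pop = tiny_population(40, seed=rep)
            f0 = pop.bits.mean(axis=0)
            child = next_generation(pop, np.full(40, 2.0), cfg,
                                    np.random.default_rng(1000 + rep))
            deltas.append(child.bits.mean(axis=0) - f0)
        deltas = np.concatenate(deltas)
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean()) < 3 * se + 1e-12


class TestRunExperiment:
    def test_zero_generations_returns_initial_population(self):
        cfg = tiny_config(generations=0, seed=9)
        res = run_experiment(cfg)
        rng = np.random.default_rng(np.random.SeedSequence([9, 0xEB01]))
        expected = Population.random(10, cfg.decoding_spec, rng)
        assert np.array_equal(res.population.bits, expected.bits)
        assert res.stats == []

    def test_population_size_constant_and_reproducible(self):
        cfg = tiny_config(generations=3, seed=11, assay_every=2)
        a = run_experiment(cfg)
        b = run_experiment(cfg)
        assert len(a.population) == cfg.population_size
        assert np.array_equal(a.population.bits, b.population.bits)
        assert [s.mean_fecundity for s in a.stats] == [s.mean_fecundity for s in b.stats]
        assert a.stats[-1].mean_helping_rate is not None  # final generation assayed

    def test_pairing_switch_schedule(self):
        cfg = tiny_config(pairing="half_related", pairing_switch=(2, "unrelated"))
        assert cfg.pairing_at(0) == "half_related"
        assert cfg.pairing_at(1) == "half_related"
        assert cfg.pairing_at(2) == "unrelated"

    def test_forager_outscores_motionless_genome(self, motionless_genome):
        # two-genotype population: a screened forager vs. a motionless robot
        spec = motionless_genome.spec
        forager = Genome(
            np.random.default_rng(8).integers(0, 2, spec.n_bits, dtype=np.uint8),
            spec,
        )
        pop = Population.from_genomes([forager, motionless_genome] * 2)
        cfg = EvolutionConfig(population_size=4, generations=1, pairing="related",
                              arena=ArenaConfig(eval_steps=5000), seed=21)
        from reciprobots.evolution import evaluate_population
        fec = evaluate_population(pop, cfg)
        # the motionless genotype can only score from food spawning beneath it
        assert fec[0] + fec[2] > 10 * (fec[1] + fec[3])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EvolutionConfig(population_size=1)
        with pytest.raises(ValueError):
            EvolutionConfig(pairing="cousins")
        with pytest.raises(ValueError):
            EvolutionConfig(per_bit_mutation=1.5)
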
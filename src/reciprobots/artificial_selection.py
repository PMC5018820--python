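"""Breeding reference strategies by modified fitness regimes.

Reciprocators are bred by paying robots for helping when their memory
input is clamped to 1 and fining them for helping when it is clamped to 0:
at the start of each evaluation every robot draws a fair-coin clamp value
that is fed to its memory input for the whole evaluation, and its score is

    food  +  help_bonus * releases_given     (clamp = 1)
    food  -  help_bonus * releases_given     (clamp = 0)

so only *conditional* helpers score well on both coin outcomes.  The
default regime runs a steady-state genetic algorithm (each cycle all
individuals are scored and the worst decile is replaced by mutated copies
of uniformly drawn survivors) with 200 individuals for 1500 generations.

Unconditional reference strategies: ``selfish`` is plain foraging
evolution with unrelated partners (efficient foragers that rarely help);
``helper`` adds an unconditional helping bonus to fecundity.  The
``reciprocator_near_selfish`` regime additionally penalizes the locus
distance to a reference genotype, selecting for conditional helpers as
mutationally close to a given Selfish genotype as possible.

Candidates from a breeding run are ranked by :func:`fixation_screen`: the
2x2 payoff matrix of candidate vs. reference is measured by simulation and
the fixation probability of a single candidate copy among N-1 residents is
computed under the frequency-dependent Moran process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .arena import ArenaConfig
from .assays import AssayConfig, chance_level_assay, helping_assay, measure_payoff
from .controller import NetworkTopology, TopologyError
from .evolution import Population
from .game_dynamics import PayoffMatrix, moran_fixation_probability
from .genome import DecodingSpec, Genome, mutate, weight_distance

__all__ = [
    "BreedingConfig",
    "BredGenotype",
    "FixationScreenResult",
    "breed_reciprocator",
    "breed_unconditional",
    "breed_near_reference",
    "fixation_screen",
]

REGIMES = ("reciprocator", "selfish", "helper", "reciprocator_near_selfish")


@dataclass(frozen=True)
class BreedingConfig:
    """Parameters of an artificial-selection run."""

    regime: str = "reciprocator"
    population_size: int = 200
    generations: int = 1500
    evaluations_per_robot: int = 5
    help_bonus: float = 1.0
    similarity_weight: float = 0.0
    reference_genome: Genome | None = None
    ga: str = "steady_state"
    replacement_fraction: float = 0.1
    per_bit_mutation: float = 1e-2
    has_memory: bool = True
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    assay: AssayConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.ga not in ("steady_state", "wright_fisher"):
            raise ValueError("ga must be steady_state or wright_fisher")
        if self.population_size < 2 or self.generations < 0:
            raise ValueError("population_size >= 2 and generations >= 0 required")
        if not 0.0 < self.replacement_fraction <= 1.0:
            raise ValueError("replacement_fraction must be in (0, 1]")
        if self.regime in ("reciprocator", "reciprocator_near_selfish") and not self.has_memory:
            raise TopologyError("conditional-helping regimes need the memory input")

    @property
    def topology(self) -> NetworkTopology:
        return NetworkTopology(has_memory=self.has_memory)

    @property
    def decoding_spec(self) -> DecodingSpec:
        return DecodingSpec(n_weights=self.topology.n_weights)


@dataclass
class BredGenotype:
    """Outcome of an unconditional breeding run."""

    genome: Genome
    score: float
    assay_rate: float | None = None
    chance_rate: float | None = None
    threshold_met: bool | None = None


@dataclass(frozen=True)
class FixationScreenResult:
    candidate_index: int
    fixation_probability: float
    payoffs: PayoffMatrix


_SEE_BOTH = np.array([1, 1], dtype=np.uint8)
_CAN_SELF = np.array([1, 1], dtype=np.uint8)
_NOT_STUCK = np.array([0, 0], dtype=np.uint8)
_DUMMY_TRAJ = np.zeros((1, 12))


def _score_population(
    population: Population, config: BreedingConfig, generation: int
) -> np.ndarray:
    """Regime-dependent scores of all individuals (may be negative)."""
    from .evolution import _decoded_networks  # shared network cache helper

    nets = _decoded_networks(population, config.topology)
    params = config.arena.params_array()
    pstuck = np.full(2, config.arena.p_stuck)
    n = len(population)
    conditional = config.regime in ("reciprocator", "reciprocator_near_selfish")
    clamp_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, generation, 0xC01])
    )
    pair_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, generation, 0xA11])
    )
    scores = np.zeros(n)
    for e in range(config.evaluations_per_robot):
        partners = pair_rng.integers(0, n - 1, size=n)
        partners[partners >= np.arange(n)] += 1
        clamps = clamp_rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        for i in range(n):
            j = int(partners[i])
            if conditional:
                clamp = clamps[i]
            else:
                clamp = np.array([-1, -1], dtype=np.int8)
            seed = np.random.SeedSequence(
                [config.seed, generation, i, e]
            ).generate_state(1, np.uint64)[0]
            out = K.run_eval(
                nets[i][0], nets[i][1], nets[j][0], nets[j][1],
                1 if config.has_memory else 0,
                clamp, _SEE_BOTH, params, pstuck, _CAN_SELF,
                config.arena.eval_steps, config.arena.n_food,
                _NOT_STUCK, 0.0, -1, seed, False, _DUMMY_TRAJ,
            )
            food, helps_given = int(out[2][0]), int(out[3][0])
            if config.regime == "selfish":
                scores[i] += food
            elif config.regime == "helper":
                scores[i] += food + config.help_bonus * helps_given
            else:  # conditional regimes
                sign = 1.0 if clamp[0] == 1 else -1.0
                scores[i] += food + sign * config.help_bonus * helps_given
    if config.regime == "reciprocator_near_selfish":
        if config.reference_genome is None:
            raise ValueError("reciprocator_near_selfish needs a reference_genome")
        for i in range(n):
            scores[i] -= config.similarity_weight * weight_distance(
                population.genome(i), config.reference_genome
            )
    return scores


def _evolve(
    config: BreedingConfig, history: list | None = None
) -> tuple[Population, np.ndarray]:
    """Run the configured GA; returns the final population and its scores.

    If ``history`` is a list it is filled with (generation, best score)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB4EED]))
    population = Population.random(config.population_size, config.decoding_spec, rng)
    for g in range(config.generations):
        scores = _score_population(population, config, g)
        if history is not None:
            history.append((g, float(scores.max())))
        if config.ga == "steady_state":
            population = _steady_state_step(population, scores, config, rng)
        else:
            population = _wright_fisher_step(population, scores, config, rng)
    # score the returned population so diagnostics match what is returned
    scores = _score_population(population, config, config.generations)
    if history is not None:
        history.append((config.generations, float(scores.max())))
    return population, scores


def _steady_state_step(
    population: Population,
    scores: np.ndarray,
    config: BreedingConfig,
    rng: np.random.Generator,
) -> Population:
    """Replace the worst decile by mutated copies of uniform survivors."""
    n = len(population)
    k = max(1, int(np.ceil(config.replacement_fraction * n)))
    order = np.argsort(scores, kind="stable")
    worst = order[:k]
    survivors = order[k:]
    bits = population.bits.copy()
    for idx in worst:
        parent = int(rng.choice(survivors))
        child = mutate(population.genome(parent), config.per_bit_mutation, rng)
        bits[idx] = child.bits
    return Population(bits, population.spec)


def _wright_fisher_step(
    population: Population,
    scores: np.ndarray,
    config: BreedingConfig,
    rng: np.random.Generator,
) -> Population:
    weights = np.clip(scores, 0.0, None)
    n = len(population)
    probs = np.full(n, 1.0 / n) if weights.sum() == 0 else weights / weights.sum()
    parents = rng.choice(n, size=n, p=probs)
    bits = population.bits[parents]
    flips = (rng.random(bits.shape) < config.per_bit_mutation).astype(np.uint8)
    return Population(bits ^ flips, population.spec)


def breed_reciprocator(
    config: BreedingConfig | None = None, history: list | None = None
) -> list[Genome]:
    """Breed conditional helpers; returns the final population's genomes,
    sorted by descending score."""
    config = config or BreedingConfig(regime="reciprocator")
    if config.regime != "reciprocator":
        raise ValueError("config.regime must be 'reciprocator'")
    population, scores = _evolve(config, history)
    order = np.argsort(-scores, kind="stable")
    return [population.genome(int(i)) for i in order]


def breed_unconditional(
    regime: str,
    config: BreedingConfig | None = None,
    history: list | None = None,
) -> BredGenotype:
    """Breed a Selfish or Helper reference genotype.

    ``selfish``: plain foraging evolution; returns the top scorer.
    ``helper``: unconditional helping bonus; returns the best scorer whose
    assayed helping rate reaches 5x its chance-level rate
    (``threshold_met``); if none qualifies, the individual with the highest
    assayed rate is returned with ``threshold_met=False``.
    """
    if regime not in ("selfish", "helper"):
        raise ValueError("regime must be 'selfish' or 'helper'")
    config = config or BreedingConfig(regime=regime, ga="wright_fisher")
    if config.regime != regime:
        raise ValueError(f"config.regime must be {regime!r}")
    population, scores = _evolve(config, history)
    order = np.argsort(-scores, kind="stable")
    if regime == "selfish":
        best = int(order[0])
        return BredGenotype(genome=population.genome(best), score=float(scores[best]))
    acfg = config.assay or AssayConfig(arena=config.arena)
    topo = config.topology
    fallback: BredGenotype | None = None
    for rank, idx in enumerate(order):
        g = population.genome(int(idx))
        seed = int(np.random.SeedSequence([config.seed, int(idx), 0xFA]).generate_state(1)[0])
        rate = helping_assay(g, topo, acfg, seed).helping_rate
        chance = chance_level_assay(g, topo, acfg, seed + 1).helping_rate
        cand = BredGenotype(
            genome=g,
            score=float(scores[int(idx)]),
            assay_rate=rate,
            chance_rate=chance,
            threshold_met=rate >= 5.0 * chance and rate > 0.0,
        )
        if cand.threshold_met:
            return cand
        if fallback is None or (cand.assay_rate or 0.0) > (fallback.assay_rate or 0.0):
            fallback = cand
        if rank >= 9:  # screen the top ten scorers only
            break
    assert fallback is not None
    return fallback


def breed_near_reference(
    config: BreedingConfig, history: list | None = None
) -> list[tuple[Genome, int]]:
    """Breed conditional helpers penalized by distance to a reference
    genotype; returns (genome, locus distance) sorted by descending score."""
    if config.regime != "reciprocator_near_selfish":
        raise ValueError("config.regime must be 'reciprocator_near_selfish'")
    if config.reference_genome is None:
        raise ValueError("reference_genome is required")
    population, scores = _evolve(config, history)
    order = np.argsort(-scores, kind="stable")
    out = []
    for i in order:
        g = population.genome(int(i))
        out.append((g, weight_distance(g, config.reference_genome)))
    return out


def fixation_screen(
    candidates: list[Genome],
    reference: Genome,
    n: int = 100,
    *,
    n_interactions: int = 100,
    topology: NetworkTopology | None = None,
    config: ArenaConfig | None = None,
    intensity: float = 1.0,
    seed: int = 0,
) -> list[FixationScreenResult]:
    """Rank candidates by Moran fixation probability against a reference.

    For each candidate the 2x2 payoff matrix {candidate, reference} is
    measured by simulated interactions, and the fixation probability of a
    single candidate copy among ``n - 1`` reference residents is computed.
    Results are sorted by descending fixation probability.
    """
    if not candidates:
        raise ValueError("no candidates to screen")
    config = config or ArenaConfig()
    topology = topology or NetworkTopology(has_memory=reference.spec.n_weights == 191)
    ref_ref = measure_payoff(
        reference, reference, n_interactions,
        topology=topology, config=config, seed=seed,
    )
    results = []
    for idx, cand in enumerate(candidates):
        pcc = measure_payoff(cand, cand, n_interactions, topology=topology,
                             config=config, seed=seed + 7919 * (idx + 1))
        pcr = measure_payoff(cand, reference, n_interactions, topology=topology,
                             config=config, seed=seed + 7919 * (idx + 1) + 1)
        prc = measure_payoff(reference, cand, n_interactions, topology=topology,
                             config=config, seed=seed + 7919 * (idx + 1) + 2)
        matrix = PayoffMatrix(
            strategy_names=("candidate", "reference"),
            payoffs=np.array([[pcc.mean, pcr.mean], [prc.mean, ref_ref.mean]]),
            standard_errors=np.array([[pcc.se, pcr.se], [prc.se, ref_ref.se]]),
        )
        rho = moran_fixation_probability(matrix, "candidate", "reference", n, intensity)
        results.append(
            FixationScreenResult(
                candidate_index=idx, fixation_probability=rho, payoffs=matrix
            )
        )
    return sorted(results, key=lambda r: -r.fixation_probability)
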
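"""Generational Wright-Fisher evolution of robot populations.

Each generation, every robot is focal in ``evaluations_per_robot`` (5)
paired foraging evaluations; its fecundity is the number of food items it
gathered across its own focal evaluations (the partner's food is credited
only in the partner's own focal evaluations).  The next generation is
sampled with replacement in proportion to fecundity (uniformly if every
fecundity is zero, which keeps the process defined at initialization), and
every offspring bit mutates independently at the per-bit rate.

Pairing conditions control genetic relatedness: ``related`` pairs every
focal with a clone of itself (R = 1), ``unrelated`` with a partner drawn
uniformly from the other N-1 genomes (R = 0), and ``half_related`` with a
clone with probability 1/2.  A reference genotype can be injected: after
reproduction each offspring is independently replaced by the injection
genotype with a small probability (1e-2 gives one injected individual per
generation on average at N = 100).

Helping rates are assayed periodically (every 25 generations by default)
on the generation's highest-fecundity individual plus a random sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels as K
from .arena import ArenaConfig
from .assays import AssayConfig, helping_assay
from .controller import NetworkTopology, build_network
from .genome import DecodingSpec, Genome, decode_genome

__all__ = [
    "EvolutionConfig",
    "GenerationStats",
    "Population",
    "ExperimentResult",
    "pair_population",
    "evaluate_population",
    "next_generation",
    "run_experiment",
    "save_run_log",
]

PAIRINGS = ("unrelated", "related", "half_related")


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of one evolutionary run."""

    population_size: int = 100
    evaluations_per_robot: int = 5
    pairing: str = "unrelated"
    has_memory: bool = False
    generations: int = 500
    per_bit_mutation: float = 1e-2
    injection_genome: Genome | None = None
    injection_prob: float = 0.0
    assay_every: int = 25
    assay_sample: int = 10
    pairing_switch: tuple[int, str] | None = None
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    assay: AssayConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("per_bit_mutation", "injection_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.pairing not in PAIRINGS:
            raise ValueError(f"pairing must be one of {PAIRINGS}")
        if self.pairing_switch is not None and self.pairing_switch[1] not in PAIRINGS:
            raise ValueError(f"pairing_switch condition must be one of {PAIRINGS}")
        if self.generations < 0 or self.evaluations_per_robot < 1:
            raise ValueError("generations >= 0 and evaluations_per_robot >= 1 required")

    @property
    def topology(self) -> NetworkTopology:
        return NetworkTopology(has_memory=self.has_memory)

    @property
    def decoding_spec(self) -> DecodingSpec:
        return DecodingSpec(n_weights=self.topology.n_weights)

    def pairing_at(self, generation: int) -> str:
        """Pairing condition in force at a given generation (supports the
        two-phase kin-recognition schedule)."""
        if self.pairing_switch is not None and generation >= self.pairing_switch[0]:
            return self.pairing_switch[1]
        return self.pairing

    def assay_config(self) -> AssayConfig:
        return self.assay if self.assay is not None else AssayConfig(arena=self.arena)


@dataclass
class Population:
    """A population as a bit matrix (one genotype per row)."""

    bits: np.ndarray
    spec: DecodingSpec

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[1] != self.spec.n_bits:
            raise ValueError("population bit matrix has the wrong shape")

    def __len__(self) -> int:
        return self.bits.shape[0]

    def genome(self, i: int) -> Genome:
        return Genome(self.bits[i].copy(), self.spec)

    def genomes(self) -> list[Genome]:
        return [self.genome(i) for i in range(len(self))]

    @classmethod
    def random(
        cls, n: int, spec: DecodingSpec, rng: np.random.Generator
    ) -> "Population":
        return cls(rng.integers(0, 2, size=(n, spec.n_bits), dtype=np.uint8), spec)

    @classmethod
    def from_genomes(cls, genomes: list[Genome]) -> "Population":
        spec = genomes[0].spec
        if any(g.spec != spec for g in genomes):
            raise ValueError("all genomes must share one decoding spec")
        return cls(np.stack([g.bits for g in genomes]), spec)


@dataclass
class GenerationStats:
    generation: int
    mean_fecundity: float
    fecundity_sd: float
    mean_helping_rate: float | None = None


@dataclass
class ExperimentResult:
    stats: list[GenerationStats]
    population: Population
    config: EvolutionConfig


def pair_population(
    population: Population,
    pairing: str,
    round_index: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Ordered (focal, partner) index pairs for one evaluation round.

    A partner index equal to the focal index means a clone of the focal.
    In the unrelated condition the partner is drawn uniformly from the
    other N-1 individuals, never the focal itself.
    """
    del round_index  # rounds differ only through the rng stream
    n = len(population)
    if pairing == "related":
        partners = np.arange(n)
    else:
        partners = rng.integers(0, n - 1, size=n)
        partners[partners >= np.arange(n)] += 1  # uniform over the others
        if pairing == "half_related":
            clones = rng.random(n) < 0.5
            partners[clones] = np.arange(n)[clones]
    return list(zip(range(n), (int(p) for p in partners)))


def _decoded_networks(population: Population, topology: NetworkTopology):
    nets = []
    for i in range(len(population)):
        net = build_network(decode_genome(population.genome(i)), topology)
        nets.append((net.w_in, net.w_out))
    return nets


_NO_CLAMP = np.array([-1, -1], dtype=np.int8)
_SEE_BOTH = np.array([1, 1], dtype=np.uint8)
_CAN_SELF = np.array([1, 1], dtype=np.uint8)
_NOT_STUCK = np.array([0, 0], dtype=np.uint8)
_DUMMY_TRAJ = np.zeros((1, 12))


def _eval_pair(net_f, net_p, has_memory, params, pstuck, steps, n_food, seed):
    """Run one evaluation; returns (focal food count, focal helping given)."""
    out = K.run_eval(
        net_f[0], net_f[1], net_p[0], net_p[1],
        has_memory, _NO_CLAMP, _SEE_BOTH, params, pstuck, _CAN_SELF,
        steps, n_food, _NOT_STUCK, 0.0, -1, seed, False, _DUMMY_TRAJ,
    )
    return int(out[2][0]), int(out[3][0])


def evaluate_population(
    population: Population,
    config: EvolutionConfig,
    generation: int = 0,
    pairing: str | None = None,
) -> np.ndarray:
    """Fecundity (total focal food across rounds) of every individual."""
    pairing = pairing or config.pairing_at(generation)
    nets = _decoded_networks(population, config.topology)
    params = config.arena.params_array()
    pstuck = np.full(2, config.arena.p_stuck)
    steps = config.arena.eval_steps
    n_food = config.arena.n_food
    has_memory = 1 if config.has_memory else 0
    fec = np.zeros(len(population), dtype=np.int64)
    for e in range(config.evaluations_per_robot):
        pair_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, generation, e, 0xA11CE])
        )
        pairs = pair_population(population, pairing, e, pair_rng)
        for i, j in pairs:
            seed = np.random.SeedSequence([config.seed, generation, i, e]).generate_state(
                1, np.uint64
            )[0]
            food, _help = _eval_pair(
                nets[i], nets[j], has_memory, params, pstuck, steps, n_food, seed
            )
            fec[i] += food
    return fec


def next_generation(
    population: Population,
    fecundities: np.ndarray,
    config: EvolutionConfig,
    rng: np.random.Generator,
    *,
    return_details: bool = False,
):
    """Wright-Fisher resampling proportional to fecundity, then mutation and
    optional genotype injection."""
    fec = np.asarray(fecundities, dtype=np.float64)
    if (fec < 0).any():
        raise ValueError("fecundities must be non-negative")
    n = len(population)
    total = fec.sum()
    probs = np.full(n, 1.0 / n) if total == 0 else fec / total
    parents = rng.choice(n, size=n, p=probs)
    bits = population.bits[parents]
    flips = (rng.random(bits.shape) < config.per_bit_mutation).astype(np.uint8)
    bits = bits ^ flips
    injected = np.zeros(n, dtype=bool)
    if config.injection_genome is not None and config.injection_prob > 0:
        injected = rng.random(n) < config.injection_prob
        bits[injected] = config.injection_genome.bits
    offspring = Population(bits, population.spec)
    if return_details:
        return offspring, parents, injected
    return offspring


def _assay_mean_rate(
    population: Population,
    fecundities: np.ndarray,
    config: EvolutionConfig,
    generation: int,
) -> float:
    """Mean assayed helping rate of the best individual plus a random sample."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, generation, 0x5A5])
    )
    best = int(np.argmax(fecundities))
    k = min(config.assay_sample, len(population))
    sample = set(rng.choice(len(population), size=k, replace=False).tolist())
    sample.add(best)
    acfg = config.assay_config()
    rates = []
    for i in sorted(sample):
        seed = int(
            np.random.SeedSequence([config.seed, generation, i, 0xA55A]).generate_state(1)[0]
        )
        res = helping_assay(population.genome(i), config.topology, acfg, seed)
        rates.append(res.helping_rate)
    return float(np.mean(rates))


def run_experiment(
    config: EvolutionConfig,
    initial_population: Population | None = None,
) -> ExperimentResult:
    """Evaluate/select/reproduce for ``config.generations`` generations.

    Returns per-generation statistics (helping assays every
    ``assay_every`` generations and at the last evaluated generation) and
    the final population.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xEB01]))
    if initial_population is None:
        population = Population.random(
            config.population_size, config.decoding_spec, rng
        )
    else:
        population = initial_population
        if len(population) != config.population_size:
            raise ValueError("initial population size does not match the config")
    stats: list[GenerationStats] = []
    for g in range(config.generations):
        fec = evaluate_population(population, config, g)
        assay_due = (g + 1) % config.assay_every == 0 or g == config.generations - 1
        stats.append(
            GenerationStats(
                generation=g,
                mean_fecundity=float(fec.mean()),
                fecundity_sd=float(fec.std(ddof=0)),
                mean_helping_rate=(
                    _assay_mean_rate(population, fec, config, g) if assay_due else None
                ),
            )
        )
        population = next_generation(population, fec, config, rng)
    return ExperimentResult(stats=stats, population=population, config=config)


def save_run_log(path: str | Path, stats: list[GenerationStats]) -> None:
    """Per-generation TSV log."""
    lines = ["# generation\tmean_fecundity\tfecundity_sd\tmean_helping_rate"]
    for s in stats:
        rate = "" if s.mean_helping_rate is None else f"{s.mean_helping_rate:.8g}"
        lines.append(
            f"{s.generation}\t{s.mean_fecundity:.8g}\t{s.fecundity_sd:.8g}\t{rate}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
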
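"""Bitstring genotypes for neural-network robot controllers.

A genotype is a flat string of bits, eight bits per connection weight.
Each 8-bit group is read most-significant-bit first as an unsigned integer
``v`` in [0, 255] and mapped linearly onto a weight interval, with both
endpoints reachable::

    w = weight_min + v / 255 * (weight_max - weight_min)

The standard controllers use 182 weights (no memory input) or 191 weights
(with the memory input); the genome layer itself accepts any positive
number of weights so that small genotypes can be used in isolation.

Mutation flips each bit independently at a fixed per-bit rate; there is no
crossover.  Distance between genotypes is counted at the level of weights
(loci): the number of 8-bit groups that differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GenomeError",
    "DecodingSpec",
    "Genome",
    "decode_genome",
    "mutate",
    "weight_distance",
    "random_genome",
    "write_genotype",
    "read_genotype",
]

BITS_PER_WEIGHT = 8

_POWERS = (2 ** np.arange(BITS_PER_WEIGHT - 1, -1, -1)).astype(np.float64)


class GenomeError(ValueError):
    """Malformed genotype or incompatible decoding specification."""


@dataclass(frozen=True)
class DecodingSpec:
    """How a bitstring maps to real-valued connection weights.

    Parameters
    ----------
    n_weights:
        Number of encoded weights (182 for the memoryless controller,
        191 with the memory input).
    weight_min, weight_max:
        Bounds of the linear byte-to-weight map.  The simulations use
        [-5, 5], which gives the logistic units both a near-linear and a
        saturating regime.
    """

    n_weights: int = 182
    weight_min: float = -5.0
    weight_max: float = 5.0
    bits_per_weight: int = BITS_PER_WEIGHT

    def __post_init__(self) -> None:
        if self.bits_per_weight != BITS_PER_WEIGHT:
            raise GenomeError(f"bits_per_weight must be {BITS_PER_WEIGHT}")
        if self.n_weights < 1:
            raise GenomeError("n_weights must be positive")
        if not self.weight_min < self.weight_max:
            raise GenomeError("weight_min must be below weight_max")

    @property
    def n_bits(self) -> int:
        return self.n_weights * self.bits_per_weight


@dataclass(frozen=True)
class Genome:
    """A bitstring genotype together with its decoding specification."""

    bits: np.ndarray
    spec: DecodingSpec = field(default_factory=DecodingSpec)

    def __post_init__(self) -> None:
        bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1 or bits.size != self.spec.n_bits:
            raise GenomeError(
                f"expected {self.spec.n_bits} bits, got shape {bits.shape}"
            )
        if bits.size and bits.max() > 1:
            raise GenomeError("genome bits must be 0 or 1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.spec == other.spec and np.array_equal(self.bits, other.bits)


def random_genome(spec: DecodingSpec, rng: np.random.Generator) -> Genome:
    """Uniform random genotype (i.i.d. fair bits)."""
    return Genome(rng.integers(0, 2, size=spec.n_bits, dtype=np.uint8), spec)


def decode_genome(genome: Genome) -> np.ndarray:
    """Decode a genotype to its weight vector.

    Returns an array of length ``spec.n_weights`` with every entry in
    ``[weight_min, weight_max]``.
    """
    spec = genome.spec
    values = genome.bits.reshape(spec.n_weights, spec.bits_per_weight) @ _POWERS
    scale = (spec.weight_max - spec.weight_min) / 255.0
    return spec.weight_min + values * scale


def mutate(genome: Genome, per_bit_rate: float, rng: np.random.Generator) -> Genome:
    """Return a mutated copy; each bit flips independently at ``per_bit_rate``."""
    if not 0.0 <= per_bit_rate <= 1.0:
        raise GenomeError(f"per-bit mutation rate {per_bit_rate} outside [0, 1]")
    flips = rng.random(genome.bits.size) < per_bit_rate
    return Genome(genome.bits ^ flips.astype(np.uint8), genome.spec)


def weight_distance(a: Genome, b: Genome) -> int:
    """Number of weight positions (loci) whose 8-bit groups differ."""
    if a.spec != b.spec:
        raise GenomeError("genomes have different decoding specifications")
    n, k = a.spec.n_weights, a.spec.bits_per_weight
    diff = (a.bits != b.bits).reshape(n, k)
    return int(diff.any(axis=1).sum())


# ---------------------------------------------------------------------------
# Genotype text files


def write_genotype(path: str | Path, genome: Genome, memory: bool | None = None) -> None:
    """Write a genotype file (header comment line + one line of bits).

    ``memory`` marks whether the genotype is meant for a controller with a
    memory input; by default it is inferred from the weight count (191).
    """
    spec = genome.spec
    if memory is None:
        memory = spec.n_weights == 191
    header = (
        f"# n_weights={spec.n_weights} bits_per_weight={spec.bits_per_weight} "
        f"weight_min={spec.weight_min!r} weight_max={spec.weight_max!r} "
        f"memory={int(memory)}"
    )
    bits = "".join("1" if b else "0" for b in genome.bits)
    Path(path).write_text(header + "\n" + bits + "\n")


def read_genotype(path: str | Path) -> tuple[Genome, bool]:
    """Read a genotype file written by :func:`write_genotype`.

    Returns the genome and its memory flag.  Round-trips exactly.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) != 2 or not lines[0].startswith("#"):
        raise GenomeError(f"malformed genotype file {path!s}")
    fields = dict(item.split("=", 1) for item in lines[0].lstrip("# ").split())
    try:
        spec = DecodingSpec(
            n_weights=int(fields["n_weights"]),
            weight_min=float(fields["weight_min"]),
            weight_max=float(fields["weight_max"]),
            bits_per_weight=int(fields["bits_per_weight"]),
        )
        memory = bool(int(fields["memory"]))
    except KeyError as exc:
        raise GenomeError(f"genotype header missing field {exc}") from exc
    row = lines[1].strip()
    if set(row) - {"0", "1"}:
        raise GenomeError("genotype bit line contains characters other than 0/1")
    bits = np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
    return Genome(bits, spec), memory
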
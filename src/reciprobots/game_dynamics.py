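"""Game-theoretic analysis and simulation on measured payoff matrices.

A payoff matrix holds the row player's mean payoff (food items per
evaluation) against each column strategy.  The package ships the reference
matrix measured at full scale for the three bred strategies Selfish,
Helper and Reciprocator (:func:`load_reference_payoffs`)::

                 Selfish  Helper  Reciprocator
    Selfish        152      205       160
    Helper         132      198       175
    Reciprocator   147      203       173

On such matrices this module classifies two-strategy games (the
Selfish/Helper restriction is a prisoner's dilemma: 205 > 198 > 152 > 132),
computes invasion barriers (the frequency above which an invader's
expected payoff under random pairing exceeds the resident's -- 5/18 for
Reciprocator invading Selfish), evaluates fixation probabilities of a
single mutant under a frequency-dependent Moran process, and simulates
finite-population Wright-Fisher dynamics over the strategy simplex with a
small mutation rate between strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "PayoffMatrix",
    "StrategyTrajectory",
    "DegenerateGameError",
    "load_payoffs",
    "load_reference_payoffs",
    "save_payoffs",
    "classify_two_strategy_game",
    "invasion_threshold",
    "moran_fixation_probability",
    "simulate_strategy_dynamics",
    "occupancy_histogram",
    "save_trajectory_tsv",
]


class DegenerateGameError(ValueError):
    """Payoff-identical strategies make the requested quantity undefined."""


@dataclass(frozen=True)
class PayoffMatrix:
    """Row-player mean payoffs for a set of named strategies."""

    strategy_names: tuple[str, ...]
    payoffs: np.ndarray
    standard_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        payoffs = np.asarray(self.payoffs, dtype=np.float64)
        object.__setattr__(self, "payoffs", payoffs)
        object.__setattr__(self, "strategy_names", tuple(self.strategy_names))
        n = len(self.strategy_names)
        if payoffs.shape != (n, n):
            raise ValueError("payoff matrix must be square over the named strategies")
        if not np.isfinite(payoffs).all() or (payoffs < 0).any():
            raise ValueError("payoffs must be finite and non-negative")
        if self.standard_errors is not None:
            se = np.asarray(self.standard_errors, dtype=np.float64)
            if se.shape != payoffs.shape:
                raise ValueError("standard errors must match the payoff shape")
            object.__setattr__(self, "standard_errors", se)

    def index(self, name: str) -> int:
        try:
            return self.strategy_names.index(name)
        except ValueError:
            raise KeyError(f"unknown strategy {name!r}") from None

    def restrict(self, names: tuple[str, str]) -> "PayoffMatrix":
        idx = [self.index(n) for n in names]
        return PayoffMatrix(
            strategy_names=tuple(names),
            payoffs=self.payoffs[np.ix_(idx, idx)],
            standard_errors=(
                None
                if self.standard_errors is None
                else self.standard_errors[np.ix_(idx, idx)]
            ),
        )


def load_payoffs(path: str | Path) -> PayoffMatrix:
    """Read a payoff matrix TSV (header row/column of strategy names)."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    names = lines[0].split("\t")[1:]
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        rows.append([float(c) for c in cells[1:]])
    return PayoffMatrix(strategy_names=tuple(names), payoffs=np.array(rows))


def load_reference_payoffs() -> PayoffMatrix:
    """The packaged full-scale Selfish/Helper/Reciprocator payoff matrix."""
    ref = resources.files("reciprobots.data").joinpath("reference_payoffs.tsv")
    with resources.as_file(ref) as path:
        return load_payoffs(path)


def save_payoffs(path: str | Path, matrix: PayoffMatrix) -> None:
    lines = ["\t" + "\t".join(matrix.strategy_names)]
    for name, row in zip(matrix.strategy_names, matrix.payoffs):
        lines.append(name + "\t" + "\t".join(f"{v:.10g}" for v in row))
    if matrix.standard_errors is not None:
        for name, row in zip(matrix.strategy_names, matrix.standard_errors):
            lines.append("# se " + name + "\t" + "\t".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def classify_two_strategy_game(
    matrix: PayoffMatrix, cooperator: str, defector: str
) -> str:
    """Label the 2x2 game between a cooperator and a defector strategy.

    With R the mutual-cooperation payoff, T the defector's temptation
    payoff against a cooperator, P the mutual-defection payoff and S the
    cooperator's payoff against a defector:

    - ``prisoners_dilemma``: T > R > P > S
    - ``snowdrift``:         T > R > S > P
    - ``stag_hunt``:         R > T > P > S
    - ``harmony``:           R > T and S > P
    - ``ambiguous``: any tie among the defining comparisons
    - ``other``: everything else
    """
    c, d = matrix.index(cooperator), matrix.index(defector)
    P_ = matrix.payoffs
    R, T, P, S = P_[c, c], P_[d, c], P_[d, d], P_[c, d]
    vals = [R, T, P, S]
    if len({float(v) for v in vals}) < 4:
        return "ambiguous"
    if T > R > P > S:
        return "prisoners_dilemma"
    if T > R > S > P:
        return "snowdrift"
    if R > T > P > S:
        return "stag_hunt"
    if R > T and S > P:
        return "harmony"
    return "other"


def invasion_threshold(
    matrix: PayoffMatrix, invader: str, resident: str
) -> float | None:
    """Invasion barrier of ``invader`` against ``resident``.

    Under random pairing at invader frequency ``x`` the expected payoffs
    are linear in ``x``; the barrier is the root of their difference,

        x * P(i,i) + (1-x) * P(i,r)  =  x * P(r,i) + (1-x) * P(r,r).

    Returns the root if it lies in (0, 1); 0.0 if the invader is favored
    at all frequencies; None if the invader is never favored in (0, 1].
    The value is invariant under adding a constant to all payoffs and
    under positive rescaling.
    """
    if invader == resident:
        raise ValueError("invader and resident must differ")
    i, r = matrix.index(invader), matrix.index(resident)
    P_ = matrix.payoffs
    a = P_[i, i] - P_[r, i]  # advantage when common
    b = P_[i, r] - P_[r, r]  # advantage when rare
    if a == 0.0 and b == 0.0:
        raise DegenerateGameError(
            f"{invader} and {resident} are payoff-identical"
        )
    if b >= 0.0 and a >= 0.0:
        return 0.0
    x = b / (b - a) if a != b else None
    if x is not None and 0.0 < x < 1.0:
        return float(x)
    return None


def moran_fixation_probability(
    matrix: PayoffMatrix,
    invader: str,
    resident: str,
    n: int,
    intensity: float = 1.0,
) -> float:
    """Fixation probability of a single invader copy in a resident
    population of size ``n`` under a frequency-dependent Moran process.

    Payoffs are averaged over random interaction partners excluding self;
    fitness is ``1 - w + w * payoff`` with ``w = intensity`` (the default
    w = 1 uses payoffs directly as fitness, mirroring fecundity-
    proportional selection in the foraging simulations).  The classical
    closed form is used:

        rho = 1 / (1 + sum_{k=1}^{N-1} prod_{j=1}^{k} f_r(j) / f_i(j))

    The neutral case gives exactly 1/N.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    if intensity < 0:
        raise ValueError("selection intensity must be >= 0")
    i, r = matrix.index(invader), matrix.index(resident)
    P_ = matrix.payoffs
    a, b, c, d = P_[i, i], P_[i, r], P_[r, i], P_[r, r]
    k = np.arange(1, n)
    pi_i = (a * (k - 1) + b * (n - k)) / (n - 1)
    pi_r = (c * k + d * (n - k - 1)) / (n - 1)
    f_i = 1.0 - intensity + intensity * pi_i
    f_r = 1.0 - intensity + intensity * pi_r
    if (f_i <= 0).any() or (f_r <= 0).any():
        raise ValueError("selection intensity makes fitness non-positive")
    gamma = f_r / f_i
    return float(1.0 / (1.0 + np.cumprod(gamma).sum()))


@dataclass
class StrategyTrajectory:
    """Per-generation strategy counts of a finite-population simulation."""

    strategy_names: tuple[str, ...]
    counts: np.ndarray  # (generations + 1, n_strategies), includes the start
    n: int

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n


def simulate_strategy_dynamics(
    matrix: PayoffMatrix,
    n: int,
    mu: float,
    generations: int,
    init_counts,
    rng: np.random.Generator | int,
    intensity: float = 1.0,
) -> StrategyTrajectory:
    """Wright-Fisher dynamics of the named strategies.

    Per generation: each strategy's expected payoff under random pairing
    excluding self, fitness ``1 - w + w * payoff``, multinomial resampling
    of ``n`` offspring proportional to count x fitness, then each offspring
    mutates with probability ``mu`` to one of the other strategies (split
    equally) -- the strategies are treated as one mutation apart.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    s = len(matrix.strategy_names)
    counts = np.asarray(init_counts, dtype=np.int64)
    if counts.shape != (s,) or counts.sum() != n or (counts < 0).any():
        raise ValueError(f"init_counts must be {s} non-negative counts summing to {n}")
    P_ = matrix.payoffs
    out = np.empty((generations + 1, s), dtype=np.int64)
    out[0] = counts
    for g in range(generations):
        payoff = (P_ @ counts - np.diag(P_) * (counts > 0)) / max(n - 1, 1)
        # the subtraction removes the self-interaction for present strategies
        fitness = 1.0 - intensity + intensity * payoff
        fitness = np.where(counts > 0, fitness, 0.0)
        if (fitness < 0).any():
            raise ValueError("selection intensity makes fitness negative")
        weight = counts * fitness
        total = weight.sum()
        probs = counts / n if total <= 0 else weight / total
        counts = rng.multinomial(n, probs)
        if mu > 0:
            mutated = np.zeros(s, dtype=np.int64)
            for j in range(s):
                m = rng.binomial(counts[j], mu)
                if m:
                    others = [t for t in range(s) if t != j]
                    dest = rng.multinomial(m, np.full(len(others), 1.0 / len(others)))
                    counts[j] -= m
                    for t, cnt in zip(others, dest):
                        mutated[t] += cnt
            counts = counts + mutated
        out[g + 1] = counts
    return StrategyTrajectory(strategy_names=matrix.strategy_names, counts=out, n=n)


def occupancy_histogram(
    trajectory: StrategyTrajectory, n_bins: int = 50
) -> np.ndarray:
    """Visit counts over the strategy simplex, binned on the first two
    frequencies.  Total counts equal the number of recorded states."""
    freq = trajectory.frequencies()
    if freq.shape[1] < 2:
        raise ValueError("occupancy needs at least two strategies")
    hist = np.zeros((n_bins, n_bins), dtype=np.int64)
    ix = np.minimum((freq[:, 0] * n_bins).astype(int), n_bins - 1)
    iy = np.minimum((freq[:, 1] * n_bins).astype(int), n_bins - 1)
    np.add.at(hist, (ix, iy), 1)
    return hist


def save_trajectory_tsv(path: str | Path, trajectory: StrategyTrajectory) -> None:
    lines = ["# generation\t" + "\t".join(trajectory.strategy_names)]
    for g, row in enumerate(trajectory.counts):
        lines.append(str(g) + "\t" + "\t".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
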
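"""Standardized behavioral measurements on single genotypes.

The helping assay places a focal robot 100 independent times in an arena
with two food items and one stuck partner that cannot free itself, and
tracks each trial for 1000 steps.  The trial-level data are the number of
trials in which the partner was released and the release times; under the
model that the focal helps with a constant per-step probability ``h``,
release times are geometric and unreleased trials are right-censored at
the trial length, and the two recorded summaries (proportion released,
mean time to release) are exactly the sufficient statistics.  The maximum
likelihood estimate has the closed form::

    h_hat = k / (sum(release_times) + (n - k) * T)

with ``k`` releases out of ``n`` trials of length ``T``.  This per-step
probability is the *helping rate*.

Variants: the chance-level assay makes the partner invisible to the
focal's sensors (helping can then only happen by chance), and the mood
assay clamps the memory input to 0 or 1 throughout.  ``measure_payoff``
runs full foraging evaluations of an ordered genotype pair and returns the
row robot's mean food count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2

from .arena import ArenaConfig, run_evaluation
from .controller import NetworkTopology, TopologyError
from .genome import Genome

__all__ = [
    "AssayConfig",
    "AssayResult",
    "helping_assay",
    "chance_level_assay",
    "mood_assay",
    "estimate_helping_rate",
    "profile_interval",
    "censored_geometric_loglik",
    "measure_payoff",
    "PayoffEstimate",
    "save_assay_report",
]


@dataclass(frozen=True)
class AssayConfig:
    """Parameters of the helping assay."""

    n_trials: int = 100
    trial_steps: int = 1000
    partner_self_release: bool = False
    partner_visible: bool = True
    memory_clamp: int | None = None
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.trial_steps < 1:
            raise ValueError("n_trials and trial_steps must be >= 1")
        if self.memory_clamp not in (None, 0, 1):
            raise ValueError("memory_clamp must be None, 0 or 1")


@dataclass
class AssayResult:
    """Trial-level outcomes plus the estimated helping rate."""

    released: int
    release_times: list[int]
    n_trials: int
    trial_steps: int
    helping_rate: float

    def __post_init__(self) -> None:
        if self.released != len(self.release_times):
            raise ValueError("released must equal the number of release times")


def _run_assay(
    genome: Genome,
    topology: NetworkTopology,
    config: AssayConfig,
    seed: int | None,
    *,
    partner_visible: bool,
    memory_clamp: int | None,
) -> AssayResult:
    base = config.seed if seed is None else seed
    clamp = -1 if memory_clamp is None else memory_clamp
    if clamp >= 0 and not topology.has_memory:
        raise TopologyError("memory clamp requested on a memoryless topology")
    times: list[int] = []
    for trial in range(config.n_trials):
        child = np.random.SeedSequence([base, trial]).generate_state(1)[0]
        res = run_evaluation(
            (genome, genome),
            topology,
            config.arena,
            int(child),
            n_steps=config.trial_steps,
            p_stuck=(0.0, 0.0),
            can_self_release=(True, config.partner_self_release),
            init_stuck=(False, True),
            min_initial_gap=config.arena.robot_diameter,
            partner_visible=(partner_visible, True),
            memory_clamp=(clamp, -1),
            end_on_release_of=1,
        )
        if res.stuck_episodes[1]:
            start, end, _helped = res.stuck_episodes[1][0]
            times.append(end - start)  # start is -1: duration = steps elapsed
    result = AssayResult(
        released=len(times),
        release_times=times,
        n_trials=config.n_trials,
        trial_steps=config.trial_steps,
        helping_rate=0.0,
    )
    result.helping_rate = estimate_helping_rate(result)
    return result


def helping_assay(
    genome: Genome,
    topology: NetworkTopology,
    config: AssayConfig | None = None,
    seed: int | None = None,
) -> AssayResult:
    """Standard helping assay: visible stuck partner, free memory input."""
    config = config or AssayConfig()
    return _run_assay(
        genome,
        topology,
        config,
        seed,
        partner_visible=config.partner_visible,
        memory_clamp=config.memory_clamp,
    )


def chance_level_assay(
    genome: Genome,
    topology: NetworkTopology,
    config: AssayConfig | None = None,
    seed: int | None = None,
) -> AssayResult:
    """Helping assay with an invisible partner.

    The partner contributes nothing to the focal's proximity or camera
    activations but remains physically present and releasable, so any
    releases occur by chance alone.
    """
    config = config or AssayConfig()
    return _run_assay(
        genome, topology, config, seed,
        partner_visible=False, memory_clamp=config.memory_clamp,
    )


def mood_assay(
    genome: Genome,
    topology: NetworkTopology,
    clamp: int,
    config: AssayConfig | None = None,
    seed: int | None = None,
) -> AssayResult:
    """Helping assay with the memory input held at ``clamp`` (0 or 1)."""
    if clamp not in (0, 1):
        raise ValueError("clamp must be 0 or 1")
    config = config or AssayConfig()
    return _run_assay(
        genome, topology, config, seed,
        partner_visible=config.partner_visible, memory_clamp=clamp,
    )


# ---------------------------------------------------------------------------
# Censored-geometric estimation


def estimate_helping_rate(result: AssayResult) -> float:
    """Closed-form MLE of the per-step helping probability."""
    n, k = result.n_trials, result.released
    if n == 0:
        raise ValueError("cannot estimate a rate from zero trials")
    if k == 0:
        return 0.0
    denom = sum(result.release_times) + (n - k) * result.trial_steps
    return k / denom


def censored_geometric_loglik(h: float, result: AssayResult) -> float:
    """Log-likelihood of ``h`` under the censored-geometric trial model."""
    n, k, T = result.n_trials, result.released, result.trial_steps
    if not 0.0 <= h <= 1.0:
        return -np.inf
    failures = sum(result.release_times) - k + (n - k) * T
    ll = 0.0
    if k:
        if h == 0.0:
            return -np.inf
        ll += k * np.log(h)
    if failures:
        if h == 1.0:
            return -np.inf
        ll += failures * np.log1p(-h)
    return ll


def profile_interval(result: AssayResult, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood confidence interval for the helping rate."""
    h_hat = estimate_helping_rate(result)
    cut = censored_geometric_loglik(h_hat, result) - chi2.ppf(level, df=1) / 2.0

    def g(h: float) -> float:
        return censored_geometric_loglik(h, result) - cut

    eps = 1e-15
    lo = 0.0 if g(eps) >= 0 else brentq(g, eps, max(h_hat, 2 * eps))
    hi = 1.0 if g(1.0 - eps) >= 0 else brentq(g, min(h_hat, 1.0 - 2 * eps), 1.0 - eps)
    return lo, hi


# ---------------------------------------------------------------------------
# Payoff measurement


@dataclass(frozen=True)
class PayoffEstimate:
    """Mean payoff (food items per evaluation) of the row robot, with SE."""

    mean: float
    se: float
    n_interactions: int


def measure_payoff(
    genome_row: Genome,
    genome_col: Genome,
    n_interactions: int = 1000,
    *,
    topology: NetworkTopology | None = None,
    config: ArenaConfig | None = None,
    seed: int = 0,
) -> PayoffEstimate:
    """Mean food count of ``genome_row`` over repeated paired evaluations."""
    topology = topology or NetworkTopology(
        has_memory=genome_row.spec.n_weights == 191
    )
    config = config or ArenaConfig()
    counts = np.empty(n_interactions)
    for i in range(n_interactions):
        child = np.random.SeedSequence([seed, i]).generate_state(1)[0]
        res = run_evaluation(
            (genome_row, genome_col), topology, config, int(child)
        )
        counts[i] = res.food_counts[0]
    se = counts.std(ddof=1) / np.sqrt(n_interactions) if n_interactions > 1 else 0.0
    return PayoffEstimate(
        mean=float(counts.mean()), se=float(se), n_interactions=n_interactions
    )


def save_assay_report(path: str | Path, result: AssayResult) -> None:
    """TSV report: one row per released trial plus a summary comment."""
    lines = ["# release_event\trelease_step"]
    for i, t in enumerate(result.release_times):
        lines.append(f"{i}\t{t}")
    lo, hi = profile_interval(result)
    lines.append(
        f"# helping_rate={result.helping_rate:.8g} ci95=[{lo:.8g},{hi:.8g}] "
        f"released={result.released}/{result.n_trials}"
    )
    Path(path).write_text("\n".join(lines) + "\n")
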
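"""TOML configuration files and run provenance.

A configuration file holds optional ``[arena]``, ``[evolution]``,
``[assay]``, ``[breeding]`` and ``[dynamics]`` tables whose keys mirror
the corresponding config dataclasses; an empty file yields the standard
experimental defaults (1e-2 per-bit mutation, N = 100, 20,000-step
evaluations, sticking/release probabilities 5e-4, ...).  Unknown tables or
keys are rejected, and all dataclass invariants are enforced on load.

Every CLI run writes a JSON manifest echoing the full configuration, the
seed, the package version and the produced files.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

from .arena import ArenaConfig
from .assays import AssayConfig
from .artificial_selection import BreedingConfig
from .evolution import EvolutionConfig
from .genome import read_genotype

__all__ = [
    "ConfigError",
    "DynamicsConfig",
    "Settings",
    "load_config",
    "dump_config",
    "RunManifest",
    "write_manifest",
]


class ConfigError(ValueError):
    """Malformed or invalid configuration file."""


@dataclass(frozen=True)
class DynamicsConfig:
    """Defaults for strategy-dynamics simulations."""

    population_size: int = 100
    mu: float = 1e-2
    generations: int = 50_000
    intensity: float = 1.0
    init_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigError(f"mu={self.mu} outside [0, 1]")
        if self.population_size < 2 or self.generations < 0:
            raise ConfigError("population_size >= 2 and generations >= 0 required")


@dataclass(frozen=True)
class Settings:
    """All section configs, composed (evolution/assay/breeding share the
    arena)."""

    arena: ArenaConfig
    evolution: EvolutionConfig
    assay: AssayConfig
    breeding: BreedingConfig
    dynamics: DynamicsConfig


_SPECIAL_KEYS = {
    "evolution": {"injection_genotype"},
    "breeding": {"reference_genotype"},
}


def _build(cls, table: dict, section: str, **extra):
    allowed = {f.name for f in fields(cls)}
    special = _SPECIAL_KEYS.get(section, set())
    for key in table:
        if key not in allowed and key not in special:
            raise ConfigError(f"unknown key {key!r} in [{section}]")
    kwargs = {k: v for k, v in table.items() if k in allowed}
    if "pairing_switch" in kwargs and kwargs["pairing_switch"] is not None:
        gen, cond = kwargs["pairing_switch"]
        kwargs["pairing_switch"] = (int(gen), str(cond))
    if "init_counts" in kwargs and kwargs["init_counts"] is not None:
        kwargs["init_counts"] = tuple(int(v) for v in kwargs["init_counts"])
    try:
        return cls(**kwargs, **extra)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid [{section}] configuration: {exc}") from exc


def load_config(path: str | Path | None = None) -> Settings:
    """Load and validate a TOML config; ``None`` gives all defaults."""
    if path is None:
        data: dict = {}
    else:
        try:
            data = tomllib.loads(Path(path).read_text())
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    known = {"arena", "evolution", "assay", "breeding", "dynamics"}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown config table [{key}]")
    arena = _build(ArenaConfig, data.get("arena", {}), "arena")
    assay = _build(AssayConfig, data.get("assay", {}), "assay", arena=arena)
    evo_table = dict(data.get("evolution", {}))
    injection = evo_table.pop("injection_genotype", None)
    injection_genome = read_genotype(injection)[0] if injection else None
    evolution = _build(
        EvolutionConfig, evo_table, "evolution",
        arena=arena, assay=assay, injection_genome=injection_genome,
    )
    breed_table = dict(data.get("breeding", {}))
    reference = breed_table.pop("reference_genotype", None)
    reference_genome = read_genotype(reference)[0] if reference else None
    breeding = _build(
        BreedingConfig, breed_table, "breeding",
        arena=arena, assay=assay, reference_genome=reference_genome,
    )
    dynamics = _build(DynamicsConfig, data.get("dynamics", {}), "dynamics")
    return Settings(
        arena=arena, evolution=evolution, assay=assay,
        breeding=breeding, dynamics=dynamics,
    )


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {}
        for f in fields(obj):
            v = getattr(obj, f.name)
            if f.name in ("arena", "assay") and not isinstance(obj, Settings):
                continue  # composed sections are echoed once at top level
            if f.name in ("injection_genome", "reference_genome"):
                v = None if v is None else f"<genotype:{v.spec.n_weights} weights>"
            out[f.name] = _as_plain(v)
        return out
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, tuple):
        return list(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def dump_config(settings: Settings) -> str:
    """Serialize settings back to normalized TOML text."""
    parts = []
    for section in ("arena", "evolution", "assay", "breeding", "dynamics"):
        table = _as_plain(getattr(settings, section))
        lines = [f"[{section}]"]
        for key, value in table.items():
            if value is None or key.endswith("_genome"):
                continue
            if isinstance(value, bool):
                text = "true" if value else "false"
            elif isinstance(value, str):
                text = json.dumps(value)
            elif isinstance(value, (list, tuple)):
                text = json.dumps(list(value))
            else:
                text = repr(value)
            lines.append(f"{key} = {text}")
        parts.append("\n".join(lines))
    return "\n\n".join(parts) + "\n"


@dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    command: str
    seed: int | None
    config: dict
    package_version: str
    started: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)


def write_manifest(path: str | Path, manifest: RunManifest) -> None:
    path = Path(path)
    for out in manifest.outputs:
        if not Path(out).exists():
            raise ConfigError(f"manifest lists missing output {out}")
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
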
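"""Configuration loading, validation, and bundled example presets.

Run configurations are plain YAML/JSON mappings mirroring the model
parameterization (lattice dimensions, patch size, kernel blocks, payoff
and life-cycle blocks, simulation settings).  Builders validate each
block and surface errors naming the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .commons import CommonsParams
from .kernels import (
    Kernel,
    island_kernel,
    truncated_binomial_kernel,
    uniform_kernel,
    validate_kernel,
)
from .lattice import Lattice
from .scaled import LifeCycle, survival_effects, wf_fecundity
from .simulate import SimConfig

__all__ = [
    "RunConfig",
    "load_config",
    "write_field_table",
    "read_field_table",
    "make_fixtures",
]

COMMANDS = (
    "relatedness",
    "kappa",
    "extended-effects",
    "omega",
    "zstar",
    "gradient",
    "simulate",
)


class ConfigError(ValueError):
    """Configuration violates the schema; the message names the field."""


def _require(block: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in block:
        raise ConfigError(f"missing required field '{where}.{key}'" if where else
                          f"missing required field '{key}'")
    return block[key]


@dataclass
class RunConfig:
    """A validated run configuration (raw mapping plus conveniences)."""

    command: str
    raw: dict[str, Any]
    path: Optional[Path] = None

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def out(self) -> Optional[str]:
        return self.raw.get("out")

    # -- builders ------------------------------------------------------

    def lattice(self) -> Lattice:
        block = _require(self.raw, "lattice", "")
        dims = _require(block, "dims", "lattice")
        try:
            return Lattice(dims)
        except Exception as exc:
            raise ConfigError(f"invalid 'lattice.dims': {exc}") from exc

    def N(self) -> int:
        N = int(_require(self.raw, "N", ""))
        if N < 1:
            raise ConfigError(f"'N' must be a positive integer, got {N}")
        return N

    def kernel(self, key: str) -> Kernel:
        block = _require(self.raw, key, "")
        lattice = self.lattice()
        ktype = _require(block, "type", key)
        if ktype == "uniform":
            return uniform_kernel(lattice)
        if ktype == "island":
            return island_kernel(lattice, float(_require(block, "move_prob", key)))
        if ktype == "truncated_binomial":
            return truncated_binomial_kernel(
                lattice,
                float(_require(block, "move_prob", key)),
                float(_require(block, "mean_distance", key)),
            )
        if ktype == "custom":
            file = _require(block, "file", key)
            table = pd.read_csv(file)
            return validate_kernel(_field_from_table(table, lattice), lattice)
        raise ConfigError(f"unknown kernel '{key}.type': {ktype!r}")

    def lifecycle(self) -> LifeCycle:
        block = self.raw.get("lifecycle", "wf_fecundity")
        if isinstance(block, str):
            if block == "wf_fecundity":
                return wf_fecundity()
            if block == "survival_effects":
                raise ConfigError(
                    "'lifecycle: survival_effects' needs a mapping with the"
                    " baseline survival, e.g. {preset: survival_effects, s: 0.9}"
                )
            raise ConfigError(f"unknown lifecycle preset {block!r}")
        if block.get("preset") == "survival_effects":
            return survival_effects(float(_require(block, "s", "lifecycle")))
        if block.get("preset") == "wf_fecundity":
            return wf_fecundity()
        try:
            return LifeCycle(
                s=float(_require(block, "s", "lifecycle")),
                s_prime=float(_require(block, "s_prime", "lifecycle")),
                f=float(_require(block, "f", "lifecycle")),
                f_prime=float(_require(block, "f_prime", "lifecycle")),
            )
        except ConfigError:
            raise
        except Exception as exc:
            raise ConfigError(f"invalid 'lifecycle' block: {exc}") from exc

    def commons_params(self) -> CommonsParams:
        payoff = _require(self.raw, "payoff", "")
        production = self.raw.get("production", {})
        lattice = self.lattice()
        N = self.N()
        try:
            return CommonsParams(
                lattice=lattice,
                N=N,
                m_kernel=self.kernel("dispersal"),
                d_kernel=self.kernel("commons_movement"),
                B=float(_require(payoff, "B", "payoff")),
                C=float(_require(payoff, "C", "payoff")),
                alpha_B=int(_require(payoff, "alpha_B", "payoff")),
                alpha_C=int(_require(payoff, "alpha_C", "payoff")),
                epsilon=float(_require(self.raw, "epsilon", "")),
                P0=float(production.get("P0", N)),
                lifecycle=self.lifecycle(),
            )
        except ConfigError:
            raise
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def sim_config(self) -> SimConfig:
        block = _require(self.raw, "sim", "")
        try:
            return SimConfig(
                params=self.commons_params(),
                generations=int(_require(block, "generations", "sim")),
                burn_in=int(block.get("burn_in", 0)),
                mutation_prob=float(block.get("mutation_prob", 1e-4)),
                mutation_sd=float(block.get("mutation_sd", 1e-2)),
                seed=int(block.get("seed", self.seed)),
                init_trait=float(block.get("init_trait", 0.0))
                if block.get("init_trait") != "zstar"
                else 0.0,
                init_env=block.get("init_env", "equilibrium"),
            )
        except ConfigError:
            raise
        except ValueError as exc:
            raise ConfigError(f"invalid 'sim' block: {exc}") from exc

    def manifest(self) -> dict[str, Any]:
        from . import __version__

        return {
            "command": self.command,
            "config": self.raw,
            "version": __version__,
            "seed": self.seed,
        }


def load_config(path: str | Path, command: Optional[str] = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cmd = command or raw.get("command")
    if cmd is None:
        raise ConfigError("missing required field 'command'")
    if cmd not in COMMANDS:
        raise ConfigError(f"unknown command {cmd!r}; expected one of {COMMANDS}")
    cfg = RunConfig(command=cmd, raw=raw, path=path)
    _validate_for_command(cfg)
    return cfg


def _validate_for_command(cfg: RunConfig) -> None:
    cfg.lattice()
    cfg.N()
    if cfg.command in ("relatedness", "kappa"):
        cfg.kernel("dispersal")
    if cfg.command == "kappa":
        cfg.lifecycle()
    if cfg.command in ("extended-effects", "omega", "zstar", "gradient", "simulate"):
        cfg.commons_params()
    if cfg.command == "simulate":
        cfg.sim_config()


# ---------------------------------------------------------------------------
# Field tables
# ---------------------------------------------------------------------------

def _field_from_table(table: pd.DataFrame, lattice: Lattice) -> np.ndarray:
    kcols = [f"k{j + 1}" for j in range(lattice.d)]
    values = np.zeros(lattice.D)
    for _, row in table.iterrows():
        idx = lattice.index_of([int(row[c]) for c in kcols])
        values[idx] = row["value"]
    return values


def write_field_table(
    fields: Mapping[int, np.ndarray], lattice: Lattice, path: str | Path
) -> pd.DataFrame:
    """Write spatial fields per time index as a long CSV.

    Columns are ``k1..kd, t, value``; rows are ordered lexicographically
    in ``(t, k)``.  The written values round-trip bitwise through
    :func:`read_field_table`.
    """
    rows = []
    for t in sorted(fields):
        values = lattice.check_field(fields[t])
        for idx in range(lattice.D):
            rows.append((*lattice.coords_of(idx), int(t), float(values[idx])))
    cols = [f"k{j + 1}" for j in range(lattice.d)] + ["t", "value"]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_field_table(path: str | Path, lattice: Lattice) -> dict[int, np.ndarray]:
    """Read a long CSV written by :func:`write_field_table`."""
    df = pd.read_csv(path)
    out: dict[int, np.ndarray] = {}
    for t, sub in df.groupby("t"):
        out[int(t)] = _field_from_table(sub, lattice)
    return out


# ---------------------------------------------------------------------------
# Bundled presets
# ---------------------------------------------------------------------------

def make_fixtures() -> dict[str, dict[str, Any]]:
    """Small, fully validated example configurations.

    ``toy_1d``: a 7-patch ring for quick exploration.  ``ring_51`` and
    ``torus_13x13``: the 1D and 2D lattices used throughout the worked
    examples (short-range dispersal).  ``commons_13x13``: the full
    commons model on the 13x13 torus with short-range dispersal and
    long-range commons movement (the posthumous-spite regime).
    ``sim_7x7``: a scaled-down individual-based simulation.
    """
    fixtures: dict[str, dict[str, Any]] = {
        "toy_1d": {
            "command": "relatedness",
            "lattice": {"dims": [7]},
            "N": 5,
            "dispersal": {
                "type": "truncated_binomial",
                "move_prob": 0.5,
                "mean_distance": 1.5,
            },
            "t_max": 3,
        },
        "ring_51": {
            "command": "relatedness",
            "lattice": {"dims": [51]},
            "N": 20,
            "dispersal": {
                "type": "truncated_binomial",
                "move_prob": 0.8,
                "mean_distance": 1.9,
            },
            "t_max": 5,
        },
        "torus_13x13": {
            "command": "kappa",
            "lattice": {"dims": [13, 13]},
            "N": 20,
            "dispersal": {
                "type": "truncated_binomial",
                "move_prob": 0.8,
                "mean_distance": 1.5,
            },
            "lifecycle": "wf_fecundity",
            "t_max": 5,
        },
        "commons_13x13": {
            "command": "zstar",
            "lattice": {"dims": [13, 13]},
            "N": 50,
            "dispersal": {
                "type": "truncated_binomial",
                "move_prob": 0.3,
                "mean_distance": 1.54,
            },
            "commons_movement": {
                "type": "truncated_binomial",
                "move_prob": 1.0,
                "mean_distance": 8.0,
            },
            "payoff": {"B": 2.0, "C": 1.0, "alpha_B": 1, "alpha_C": 4},
            "epsilon": 0.5,
            "production": {"P0": 50.0},
            "lifecycle": "wf_fecundity",
        },
        "sim_7x7": {
            "command": "simulate",
            "lattice": {"dims": [7, 7]},
            "N": 20,
            "dispersal": {
                "type": "truncated_binomial",
                "move_prob": 0.3,
                "mean_distance": 1.5,
            },
            "commons_movement": {
                "type": "truncated_binomial",
                "move_prob": 1.0,
                "mean_distance": 5.0,
            },
            "payoff": {"B": 2.0, "C": 1.0, "alpha_B": 1, "alpha_C": 4},
            "epsilon": 0.5,
            "production": {"P0": 20.0},
            "lifecycle": "wf_fecundity",
            "sim": {
                "generations": 4000,
                "burn_in": 1000,
                "mutation_prob": 1e-4,
                "mutation_sd": 1e-2,
                "init_trait": 0.0,
            },
            "seed": 1,
        },
    }
    return fixtures


def fixture_config(name: str) -> RunConfig:
    """A validated :class:`RunConfig` for a bundled preset."""
    fixtures = make_fixtures()
    if name not in fixtures:
        raise ConfigError(f"unknown fixture {name!r}; have {sorted(fixtures)}")
    raw = fixtures[name]
    cfg = RunConfig(command=raw["command"], raw=raw)
    _validate_for_command(cfg)
    return cfg
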
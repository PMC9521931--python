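"""Configuration, fixtures, and output writers shared by all modules.

Every stochastic run records its seed and full parameter set in its
outputs; a single global seed expands deterministically into per-component
stream seeds so that runs are byte-reproducible across module boundaries.
Strategy naming in all I/O uses the three-letter *abc* notation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .games import PRESETS, SymmetricGame2x2, preset
from .twostage import STRATEGY_INDEX, STRATEGY_NAMES


class ConfigError(ValueError):
    """Raised for unparseable or invalid run configuration."""


_GAME_KEYS = {"preset", "reward", "sucker", "temptation", "punishment", "labels", "strategy_labels"}
_TOP_KEYS = {
    "pd",
    "game_b",
    "model",
    "nu",
    "eta",
    "pi0",
    "seed",
    "out",
    "steps",
    "generations",
    "n",
    "samples",
    "lattice_side",
    "cadence",
    "init",
    "tol",
    "max_iter",
    "log_level",
}
_DEFAULTS = {"model": "direct", "nu": 0.005, "eta": 0.0, "pi0": 0.0, "seed": 0, "log_level": "INFO"}


def _parse_game(block, default_labels=("C", "D")) -> SymmetricGame2x2:
    if isinstance(block, str):
        return preset(block)
    if not isinstance(block, dict):
        raise ConfigError(f"game block must be a preset name or a mapping, got {block!r}")
    unknown = set(block) - _GAME_KEYS
    if unknown:
        raise ConfigError(f"unknown game keys: {sorted(unknown)}")
    if "preset" in block:
        return preset(block["preset"])
    try:
        labels = tuple(block.get("labels", block.get("strategy_labels", default_labels)))
        return SymmetricGame2x2(
            block["reward"], block["sucker"], block["temptation"], block["punishment"], labels
        )
    except KeyError as e:
        raise ConfigError(f"game block missing payoff key {e}") from None


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    pd: SymmetricGame2x2
    game_b: SymmetricGame2x2
    model: str = "direct"
    nu: float = 0.005
    eta: float = 0.0
    pi0: float = 0.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("direct", "reputation"):
            raise ConfigError(f"model must be 'direct' or 'reputation', got {self.model!r}")
        if not 0.0 <= self.nu <= 1.0:
            raise ConfigError(f"nu must lie in [0, 1], got {self.nu}")
        if not 0.0 <= self.eta <= 1.0:
            raise ConfigError(f"eta must lie in [0, 1], got {self.eta}")
        if self.pi0 < 0:
            raise ConfigError(f"pi0 must be nonnegative, got {self.pi0}")

    def to_dict(self) -> dict:
        return {
            "pd": self.pd.to_dict(),
            "game_b": self.game_b.to_dict(),
            "model": self.model,
            "nu": self.nu,
            "eta": self.eta,
            "pi0": self.pi0,
            "seed": self.seed,
            **self.extra,
        }

    def component_seed(self, component: str) -> int:
        """Deterministic per-component stream seed derived from the global seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(component.encode()) % (2**31)])
        return int(ss.generate_state(1)[0] % (2**31))


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config file; unknown keys are rejected."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text())
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a key-value mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}
    if "pd" not in merged or "game_b" not in merged:
        raise ConfigError("config must name both 'pd' and 'game_b' games")
    pd_game = _parse_game(merged.pop("pd"), ("C", "D"))
    gb = _parse_game(merged.pop("game_b"), ("d", "u"))
    known = {k: merged.pop(k) for k in ("model", "nu", "eta", "pi0", "seed") if k in merged}
    merged.pop("log_level", None)
    return RunConfig(pd=pd_game, game_b=gb, extra=merged, **known)


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Fixtures (named initial conditions)
# ---------------------------------------------------------------------------


def make_fixture(name: str, kind: str, n: int | None = None, side: int | None = None, seed: int = 0):
    """Build a named initial condition.

    ``name``: ``center``, ``uniform_random``, ``simplex_random``,
    ``monomorphic:<s>`` or ``mixture:<s1>,<s2>``.
    ``kind``: ``distribution`` (length-8 frequency vector), ``population``
    (length-n id array) or ``grid`` (side x side id array).
    """
    rng = np.random.default_rng(seed)
    if kind == "population" and not n:
        raise ConfigError("population fixtures need n")
    if kind == "grid" and not side:
        raise ConfigError("grid fixtures need side")

    def ids(shape):
        if name == "center" or name == "uniform_random":
            return rng.integers(0, 8, size=shape)
        if name == "simplex_random":
            w = rng.dirichlet(np.ones(8))
            return rng.choice(8, size=shape, p=w)
        if name.startswith("monomorphic:"):
            return np.full(shape, STRATEGY_INDEX[_strategy(name)], dtype=np.int8)
        if name.startswith("mixture:"):
            a, b = _mixture(name)
            return rng.choice([a, b], size=shape)
        raise ConfigError(f"unknown fixture {name!r}")

    if kind == "distribution":
        if name == "center" or name == "uniform_random":
            return np.full(8, 0.125)
        if name == "simplex_random":
            return rng.dirichlet(np.ones(8))
        if name.startswith("monomorphic:"):
            f = np.zeros(8)
            f[STRATEGY_INDEX[_strategy(name)]] = 1.0
            return f
        if name.startswith("mixture:"):
            a, b = _mixture(name)
            f = np.zeros(8)
            f[a] = f[b] = 0.5
            return f
        raise ConfigError(f"unknown fixture {name!r}")
    if kind == "population":
        return ids(n)
    if kind == "grid":
        return ids((side, side))
    raise ConfigError(f"unknown fixture kind {kind!r}")


def _strategy(name: str) -> str:
    s = name.split(":", 1)[1]
    if s not in STRATEGY_INDEX:
        raise ConfigError(f"unknown strategy {s!r} in fixture {name!r}")
    return s


def _mixture(name: str):
    parts = name.split(":", 1)[1].split(",")
    if len(parts) != 2:
        raise ConfigError(f"mixture fixture needs two strategies, got {name!r}")
    return tuple(STRATEGY_INDEX[_strategy(f"m:{p.strip()}")] for p in parts)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_trajectory(df: pd.DataFrame, path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(p, index=False)
    return p


def write_report(obj, path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    payload = obj.as_dict() if hasattr(obj, "as_dict") else obj
    p.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    return p


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, complex):
        return {"re": o.real, "im": o.imag}
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_grid(grid: np.ndarray, path, sidecar: dict | None = None) -> Path:
    """Plain-text snapshot: L lines of L space-separated strategy ids,
    with an optional JSON sidecar holding parameters and step number."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(p, np.asarray(grid, dtype=int), fmt="%d")
    if sidecar is not None:
        write_report(sidecar, p.with_suffix(p.suffix + ".json"))
    return p


def read_grid(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int8)
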
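"""Simulation configuration: schema, defaults, validation and YAML round-trip.

A :class:`SimulationConfig` is the full, seedable specification of one run.
``load_config`` reads a YAML file, rejects unknown keys (no silent typos),
fills documented defaults and validates every constraint, naming the
offending key in each error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .model_core import PairUpdateVariant, RefutationContext, TransitionParams
from .population import InitSpec, TopologyParams

__all__ = ["SimulationConfig", "ConfigError", "load_config", "write_config", "config_to_dict"]


class ConfigError(ValueError):
    """Raised for unparseable, unknown or constraint-violating configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one simulation run.

    ``r_sr_override``, when set, replaces the per-contact transmission
    probability w*b*a*v with a fixed level (the network-intimacy experiment
    mode).  All randomness derives from ``seed``.
    """

    n: int = 1000
    days: int = 30
    seed: int = 0
    ctx: RefutationContext = field(default_factory=lambda: RefutationContext(a=0.8, v=0.8))
    transition: TransitionParams = field(
        default_factory=lambda: TransitionParams(
            f_s=0.001, f_r=0.001, lambda_gate=0.25, spreader_active_days=3
        )
    )
    init: InitSpec = field(default_factory=InitSpec)
    topology: TopologyParams = field(default_factory=TopologyParams)
    pair_update_variant: PairUpdateVariant = PairUpdateVariant.CONVERGENT
    r_sr_override: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("n: population size must be at least 2")
        if self.days < 0:
            raise ConfigError("days: horizon must be non-negative")
        if self.r_sr_override is not None and not (0.0 <= self.r_sr_override <= 1.0):
            raise ConfigError("r_sr_override: must lie in [0, 1]")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


_SCHEMA = {
    "n": None,
    "days": None,
    "seed": None,
    "pair_update_variant": None,
    "r_sr_override": None,
    "ctx": {"a", "v"},
    "transition": {"f_s", "f_r", "lambda_gate", "spreader_active_days"},
    "init": {
        "frac_s",
        "frac_r",
        "s_emotion",
        "r_emotion",
        "m_emotion",
        "d_range",
        "w_range",
        "b_range",
    },
    "topology": {
        "mode",
        "radius",
        "graph_kind",
        "k",
        "p",
        "contacts_per_agent_per_day",
    },
}


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {section}: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _tupled(value):
    if isinstance(value, list):
        return tuple(value)
    return value


def config_from_dict(data: dict) -> SimulationConfig:
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys("config", data, _SCHEMA)
    kwargs: dict = {}
    for key in ("n", "days", "seed", "r_sr_override"):
        if key in data and data[key] is not None:
            kwargs[key] = data[key]
    if "pair_update_variant" in data:
        try:
            kwargs["pair_update_variant"] = PairUpdateVariant(data["pair_update_variant"])
        except ValueError:
            raise ConfigError(
                f"pair_update_variant: unknown variant {data['pair_update_variant']!r}; "
                f"expected one of {[v.value for v in PairUpdateVariant]}"
            ) from None
    try:
        if "ctx" in data:
            _check_keys("ctx", data["ctx"], _SCHEMA["ctx"])
            kwargs["ctx"] = RefutationContext(**data["ctx"])
        if "transition" in data:
            _check_keys("transition", data["transition"], _SCHEMA["transition"])
            kwargs["transition"] = TransitionParams(**data["transition"])
        if "init" in data:
            _check_keys("init", data["init"], _SCHEMA["init"])
            init_kwargs = {k: _tupled(v) for k, v in data["init"].items()}
            kwargs["init"] = InitSpec(**init_kwargs)
        if "topology" in data:
            _check_keys("topology", data["topology"], _SCHEMA["topology"])
            kwargs["topology"] = TopologyParams(**data["topology"])
        return SimulationConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: SimulationConfig) -> dict:
    def _plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, PairUpdateVariant):
            return obj.value
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {
        "n": config.n,
        "days": config.days,
        "seed": config.seed,
        "ctx": _plain(config.ctx),
        "transition": _plain(config.transition),
        "init": _plain(config.init),
        "topology": _plain(config.topology),
        "pair_update_variant": config.pair_update_variant.value,
        "r_sr_override": config.r_sr_override,
    }


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}") from exc
    if data is None:
        data = {}
    return config_from_dict(data)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration as YAML; ``load_config`` round-trips it."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False), encoding="utf-8")
    tmp.replace(path)
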
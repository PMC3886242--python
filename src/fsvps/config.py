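"""Flat YAML run configuration mirroring the parameter groups.

Every section maps onto one parameter dataclass; unknown sections or keys are
rejected with the offending name, so a typo never silently falls back to a
default.  All defaults are the reference-protocol values (alpha = 0.98,
lambda = 4, 0.9 threshold coefficient, 1% floor, TR = 1 s, 30 s blocks, 10
discarded repetitions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chain import ChainConfig
from .spectral import FilterConfig
from .types import (
    AcquisitionParams,
    BoldModel,
    ComponentSpec,
    NoiseModel,
    ParameterError,
    SessionDesign,
)

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_DEFAULT_WATER = {"amplitude": 1.0, "frequency": 0.0, "phase": 0.5}
_DEFAULT_CONTAMINANTS = [
    # Lipid-like line well off-water, mostly removed by the Gaussian window.
    {"amplitude": 0.05, "frequency": -180.0, "phase": 0.0, "t2star": 0.03},
]


@dataclass
class RunConfig:
    """Validated bundle of every parameter group plus the seed."""

    seed: int = 0
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    design: SessionDesign = field(default_factory=SessionDesign)
    bold: BoldModel = field(default_factory=BoldModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    filter: FilterConfig = field(default_factory=FilterConfig)
    chain: ChainConfig = field(default_factory=ChainConfig)
    water: dict = field(default_factory=lambda: dict(_DEFAULT_WATER))
    contaminants: list = field(
        default_factory=lambda: [dict(c) for c in _DEFAULT_CONTAMINANTS]
    )

    def water_component(self) -> ComponentSpec:
        return ComponentSpec(t2star=self.bold.baseline_t2star, **self.water)

    def contaminant_components(self) -> list[ComponentSpec]:
        return [ComponentSpec(**c) for c in self.contaminants]

    def noise_with_seed(self) -> NoiseModel:
        return dataclasses.replace(self.noise, rng_seed=self.seed)

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "water": dict(self.water),
            "contaminants": [dict(c) for c in self.contaminants],
        }
        for name in ("acquisition", "bold", "noise", "filter", "chain"):
            out[name] = dataclasses.asdict(getattr(self, name))
        d = self.design
        out["design"] = {
            "tr": d.tr,
            "n_reps": d.n_reps,
            "n_discard": d.n_discard,
            "block_len": d.block_len,
        }
        return out


_SECTION_TYPES = {
    "acquisition": AcquisitionParams,
    "design": SessionDesign,
    "bold": BoldModel,
    "noise": NoiseModel,
    "filter": FilterConfig,
    "chain": ChainConfig,
}


def _build_section(name: str, cls, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    if name == "design":
        allowed.discard("labels")
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {', '.join(sorted(unknown))}")
    try:
        return cls(**data)
    except ParameterError as exc:
        raise ConfigError(f"invalid value in [{name}]: {exc}") from exc


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML config (or the defaults) and validate every group."""
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw = loaded

    known_top = set(_SECTION_TYPES) | {"seed", "water", "contaminants"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")

    kwargs: dict = {}
    for name, cls in _SECTION_TYPES.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"[{name}] must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    if "water" in raw:
        w = dict(raw["water"])
        unknown = set(w) - {"amplitude", "frequency", "phase"}
        if unknown:
            raise ConfigError(f"unknown key(s) in [water]: {', '.join(sorted(unknown))}")
        kwargs["water"] = {**_DEFAULT_WATER, **w}
    if "contaminants" in raw:
        if not isinstance(raw["contaminants"], list):
            raise ConfigError("[contaminants] must be a list")
        for c in raw["contaminants"]:
            unknown = set(c) - {"amplitude", "frequency", "phase", "t2star"}
            if unknown:
                raise ConfigError(
                    f"unknown key(s) in contaminant: {', '.join(sorted(unknown))}"
                )
        kwargs["contaminants"] = [dict(c) for c in raw["contaminants"]]

    cfg = RunConfig(seed=int(raw.get("seed", 0)), **kwargs)
    if seed is not None:
        cfg.seed = int(seed)
    # Exercise the derived constructors so invariant violations surface now.
    try:
        cfg.water_component()
        cfg.contaminant_components()
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg
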
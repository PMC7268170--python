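"""YAML/JSON run configuration: validation, defaults, round-tripping.

A config document has up to five blocks::

    parameters:  {any ModelParameters field: value}
    experiment:  {ne: [...], duration_h: 144, l0: [...], mutant: WT,
                  init_pools: zero, allocation_mode: literal}
    flags:       {preset: L7}  or explicit booleans {basic: true, ...}
    solver:      {rtol: 1e-8, atol: 1e-10, sample_interval_h: 1.0, method: LSODA}
    output:      {directory: ., plot: false}

Unknown keys anywhere are rejected with an error naming the key.  An empty
document yields the defaults: published parameter values, the full model
(preset L7), the wild-type split-root experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .experiments import NE_HIGH, NE_LOW, SPLIT_ROOT_DURATION_H
from .params import ExperimentSpec, LayerFlags, ModelParameters

__all__ = ["ConfigError", "SolverSettings", "OutputSettings", "RunConfig",
           "load_config", "dump_config"]


class ConfigError(ValueError):
    """A configuration document failed validation."""


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_interval_h: float = 1.0
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigError("solver tolerances must be > 0")
        if self.sample_interval_h <= 0:
            raise ConfigError("sample_interval_h must be > 0")


@dataclass(frozen=True)
class OutputSettings:
    directory: str = "."
    plot: bool = False


@dataclass(frozen=True)
class RunConfig:
    parameters: ModelParameters = field(default_factory=ModelParameters)
    experiment: ExperimentSpec = field(
        default_factory=lambda: ExperimentSpec(
            ne=(NE_LOW, NE_HIGH), duration=SPLIT_ROOT_DURATION_H
        )
    )
    solver: SolverSettings = field(default_factory=SolverSettings)
    output: OutputSettings = field(default_factory=OutputSettings)

    def to_dict(self) -> dict:
        """Plain-dict form suitable for YAML serialisation (round-trips)."""
        exp = self.experiment
        d = {
            "parameters": {
                f.name: getattr(self.parameters, f.name)
                for f in fields(ModelParameters)
                if getattr(self.parameters, f.name) is not None
            },
            "experiment": {
                "ne": list(exp.ne),
                "duration_h": exp.duration,
                "l0": list(exp.L0),
                "mutant": exp.mutant,
                "init_pools": exp.init_pools,
                "allocation_mode": exp.allocation_mode,
            },
            "flags": {name: getattr(exp.flags, name)
                      for name in LayerFlags._LADDER},
            "solver": dataclasses.asdict(self.solver),
            "output": dataclasses.asdict(self.output),
        }
        return d


_PARAM_FIELDS = {f.name for f in fields(ModelParameters)}
_EXPERIMENT_KEYS = {"ne", "duration_h", "l0", "mutant", "init_pools",
                    "allocation_mode", "n"}
_FLAG_KEYS = set(LayerFlags._LADDER) | {"preset"}
_SOLVER_KEYS = {f.name for f in fields(SolverSettings)}
_OUTPUT_KEYS = {f.name for f in fields(OutputSettings)}
_BLOCKS = {"parameters", "experiment", "flags", "solver", "output"}


def _reject_unknown(block: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{block}' block: {', '.join(sorted(unknown))}"
        )


def _build_flags(block: dict) -> LayerFlags:
    _reject_unknown("flags", block, _FLAG_KEYS)
    if "preset" in block:
        if len(block) > 1:
            raise ConfigError("flags: give either 'preset' or explicit booleans")
        return LayerFlags.preset(block["preset"])
    try:
        return LayerFlags(**{k: bool(v) for k, v in block.items()})
    except ValueError as err:
        raise ConfigError(f"flags: {err}") from err


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    _reject_unknown("top level", doc, _BLOCKS)

    params_block = doc.get("parameters") or {}
    _reject_unknown("parameters", params_block, _PARAM_FIELDS)
    try:
        parameters = ModelParameters(**params_block)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"parameters: {err}") from err

    flags_block = doc.get("flags") or {}
    flags = LayerFlags.full() if not flags_block else _build_flags(flags_block)

    exp_block = dict(doc.get("experiment") or {})
    _reject_unknown("experiment", exp_block, _EXPERIMENT_KEYS)
    n = exp_block.pop("n", None)
    ne = exp_block.pop("ne", None)
    if ne is None:
        ne = [NE_LOW, NE_HIGH] if n in (None, 2) else [NE_LOW] * int(n)
    elif not isinstance(ne, (list, tuple)):
        ne = [ne]
    if n is not None and int(n) != len(ne):
        raise ConfigError(f"experiment: n={n} but ne has {len(ne)} entries")
    l0 = exp_block.pop("l0", None)
    if l0 is not None and not isinstance(l0, (list, tuple)):
        l0 = [l0] * len(ne)
    try:
        experiment = ExperimentSpec(
            ne=tuple(ne),
            duration=float(exp_block.pop("duration_h", SPLIT_ROOT_DURATION_H)),
            L0=tuple(l0) if l0 is not None else None,
            flags=flags,
            **exp_block,
        )
    except (TypeError, ValueError) as err:
        raise ConfigError(f"experiment: {err}") from err

    solver_block = doc.get("solver") or {}
    _reject_unknown("solver", solver_block, _SOLVER_KEYS)
    solver = SolverSettings(**solver_block)

    output_block = doc.get("output") or {}
    _reject_unknown("output", output_block, _OUTPUT_KEYS)
    output = OutputSettings(**output_block)

    return RunConfig(parameters=parameters, experiment=experiment,
                     solver=solver, output=output)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config as YAML such that ``load_config`` reproduces it."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
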
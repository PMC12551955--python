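"""Run configuration: YAML schema, validation, and assembly of model objects."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import scenarios as scen
from .decision import DecisionProblemSpec, biweekly_mask, weekly_mask
from .dynamics import Network, Node
from .errors import ConfigurationError
from .genetics import InheritanceCube, apply_ridl, mendelian_cube
from .thermal import SpeciesParams, load_species_preset

__all__ = ["RunConfig", "load_config", "build_inputs"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciesConfig(_Strict):
    preset: str | None = None
    custom: dict | None = None

    def build(self) -> SpeciesParams:
        if (self.preset is None) == (self.custom is None):
            raise ConfigurationError("species block needs exactly one of 'preset' or 'custom'")
        if self.preset is not None:
            return load_species_preset(self.preset)
        return SpeciesParams.from_dict(self.custom)


class GeneticsConfig(_Strict):
    mechanism: Literal["ridl", "none"] = "ridl"
    penetrance: float = 1.0
    female_only: bool = False
    release_genotype: str | None = None

    def build(self) -> InheritanceCube:
        cube = mendelian_cube()
        if self.mechanism == "ridl":
            cube = apply_ridl(cube, self.penetrance, female_only=self.female_only)
        return cube


class NodeConfig(_Strict):
    name: str
    K: float
    species: str | None = None  # per-node preset override


class NetworkConfig(_Strict):
    nodes: list[NodeConfig] = Field(min_length=1)
    migration: list[list] = Field(default_factory=list)  # [from, to, rate]


class GenerateEntry(_Strict):
    preset: str | None = None
    seed: int | None = None
    weight: float | None = None
    T_mean: float | None = None
    amplitude: float | None = None
    phase: float | None = None
    warming_offset: float | None = None
    ar1_rho: float | None = None
    daily_sd: float | None = None
    label: str | None = None

    def build(self, default_seed: int) -> scen.ScenarioParams:
        if self.preset is not None:
            p = scen.preset(self.preset)
        else:
            if self.T_mean is None or self.amplitude is None:
                raise ConfigurationError(
                    "generator entry without a preset must give T_mean and amplitude"
                )
            p = scen.ScenarioParams(T_mean=self.T_mean, amplitude=self.amplitude)
        overrides = {
            k: v
            for k, v in {
                "T_mean": self.T_mean,
                "amplitude": self.amplitude,
                "phase": self.phase,
                "warming_offset": self.warming_offset,
                "ar1_rho": self.ar1_rho,
                "daily_sd": self.daily_sd,
                "label": self.label,
            }.items()
            if v is not None
        }
        overrides["seed"] = self.seed if self.seed is not None else default_seed
        from dataclasses import replace

        return replace(p, **overrides)


class ScenariosConfig(_Strict):
    manifest: str | None = None  # CSV (series_file, weight)
    generate: list[GenerateEntry] | None = None
    t_end: int = 365

    def build(self, base_dir: Path, base_seed: int = 0) -> scen.ScenarioSet:
        if (self.manifest is None) == (self.generate is None):
            raise ConfigurationError(
                "scenarios block needs exactly one of 'manifest' or 'generate'"
            )
        if self.manifest is not None:
            from .io import read_scenario_set

            return read_scenario_set(base_dir / self.manifest)
        params = [
            e.build(default_seed=base_seed + i) for i, e in enumerate(self.generate)
        ]
        weights = [e.weight for e in self.generate]
        if all(w is None for w in weights):
            weights = None
        elif any(w is None for w in weights):
            raise ConfigurationError("give weights for all generator entries or none")
        return scen.generate_scenario_set(params, weights, T_end=self.t_end)


class DecisionConfig(_Strict):
    t_end: int = 365
    t_0: int = 200
    psi: float = 0.20
    mask: str | list[int] = "weekly"
    mask_start: int = 1
    c_max: float = 1e5
    budget: float | None = None
    alpha_c: float = 1.0
    alpha_f: float = 1.0
    tracking_window: Literal["from_start_day", "full_horizon"] = "from_start_day"
    n_sub: int = 4
    release_nodes: list[str] | None = None
    release_genotype: str | None = None

    def build(self) -> DecisionProblemSpec:
        if isinstance(self.mask, str):
            if self.mask == "weekly":
                mask = weekly_mask(self.t_end, start=self.mask_start)
            elif self.mask == "biweekly":
                mask = biweekly_mask(self.t_end, start=self.mask_start)
            else:
                raise ConfigurationError(
                    f"mask must be 'weekly', 'biweekly' or a list of days, got {self.mask!r}"
                )
        else:
            mask = tuple(int(d) for d in self.mask)
        return DecisionProblemSpec(
            t_end=self.t_end,
            t_0=self.t_0,
            psi=self.psi,
            release_mask=mask,
            c_max=self.c_max,
            budget=self.budget,
            alpha_c=self.alpha_c,
            alpha_f=self.alpha_f,
            tracking_window=self.tracking_window,
            n_sub=self.n_sub,
            release_nodes=tuple(self.release_nodes) if self.release_nodes else None,
            release_genotype=self.release_genotype,
        )


class SolverConfig(_Strict):
    maxiter: int = 400
    ftol: float = 1e-10
    gtol: float = 1e-8
    fd_step: float | None = None

    def options(self) -> dict:
        out = {"maxiter": self.maxiter, "ftol": self.ftol, "gtol": self.gtol}
        if self.fd_step is not None:
            out["fd_step"] = self.fd_step
        return out


class RunConfig(_Strict):
    species: SpeciesConfig
    genetics: GeneticsConfig = GeneticsConfig()
    network: NetworkConfig
    scenarios: ScenariosConfig
    decision: DecisionConfig = DecisionConfig()
    solver: SolverConfig = SolverConfig()
    output_dir: str = "out"
    log_level: str = "INFO"

    # populated by load_config
    _base_dir: Path = Path(".")
    _raw_text: str = ""

    def build_network(self) -> Network:
        default_species = self.species.build()
        nodes = []
        for nc in self.network.nodes:
            sp = load_species_preset(nc.species) if nc.species else default_species
            nodes.append(Node(name=nc.name, species=sp, K=nc.K))
        names = [n.name for n in nodes]
        mig = np.zeros((len(nodes), len(nodes)))
        for entry in self.network.migration:
            if len(entry) != 3:
                raise ConfigurationError(
                    f"migration entries must be [from, to, rate], got {entry!r}"
                )
            src, dst, rate = entry
            if src not in names or dst not in names:
                raise ConfigurationError(f"migration references unknown node in {entry!r}")
            mig[names.index(src), names.index(dst)] = float(rate)
        return Network(nodes=tuple(nodes), migration=mig)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys and invariant violations raise :class:`ConfigurationError`
    with an aggregated description.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        cfg = RunConfig(**data)
    except ValidationError as err:
        lines = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"]) or "<root>"
            lines.append(f"  {loc}: {e['msg']}")
        raise ConfigurationError(
            "invalid configuration:\n" + "\n".join(lines)
        ) from None
    object.__setattr__(cfg, "_base_dir", path.parent)
    object.__setattr__(cfg, "_raw_text", text)
    return cfg


def build_inputs(cfg: RunConfig, base_seed: int = 0):
    """Assemble (cube, network, scenario_set, spec, solver options) from a config."""
    cube = cfg.genetics.build()
    network = cfg.build_network()
    scenario_set = cfg.scenarios.build(cfg._base_dir, base_seed=base_seed)
    dec = cfg.decision
    if cfg.genetics.release_genotype and dec.release_genotype is None:
        dec = dec.model_copy(update={"release_genotype": cfg.genetics.release_genotype})
    spec = dec.build()
    if scenario_set.horizon < spec.t_end:
        raise ConfigurationError(
            f"scenario horizon {scenario_set.horizon} days does not cover the "
            f"decision horizon {spec.t_end} days"
        )
    return cube, network, scenario_set, spec, cfg.solver.options()
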
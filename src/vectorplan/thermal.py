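"""Temperature-dependent life-history rates.

Each life-history trait (stage development, stage mortality, adult
fecundity) is described by a :class:`ThermalResponse` — a small family of
standard thermal-performance forms — and a species is a bundle of such
responses, one per stage (:class:`SpeciesParams`).  Evaluating the bundle
at a daily temperature yields a :class:`StageRates` record consumed by the
population dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ThermalResponse",
    "StageRates",
    "SpeciesParams",
    "briere_rate",
    "quadratic_rate",
    "linear_rate",
    "stage_rates_at",
    "JUVENILE_STAGES",
    "MORTALITY_STAGES",
]

JUVENILE_STAGES = ("egg", "larva", "pupa")
MORTALITY_STAGES = ("egg", "larva", "pupa", "adult")

_FORMS = ("constant", "linear", "quadratic", "briere")
_N_PARAMS = {"constant": 1, "linear": 2, "quadratic": 3, "briere": 3}


def briere_rate(T, a: float, t_min: float, t_max: float):
    """Brière-1 thermal performance: ``a*T*(T-t_min)*sqrt(t_max-T)``.

    Zero (continuously) outside ``[t_min, t_max]``.  Vectorized in ``T``.
    """
    if t_min >= t_max:
        raise ConfigurationError(
            f"briere: t_min ({t_min}) must be < t_max ({t_max})"
        )
    if a <= 0:
        raise ConfigurationError(f"briere: coefficient a must be > 0, got {a}")
    T = np.asarray(T, dtype=float)
    inside = (T >= t_min) & (T <= t_max)
    root = np.sqrt(np.where(inside, t_max - T, 0.0))
    val = np.where(inside, a * T * (T - t_min) * root, 0.0)
    # T < 0 with T - t_min < 0 could otherwise go negative inside the window
    val = np.maximum(val, 0.0)
    return val if val.ndim else float(val)


def quadratic_rate(T, c: float, t_min: float, t_max: float):
    """Concave quadratic performance ``c*(T-t_min)*(t_max-T)``, clamped at 0 outside."""
    if t_min >= t_max:
        raise ConfigurationError(
            f"quadratic: t_min ({t_min}) must be < t_max ({t_max})"
        )
    T = np.asarray(T, dtype=float)
    val = np.maximum(c * (T - t_min) * (t_max - T), 0.0)
    inside = (T >= t_min) & (T <= t_max)
    val = np.where(inside, val, 0.0)
    return val if val.ndim else float(val)


def linear_rate(T, a: float, b: float):
    """Affine response ``a + b*T``, clamped at 0."""
    T = np.asarray(T, dtype=float)
    val = np.maximum(a + b * T, 0.0)
    return val if val.ndim else float(val)


@dataclass(frozen=True)
class ThermalResponse:
    """One trait's temperature dependence.

    Parameters
    ----------
    form:
        One of ``constant`` (params ``[c]``), ``linear`` (``[a, b]`` for
        ``a + b*T``), ``quadratic`` (``[c, t_min, t_max]``) or ``briere``
        (``[a, t_min, t_max]``).
    params:
        Form-specific coefficients.
    floor:
        Minimum rate (per day) the evaluated response is clamped to;
        must be >= 0.
    """

    form: str
    params: tuple
    floor: float = 0.0

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ConfigurationError(
                f"unknown thermal response form {self.form!r}; expected one of {_FORMS}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if len(self.params) != _N_PARAMS[self.form]:
            raise ConfigurationError(
                f"{self.form} response takes {_N_PARAMS[self.form]} params, "
                f"got {len(self.params)}"
            )
        if self.floor < 0:
            raise ConfigurationError(f"floor must be >= 0, got {self.floor}")
        if self.form in ("quadratic", "briere"):
            _, t_min, t_max = self.params
            if t_min >= t_max:
                raise ConfigurationError(
                    f"{self.form}: t_min ({t_min}) must be < t_max ({t_max})"
                )
        if self.form == "briere" and self.params[0] <= 0:
            raise ConfigurationError("briere: coefficient a must be > 0")

    def __call__(self, T):
        if self.form == "constant":
            T = np.asarray(T, dtype=float)
            raw = np.full_like(T, self.params[0])
            raw = raw if raw.ndim else float(raw)
        elif self.form == "linear":
            raw = linear_rate(T, *self.params)
        elif self.form == "quadratic":
            raw = quadratic_rate(T, *self.params)
        else:
            raw = briere_rate(T, *self.params)
        out = np.maximum(raw, self.floor)
        return out if np.ndim(out) else float(out)

    def to_dict(self) -> dict:
        return {"form": self.form, "params": list(self.params), "floor": self.floor}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThermalResponse":
        extra = set(d) - {"form", "params", "floor", "units"}
        if extra:
            raise ConfigurationError(
                f"unknown keys in thermal response: {sorted(extra)}"
            )
        return cls(d["form"], tuple(d["params"]), float(d.get("floor", 0.0)))


def constant(value: float, floor: float = 0.0) -> ThermalResponse:
    """Convenience constructor for a temperature-independent rate."""
    return ThermalResponse("constant", (value,), floor)


@dataclass(frozen=True)
class StageRates:
    """All rates for one species at one temperature (units: per day)."""

    development: Mapping[str, float]  # egg, larva, pupa
    mortality: Mapping[str, float]  # egg, larva, pupa, adult
    fecundity: float  # eggs / female / day

    def __post_init__(self):
        for name, table in (("development", self.development), ("mortality", self.mortality)):
            for stage, rate in table.items():
                if not np.isfinite(rate) or rate < 0:
                    raise ConfigurationError(
                        f"{name} rate for stage {stage!r} must be finite and >= 0, got {rate}"
                    )
        if not np.isfinite(self.fecundity) or self.fecundity < 0:
            raise ConfigurationError(f"fecundity must be finite and >= 0, got {self.fecundity}")


@dataclass(frozen=True)
class SpeciesParams:
    """Stage-structured life history with per-stage thermal responses."""

    name: str
    development: Mapping[str, ThermalResponse] = field(default_factory=dict)
    mortality: Mapping[str, ThermalResponse] = field(default_factory=dict)
    fecundity: ThermalResponse | None = None

    def __post_init__(self):
        missing = [s for s in JUVENILE_STAGES if s not in self.development]
        if missing:
            raise ConfigurationError(f"species {self.name!r}: missing development response for {missing}")
        missing = [s for s in MORTALITY_STAGES if s not in self.mortality]
        if missing:
            raise ConfigurationError(f"species {self.name!r}: missing mortality response for {missing}")
        if self.fecundity is None:
            raise ConfigurationError(f"species {self.name!r}: missing fecundity response")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "development": {k: v.to_dict() for k, v in self.development.items()},
            "mortality": {k: v.to_dict() for k, v in self.mortality.items()},
            "fecundity": self.fecundity.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpeciesParams":
        return cls(
            name=d["name"],
            development={k: ThermalResponse.from_dict(v) for k, v in d["development"].items()},
            mortality={k: ThermalResponse.from_dict(v) for k, v in d["mortality"].items()},
            fecundity=ThermalResponse.from_dict(d["fecundity"]),
        )


def stage_rates_at(T: float, species: SpeciesParams) -> StageRates:
    """Evaluate every thermal response of ``species`` at temperature ``T`` (°C)."""
    return StageRates(
        development={s: species.development[s](T) for s in JUVENILE_STAGES},
        mortality={s: species.mortality[s](T) for s in MORTALITY_STAGES},
        fecundity=species.fecundity(T),
    )


def available_presets() -> list[str]:
    from importlib import resources

    root = resources.files("vectorplan") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_species_preset(name: str) -> SpeciesParams:
    """Load one of the shipped species parameter files (editable YAML)."""
    from importlib import resources

    import yaml

    path = resources.files("vectorplan") / "presets" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown species preset {name!r}; available: {available_presets()}"
        ) from None
    return SpeciesParams.from_dict(yaml.safe_load(text))
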
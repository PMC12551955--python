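"""Synthetic daily-temperature scenarios.

A scenario is an annual sinusoid plus a warming offset plus seeded AR(1)
daily noise; sets of scenarios carry probability weights.  The generator
stands in for observed / downscaled-projection series so regimes like
"historic vs future" and "median vs high daily variability" can be
emulated without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "TemperatureSeries",
    "ScenarioSet",
    "ScenarioParams",
    "generate_scenario",
    "generate_scenario_set",
    "preset",
    "mean_series",
    "PRESET_NAMES",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily temperatures, 1-based day indexing (``temps[0]`` is day 1)."""

    temps: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.temps, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ConfigurationError("temperature series must be a nonempty 1-D array")
        if not np.all(np.isfinite(t)):
            raise ConfigurationError("temperature series contains non-finite values")
        object.__setattr__(self, "temps", t)

    def __len__(self) -> int:
        return self.temps.size

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)


@dataclass(frozen=True)
class ScenarioSet:
    """Temperature series ``X_1..X_N`` with probability weights ``p_k``."""

    series: tuple[TemperatureSeries, ...]
    weights: np.ndarray

    def __post_init__(self):
        series = tuple(self.series)
        object.__setattr__(self, "series", series)
        w = np.asarray(self.weights, dtype=float)
        if len(series) == 0:
            raise ConfigurationError("scenario set must contain at least one series")
        if w.shape != (len(series),):
            raise ConfigurationError("one weight per series required")
        if np.any(w < 0):
            raise ConfigurationError("scenario weights must be >= 0")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError(f"scenario weights sum to {w.sum()!r}, not 1")
        lengths = {len(s) for s in series}
        if len(lengths) != 1:
            raise ConfigurationError(f"scenario series have unequal lengths {sorted(lengths)}")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.series)

    @property
    def horizon(self) -> int:
        return len(self.series[0])


@dataclass(frozen=True)
class ScenarioParams:
    """Generator parameters: sinusoid + warming offset + AR(1) noise."""

    T_mean: float  # annual mean, °C
    amplitude: float  # seasonal half-range, °C
    phase: float = 0.0  # day offset of the sinusoid
    warming_offset: float = 0.0  # additive shift (future regimes), °C
    ar1_rho: float = 0.0  # daily noise autocorrelation
    daily_sd: float = 0.0  # stationary noise sd, °C
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.daily_sd < 0:
            raise ConfigurationError("daily_sd must be >= 0")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigurationError("ar1_rho must satisfy |rho| < 1 (stationarity)")


def generate_scenario(params: ScenarioParams, T_end: int = 365) -> TemperatureSeries:
    """Seeded synthetic series of length ``T_end``.

    ``temp_t = T_mean + delta + A*sin(2*pi*(t - phase)/365) + e_t`` with
    ``e_t = rho*e_{t-1} + N(0, sd^2*(1 - rho^2))``, ``e_0 = 0``.  The
    innovation variance makes ``sd`` the *stationary* standard deviation
    of the noise.  Identical seed + params give identical output
    (numpy ``default_rng``, fixed algorithm).
    """
    if T_end < 1:
        raise ConfigurationError("T_end must be >= 1")
    t = np.arange(1, T_end + 1, dtype=float)
    base = (
        params.T_mean
        + params.warming_offset
        + params.amplitude * np.sin(2.0 * np.pi * (t - params.phase) / 365.0)
    )
    e = np.zeros(T_end)
    if params.daily_sd > 0:
        rng = np.random.default_rng(params.seed)
        innov_sd = params.daily_sd * np.sqrt(1.0 - params.ar1_rho**2)
        eps = rng.normal(0.0, innov_sd, size=T_end)
        prev = 0.0
        for i in range(T_end):
            prev = params.ar1_rho * prev + eps[i]
            e[i] = prev
    return TemperatureSeries(temps=base + e, label=params.label or f"seed{params.seed}")


def generate_scenario_set(
    param_list: list[ScenarioParams],
    weights=None,
    T_end: int = 365,
) -> ScenarioSet:
    """Generate all series; weights default to uniform, else normalized to 1."""
    if not param_list:
        raise ConfigurationError("param_list must be nonempty")
    n = len(param_list)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ConfigurationError("one weight per scenario required")
        if np.any(w < 0):
            raise ConfigurationError("scenario weights must be >= 0")
        total = w.sum()
        if total <= 0:
            raise ConfigurationError("scenario weights must sum to a positive value")
        if abs(total - 1.0) > _WEIGHT_TOL:
            warnings.warn(
                f"scenario weights sum to {total:g}; renormalizing to 1", stacklevel=2
            )
            w = w / total
    series = tuple(generate_scenario(p, T_end) for p in param_list)
    return ScenarioSet(series=series, weights=w)


_PRESETS = {
    # tropical-coastal defaults; "future" adds a warming offset, "high"
    # doubles the daily variability.  Editable documentation-level values.
    "historic_median": ScenarioParams(
        T_mean=27.0, amplitude=3.0, phase=105.0, warming_offset=0.0,
        ar1_rho=0.6, daily_sd=1.1, label="historic_median",
    ),
    "historic_high": ScenarioParams(
        T_mean=27.0, amplitude=3.0, phase=105.0, warming_offset=0.0,
        ar1_rho=0.6, daily_sd=2.2, label="historic_high",
    ),
    "future_median": ScenarioParams(
        T_mean=27.0, amplitude=3.0, phase=105.0, warming_offset=1.8,
        ar1_rho=0.6, daily_sd=1.1, label="future_median",
    ),
    "future_high": ScenarioParams(
        T_mean=27.0, amplitude=3.0, phase=105.0, warming_offset=1.8,
        ar1_rho=0.6, daily_sd=2.2, label="future_high",
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> ScenarioParams:
    """Named regime defaults: {historic, future} x {median, high} variability."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown scenario preset {name!r}; known: {PRESET_NAMES}") from None


def with_seed(params: ScenarioParams, seed: int) -> ScenarioParams:
    return replace(params, seed=seed)


def mean_series(scenario_set: ScenarioSet) -> TemperatureSeries:
    """Pointwise probability-weighted mean of the set's series."""
    stacked = np.stack([s.temps for s in scenario_set.series])
    return TemperatureSeries(
        temps=scenario_set.weights @ stacked, label="weighted_mean"
    )
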
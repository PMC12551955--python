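"""File formats: temperature / schedule / trajectory CSVs, manifests.

All CSVs use '.' decimal, comma separators and a header row; floats are
written with ``%.17g`` so write -> read round-trips to better than 1e-12.
Day indexing is 1-based everywhere.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import ReleaseEvent, ReleaseSchedule, StateLayout, Trajectory
from .errors import ConfigurationError
from .scenarios import ScenarioSet, TemperatureSeries

__all__ = [
    "read_temperature_csv",
    "write_temperature_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_scenario_set",
    "read_scenario_set",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"
_STAGE_ORDER = ("egg", "larva", "pupa", "male", "female")


def _write_df(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- temperature -------------------------------------------------------------


def write_temperature_csv(path, series: TemperatureSeries) -> None:
    _write_df(pd.DataFrame({"day": series.days, "temp_C": series.temps}), path)


def read_temperature_csv(path, t_end: int | None = None) -> TemperatureSeries:
    df = pd.read_csv(path)
    expected = ["day", "temp_C"]
    if list(df.columns) != expected:
        raise ConfigurationError(
            f"{path}: temperature CSV must have columns {expected}, got {list(df.columns)}"
        )
    days = df["day"].to_numpy()
    if not np.array_equal(days, np.arange(1, len(days) + 1)):
        raise ConfigurationError(
            f"{path}: temperature CSV must have exactly one row per day 1..N"
        )
    if t_end is not None and len(days) != t_end:
        raise ConfigurationError(
            f"{path}: expected {t_end} days of temperature, found {len(days)}"
        )
    return TemperatureSeries(temps=df["temp_C"].to_numpy(dtype=float), label=Path(path).stem)


# -- schedules ---------------------------------------------------------------


def write_schedule_csv(path, schedule: ReleaseSchedule, round_counts: bool = True) -> None:
    """Write a release schedule; counts are rounded to whole organisms by
    default (pass ``round_counts=False`` to keep raw solver values)."""
    rows = [
        {
            "day": e.day,
            "node": e.node,
            "genotype": e.genotype,
            "count": round(e.count) if round_counts else e.count,
        }
        for e in schedule.entries
    ]
    df = pd.DataFrame(rows, columns=["day", "node", "genotype", "count"])
    _write_df(df, path)


def read_schedule_csv(path, horizon: int) -> ReleaseSchedule:
    df = pd.read_csv(path)
    expected = ["day", "node", "genotype", "count"]
    if list(df.columns) != expected:
        raise ConfigurationError(
            f"{path}: schedule CSV must have columns {expected}, got {list(df.columns)}"
        )
    entries = tuple(
        ReleaseEvent(day=int(r.day), node=str(r.node), genotype=str(r.genotype), count=float(r.count))
        for r in df.itertuples()
    )
    return ReleaseSchedule(entries=entries, horizon=horizon)


# -- trajectories ------------------------------------------------------------


def write_trajectory_csv(path, traj: Trajectory) -> None:
    """Tidy format: (day, node, stage, genotype_female, genotype_male_or_NA, count).

    Juvenile and male rows carry the genotype in ``genotype_female`` and NA
    in ``genotype_male_or_NA``; female rows carry both own and mate genotype.
    """
    lay = traj.layout
    G = lay.G
    labels = traj.genotype_labels
    recs = []
    for ti, day in enumerate(traj.days):
        for ni, node in enumerate(traj.node_names):
            x = traj.states[ti, ni]
            for stage, sl in (("egg", lay.E), ("larva", lay.L), ("pupa", lay.P), ("male", lay.M)):
                for g in range(G):
                    recs.append((int(day), node, stage, labels[g], "", x[sl][g]))
            F = x[lay.F].reshape(G, G)
            for gf in range(G):
                for gm in range(G):
                    recs.append((int(day), node, "female", labels[gf], labels[gm], F[gf, gm]))
    df = pd.DataFrame(
        recs,
        columns=["day", "node", "stage", "genotype_female", "genotype_male_or_NA", "count"],
    )
    _write_df(df, path)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path, keep_default_na=False)
    days = np.sort(df["day"].unique())
    nodes = tuple(dict.fromkeys(df["node"].astype(str)))
    juvenile = df[df["stage"] != "female"]
    labels = tuple(dict.fromkeys(juvenile["genotype_female"].astype(str)))
    G = len(labels)
    lay = StateLayout(G)
    gi = {g: i for i, g in enumerate(labels)}
    ni = {n: i for i, n in enumerate(nodes)}
    di = {int(d): i for i, d in enumerate(days)}
    stage_slice = {"egg": lay.E, "larva": lay.L, "pupa": lay.P, "male": lay.M}
    states = np.zeros((len(days), len(nodes), lay.n))
    for r in df.itertuples():
        t, n = di[int(r.day)], ni[str(r.node)]
        if r.stage == "female":
            idx = lay.F.start + gi[str(r.genotype_female)] * G + gi[str(r.genotype_male_or_NA)]
        else:
            idx = stage_slice[r.stage].start + gi[str(r.genotype_female)]
        states[t, n, idx] = float(r.count)
    return Trajectory(
        days=days.astype(int),
        states=states,
        node_names=nodes,
        genotype_labels=labels,
        meta={"mode": "csv", "source": str(path)},
    )


# -- scenario sets -----------------------------------------------------------


def write_scenario_set(out_dir, scenario_set: ScenarioSet) -> Path:
    """One CSV per series plus a ``scenario_manifest.csv`` (series_file, weight)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (series, w) in enumerate(zip(scenario_set.series, scenario_set.weights)):
        stem = series.label or f"scenario_{i}"
        fname = f"{stem}.csv"
        write_temperature_csv(out_dir / fname, series)
        rows.append({"series_file": fname, "weight": w})
    manifest = out_dir / "scenario_manifest.csv"
    _write_df(pd.DataFrame(rows, columns=["series_file", "weight"]), manifest)
    return manifest


def read_scenario_set(manifest_path) -> ScenarioSet:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    expected = ["series_file", "weight"]
    if list(df.columns) != expected:
        raise ConfigurationError(
            f"{manifest_path}: scenario manifest must have columns {expected}"
        )
    series = tuple(
        read_temperature_csv(manifest_path.parent / f) for f in df["series_file"]
    )
    return ScenarioSet(series=series, weights=df["weight"].to_numpy(dtype=float))


# -- run manifest ------------------------------------------------------------


def write_manifest(out_dir, config_text: str, seed: int | None = None, extra: dict | None = None) -> Path:
    """Provenance record: config hash, seed, package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "vectorplan",
        "version": __version__,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
    }
    payload.update(extra or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
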
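"""Readers and writers: parameter files, scenarios, datasets, trajectories.

Configuration uses YAML (JSON is a YAML subset and therefore accepted);
tabular data uses UTF-8 CSV with a header row and '.' decimal separator.
Times are days from scenario start.  On load, parameter files are validated
as a whole (every violation is reported, not just the first), derived
constants are recomputed, and any stored derived values are cross-checked
against the recomputed ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationError, TimeSeriesDataset
from .engine import Trajectory
from .erythropoiesis import ChemoSchedule
from .interventions import (EpoDose, IvIronDose, OralIronCourse, Phlebotomy,
                            Scenario)
from .parameters import (CellKineticParams, EpoPkParams, IronParams,
                         ParameterError, ParameterSet, ReferenceValues,
                         RegulatorWeights, SigmoidBank, SigmoidParams,
                         UnitBridges)

_SIGMOID_KEYS = ("v_min", "v_max", "v_nor", "b")
_GROUP_TYPES = {
    "sigmoids": SigmoidBank,
    "weights": RegulatorWeights,
    "iron": IronParams,
    "references": ReferenceValues,
    "cells": CellKineticParams,
    "epo": EpoPkParams,
    "bridges": UnitBridges,
}
_DERIVED_CHECK_TOL = 1e-8


class SchemaError(ParameterError):
    """Configuration file does not match the expected schema."""


# ---------------------------------------------------------------------------
# parameters


def parameters_to_dict(params: ParameterSet, include_derived: bool = True) -> dict:
    out: dict[str, Any] = {}
    for group, typ in _GROUP_TYPES.items():
        obj = getattr(params, group)
        d: dict[str, Any] = {}
        for f in fields(obj):
            val = getattr(obj, f.name)
            if isinstance(val, SigmoidParams):
                d[f.name] = {k: float(getattr(val, k)) for k in _SIGMOID_KEYS}
            elif isinstance(val, int):
                d[f.name] = val
            else:
                d[f.name] = float(val)
        out[group] = d
    if include_derived and params.derived is not None:
        out["derived"] = dataclasses.asdict(params.derived)
    return out


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter file (YAML) including the derived constants for
    cross-checking on load."""
    Path(path).write_text(
        yaml.safe_dump(parameters_to_dict(params), sort_keys=False))


def read_parameters(path: str | Path) -> ParameterSet:
    """Load, validate and finalise a parameter file.

    Unknown keys, missing sections and inadmissible values are collected
    and reported together.  Derived constants are always recomputed; stored
    values that disagree with the recomputed ones are an error.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: parameter file must be a mapping")
    errs: list[str] = []
    groups: dict[str, Any] = {}
    stored_derived = raw.pop("derived", None)
    for key in raw:
        if key not in _GROUP_TYPES:
            errs.append(f"unknown section {key!r}")
    for group, typ in _GROUP_TYPES.items():
        section = raw.get(group)
        if section is None:
            errs.append(f"missing section {group!r}")
            continue
        field_names = {f.name for f in fields(typ)}
        kwargs: dict[str, Any] = {}
        for key, val in section.items():
            if key not in field_names:
                errs.append(f"{group}: unknown key {key!r}")
            elif group == "sigmoids":
                if not isinstance(val, dict) or set(val) != set(_SIGMOID_KEYS):
                    errs.append(f"sigmoids.{key}: expected keys {_SIGMOID_KEYS}")
                else:
                    kwargs[key] = SigmoidParams(**{k: float(val[k]) for k in _SIGMOID_KEYS})
            elif key == "n_ages":
                kwargs[key] = int(val)
            else:
                try:
                    kwargs[key] = float(val)
                except (TypeError, ValueError):
                    errs.append(f"{group}.{key}: not a number ({val!r})")
        try:
            groups[group] = typ(**kwargs)
        except TypeError as exc:
            errs.append(f"{group}: {exc}")
    if errs:
        raise SchemaError("invalid parameter file:\n  " + "\n  ".join(errs))
    params = ParameterSet(**groups)
    errs = params.check()
    if errs:
        raise SchemaError("invalid parameter file:\n  " + "\n  ".join(errs))
    params = params.finalize()
    if stored_derived:
        recomputed = dataclasses.asdict(params.derived)
        for key, val in stored_derived.items():
            if key not in recomputed:
                raise SchemaError(f"derived: unknown key {key!r}")
            if abs(float(val) - recomputed[key]) > _DERIVED_CHECK_TOL * max(
                    1.0, abs(recomputed[key])):
                raise SchemaError(
                    f"stored derived constant {key} = {val} disagrees with "
                    f"recomputed value {recomputed[key]!r}")
    return params


def default_parameter_path() -> Path:
    """Path of the parameter file shipped with the package."""
    return Path(__file__).parent / "data" / "default_params.yaml"


# ---------------------------------------------------------------------------
# scenarios


def scenario_to_dict(scenario: Scenario) -> dict:
    out: dict[str, Any] = {"label": scenario.label, "horizon": scenario.horizon}
    if scenario.iron_iv:
        out["iron_iv"] = [{"time": d.time, "dose_mg": d.dose_mg}
                          for d in scenario.iron_iv]
    if scenario.iron_oral:
        out["iron_oral"] = [{"start": c.start, "end": c.end, "dose_mg": c.dose_mg,
                             "times_per_day": c.times_per_day}
                            for c in scenario.iron_oral]
    if scenario.epo:
        out["epo"] = [{"time": e.time, "dose": e.dose, "unit": e.unit,
                       "route": e.route} for e in scenario.epo]
    if scenario.phlebotomies:
        out["phlebotomies"] = [{"time": p.time, "fraction": p.fraction}
                               for p in scenario.phlebotomies]
    for key in ("diet_factor", "hep_inflammation", "hep_production_factor"):
        val = getattr(scenario, key)
        if val != getattr(Scenario, key):
            out[key] = val
    if scenario.oral_pulse_width != Scenario.oral_pulse_width:
        out["oral_pulse_width"] = scenario.oral_pulse_width
    if scenario.chemo is not None:
        out["chemo"] = {"times": list(scenario.chemo.times),
                        "kill_rate": scenario.chemo.kill_rate,
                        "window": scenario.chemo.window,
                        "delay": scenario.chemo.delay}
    return out


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))


def read_scenario(path: str | Path) -> Scenario:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: scenario file must be a mapping")
    known = {"label", "horizon", "iron_iv", "iron_oral", "epo", "phlebotomies",
             "diet_factor", "hep_inflammation", "hep_production_factor",
             "chemo", "oral_pulse_width"}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"scenario: unknown keys {sorted(unknown)}")
    try:
        kwargs: dict[str, Any] = {
            "label": str(raw.get("label", Path(path).stem)),
            "horizon": float(raw["horizon"]),
            "iron_iv": tuple(IvIronDose(float(d["time"]), float(d["dose_mg"]))
                             for d in raw.get("iron_iv", [])),
            "iron_oral": tuple(
                OralIronCourse(float(c["start"]), float(c["end"]),
                               float(c["dose_mg"]), int(c.get("times_per_day", 1)))
                for c in raw.get("iron_oral", [])),
            "epo": tuple(EpoDose(float(e["time"]), float(e["dose"]),
                                 e.get("unit", "iu_per_kg"), e.get("route", "sc"))
                         for e in raw.get("epo", [])),
            "phlebotomies": tuple(Phlebotomy(float(p["time"]), float(p["fraction"]))
                                  for p in raw.get("phlebotomies", [])),
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"scenario: malformed entry ({exc})") from exc
    for key in ("diet_factor", "hep_inflammation", "hep_production_factor",
                "oral_pulse_width"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "chemo" in raw and raw["chemo"] is not None:
        c = raw["chemo"]
        kwargs["chemo"] = ChemoSchedule(
            times=tuple(float(t) for t in c["times"]),
            kill_rate=float(c["kill_rate"]),
            window=float(c.get("window", 4.0)),
            delay=float(c.get("delay", 1.0)))
    return Scenario(**kwargs)


# ---------------------------------------------------------------------------
# time-series datasets and trajectories


def read_timeseries(path: str | Path) -> list[TimeSeriesDataset]:
    """Read a long-format dataset CSV with columns time_days, observable,
    value and optional sd; returns one dataset per observable.

    Unsorted or duplicate times and nonpositive values are reported with
    their (1-based, header-inclusive) row number.
    """
    frame = pd.read_csv(path)
    required = {"time_days", "observable", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise CalibrationError(f"{path}: missing columns {sorted(missing)}")
    has_sd = "sd" in frame.columns
    out = []
    for name, g in frame.groupby("observable", sort=True):
        rows = g.index.to_numpy() + 2  # 1-based with header row
        t = g["time_days"].to_numpy(dtype=float)
        v = g["value"].to_numpy(dtype=float)
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise CalibrationError(
                f"{path}: times for {name!r} not strictly increasing at row "
                f"{rows[bad[0] + 1]}")
        nonpos = np.where(v <= 0)[0]
        if nonpos.size:
            raise CalibrationError(
                f"{path}: nonpositive value for {name!r} at row {rows[nonpos[0]]}")
        sd = g["sd"].to_numpy(dtype=float) if has_sd else None
        if sd is not None and np.all(np.isnan(sd)):
            sd = None
        out.append(TimeSeriesDataset(observable=str(name), times=t, values=v, sd=sd))
    if not out:
        raise CalibrationError(f"{path}: no data rows")
    return out


def write_timeseries(datasets: list[TimeSeriesDataset], path: str | Path) -> None:
    frames = []
    for ds in datasets:
        f = pd.DataFrame({"time_days": ds.times, "observable": ds.observable,
                          "value": ds.values})
        f["sd"] = ds.sd if ds.sd is not None else np.nan
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the observables of a trajectory as long-format CSV
    (time_days, variable, value)."""
    traj.to_long_frame().to_csv(path, index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back into a wide observable DataFrame indexed
    by time."""
    long = pd.read_csv(path)
    required = {"time_days", "variable", "value"}
    missing = required - set(long.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return long.pivot(index="time_days", columns="variable", values="value")
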
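"""CSV/JSON readers and writers for the pipeline's data structures.

Formats (comma-separated, UTF-8, "." decimal):

* binned observations — header of half-open slot intervals ``lo:hi``
  (optionally preceded by a ``period`` column), one row of integer hit
  counts per 31-day registration period;
* binned distribution — columns ``slot_lo, slot_hi, mass``;
* observation table — columns ``patient_id, visit_time_days, value``;
* simulation config and fit results — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evolution import BinnedDistribution
from .fitting import FitResult
from .synthetic_data import BinnedObservations, SimulationConfig

__all__ = [
    "read_binned_observations",
    "write_binned_observations",
    "read_distribution",
    "write_distribution",
    "read_observation_table",
    "write_observation_table",
    "read_simulation_config",
    "write_fit_result",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending cell."""


def _parse_interval(text: str, col: int) -> tuple[float, float]:
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ParseError(
            f"header column {col}: expected 'lo:hi' interval, got {text!r}"
        )
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ParseError(f"header column {col}: non-numeric bound in {text!r}") from exc


def read_binned_observations(path: str | Path) -> BinnedObservations:
    """Read per-period slot hit counts; validates edges, counts and shape."""
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    start = 1 if cols and cols[0].strip().lower() == "period" else 0
    interval_cols = cols[start:]
    if not interval_cols:
        raise ParseError(f"{path}: no slot-interval columns found")
    bounds = [_parse_interval(c, i + start) for i, c in enumerate(interval_cols)]
    edges = [bounds[0][0]] + [hi for _, hi in bounds]
    for i in range(len(bounds) - 1):
        if bounds[i][1] != bounds[i + 1][0]:
            raise ParseError(
                f"header column {i + start + 1}: slots not contiguous "
                f"({bounds[i][1]} != {bounds[i + 1][0]})"
            )
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ParseError(f"{path}: slot edges are not strictly increasing")

    counts = np.zeros((len(df), len(interval_cols)), dtype=np.int64)
    for r in range(len(df)):
        for c, col in enumerate(interval_cols):
            cell = df.iloc[r][col]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ParseError(f"row {r}, column {c + start}: missing count")
            try:
                val = int(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"row {r}, column {c + start}: non-integer count {cell!r}"
                ) from exc
            if val < 0:
                raise ParseError(f"row {r}, column {c + start}: negative count {val}")
            counts[r, c] = val
    return BinnedObservations(slot_edges=edges, counts=counts)


def write_binned_observations(obs: BinnedObservations, path: str | Path) -> None:
    header = ["period"] + [
        f"{lo:g}:{hi:g}" for lo, hi in zip(obs.slot_edges[:-1], obs.slot_edges[1:])
    ]
    rows = [[p] + list(map(int, row)) for p, row in enumerate(obs.counts)]
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)


def read_distribution(path: str | Path) -> BinnedDistribution:
    df = pd.read_csv(path)
    for col in ("slot_lo", "slot_hi", "mass"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    edges = np.concatenate([df["slot_lo"].to_numpy(float), [float(df["slot_hi"].iloc[-1])]])
    if not np.allclose(df["slot_hi"].to_numpy(float), edges[1:]):
        raise ParseError(f"{path}: slot_lo/slot_hi columns are not contiguous")
    return BinnedDistribution(slot_edges=edges, masses=df["mass"].to_numpy(float))


def write_distribution(dist: BinnedDistribution, path: str | Path) -> None:
    pd.DataFrame(
        {
            "slot_lo": dist.slot_edges[:-1],
            "slot_hi": dist.slot_edges[1:],
            "mass": dist.masses,
        }
    ).to_csv(path, index=False)


def read_observation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("patient_id", "visit_time_days", "value"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if not np.isfinite(df["value"].to_numpy(float)).all():
        raise ParseError(f"{path}: non-finite measurement values")
    return df


def write_observation_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from JSON.

    ``baseline_masses`` (with ``slot_edges``) optionally overrides the
    default baseline distribution.
    """
    with open(path) as fh:
        raw = json.load(fh)
    baseline = None
    masses = raw.pop("baseline_masses", None)
    if "slot_edges" in raw:
        raw["slot_edges"] = np.asarray(raw["slot_edges"], dtype=float)
    if masses is not None:
        edges = raw.get("slot_edges")
        if edges is None:
            from .synthetic_data import DEFAULT_SLOT_EDGES

            edges = DEFAULT_SLOT_EDGES
        baseline = BinnedDistribution(slot_edges=edges, masses=np.asarray(masses, float))
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return SimulationConfig(baseline_dist=baseline, **raw)


def write_fit_result(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(result.to_json() + "\n")
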
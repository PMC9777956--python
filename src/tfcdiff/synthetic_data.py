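"""Synthetic cohorts with subdiffusive latent dynamics.

The clinical dataset the model was designed for (605 heart-failure
patients, 2860 thoracic-fluid-content measurements at irregular visit
times over up to 12 months, binned into 15 value slots per 31-day
registration period) is not publicly deposited.  This module generates
cohorts with the same statistical structure so the full pipeline is
testable end to end:

* each patient's latent TFC value follows an uncoupled continuous-time
  random walk (CTRW): Pareto-tailed waiting times with exponent
  ``ctrw_alpha`` alternate with Gaussian jumps, the renewal process whose
  hydrodynamic limit is the fractional Fokker-Planck equation;
* visits arrive as a Poisson count per patient (floored at one) at times
  uniform over the follow-up, sampling the latent value at the most
  recent renewal;
* measurements are accumulated into half-open value slots per 31-day
  registration period.

Reproducibility: one root seed; each patient's stream is derived from
``(seed, patient_id)`` so enlarging the cohort never reshuffles existing
patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .evolution import BinnedDistribution

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "BinnedObservations",
    "default_baseline",
    "sample_waiting_times",
    "simulate_trajectory",
    "simulate_cohort",
    "bin_observations",
    "empirical_msd",
]

#: Default 15 equal-width slots over a plausible TFC value range.  The
#: slot layout is configuration, not science: the clinical study never
#: published its edges.
DEFAULT_SLOT_EDGES = np.linspace(20.0, 80.0, 16)


def default_baseline(slot_edges: np.ndarray | None = None) -> BinnedDistribution:
    """Baseline distribution of patient initial values.

    A discretized normal (mean 40, sd 8 value units) over the slots: most
    patients sit in the lower-middle of the observable range, with the
    upper tail representing fluid-overloaded presentations.
    """
    edges = DEFAULT_SLOT_EDGES if slot_edges is None else np.asarray(slot_edges, float)
    cdf = stats.norm.cdf(edges, loc=40.0, scale=8.0)
    masses = np.diff(cdf)
    return BinnedDistribution(slot_edges=edges, masses=masses / masses.sum())


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation parameters.

    Defaults emulate the clinical registration protocol: 605 patients
    followed for up to 12 months (372 days), a mean of 2860/605 visits per
    patient (so the expected total measurement count matches the study),
    15 value slots, 31-day registration periods and a 5-period window.
    ``ctrw_alpha`` defaults to 0.47, the subdiffusion exponent the model
    ultimately estimates from the clinical data; ``jump_scale`` and
    ``waiting_scale`` are chosen so that slot-crossing excursions are
    common within one registration period.
    """

    n_patients: int = 605
    follow_up_days: int = 372
    visit_rate: float = 2860.0 / 605.0
    ctrw_alpha: float = 0.47
    jump_scale: float = 3.0
    waiting_scale: float = 2.0
    baseline_dist: BinnedDistribution | None = None
    slot_edges: np.ndarray = field(default_factory=lambda: DEFAULT_SLOT_EDGES.copy())
    period_length_days: float = 31.0
    n_periods: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.follow_up_days < 1 or self.n_periods < 1:
            raise ValueError("n_patients, follow_up_days and n_periods must be >= 1")
        if not (self.visit_rate > 0):
            raise ValueError("visit_rate must be positive")
        if not (0.0 < self.ctrw_alpha < 2.0):
            raise ValueError(f"ctrw_alpha must be in (0, 2), got {self.ctrw_alpha!r}")
        if self.jump_scale < 0 or not (self.waiting_scale > 0):
            raise ValueError("jump_scale must be >= 0 and waiting_scale > 0")
        edges = np.asarray(self.slot_edges, dtype=float)
        object.__setattr__(self, "slot_edges", edges)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("slot_edges must be strictly increasing")
        if not (self.period_length_days > 0):
            raise ValueError("period_length_days must be positive")

    def baseline(self) -> BinnedDistribution:
        if self.baseline_dist is not None:
            return self.baseline_dist
        return default_baseline(self.slot_edges)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Trajectory:
    """Latent CTRW path: renewal times (days) and the value after each renewal."""

    times: np.ndarray
    values: np.ndarray
    follow_up_days: float = math.inf

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if times.size and (times[0] < 0 or (np.diff(times) <= 0).any()):
            raise ValueError("times must be nonnegative and strictly increasing")

    def value_at(self, t: float | np.ndarray) -> np.ndarray:
        """Value held at time t: the value set at the last renewal <= t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.values[np.clip(idx, 0, None)]


@dataclass(frozen=True)
class BinnedObservations:
    """Hit counts per value slot per registration period (rows = periods)."""

    slot_edges: np.ndarray
    counts: np.ndarray
    period_length_days: float = 31.0
    n_overflow: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.slot_edges, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "slot_edges", edges)
        object.__setattr__(self, "counts", counts)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("slot edges must be strictly increasing")
        if counts.ndim != 2 or counts.shape[1] != edges.size - 1:
            raise ValueError(
                f"counts must be (n_periods, {edges.size - 1}), got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_periods(self) -> int:
        return self.counts.shape[0]


def sample_waiting_times(
    alpha: float, scale: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. Pareto-tailed waiting times w = scale * u^(-1/alpha).

    Survival P(W > w) = (w / scale)^(-alpha) for w >= scale.  For
    alpha <= 1 the mean waiting time diverges, the regime that produces
    subdiffusive (t^alpha) growth of the walk's mean squared displacement.
    """
    if not (0.0 < alpha < 2.0):
        raise ValueError(f"alpha must be in (0, 2), got {alpha!r}")
    if not (scale > 0.0):
        raise ValueError(f"scale must be positive, got {scale!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.uniform(size=n)
    return scale * u ** (-1.0 / alpha)


def simulate_trajectory(
    cfg: SimulationConfig, start_value: float, rng: np.random.Generator
) -> Trajectory:
    """Simulate one latent CTRW path up to the follow-up horizon.

    Pareto waits alternate with Gaussian jumps (mean 0, sd ``jump_scale``);
    the value is recorded at each renewal and held constant in between.
    """
    horizon = float(cfg.follow_up_days)
    times = [0.0]
    block = 256
    t_acc: list[np.ndarray] = []
    last = 0.0
    while last < horizon:
        waits = sample_waiting_times(cfg.ctrw_alpha, cfg.waiting_scale, block, rng)
        cum = last + np.cumsum(waits)
        t_acc.append(cum)
        last = float(cum[-1])
    renewals = np.concatenate(t_acc)
    renewals = renewals[renewals <= horizon]
    n_jumps = renewals.size
    jumps = rng.normal(0.0, cfg.jump_scale, size=n_jumps) if n_jumps else np.empty(0)
    values = start_value + np.concatenate([[0.0], np.cumsum(jumps)])
    return Trajectory(
        times=np.concatenate([[0.0], renewals]),
        values=values,
        follow_up_days=horizon,
    )


def _draw_start_value(baseline: BinnedDistribution, rng: np.random.Generator) -> float:
    slot = rng.choice(baseline.n_slots, p=baseline.masses)
    lo, hi = baseline.slot_edges[slot], baseline.slot_edges[slot + 1]
    return float(rng.uniform(lo, hi))


def simulate_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Generate an observation table (patient_id, visit_time_days, value).

    Each patient draws an initial value from the baseline distribution
    (uniform within the chosen slot), a Poisson visit count (floored at 1)
    and uniform visit times, then samples their latent CTRW at each visit.
    """
    baseline = cfg.baseline()
    records: list[tuple[int, float, float]] = []
    for pid in range(1, cfg.n_patients + 1):
        rng = np.random.default_rng([cfg.seed, pid])
        start = _draw_start_value(baseline, rng)
        n_visits = max(1, int(rng.poisson(cfg.visit_rate)))
        visit_times = np.sort(rng.uniform(0.0, cfg.follow_up_days, size=n_visits))
        traj = simulate_trajectory(cfg, start, rng)
        values = traj.value_at(visit_times)
        records.extend(
            (pid, float(tv), float(v)) for tv, v in zip(visit_times, values)
        )
    return pd.DataFrame.from_records(
        records, columns=["patient_id", "visit_time_days", "value"]
    )


def bin_observations(
    table: pd.DataFrame,
    edges: np.ndarray | None = None,
    period_length_days: float = 31.0,
    n_periods: int = 5,
) -> BinnedObservations:
    """Accumulate observation records into per-period slot hit counts.

    Slots are half-open ``[lo, hi)`` with the last slot closed above; a
    value exactly on an interior edge belongs to the upper slot.  Records
    beyond the registration window are ignored; in-window values outside
    the slot range are excluded and reported via ``n_overflow``.
    """
    edges = DEFAULT_SLOT_EDGES if edges is None else np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be strictly increasing")
    t = table["visit_time_days"].to_numpy(dtype=float)
    v = table["value"].to_numpy(dtype=float)
    in_window = (t >= 0) & (t < n_periods * period_length_days)
    t, v = t[in_window], v[in_window]
    in_range = (v >= edges[0]) & (v <= edges[-1])
    n_overflow = int((~in_range).sum())
    t, v = t[in_range], v[in_range]
    period = np.floor(t / period_length_days).astype(int)
    slot = np.searchsorted(edges, v, side="right") - 1
    slot = np.minimum(slot, edges.size - 2)  # last slot closed above
    counts = np.zeros((n_periods, edges.size - 1), dtype=np.int64)
    np.add.at(counts, (period, slot), 1)
    return BinnedObservations(
        slot_edges=edges,
        counts=counts,
        period_length_days=period_length_days,
        n_overflow=n_overflow,
    )


def empirical_msd(trajectories: list[Trajectory], t_grid: np.ndarray) -> np.ndarray:
    """Ensemble-averaged squared displacement (x(t) - x(0))^2 at each t."""
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    t_grid = np.asarray(t_grid, dtype=float)
    horizon = max(traj.follow_up_days if math.isfinite(traj.follow_up_days)
                  else traj.times[-1] for traj in trajectories)
    if (t_grid > horizon).any():
        raise ValueError(f"t beyond all follow-ups (max {horizon})")
    acc = np.zeros(t_grid.size)
    for traj in trajectories:
        disp = traj.value_at(t_grid) - traj.values[0]
        acc += disp * disp
    return acc / len(trajectories)
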
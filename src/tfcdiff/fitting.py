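"""Estimation of the subdiffusion parameters (alpha, K_alpha).

The model is fit exactly the way the clinical analysis scores it: take an
initial binned distribution (the pooled stationary estimate, or the first
registration period), evolve it with the FFPE propagator to the
observation horizon, and minimize the root-mean-square error (RMSE)
between modelled and observed slot masses over a coarse (alpha, K) grid,
optionally polished by a Nelder-Mead simplex.  The headline summary of a
fit is the Hurst exponent H = alpha/2: H = 1/2 is ordinary diffusion,
H < 1/2 signals a "fat-tailed" subdiffusive process in which large sudden
excursions of the monitored parameter are to be expected.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .evolution import BinnedDistribution, evolve_distribution, stationary_estimate
from .propagator import (
    AdmissibilityReport,
    FractionalParams,
    SeriesSettings,
    check_admissibility,
)

__all__ = ["FitConfig", "FitResult", "rmse", "hurst", "fit_distributions", "fit_params"]

logger = logging.getLogger(__name__)


def rmse(model: BinnedDistribution, observed: BinnedDistribution) -> float:
    """Root-mean-square error between two distributions' slot masses."""
    if model.slot_edges.size != observed.slot_edges.size or not np.allclose(
        model.slot_edges, observed.slot_edges
    ):
        raise ValueError("model and observed distributions use different slot edges")
    diff = model.masses - observed.masses
    return float(np.sqrt(np.mean(diff * diff)))


def hurst(alpha: float) -> float:
    """Hurst exponent H = alpha / 2 of the subdiffusive process."""
    if not (0.0 < alpha < 2.0):
        raise ValueError(f"alpha must be in (0, 2), got {alpha!r}")
    return alpha / 2.0


def _default_alpha_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 2.0, 0.05), 10)


def _default_k_grid() -> np.ndarray:
    return np.logspace(-2.0, 2.0, 41)


@dataclass(frozen=True)
class FitConfig:
    """Search configuration for the (alpha, K_alpha) RMSE fit.

    ``horizon_t`` is the length of the full observation window in
    registration periods (default 5, the five-month protocol window).
    ``target`` selects what the evolved model is scored against: the final
    period's frequencies ("final_period", default) or every period jointly
    ("all_periods").  ``initial`` selects the starting distribution: the
    pooled stationary estimate ("stationary", default) or the first
    period's frequencies ("first_period").
    """

    alpha_grid: np.ndarray = field(default_factory=_default_alpha_grid)
    k_grid: np.ndarray = field(default_factory=_default_k_grid)
    refine: bool = True
    horizon_t: float = 5.0
    target: str = "final_period"
    initial: str = "stationary"
    keep_trace: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_grid, dtype=float)
        k = np.asarray(self.k_grid, dtype=float)
        object.__setattr__(self, "alpha_grid", a)
        object.__setattr__(self, "k_grid", k)
        if a.size == 0 or k.size == 0:
            raise ValueError("alpha_grid and k_grid must be non-empty")
        if not np.all(np.diff(a) > 0) or not np.all(np.diff(k) > 0):
            raise ValueError("grids must be strictly increasing")
        if a[0] <= 0.0 or a[-1] >= 2.0:
            raise ValueError("alpha_grid must lie strictly inside (0, 2)")
        if k[0] <= 0.0:
            raise ValueError("k_grid must be strictly positive")
        if not (self.horizon_t > 0.0):
            raise ValueError("horizon_t must be positive")
        if self.target not in ("final_period", "all_periods"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.initial not in ("stationary", "first_period"):
            raise ValueError(f"unknown initial {self.initial!r}")


@dataclass(frozen=True)
class FitResult:
    """Fitted subdiffusion parameters and fit diagnostics."""

    alpha: float
    k_alpha: float
    hurst: float
    rmse: float
    admissible: bool
    n_evaluations: int
    search_trace: list[tuple[float, float, float]] | None = None
    admissibility: AdmissibilityReport | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 2.0) or not (self.k_alpha > 0.0):
            raise ValueError("fit result carries an inadmissible parameter pair")
        if abs(self.hurst - self.alpha / 2.0) > 0.0:
            raise ValueError("hurst must equal alpha/2 exactly")
        if self.rmse < 0.0:
            raise ValueError("rmse must be nonnegative")

    def to_json(self) -> str:
        payload = {
            "alpha": self.alpha,
            "k_alpha": self.k_alpha,
            "hurst": self.hurst,
            "rmse": self.rmse,
            "admissible": self.admissible,
            "n_evaluations": self.n_evaluations,
        }
        if self.search_trace is not None:
            payload["search_trace"] = [list(row) for row in self.search_trace]
        return json.dumps(payload, sort_keys=True)


def _objective(
    initial: BinnedDistribution,
    targets: list[tuple[float, BinnedDistribution]],
    params: FractionalParams,
    settings: SeriesSettings,
) -> float:
    """Pooled RMSE of the evolved model against every target distribution."""
    sq_sum = 0.0
    n = 0
    for t, observed in targets:
        model = evolve_distribution(initial, t, params, settings)
        diff = model.masses - observed.masses
        sq_sum += float(np.dot(diff, diff))
        n += diff.size
    return math.sqrt(sq_sum / n)


def fit_distributions(
    initial: BinnedDistribution,
    targets: list[tuple[float, BinnedDistribution]],
    config: FitConfig | None = None,
    settings: SeriesSettings | None = None,
) -> FitResult:
    """Grid-search (alpha, K_alpha) minimizing RMSE against target distributions.

    ``targets`` is a list of (evolution time, observed distribution)
    pairs.  Ties are broken toward smaller alpha, then smaller K (the grid
    is scanned in increasing order and only strict improvements replace
    the incumbent).  With ``config.refine`` a Nelder-Mead simplex in
    (alpha, log10 K) polishes the best grid point.
    """
    if config is None:
        config = FitConfig()
    if settings is None:
        settings = SeriesSettings()
    if not targets:
        raise ValueError("need at least one target distribution")
    for t, obs in targets:
        if not (t > 0.0):
            raise ValueError("target times must be strictly positive")
        if obs.slot_edges.size != initial.slot_edges.size or not np.allclose(
            obs.slot_edges, initial.slot_edges
        ):
            raise ValueError("targets must share the initial distribution's edges")

    best: tuple[float, float, float] | None = None  # (rmse, alpha, k)
    trace: list[tuple[float, float, float]] = []
    n_evaluations = 0
    rejections: list[str] = []
    for a in config.alpha_grid:
        for k in config.k_grid:
            try:
                params = FractionalParams(alpha=float(a), k_alpha=float(k))
                score = _objective(initial, targets, params, settings)
            except ValueError as exc:
                rejections.append(f"(alpha={a:.4g}, k={k:.4g}): {exc}")
                logger.debug("skipping inadmissible pair alpha=%s k=%s: %s", a, k, exc)
                continue
            n_evaluations += 1
            if config.keep_trace:
                trace.append((float(a), float(k), score))
            if best is None or score < best[0]:
                best = (score, float(a), float(k))
    if best is None:
        raise RuntimeError(
            "no admissible (alpha, K) pair on the search grid; rejections: "
            + "; ".join(rejections[:10])
        )

    best_rmse, best_a, best_k = best
    if config.refine:
        # polish locally but stay inside the declared search hull: the
        # propagator degenerates toward two ballistic peaks as alpha -> 2
        # and the grid bounds define the model space being searched
        a_lo, a_hi = float(config.alpha_grid[0]), float(config.alpha_grid[-1])
        lk_lo, lk_hi = math.log10(config.k_grid[0]), math.log10(config.k_grid[-1])

        def neg_bounded(v: np.ndarray) -> float:
            a, log_k = float(v[0]), float(v[1])
            if not (a_lo <= a <= a_hi and lk_lo <= log_k <= lk_hi):
                return math.inf
            try:
                params = FractionalParams(alpha=a, k_alpha=10.0 ** log_k)
                return _objective(initial, targets, params, settings)
            except (ValueError, RuntimeError):
                return math.inf

        res = optimize.minimize(
            neg_bounded,
            x0=np.array([best_a, math.log10(best_k)]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-10, "maxfev": 200},
        )
        n_evaluations += int(res.nfev)
        if math.isfinite(res.fun) and res.fun < best_rmse:
            best_rmse = float(res.fun)
            best_a = float(res.x[0])
            best_k = float(10.0 ** res.x[1])

    report = check_admissibility(
        FractionalParams(best_a, best_k),
        x_grid=initial.slot_edges,
        t_grid=[t for t, _ in targets],
        settings=settings,
        x0=float(initial.centers[np.argmax(initial.masses)]),
    )
    return FitResult(
        alpha=best_a,
        k_alpha=best_k,
        hurst=best_a / 2.0,
        rmse=best_rmse,
        admissible=report.admissible,
        n_evaluations=n_evaluations,
        search_trace=trace if config.keep_trace else None,
        admissibility=report,
    )


def fit_params(
    obs,
    config: FitConfig | None = None,
    settings: SeriesSettings | None = None,
) -> FitResult:
    """Fit (alpha, K_alpha) to binned per-period observations.

    Builds the initial distribution and scoring targets according to
    ``config`` and delegates to :func:`fit_distributions`.  Period p
    (0-based) is placed at evolution time ``(p+1) * horizon_t / n_periods``
    when starting from the stationary pool, or ``p * horizon_t /
    n_periods`` when starting from the first period's own frequencies.
    """
    if config is None:
        config = FitConfig()
    counts = np.asarray(obs.counts, dtype=float)
    n_periods = counts.shape[0]
    if config.target == "final_period" and n_periods < 2:
        raise ValueError("need at least 2 periods to fit the final period")
    edges = np.asarray(obs.slot_edges, dtype=float)
    per = config.horizon_t / n_periods

    def period_dist(p: int) -> BinnedDistribution:
        row = counts[p]
        if row.sum() <= 0:
            raise ValueError(f"period {p} contains no hits")
        return BinnedDistribution(slot_edges=edges, masses=row / row.sum())

    if config.initial == "stationary":
        initial = stationary_estimate(obs)
        offset = 0
    else:
        initial = period_dist(0)
        offset = 1
    if config.target == "final_period":
        targets = [(config.horizon_t - (per if offset else 0.0), period_dist(n_periods - 1))]
    else:
        targets = [
            ((p + 1 - offset) * per, period_dist(p))
            for p in range(offset, n_periods)
        ]
    return fit_distributions(initial, targets, config, settings)
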
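"""Green's function of the fractional Fokker-Planck equation (FFPE).

The FFPE describes subdiffusive spreading of a probability density::

    dP/dt = D_t^{1-alpha} K_alpha d^2P/dx^2,      0 < alpha < 2,

where ``D_t^{1-alpha}`` is the Riemann-Liouville fractional derivative and
``K_alpha`` the generalized diffusion coefficient.  Its free-space
propagator (Green's function) admits the similarity-series representation

    P(x, t | x0) = f_{beta,gamma}(t, g) / (2 sqrt(K_alpha)),
    f_{beta,gamma}(t, g) = t^{-(1+beta)} sum_{k>=0} (-g t^{-gamma})^k
                           / (k! * Gamma(-k*gamma - beta)),

with ``beta = alpha/2 - 1``, ``gamma = alpha/2`` and similarity argument
``g = |x - x0| / sqrt(K_alpha)``.  At ``alpha = 1`` the series collapses to
the classical Gaussian heat kernel; for ``alpha < 1`` the density has a
cusp at ``x0`` and tails much heavier than Gaussian ("fat tails"), the
mechanism this package uses to model sudden large excursions of a
monitored clinical parameter.

The reciprocal Gamma function is entire, so series terms whose Gamma
argument sits on a pole vanish identically (at ``alpha = 1`` every odd
term).  The alternating series loses precision for large
``z = g / t^gamma``; beyond ``SeriesSettings.regime_threshold`` (or on
detected non-convergence) evaluation falls back to numerical inversion of
the exact Laplace-domain representation

    P~(x, s) = s^{alpha/2 - 1} / (2 sqrt(K_alpha))
               * exp(-|x - x0| s^{alpha/2} / sqrt(K_alpha)),

via a fixed-Talbot contour, which also serves as an independent oracle
(:func:`laplace_oracle`).

Mean squared displacement: ``<(x - x0)^2> = 2 K_alpha t^alpha /
Gamma(1 + alpha)``, i.e. Hurst exponent ``H = alpha/2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, NamedTuple, Sequence

import mpmath as mp
import numpy as np
from scipy import integrate, special

__all__ = [
    "FractionalParams",
    "PropagatorQuery",
    "SeriesSettings",
    "SeriesResult",
    "AdmissibilityReport",
    "SeriesConvergenceError",
    "TalbotContourError",
    "derived_exponents",
    "series_f",
    "series_terms",
    "evaluate_propagator",
    "propagator_profile",
    "gaussian_limit_propagator",
    "laplace_oracle",
    "msd",
    "propagator_mass",
    "propagator_second_moment",
    "check_admissibility",
]

_RGAMMA_DIRECT_LIMIT = 170.0  # |arg| above which Gamma overflows double precision


class SeriesConvergenceError(RuntimeError):
    """Truncated series did not converge and no fallback was available.

    Carries the partial sum and the magnitude of the last computed term so
    a caller can decide whether the partial result is still usable.
    """

    def __init__(self, message: str, partial_sum: float, last_term: float):
        super().__init__(message)
        self.partial_sum = partial_sum
        self.last_term = last_term


class TalbotContourError(RuntimeError):
    """Fixed-Talbot inversion produced a non-finite or inconsistent value."""


@dataclass(frozen=True)
class FractionalParams:
    """Subdiffusion parameter pair (alpha, K_alpha).

    Parameters
    ----------
    alpha
        Anomalous-diffusion exponent, dimensionless, constrained to
        ``0 < alpha < 2`` (alpha = 1 is classical diffusion, alpha < 1
        subdiffusion).
    k_alpha
        Generalized diffusion coefficient, in squared value units per
        time-unit**alpha.  Throughout this package one time unit is one
        31-day registration period.
    """

    alpha: float
    k_alpha: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 2.0) or not math.isfinite(self.alpha):
            raise ValueError(
                f"alpha must satisfy 0 < alpha < 2, got {self.alpha!r}"
            )
        if not (self.k_alpha > 0.0) or not math.isfinite(self.k_alpha):
            raise ValueError(f"k_alpha must be positive, got {self.k_alpha!r}")

    @property
    def beta(self) -> float:
        return self.alpha / 2.0 - 1.0

    @property
    def gamma(self) -> float:
        return self.alpha / 2.0

    @property
    def hurst(self) -> float:
        """Hurst exponent H = alpha/2 (H = 1/2 is ordinary diffusion)."""
        return self.alpha / 2.0


@dataclass(frozen=True)
class PropagatorQuery:
    """A single propagator evaluation point (x, t) given the start x0."""

    x: float
    x0: float
    t: float

    def __post_init__(self) -> None:
        if not (self.t > 0.0) or not math.isfinite(self.t):
            raise ValueError(f"t must be strictly positive, got {self.t!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.x0)):
            raise ValueError("x and x0 must be finite")

    def g(self, params: FractionalParams) -> float:
        """Similarity argument g = |x - x0| / sqrt(K_alpha); zero iff x == x0."""
        return abs(self.x - self.x0) / math.sqrt(params.k_alpha)


@dataclass(frozen=True)
class SeriesSettings:
    """Numerical controls for the propagator series and its Talbot fallback."""

    k_max: int = 250
    term_tol: float = 1e-14
    regime_threshold: float = 5.0
    talbot_degree: int = 32
    talbot_dps: int = 30

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not (self.term_tol > 0.0):
            raise ValueError("term_tol must be positive")
        if not (self.regime_threshold > 0.0):
            raise ValueError("regime_threshold must be positive")
        if self.talbot_degree < 32:
            raise ValueError("talbot_degree must be >= 32")


class SeriesResult(NamedTuple):
    """Value of f_{beta,gamma} plus evaluation diagnostics."""

    value: float
    n_terms: int
    last_term: float
    fallback: bool


def derived_exponents(params: FractionalParams) -> tuple[float, float]:
    """Return (beta, gamma) = (alpha/2 - 1, alpha/2)."""
    return params.beta, params.gamma


def _params_from_exponents(beta: float, gamma: float) -> None:
    """Validate that (beta, gamma) derive from an admissible alpha."""
    alpha = 2.0 * gamma
    if abs((gamma - 1.0) - beta) > 1e-12:
        raise ValueError(f"beta must equal gamma - 1, got beta={beta}, gamma={gamma}")
    if not (0.0 < alpha < 2.0):
        raise ValueError(f"exponents imply alpha={alpha}, outside (0, 2)")


def series_terms(
    t: float, g: float, beta: float, gamma: float, k_max: int = 250
) -> np.ndarray:
    """All truncated-series terms of f_{beta,gamma}(t, g), including the
    ``t^{-(1+beta)}`` prefactor.

    Terms whose reciprocal-Gamma argument is a non-positive integer are
    exactly zero (pole of Gamma).  Exposed mainly for diagnostics and tests.
    """
    ks = np.arange(k_max + 1)
    arg = -ks * gamma - beta
    z = g * t ** (-gamma)
    pref = t ** (-(1.0 + beta))
    if z == 0.0:
        terms = np.zeros(k_max + 1)
        terms[0] = special.rgamma(-beta)
        return pref * terms
    direct = np.abs(arg) <= _RGAMMA_DIRECT_LIMIT
    logc = ks * math.log(z) - special.gammaln(ks + 1.0)
    sign = np.where(ks % 2 == 0, 1.0, -1.0)
    terms = np.zeros(k_max + 1)
    terms[direct] = special.rgamma(arg[direct]) * np.exp(logc[direct]) * sign[direct]
    if not direct.all():
        # reflection formula in log space: 1/Gamma(-y) = -sin(pi y) Gamma(1+y) / pi
        y = -arg[~direct]
        s = np.sin(np.pi * y)
        logmag = special.gammaln(1.0 + y) + np.log(np.abs(s)) - math.log(math.pi)
        terms[~direct] = -np.sign(s) * np.exp(logmag + logc[~direct]) * sign[~direct]
    return pref * terms


_MP_COEFF_CACHE: dict[tuple[float, float, int], list] = {}


def _series_mp_coeffs(beta: float, gamma: float, dps: int, n: int) -> list:
    """Series coefficients 1/(k! Gamma(-k gamma - beta)) at dps digits,
    cached per exponent pair and grown on demand."""
    key = (beta, gamma, dps)
    coeffs = _MP_COEFF_CACHE.setdefault(key, [])
    if len(coeffs) < n:
        with mp.workdps(dps):
            for k in range(len(coeffs), n):
                coeffs.append(
                    mp.rgamma(-k * mp.mpf(gamma) - mp.mpf(beta)) / mp.factorial(k)
                )
    return coeffs


@lru_cache(maxsize=200_000)
def _series_mp(
    t: float, g: float, beta: float, gamma: float, k_max: int, dps: int
) -> float:
    """Resum the propagator series in arbitrary precision.

    Rescues evaluation points where double-precision cancellation destroys
    the alternating sum (large z at alpha near 2); raises
    :class:`SeriesConvergenceError` if the extended series still has not
    converged.
    """
    with mp.workdps(dps):
        mt = mp.mpf(t)
        z = mp.mpf(g) * mt ** (-mp.mpf(gamma))
        total = mp.mpf(0)
        peak = mp.mpf(0)
        term = mp.mpf(0)
        zpow = mp.mpf(1)
        converged = False
        chunk = 128
        k = 0
        small_run = 0  # Gamma-pole terms are exactly zero; require two in a row
        while k <= k_max:
            coeffs = _series_mp_coeffs(beta, gamma, dps, min(k + chunk, k_max + 1))
            for c in coeffs[k : k + chunk]:
                term = c * zpow
                total += term
                zpow *= -z
                if abs(term) > peak:
                    peak = abs(term)
                if abs(term) < mp.mpf(1e-30) * max(abs(total), mp.mpf(1e-300)):
                    small_run += 1
                    if k >= 2 and small_run >= 2:
                        converged = True
                        break
                else:
                    small_run = 0
                k += 1
            if converged:
                break
        # escalate precision if cancellation consumed the working digits
        if peak > 0 and abs(total) > 0:
            lost = float(mp.log10(peak / abs(total)))
            if lost > dps - 20:
                return _series_mp(t, g, beta, gamma, k_max, int(lost) + 40)
        if not converged:
            raise SeriesConvergenceError(
                f"series not converged after {k_max + 1} terms at g={g:.6g}, "
                f"t={t:.6g} even in extended precision",
                partial_sum=float(mt ** (-(1 + mp.mpf(beta))) * total),
                last_term=float(abs(term)),
            )
        return float(mt ** (-(1 + mp.mpf(beta))) * total)


def _kahan_sum(terms: np.ndarray) -> np.ndarray:
    """Compensated (Kahan) summation along the leading axis."""
    total = np.zeros(terms.shape[1:])
    comp = np.zeros_like(total)
    for row in terms:
        y = row - comp
        tmp = total + y
        comp = (tmp - total) - y
        total = tmp
    return total


def _f_series_batch(
    t: float,
    g: np.ndarray,
    beta: float,
    gamma: float,
    settings: SeriesSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized truncated series over an array of similarity arguments.

    Returns (values, ok) where ``ok`` is False for elements whose series
    did not converge cleanly (tail terms above tolerance, or cancellation
    so severe that fewer than ~6 significant digits survive).
    """
    k_max = settings.k_max
    ks = np.arange(k_max + 1)
    arg = -ks * gamma - beta
    pref = t ** (-(1.0 + beta))
    z = np.asarray(g, dtype=float) * t ** (-gamma)

    direct = np.abs(arg) <= _RGAMMA_DIRECT_LIMIT
    a = np.zeros(k_max + 1)
    a[direct] = special.rgamma(arg[direct])
    # large-|arg| coefficients handled in log space below
    y = -arg[~direct]
    s = np.sin(np.pi * y)
    log_a_big = special.gammaln(1.0 + y) + np.log(np.abs(s)) - math.log(math.pi)
    sign_a_big = -np.sign(s)

    zero = z == 0.0
    with np.errstate(divide="ignore"):
        logz = np.where(~zero, np.log(np.where(zero, 1.0, z)), 0.0)  # z==0 fixed below
    # term matrix (k, point); computed via logs to dodge overflow in k!.
    logc = ks[:, None] * logz[None, :] - special.gammaln(ks + 1.0)[:, None]
    sign_k = np.where(ks % 2 == 0, 1.0, -1.0)[:, None]
    terms = np.zeros_like(logc)
    with np.errstate(over="ignore", invalid="ignore"):
        terms[direct] = a[direct][:, None] * np.exp(logc[direct]) * sign_k[direct]
        if not direct.all():
            terms[~direct] = (
                sign_a_big[:, None]
                * np.exp(log_a_big[:, None] + logc[~direct])
                * sign_k[~direct]
            )
    terms = np.nan_to_num(terms, nan=0.0, posinf=np.inf, neginf=-np.inf)
    # z == 0: only the k = 0 term survives
    if zero.any():
        terms[:, zero] = 0.0
        terms[0, zero] = special.rgamma(-beta)

    total = _kahan_sum(terms)
    abs_terms = np.abs(terms)
    tail_ok = np.maximum(abs_terms[-1], abs_terms[-2]) < settings.term_tol
    peak = abs_terms.max(axis=0)
    # cancellation guard: double-precision rounding of the largest term must
    # leave at least ~6 significant digits in the sum
    with np.errstate(divide="ignore", invalid="ignore"):
        cancel_ok = peak * 2.3e-16 <= 1e-7 * np.maximum(np.abs(total), 1e-300)
    cancel_ok = cancel_ok | (peak == 0.0)
    ok = tail_ok & cancel_ok & np.isfinite(total)
    return pref * total, ok


def _saddle_log_suppression(z: float, gamma: float) -> float:
    """Natural-log suppression of f(t, g) relative to its peak scale t^-gamma.

    The Laplace inversion of exp(-g s^gamma) has saddle point
    ``s* = (g gamma / t)^{1/(1-gamma)}`` giving the stretched-exponential
    tail ``exp(-((z gamma)^{1/(1-gamma)}) (1-gamma)/gamma)`` with
    ``z = g t^-gamma``.
    """
    log_s = math.log(z * gamma) / (1.0 - gamma) + math.log((1.0 - gamma) / gamma)
    return math.exp(log_s) if log_s < 700.0 else math.inf


def _saddle_point(t: float, g: float, gamma: float, power: float) -> float:
    """One-term steepest-descent inversion of s^power exp(-g s^gamma).

    Exact for gamma = 1/2; relative error O((z gamma)^{-1/(1-gamma)})
    otherwise, used only where the result is negligibly small anyway.
    """
    log_s_star = math.log(g * gamma / t) / (1.0 - gamma)
    if log_s_star > 700.0:
        return 0.0
    s_star = math.exp(log_s_star)
    log_phi = -(1.0 - gamma) / gamma * t * s_star
    log_curv = (
        math.log(g * gamma * (1.0 - gamma)) + (gamma - 2.0) * log_s_star
    )
    arg = log_phi + power * log_s_star - 0.5 * (math.log(2.0 * math.pi) + log_curv)
    return math.exp(arg) if arg > -745.0 else 0.0


@lru_cache(maxsize=200_000)
def _talbot_mp(
    t: float, g: float, gamma: float, power: float, degree: int, dps: int
) -> float:
    """Arbitrary-precision fixed-Talbot inversion of s^power exp(-g s^gamma).

    Both the contour degree and the working precision are escalated until
    two consecutive evaluations agree: raising precision alone cannot fix
    the quadrature's own discretization error, and raising degree alone
    amplifies round-off.  A contour that never stabilizes raises instead
    of returning a wrong value.
    """

    def F(s, mg, mgam, mpow):
        return s ** mpow * mp.exp(-mg * s ** mgam)

    prev = None
    scale = t ** (-(1.0 + power))  # crude magnitude scale of the inverse
    deg, cur_dps = degree, dps
    for _ in range(6):
        with mp.workdps(cur_dps):
            mg, mgam, mpow = mp.mpf(g), mp.mpf(gamma), mp.mpf(power)
            val = _fixed_talbot(lambda s: F(s, mg, mgam, mpow), mp.mpf(t), deg)
            out = float(val)
        if (
            prev is not None
            and math.isfinite(out)
            and abs(out - prev) <= 1e-11 * max(abs(out), 1e-14 * scale)
        ):
            return out
        prev = out if math.isfinite(out) else None
        deg *= 2
        cur_dps = max(2 * cur_dps, int(0.8 * deg))
    raise TalbotContourError(
        f"Talbot contour failed to stabilize for t={t}, g={g}, "
        f"gamma={gamma}, power={power}"
    )


def _fixed_talbot(F: Callable, t, degree: int):
    """Abate-Valko fixed-Talbot quadrature at mpmath working precision."""
    r = mp.mpf(2 * degree) / (5 * t)
    total = mp.mpf(0.5) * F(r) * mp.exp(r * t)
    for k in range(1, degree):
        theta = mp.pi * k / degree
        cot = mp.cot(theta)
        s = r * theta * (cot + 1j)
        sigma = theta + (theta * cot - 1) * cot
        total += (mp.exp(t * s) * F(s) * (1 + 1j * sigma)).real
    return total * r / degree


def _talbot_float(
    t: float, g: np.ndarray, gamma: float, power: float, degree: int = 64
) -> np.ndarray:
    """Double-precision fixed-Talbot inversion of s^power exp(-g s^gamma).

    Accurate to ~1e-9 relative wherever the contour stays within double
    range; overflow/cancellation shows up as non-finite output, which the
    caller escalates to the arbitrary-precision path."""
    g = np.asarray(g, dtype=float)
    r = 2.0 * degree / (5.0 * t)
    theta = np.pi * np.arange(1, degree) / degree
    cot = 1.0 / np.tan(theta)
    s = r * theta * (cot + 1j)
    sigma = theta + (theta * cot - 1.0) * cot
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        Fs = s[None, :] ** power * np.exp(-g[:, None] * s[None, :] ** gamma)
        vals = np.real(np.exp(t * s)[None, :] * Fs * (1.0 + 1j * sigma)[None, :])
        head = 0.5 * r ** power * np.exp(-g * r ** gamma) * np.exp(r * t)
        out = (head + vals.sum(axis=1)) * r / degree
    return out


def _invert_exp_tail(
    t: float,
    g: float,
    gamma: float,
    power: float,
    settings: "SeriesSettings",
) -> float:
    """Invert s^power exp(-g s^gamma) at time t, choosing the evaluator.

    Deeply suppressed values (saddle suppression > ~45 nats below the
    peak scale) use the closed-form saddle approximation; the moderate
    band uses the double-precision Talbot contour, escalating to the
    arbitrary-precision contour when doubles overflow.
    """
    if g <= 0.0:
        # pure power law: invL[s^power] = t^{-1-power} / Gamma(-power)
        return t ** (-1.0 - power) * float(special.rgamma(-power))
    z = g * t ** (-gamma)
    # > 25 nats below peak scale: value < ~1e-11 * scale, saddle's few-percent
    # relative error is far below every downstream absolute tolerance
    if _saddle_log_suppression(z, gamma) > 25.0:
        return _saddle_point(t, g, gamma, power)
    val = float(_talbot_float(t, np.array([g]), gamma, power)[0])
    # the inverse is positive and monotone decreasing in g, so the g = 0
    # closed form bounds it; a finite value outside [0, bound] is contour
    # round-off garbage, not a usable number
    bound = t ** (-1.0 - power) * float(special.rgamma(-power))
    scale = t ** (-1.0 - power)
    if math.isfinite(val) and -1e-11 * scale <= val <= bound * (1.0 + 1e-9):
        return max(val, 0.0)
    if _saddle_log_suppression(z, gamma) > 8.0:
        # double contour overflowed but the value is < ~3e-4 of peak scale;
        # the saddle's few-percent relative error is below the absolute
        # accuracy any consumer of this deep-suppression band requires
        return _saddle_point(t, g, gamma, power)
    return _talbot_mp(
        float(t), float(g), float(gamma), float(power),
        settings.talbot_degree, settings.talbot_dps,
    )


def _f_values(
    t: float,
    g: np.ndarray,
    beta: float,
    gamma: float,
    settings: SeriesSettings,
    allow_fallback: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate f_{beta,gamma}(t, g) for an array of g.

    Returns (values, fallback_mask).  Elements beyond the series regime, or
    whose series failed to converge, are evaluated by Talbot inversion.
    """
    g = np.atleast_1d(np.asarray(g, dtype=float))
    z = g * t ** (-gamma)
    # the series is practical only while its turnover index
    # k* ~ (z gamma^gamma)^(1/(1-gamma)) sits well inside k_max (it explodes
    # as alpha -> 2); points beyond go straight to the tail evaluator
    with np.errstate(divide="ignore"):
        log_kturn = (np.log(np.where(z > 0, z, 1.0)) + gamma * math.log(gamma)) / (
            1.0 - gamma
        )
    series_practical = log_kturn <= math.log(0.6 * settings.k_max)
    # a middle band is still summable with the extended-precision series
    # (up to 4 k_max terms); beyond it the tail evaluator takes over
    series_mp_band = (~series_practical) & (
        log_kturn <= math.log(2.0 * settings.k_max)
    )
    in_regime = (z <= settings.regime_threshold) & series_practical
    mp_band = (z <= settings.regime_threshold) & series_mp_band
    values = np.empty_like(g)
    fallback = np.zeros(g.shape, dtype=bool)
    if mp_band.any():
        for idx in np.flatnonzero(mp_band):
            zi = float(z.flat[idx])
            # deep-suppression points do not deserve the slow extended
            # series; the tail evaluator's saddle branch handles them
            if _saddle_log_suppression(zi, gamma) > 25.0:
                mp_band.flat[idx] = False
                fallback.flat[idx] = True
                continue
            try:
                values.flat[idx] = _series_mp(
                    float(t), float(g.flat[idx]), float(beta), float(gamma),
                    4 * settings.k_max, 40,
                )
            except SeriesConvergenceError:
                if not allow_fallback:
                    raise
                fallback.flat[idx] = True
        mp_band &= ~fallback

    if in_regime.any():
        vals, ok = _f_series_batch(t, g[in_regime], beta, gamma, settings)
        values[in_regime] = vals
        bad = ~ok
        if bad.any():
            # cancellation or slow convergence in doubles: resum the same
            # series in extended precision (still the series path, so the
            # Talbot oracle remains an independent cross-check)
            for idx in np.flatnonzero(in_regime)[np.flatnonzero(bad)]:
                try:
                    values.flat[idx] = _series_mp(
                        float(t), float(g.flat[idx]), float(beta), float(gamma),
                        4 * settings.k_max, 40,
                    )
                except SeriesConvergenceError:
                    if not allow_fallback:
                        raise
                    fallback.flat[idx] = True
    fallback |= ~(in_regime | mp_band)
    if fallback.any():
        if not allow_fallback and (~(in_regime | mp_band)).any():
            raise SeriesConvergenceError(
                "evaluation outside the series regime with fallback disabled",
                partial_sum=float("nan"),
                last_term=float("inf"),
            )
        gf = g[fallback]
        out = np.array(
            [_invert_exp_tail(t, float(gi), gamma, beta, settings) for gi in gf]
        )
        values[fallback] = out
    return values, fallback


def series_f(
    t: float,
    g: float,
    beta: float,
    gamma: float,
    settings: SeriesSettings | None = None,
) -> SeriesResult:
    """Evaluate the similarity function f_{beta,gamma}(t, g).

    Uses the truncated power series inside the convergence regime
    (``g/t^gamma <= regime_threshold``) and the Talbot-inverted Laplace
    representation outside it or on detected non-convergence; the
    ``fallback`` flag in the result records which path produced the value.
    """
    if settings is None:
        settings = SeriesSettings()
    if not (t > 0.0):
        raise ValueError(f"t must be positive, got {t!r}")
    if not (g >= 0.0):
        raise ValueError(f"g must be nonnegative, got {g!r}")
    _params_from_exponents(beta, gamma)
    values, fb = _f_values(t, np.array([g]), beta, gamma, settings)
    if fb[0]:
        return SeriesResult(float(values[0]), 0, float("nan"), True)
    terms = series_terms(t, g, beta, gamma, settings.k_max)
    abs_t = np.abs(terms)
    below = np.flatnonzero(
        (abs_t < settings.term_tol) & (np.roll(abs_t, -1) < settings.term_tol)
    )
    n_terms = int(below[0]) + 1 if below.size else settings.k_max + 1
    return SeriesResult(float(values[0]), n_terms, float(abs_t[min(n_terms, settings.k_max)]), False)


def evaluate_propagator(
    q: PropagatorQuery,
    params: FractionalParams,
    settings: SeriesSettings | None = None,
) -> float:
    """FFPE propagator density P(x, t | x0), per value unit."""
    if settings is None:
        settings = SeriesSettings()
    res = series_f(q.t, q.g(params), params.beta, params.gamma, settings)
    return res.value / (2.0 * math.sqrt(params.k_alpha))


def propagator_profile(
    x: np.ndarray,
    x0: float,
    t: float,
    params: FractionalParams,
    settings: SeriesSettings | None = None,
) -> np.ndarray:
    """Vectorized propagator density over an array of evaluation points."""
    if settings is None:
        settings = SeriesSettings()
    if not (t > 0.0):
        raise ValueError(f"t must be positive, got {t!r}")
    g = np.abs(np.asarray(x, dtype=float) - x0) / math.sqrt(params.k_alpha)
    values, _ = _f_values(t, g, params.beta, params.gamma, settings)
    return values / (2.0 * math.sqrt(params.k_alpha))


def gaussian_limit_propagator(q: PropagatorQuery, k: float) -> float:
    """Classical heat kernel 1/sqrt(4 pi k t) exp(-(x-x0)^2/(4 k t)).

    This is the exact alpha = 1 reduction of the FFPE propagator and the
    analytic oracle used in tests.
    """
    if not (k > 0.0):
        raise ValueError(f"diffusion coefficient must be positive, got {k!r}")
    var = 2.0 * k * q.t
    return math.exp(-((q.x - q.x0) ** 2) / (2.0 * var)) / math.sqrt(2.0 * math.pi * var)


def laplace_oracle(
    q: PropagatorQuery,
    params: FractionalParams,
    degree: int = 32,
    dps: int = 30,
) -> float:
    """Propagator density via high-precision inverse Laplace transform.

    Inverts ``P~(x, s) = s^{alpha/2-1}/(2 sqrt(K)) exp(-|x-x0| s^{alpha/2} /
    sqrt(K))`` on a fixed-Talbot contour with ``degree`` nodes at ``dps``
    decimal digits.  Fully independent of the series evaluation and used as
    the brute-force cross-check.
    """
    if degree < 32:
        raise ValueError("degree must be >= 32")
    val = _talbot_mp(
        float(q.t), float(q.g(params)), float(params.gamma),
        float(params.gamma - 1.0), degree, dps,
    )
    return val / (2.0 * math.sqrt(params.k_alpha))


def msd(params: FractionalParams, t: float) -> float:
    """Mean squared displacement <(x-x0)^2> = 2 K_alpha t^alpha / Gamma(1+alpha)."""
    if not (t > 0.0):
        raise ValueError(f"t must be positive, got {t!r}")
    return 2.0 * params.k_alpha * t ** params.alpha / special.gamma(1.0 + params.alpha)


def _tail_mass(params: FractionalParams, g0: float, t: float, settings: SeriesSettings) -> float:
    """Two-sided probability mass beyond similarity argument g0.

    In the Laplace domain ``int_{g0}^inf f~ dg = s^{-1} exp(-g0 s^gamma)``,
    so the tail mass is a single inversion (a Mittag-Leffler-type survival
    function; erfc at alpha = 1).
    """
    return _invert_exp_tail(t, g0, params.gamma, -1.0, settings)


def _tail_second_moment(
    params: FractionalParams, g0: float, t: float, settings: SeriesSettings
) -> float:
    """Two-sided contribution of |g| > g0 to <(x-x0)^2> (value units^2).

    Termwise Laplace inversion of ``int_{g0}^inf g^2 f~ dg =
    exp(-g0 s^gamma) (g0^2 s^-1 + 2 g0 s^{-1-gamma} + 2 s^{-1-2 gamma})``.
    """
    gamma = params.gamma
    val = (
        g0 ** 2 * _invert_exp_tail(t, g0, gamma, -1.0, settings)
        + 2.0 * g0 * _invert_exp_tail(t, g0, gamma, -1.0 - gamma, settings)
        + 2.0 * _invert_exp_tail(t, g0, gamma, -1.0 - 2.0 * gamma, settings)
    )
    return params.k_alpha * val


def propagator_mass(
    params: FractionalParams,
    t: float,
    settings: SeriesSettings | None = None,
) -> float:
    """Total probability mass of the propagator (should be 1).

    Central region (series regime) by adaptive quadrature, far tail by the
    analytic Laplace-domain tail-mass inversion.
    """
    if settings is None:
        settings = SeriesSettings()
    sqrt_k = math.sqrt(params.k_alpha)
    g0 = settings.regime_threshold * t ** params.gamma
    L = g0 * sqrt_k

    def dens(x: float) -> float:
        vals, _ = _f_values(t, np.array([abs(x) / sqrt_k]), params.beta, params.gamma, settings)
        return float(vals[0]) / (2.0 * sqrt_k)

    central, _ = integrate.quad(dens, 0.0, L, limit=300)
    return 2.0 * central + _tail_mass(params, g0, t, settings)


def propagator_second_moment(
    params: FractionalParams,
    t: float,
    settings: SeriesSettings | None = None,
) -> float:
    """Numerical second central moment of the propagator (value units^2).

    Independent cross-check for :func:`msd`; heavy tails carry a
    non-negligible share of the variance at small alpha, handled by the
    analytic tail-moment inversion.
    """
    if settings is None:
        settings = SeriesSettings()
    sqrt_k = math.sqrt(params.k_alpha)
    g0 = settings.regime_threshold * t ** params.gamma
    L = g0 * sqrt_k

    def integrand(x: float) -> float:
        vals, _ = _f_values(t, np.array([abs(x) / sqrt_k]), params.beta, params.gamma, settings)
        return x * x * float(vals[0]) / (2.0 * sqrt_k)

    central, _ = integrate.quad(integrand, 0.0, L, limit=300)
    return 2.0 * central + _tail_second_moment(params, g0, t, settings)


@dataclass
class AdmissibilityReport:
    """Outcome of the probabilistic-admissibility check for one (alpha, K) pair.

    A pair is admissible when the evaluated solution behaves as a proper
    probability density on the requested grids: nonnegative everywhere,
    unit total mass at every t, and per-slot probability masses within
    [0, 1].  The upper bound is applied to slot masses, not raw densities:
    a legitimate density exceeds 1 whenever its scale parameter is small.
    """

    alpha: float
    k_alpha: float
    density_min: float
    density_max: float
    nonneg_ok: bool
    normalized_ok: bool
    slot_mass_ok: bool
    per_t: list[dict] = field(default_factory=list)

    @property
    def admissible(self) -> bool:
        return self.nonneg_ok and self.normalized_ok and self.slot_mass_ok

    def to_json(self) -> str:
        payload = {
            "alpha": self.alpha,
            "k_alpha": self.k_alpha,
            "density_min": self.density_min,
            "density_max": self.density_max,
            "nonneg_ok": self.nonneg_ok,
            "normalized_ok": self.normalized_ok,
            "slot_mass_ok": self.slot_mass_ok,
            "admissible": self.admissible,
            "per_t": self.per_t,
        }
        return json.dumps(payload, sort_keys=True)


def check_admissibility(
    params: FractionalParams,
    x_grid: Sequence[float],
    t_grid: Sequence[float],
    settings: SeriesSettings | None = None,
    x0: float = 0.0,
    norm_tol: float = 1e-3,
) -> AdmissibilityReport:
    """Verify that (alpha, K_alpha) yields a proper probability density.

    ``x_grid`` supplies both the density evaluation points and (as
    consecutive cells) the slots whose probability masses are bounded by 1.
    Parameter pairs outside ``0 < alpha < 2`` or ``K <= 0`` never reach this
    function: :class:`FractionalParams` rejects them at construction.
    """
    if settings is None:
        settings = SeriesSettings()
    x_grid = np.asarray(x_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if x_grid.size == 0 or t_grid.size == 0:
        raise ValueError("x_grid and t_grid must be non-empty")
    if (t_grid <= 0).any():
        raise ValueError("all t values must be strictly positive")

    dmin, dmax = math.inf, -math.inf
    nonneg_ok = True
    normalized_ok = True
    slot_mass_ok = True
    per_t: list[dict] = []
    for t in t_grid:
        dens = propagator_profile(x_grid, x0, float(t), params, settings)
        dmin = min(dmin, float(dens.min()))
        dmax = max(dmax, float(dens.max()))
        if (dens < -1e-9).any():
            nonneg_ok = False
        total = propagator_mass(params, float(t), settings)
        if abs(total - 1.0) > norm_tol:
            normalized_ok = False
        if x_grid.size >= 2:
            # trapezoid slot masses over consecutive grid cells
            slot_masses = 0.5 * (dens[1:] + dens[:-1]) * np.diff(x_grid)
            max_slot = float(slot_masses.max())
            if (slot_masses > 1.0 + 1e-9).any():
                slot_mass_ok = False
        else:
            max_slot = float("nan")
        per_t.append(
            {
                "t": float(t),
                "density_min": float(dens.min()),
                "density_max": float(dens.max()),
                "total_mass": total,
                "max_slot_mass": max_slot,
            }
        )
    return AdmissibilityReport(
        alpha=params.alpha,
        k_alpha=params.k_alpha,
        density_min=dmin,
        density_max=dmax,
        nonneg_ok=nonneg_ok,
        normalized_ok=normalized_ok,
        slot_mass_ok=slot_mass_ok,
        per_t=per_t,
    )
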
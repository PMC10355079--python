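"""Optimal-migration models: flight range, energy- and time-minimizing
flight numbers.

The flight range equation relates fuel load f (proportion of lean body
mass) to potential flight distance

    Y(f) = c (1 - 1 / sqrt(1 + f)),

with c a composite coefficient (km) covering morphology and energy
conversion efficiency; c = 15000 km is a reasonable shorebird value and the
package default.

Energy minimizers maximize distance per unit fuel R(f) = (Y(f) - Y(f0)) / f,
where f0 is the energy cost of search/settling at a stopover; the number of
flights over distance D is D / Y(f*) for the optimal departure load f*.

Time minimizers choose the integer number of flights n minimizing the total
migration time

    T(n) = n ( (1/k) (c^2 / (c - D/n)^2 - 1) + te ),

with k the fuel deposition rate (proportion of lean body mass per day) and
te the search/settling time cost (days).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "DEFAULT_C_KM",
    "EnergyMinSpec",
    "TimeMinSpec",
    "flight_range",
    "optimal_departure_fuel",
    "n_flights_energy",
    "total_migration_time",
    "optimal_n_time",
    "optimal_n_time_continuous",
    "sweep_energy",
    "sweep_time",
]

DEFAULT_C_KM = 15000.0


def flight_range(f, c: float = DEFAULT_C_KM):
    """Potential flight distance Y(f) = c(1 - 1/sqrt(1+f)) in km."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("fuel load f must be >= 0")
    if c <= 0:
        raise ValueError("c must be positive")
    out = c * (1.0 - 1.0 / np.sqrt(1.0 + f))
    return float(out) if out.ndim == 0 else out


def optimal_departure_fuel(f0: float, c: float = DEFAULT_C_KM, xatol: float = 1e-6) -> float:
    """Departure fuel load f* maximizing distance per unit fuel
    R(f) = (Y(f) - Y(f0)) / f.

    Solved by bounded scalar minimization of -R; the bracket [1e-9, 10] is
    far wider than any biologically plausible optimum.
    """
    if not 0.0 < f0 < 1.0:
        raise ValueError("f0 must be in (0, 1)")
    y0 = flight_range(f0, c)

    def neg_rate(f):
        return -(flight_range(f, c) - y0) / f

    res = minimize_scalar(neg_rate, bounds=(1e-9, 10.0), method="bounded",
                          options={"xatol": xatol})
    if not np.isfinite(res.fun):
        raise RuntimeError("non-finite objective in fuel optimization")
    return float(res.x)


def n_flights_energy(D: float, f0: float, c: float = DEFAULT_C_KM,
                     fractional: bool = False) -> float:
    """Number of flights for an energy minimizer over distance D (km).

    Divides D by the range at the optimal departure fuel; a partial flight
    still requires a flight, so the count is rounded up (pass
    ``fractional=True`` for the raw quotient).
    """
    if D <= 0:
        raise ValueError("D must be positive")
    y_star = flight_range(optimal_departure_fuel(f0, c), c)
    q = D / y_star
    return q if fractional else int(math.ceil(q - 1e-12))


def total_migration_time(n: int, D: float, k: float, te: float,
                         c: float = DEFAULT_C_KM) -> float:
    """Total migration time T(n) in days for n equal flights over D km."""
    if k <= 0 or te < 0:
        raise ValueError("require k > 0 and te >= 0")
    step = D / n
    if step >= c:
        raise ValueError("infeasible: per-flight distance D/n must be < c")
    return n * ((1.0 / k) * (c**2 / (c - step) ** 2 - 1.0) + te)


def optimal_n_time(D: float, k: float, te: float, c: float = DEFAULT_C_KM,
                   n_max: int = 50) -> int:
    """Integer number of flights minimizing total migration time.

    Exhaustive over n in [1, n_max]; ties break toward fewer flights.  A
    warning is raised when the optimum sits at n_max (grid too small).
    """
    if not 0 < D < c:
        raise ValueError("require 0 < D < c for a feasible single flight")
    ns = np.arange(1, n_max + 1)
    steps = D / ns
    T = ns * ((1.0 / k) * (c**2 / (c - steps) ** 2 - 1.0) + te)
    best = int(ns[np.argmin(T)])
    if best == n_max:
        warnings.warn("optimal n at n_max boundary; increase n_max", stacklevel=2)
    return best


def optimal_n_time_continuous(D: float, k: float, te: float,
                              c: float = DEFAULT_C_KM) -> float:
    """Continuous-relaxation diagnostic: real-valued n minimizing T(n)."""
    res = minimize_scalar(
        lambda n: total_migration_time(n, D, k, te, c),
        bounds=(max(D / c * (1 + 1e-9), 1e-6), 200.0),
        method="bounded",
    )
    return float(res.x)


@dataclass(frozen=True)
class EnergyMinSpec:
    """Sweep specification for the energy-minimization prediction surface."""

    c: float = DEFAULT_C_KM
    f0_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.005, 0.1 + 1e-9, 0.005), 3)
    )
    D_grid: np.ndarray = field(default_factory=lambda: np.arange(500, 3501, 100))


@dataclass(frozen=True)
class TimeMinSpec:
    """Sweep specification for the time-minimization prediction surface."""

    c: float = DEFAULT_C_KM
    k_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.01, 0.04 + 1e-9, 0.01), 3)
    )
    te_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.1, 2.0 + 1e-9, 0.1), 2)
    )
    D_grid: np.ndarray = field(default_factory=lambda: np.arange(500, 3501, 100))
    n_max: int = 50


def sweep_energy(spec: EnergyMinSpec = EnergyMinSpec()) -> pd.DataFrame:
    """Optimal flight counts over the (D, f0) grid (long format)."""
    rows = []
    for f0 in spec.f0_grid:
        f_star = optimal_departure_fuel(float(f0), spec.c)
        y_star = flight_range(f_star, spec.c)
        for D in spec.D_grid:
            q = float(D) / y_star
            rows.append(
                {
                    "D_km": int(D),
                    "f0": float(f0),
                    "f_star": f_star,
                    "range_km": y_star,
                    "n_star": int(math.ceil(q - 1e-12)),
                    "n_fractional": q,
                }
            )
    return pd.DataFrame(rows)


def sweep_time(spec: TimeMinSpec = TimeMinSpec()) -> pd.DataFrame:
    """Optimal flight counts over the (D, k, te) grid (long format)."""
    rows = []
    for k in spec.k_grid:
        for te in spec.te_grid:
            for D in spec.D_grid:
                rows.append(
                    {
                        "D_km": int(D),
                        "k": float(k),
                        "te_d": float(te),
                        "n_star": optimal_n_time(float(D), float(k), float(te),
                                                 spec.c, spec.n_max),
                    }
                )
    return pd.DataFrame(rows)
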
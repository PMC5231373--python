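"""Kohlrausch–Williams–Watts (stretched-exponential) relaxation fitting.

A droplet deformed by a magnetic field, or relaxing back to a sphere after
the field is removed, changes each geometric magnitude y(t) (aspect ratio,
major diameter, area) according to the stretched-exponential law

    y(t) = a + b * (1 - exp(-(t / lambda_c) ** beta))

where ``a`` is the initial value of the magnitude, ``b`` the signed total
amplitude of the change (positive for elongation, negative for dimension
recovery), ``lambda_c`` the characteristic relaxation time in seconds and
``beta`` the stretching exponent (``beta = 1`` is a mono-exponential
process; ``beta < 1`` broadens the underlying relaxation-time
distribution).  The equivalent decaying parameterization
``y(t) = a' + b' * exp(-(t/lambda_c)**beta)`` with ``a' = a + b``,
``b' = -b`` is available through ``form="decaying"``.

Each curve is fitted by minimizing the sum of squared residuals with a
seeded DE/rand/1/bin differential-evolution global search followed by a
Nelder–Mead polish, which recovers noiseless parameters to near machine
precision and is robust to the multi-modal objective produced by the
(lambda_c, beta) coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .features import RelaxationCurve

__all__ = ["KWWParams", "DEConfig", "KWWFit", "kww_value", "fit_kww", "r_squared"]


@dataclass(frozen=True)
class KWWParams:
    """Parameters of one stretched-exponential relaxation curve.

    Units of ``a`` and ``b`` follow the magnitude being described
    (dimensionless for aspect ratio, um for major diameter, um^2 for area);
    ``lambda_c`` is in seconds and ``beta`` dimensionless.
    """

    a: float
    b: float
    lambda_c: float
    beta: float

    def __post_init__(self) -> None:
        if not self.lambda_c > 0:
            raise ValueError(f"lambda_c must be positive, got {self.lambda_c}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution hyperparameters (DE/rand/1/bin).

    The defaults are population 40 (10 per parameter), F = 0.8, CR = 0.9,
    at most 300 generations with a 1e-8 stagnation tolerance, followed by a
    derivative-free simplex polish from the DE optimum.
    """

    population_size: int = 40
    weight_f: float = 0.8
    crossover_cr: float = 0.9
    max_generations: int = 300
    tolerance: float = 1e-8
    seed: int = 0
    bounds: tuple[tuple[float, float], ...] | None = None
    polish: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be at least 4")
        if not 0 < self.weight_f <= 2:
            raise ValueError("weight_f must be in (0, 2]")
        if not 0 <= self.crossover_cr <= 1:
            raise ValueError("crossover_cr must be in [0, 1]")
        if self.bounds is not None:
            for lo, hi in self.bounds:
                if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                    raise ValueError("bounds must be finite with low < high")


@dataclass(frozen=True)
class KWWFit:
    """Result of fitting one relaxation curve."""

    params: KWWParams
    r2: float
    n_points: int
    de_evals: int
    seed: int
    bounds: tuple[tuple[float, float], ...]
    converged: bool
    droplet_id: str = ""
    magnitude: str = ""
    process: str = ""


def kww_value(
    t: float | Sequence[float] | np.ndarray,
    p: KWWParams,
    form: str = "rising",
) -> float | np.ndarray:
    """Evaluate the stretched-exponential law at time(s) ``t`` (seconds).

    With the canonical ``"rising"`` form the value at ``t = 0`` is ``a``
    and the ``t -> inf`` plateau is ``a + b``; the ``"decaying"`` form
    starts at ``a + b`` and decays to ``a``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("times must be non-negative")
    decay = np.exp(-((t_arr / p.lambda_c) ** p.beta))
    if form == "rising":
        out = p.a + p.b * (1.0 - decay)
    elif form == "decaying":
        out = p.a + p.b * decay
    else:
        raise ValueError(f"unknown form {form!r}")
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def r_squared(observed: Sequence[float], fitted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SSres/SStot."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.size == 0 or obs.shape != fit.shape:
        raise ValueError("observed and fitted must be equal-length and non-empty")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero total variance: R^2 undefined")
    ss_res = float(np.sum((obs - fit) ** 2))
    return 1.0 - ss_res / ss_tot


def default_bounds(
    times: np.ndarray, values: np.ndarray
) -> tuple[tuple[float, float], ...]:
    """Data-driven box constraints for (a, b, lambda_c, beta).

    ``a`` may range three data spans beyond the observed values, ``b`` is
    sign-free within three spans, ``lambda_c`` up to ten times the last
    sampled time and ``beta`` up to 15 (observed stretching exponents reach
    12 in strongly non-exponential recoveries).
    """
    span = float(values.max() - values.min())
    if span == 0.0:
        raise ValueError("flat curve: KWW parameters are unidentifiable")
    return (
        (float(values.min()) - 3.0 * span, float(values.max()) + 3.0 * span),
        (-3.0 * span, 3.0 * span),
        (0.1, 10.0 * float(times.max())),
        (0.1, 15.0),
    )


def _fit_arrays(
    times: np.ndarray, values: np.ndarray, de: DEConfig
) -> tuple[KWWParams, float, int, bool, tuple[tuple[float, float], ...]]:
    bounds = de.bounds if de.bounds is not None else default_bounds(times, values)
    if len(bounds) != 4:
        raise ValueError("need bounds for the four parameters (a, b, lambda_c, beta)")

    def sse(p: np.ndarray) -> float:
        a, b, lam, beta = p
        return float(np.sum((a + b * (1.0 - np.exp(-((times / lam) ** beta))) - values) ** 2))

    # scipy's popsize is per-dimension; round up to reach the configured total.
    popsize = max(1, math.ceil(de.population_size / 4))
    result = differential_evolution(
        sse,
        bounds=bounds,
        strategy="rand1bin",
        popsize=popsize,
        mutation=de.weight_f,
        recombination=de.crossover_cr,
        maxiter=de.max_generations,
        tol=de.tolerance,
        seed=de.seed,
        polish=False,
        init="latinhypercube",
    )
    x, nfev = result.x, int(result.nfev)
    if de.polish:
        polished = minimize(
            sse,
            x,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000, "maxfev": 10000},
        )
        if polished.fun <= result.fun:
            x = polished.x
        nfev += int(polished.nfev)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x = np.clip(x, lo, hi)
    params = KWWParams(a=float(x[0]), b=float(x[1]), lambda_c=float(x[2]), beta=float(x[3]))
    fitted = kww_value(times, params)
    return params, r_squared(values, fitted), nfev, bool(result.success), tuple(bounds)


def fit_kww(curve: "RelaxationCurve", de: DEConfig | None = None) -> KWWFit:
    """Fit the stretched-exponential model to one relaxation curve.

    Parameters
    ----------
    curve
        A :class:`~droprelax.features.RelaxationCurve` (or any object with
        ``times_s``, ``values`` and the identifying labels).
    de
        Optimizer configuration; defaults to :class:`DEConfig`.

    Returns
    -------
    KWWFit with the fitted (a, b, lambda_c, beta), the coefficient of
    determination, and the optimizer bookkeeping needed to reproduce the
    fit (seed, bounds, function evaluations).
    """
    de = de or DEConfig()
    times = np.asarray(curve.times_s, dtype=float)
    values = np.asarray(curve.values, dtype=float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size < 5:
        raise ValueError("need at least 5 points to fit 4 parameters")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.any(times > 0):
        raise ValueError("need positive times beyond t=0")
    params, r2, nfev, converged, bounds = _fit_arrays(times, values, de)
    return KWWFit(
        params=params,
        r2=r2,
        n_points=int(times.size),
        de_evals=nfev,
        seed=de.seed,
        bounds=bounds,
        converged=converged,
        droplet_id=getattr(curve, "droplet_id", ""),
        magnitude=getattr(curve, "magnitude", ""),
        process=getattr(curve, "process", ""),
    )
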
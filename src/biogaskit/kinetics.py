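"""Batch anaerobic-digestion kinetics: simulation, fitting, optimal HRT.

Cumulative gas production in a batch digester is modelled with either the
modified Gompertz curve,

    B(t) = b0 * exp(-exp(rmax*e/b0 * (lag - t) + 1)),

the standard sigmoidal form for batch anaerobic digestion (asymptote b0,
maximum daily rate rmax, lag time lag), or first-order kinetics
``B(t) = b0*(1 - exp(-k*t))``.  Temperature enters through a cardinal
temperature model (CTMI): a dimensionless multiplier in [0, 1] that is 1 at
the mesophilic optimum and 0 at or beyond the cardinal minimum/maximum,
applied to the rate parameter.  With the default cardinal triple
(10, 35, 45) degC a mesophilic digester at 35 degC runs at full rate, a
psychrophilic one at 25 degC runs slower (longer optimal HRT), and a
45 degC digester produces nothing -- the qualitative temperature response
observed for sewage-sludge digestion.

The "optimal" hydraulic retention time is operationalized either as the
time to reach a fraction q of the asymptote (default q = 0.95) or as the
time of peak daily production rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .errors import FitError

__all__ = [
    "BatchKineticsParams",
    "TemperatureResponse",
    "BatchSeries",
    "FitResult",
    "gompertz_cumulative",
    "first_order_cumulative",
    "cumulative_model",
    "temperature_factor",
    "simulate_batch",
    "fit_kinetics",
    "optimal_hrt",
    "series_to_frame",
    "read_series_csv",
    "write_series_csv",
]

ModelId = Literal["gompertz", "first_order"]

#: Columns of the time-series CSV dialect used throughout the package.
SERIES_COLUMNS = (
    "reactor_id",
    "day",
    "cumulative_biogas",
    "methane_fraction",
    "temperature_c",
    "ph",
    "loading_ratio",
)


@dataclass(frozen=True)
class BatchKineticsParams:
    """Parameters of a cumulative batch-production model.

    b0: ultimate cumulative yield (volume units; whatever the data are in).
    rmax: maximum daily production rate (volume/day), Gompertz model.
    k: first-order rate constant (1/day), first-order model.
    lag: lag phase (days), Gompertz model only.
    """

    b0: float
    rmax: float = 0.0
    lag: float = 0.0
    k: float = 0.0
    model_id: ModelId = "gompertz"

    def __post_init__(self) -> None:
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if self.lag < 0:
            raise ValueError("lag must be non-negative")
        if self.model_id == "gompertz" and self.rmax <= 0:
            raise ValueError("gompertz model requires rmax > 0")
        if self.model_id == "first_order" and self.k <= 0:
            raise ValueError("first_order model requires k > 0")
        if self.model_id not in ("gompertz", "first_order"):
            raise ValueError(f"unknown model_id {self.model_id!r}")

    def scaled_rate(self, factor: float) -> "BatchKineticsParams":
        """Return a copy with the rate parameter multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("rate factor must be positive; use the zero-curve "
                             "path for dead temperatures")
        if self.model_id == "gompertz":
            return replace(self, rmax=self.rmax * factor)
        return replace(self, k=self.k * factor)


@dataclass(frozen=True)
class TemperatureResponse:
    """Cardinal temperatures (degC) for the CTMI rate multiplier."""

    t_min: float = 10.0
    t_opt: float = 35.0
    t_max: float = 45.0

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError("cardinal temperatures must satisfy t_min < t_opt < t_max")


@dataclass(frozen=True)
class BatchSeries:
    """One reactor's batch time series with its condition labels."""

    times: np.ndarray  # days, strictly increasing, >= 0
    cumulative_biogas: np.ndarray  # volume units, non-decreasing
    methane_fraction: np.ndarray  # per-observation fraction in [0, 1]
    reactor_id: str = "r0"
    temperature_c: float = 35.0
    ph: float = 7.0
    loading_ratio: str = "1:3"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.cumulative_biogas, dtype=float)
        m = np.asarray(self.methane_fraction, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative_biogas", v)
        object.__setattr__(self, "methane_fraction", m)
        if not (len(t) == len(v) == len(m)):
            raise ValueError("times, cumulative_biogas, methane_fraction must align")
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("times must be strictly increasing and non-negative")
        if np.any(np.diff(v) < -1e-9):
            raise ValueError("cumulative_biogas must be non-decreasing")
        if len(m) and (np.nanmin(m) < 0 or np.nanmax(m) > 1):
            raise ValueError("methane_fraction must lie in [0, 1]")

    @property
    def cumulative_methane(self) -> np.ndarray:
        return self.cumulative_biogas * self.methane_fraction


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus diagnostics from nonlinear least squares."""

    params: BatchKineticsParams
    sse: float
    stderr: dict[str, float | None]
    converged: bool
    n_obs: int
    lmfit_result: object = field(repr=False, compare=False, default=None)


# --------------------------------------------------------------------------
# cumulative models


def gompertz_cumulative(p: BatchKineticsParams, t) -> np.ndarray | float:
    """Modified Gompertz cumulative volume at time(s) ``t`` (days)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    inner = p.rmax * math.e / p.b0 * (p.lag - t_arr) + 1.0
    # exp(inner) saturates to "no gas yet" well before float overflow
    out = p.b0 * np.exp(-np.exp(np.minimum(inner, 50.0)))
    return out if isinstance(t, (np.ndarray, list, tuple)) else float(out)


def first_order_cumulative(p: BatchKineticsParams, t) -> np.ndarray | float:
    """First-order cumulative volume ``b0*(1 - exp(-k t))``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = p.b0 * (1.0 - np.exp(-p.k * t_arr))
    return out if isinstance(t, (np.ndarray, list, tuple)) else float(out)


def cumulative_model(p: BatchKineticsParams, t):
    """Dispatch on ``p.model_id``."""
    if p.model_id == "gompertz":
        return gompertz_cumulative(p, t)
    return first_order_cumulative(p, t)


def _daily_rate(p: BatchKineticsParams, t: float) -> float:
    """Analytic dB/dt for either model."""
    if p.model_id == "gompertz":
        u = p.rmax * math.e / p.b0 * (p.lag - t) + 1.0
        return p.b0 * math.exp(-math.exp(u)) * math.exp(u) * (p.rmax * math.e / p.b0)
    return p.b0 * p.k * math.exp(-p.k * t)


# --------------------------------------------------------------------------
# temperature response


def temperature_factor(T: float, tr: TemperatureResponse = TemperatureResponse()) -> float:
    """CTMI dimensionless rate multiplier in [0, 1].

    f(T) = (T-t_max)(T-t_min)^2 / { (t_opt-t_min) *
           [ (t_opt-t_min)(T-t_opt) - (t_opt-t_max)(t_opt+t_min-2T) ] }

    Clipped to 0 outside the open interval (t_min, t_max); exactly 1 at
    t_opt.  Raises on a degenerate cardinal triple whose denominator
    vanishes at the requested temperature.
    """
    if T <= tr.t_min or T >= tr.t_max:
        return 0.0
    num = (T - tr.t_max) * (T - tr.t_min) ** 2
    den = (tr.t_opt - tr.t_min) * (
        (tr.t_opt - tr.t_min) * (T - tr.t_opt)
        - (tr.t_opt - tr.t_max) * (tr.t_opt + tr.t_min - 2.0 * T)
    )
    if den == 0.0:
        raise ValueError(
            f"degenerate cardinal temperatures {tr}: CTMI denominator is zero at T={T}"
        )
    return float(np.clip(num / den, 0.0, 1.0))


def simulate_batch(
    p: BatchKineticsParams,
    tr: TemperatureResponse,
    T: float,
    times: Sequence[float],
    methane_fraction: float | Callable[[np.ndarray], np.ndarray] = 0.41,
    reactor_id: str = "sim",
    ph: float = 8.5,
    loading_ratio: str = "1:3",
) -> BatchSeries:
    """Deterministic batch simulation at temperature ``T``.

    The CTMI factor scales the rate parameter (rmax or k).  Outside the
    viable window (factor 0) the curve is identically zero and the series
    is flagged ``"no_production"`` rather than raising: a thermally dead
    digester is a result, not an error.
    """
    t = np.asarray(times, dtype=float)
    f = temperature_factor(T, tr)
    if callable(methane_fraction):
        mf = np.asarray(methane_fraction(t), dtype=float)
    else:
        mf = np.full_like(t, float(methane_fraction))
    if f == 0.0:
        return BatchSeries(
            times=t,
            cumulative_biogas=np.zeros_like(t),
            methane_fraction=mf,
            reactor_id=reactor_id,
            temperature_c=T,
            ph=ph,
            loading_ratio=loading_ratio,
            flags=("no_production",),
        )
    curve = cumulative_model(p.scaled_rate(f), t)
    return BatchSeries(
        times=t,
        cumulative_biogas=np.asarray(curve, dtype=float),
        methane_fraction=mf,
        reactor_id=reactor_id,
        temperature_c=T,
        ph=ph,
        loading_ratio=loading_ratio,
    )


# --------------------------------------------------------------------------
# fitting


def _initial_guess(t: np.ndarray, y: np.ndarray, model_id: ModelId) -> dict[str, float]:
    # b0 <- 1.2x max observed; rmax <- max finite difference;
    # lag <- first time the signal exceeds 5% of max.
    b0 = 1.2 * float(np.max(y)) if np.max(y) > 0 else 1.0
    dy = np.diff(y) / np.diff(t)
    rmax = float(np.max(dy)) if len(dy) and np.max(dy) > 0 else b0 / max(t[-1], 1.0)
    above = t[y > 0.05 * np.max(y)] if np.max(y) > 0 else t
    lag = float(above[0]) if len(above) else 0.0
    if model_id == "first_order":
        return {"b0": b0, "k": max(rmax / b0, 1e-3)}
    return {"b0": b0, "rmax": rmax, "lag": lag}


def fit_kinetics(
    series: BatchSeries,
    model_id: ModelId = "gompertz",
    init_strategy: Literal["heuristic", "random"] = "heuristic",
    seed: int | None = None,
) -> FitResult:
    """Nonlinear least squares of a cumulative model to one reactor series.

    Deterministic given ``seed`` and ``init_strategy``: the default
    heuristic start needs no randomness at all; ``"random"`` perturbs the
    heuristic start by up to +/-30% with a seeded generator (useful to
    probe sensitivity to initialization).  Requires >= 4 observations.
    Raises :class:`FitError` carrying the last iterate on non-convergence.
    """
    t = series.times
    y = series.cumulative_biogas
    if len(t) < 4:
        raise ValueError(f"need >= 4 observations to fit, got {len(t)}")
    if np.any(y < 0):
        raise ValueError("cumulative volumes must be non-negative")

    guess = _initial_guess(t, y, model_id)
    if init_strategy == "random":
        rng = np.random.default_rng(seed)
        guess = {k: v * float(rng.uniform(0.7, 1.3)) for k, v in guess.items()}
    elif init_strategy != "heuristic":
        raise ValueError(f"unknown init_strategy {init_strategy!r}")

    if model_id == "gompertz":
        def func(t, b0, rmax, lag):
            return b0 * np.exp(-np.exp(rmax * math.e / b0 * (lag - t) + 1.0))
        model = lmfit.Model(func)
        params = model.make_params(
            b0=dict(value=guess["b0"], min=1e-12),
            rmax=dict(value=guess["rmax"], min=1e-12),
            lag=dict(value=guess["lag"], min=0.0),
        )
    elif model_id == "first_order":
        def func(t, b0, k):
            return b0 * (1.0 - np.exp(-k * t))
        model = lmfit.Model(func)
        params = model.make_params(
            b0=dict(value=guess["b0"], min=1e-12),
            k=dict(value=guess["k"], min=1e-12),
        )
    else:
        raise ValueError(f"unknown model_id {model_id!r}")

    result = model.fit(y, params, t=t)
    best = {name: float(par.value) for name, par in result.params.items()}
    if not result.success:
        raise FitError(f"fit did not converge: {result.message}", last_params=best)

    fitted = BatchKineticsParams(model_id=model_id, **best)
    stderr = {
        name: (float(par.stderr) if par.stderr is not None else None)
        for name, par in result.params.items()
    }
    return FitResult(
        params=fitted,
        sse=float(np.sum(result.residual**2)),
        stderr=stderr,
        converged=bool(result.success),
        n_obs=len(t),
        lmfit_result=result,
    )


# --------------------------------------------------------------------------
# optimal HRT


def optimal_hrt(
    p: BatchKineticsParams,
    criterion: Literal["fraction_of_asymptote", "peak_daily_rate"] = "fraction_of_asymptote",
    q: float = 0.95,
    tol_days: float = 0.01,
) -> float:
    """Operational optimal hydraulic retention time (days).

    ``fraction_of_asymptote``: smallest t with B(t) >= q*b0, located by
    root bracketing/bisection to ``tol_days``.  ``peak_daily_rate``:
    argmax of dB/dt (the inflection point for Gompertz; t = 0 for
    first-order kinetics, whose rate decays monotonically).
    """
    if criterion == "fraction_of_asymptote":
        if not (0.0 < q < 1.0):
            raise ValueError("q must lie strictly between 0 and 1")
        target = q * p.b0

        def g(t: float) -> float:
            return float(cumulative_model(p, float(t))) - target

        hi = max(p.lag, 1.0)
        while g(hi) < 0:
            hi *= 2.0
            if hi > 1e7:  # pragma: no cover - pathological parameters
                raise RuntimeError("failed to bracket the q-fraction time")
        lo = 0.0
        return float(brentq(g, lo, hi, xtol=tol_days))

    if criterion == "peak_daily_rate":
        if p.model_id == "first_order":
            return 0.0
        # bracket the Gompertz inflection t* = lag + b0/(rmax*e)
        guess = p.lag + p.b0 / (p.rmax * math.e)
        res = minimize_scalar(
            lambda t: -_daily_rate(p, t),
            bounds=(0.0, max(4.0 * guess, guess + 10.0)),
            method="bounded",
            options={"xatol": tol_days / 10},
        )
        return float(res.x)

    raise ValueError(f"unknown criterion {criterion!r}")


# --------------------------------------------------------------------------
# time-series CSV dialect


def series_to_frame(series: Iterable[BatchSeries]) -> pd.DataFrame:
    """Tidy long-format DataFrame in the package's CSV dialect."""
    rows = []
    for s in series:
        for t, v, m in zip(s.times, s.cumulative_biogas, s.methane_fraction):
            rows.append(
                {
                    "reactor_id": s.reactor_id,
                    "day": t,
                    "cumulative_biogas": v,
                    "methane_fraction": m,
                    "temperature_c": s.temperature_c,
                    "ph": s.ph,
                    "loading_ratio": s.loading_ratio,
                }
            )
    return pd.DataFrame(rows, columns=list(SERIES_COLUMNS))


def write_series_csv(series: Iterable[BatchSeries], path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def read_series_csv(source) -> list[BatchSeries]:
    """Read the time-series CSV dialect back into BatchSeries objects."""
    df = pd.read_csv(source)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"series CSV missing columns: {missing}")
    out = []
    for rid, grp in df.groupby("reactor_id", sort=True):
        grp = grp.sort_values("day")
        out.append(
            BatchSeries(
                times=grp["day"].to_numpy(dtype=float),
                cumulative_biogas=grp["cumulative_biogas"].to_numpy(dtype=float),
                methane_fraction=grp["methane_fraction"].to_numpy(dtype=float),
                reactor_id=str(rid),
                temperature_c=float(grp["temperature_c"].iloc[0]),
                ph=float(grp["ph"].iloc[0]),
                loading_ratio=str(grp["loading_ratio"].iloc[0]),
            )
        )
    return out
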
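"""Survival analysis for bacterial replicative aging.

Quantifies aging in mother-machine lifespan data through two estimators:
the nonparametric Kaplan–Meier product-limit survival curve (delegated to
:mod:`lifelines`) and the parametric Gompertz survival law

.. math::

    S(t) = \\exp\\left(-\\frac{a}{b}\\left(e^{bt} - 1\\right)\\right),
    \\qquad \\lambda(t) = a\\, e^{bt},

where ``a`` is the initial hazard and ``b`` the aging (hazard-accumulation)
rate.  A strictly positive ``b`` means mortality risk grows exponentially
with time — the operational signature of aging; ``b = 0`` recovers the
memoryless exponential lifetime ``S(t) = exp(-a t)``.  For a population
that keeps dividing, persistence requires ``b`` well below 1 per unit of
the chosen clock.

Fits are available as least squares on the Kaplan–Meier curve
(``nls_on_km``, the survival-curve fit typically shown in figures) or as a
censoring-aware maximum-likelihood fit (``mle``), with nonparametric
bootstrap confidence bounds resampled over cells.  Event times may be
measured on a calendar clock (hours) or as replicative-generation counts;
fitted objects carry the clock label so h^-1 and gen^-1 rates are never
mixed up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.optimize import least_squares, minimize
from sklearn.base import BaseEstimator

__all__ = [
    "SurvivalCurve",
    "GompertzFit",
    "GompertzFitter",
    "kaplan_meier",
    "gompertz_survival",
    "gompertz_hazard",
    "gompertz_isf",
    "fit_gompertz",
    "fit_gompertz_curve",
    "event_table_from_lifespans",
    "compare_groups",
]

_LOG_A_BOUNDS = (-30.0, 10.0)
_B_BOUNDS = (0.0, 100.0)
_B0_GRID = (0.0, 0.02, 0.1, 0.3, 1.0)


def _validate_ab(a: float, b: float) -> None:
    if not np.isfinite(a) or a <= 0:
        raise ValueError(f"initial hazard a must be finite and > 0, got {a}")
    if not np.isfinite(b) or b < 0:
        raise ValueError(f"aging rate b must be finite and >= 0, got {b}")


def _phi(x: np.ndarray) -> np.ndarray:
    """expm1(x)/x with the continuous limit phi(0) = 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    with np.errstate(over="ignore"):
        out[nz] = np.expm1(x[nz]) / x[nz]
    return out


def gompertz_survival(t, a: float, b: float):
    """Gompertz survival S(t) = exp(-(a/b)(e^{bt}-1)); b=0 gives exp(-at)."""
    _validate_ab(a, b)
    scalar = np.isscalar(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    # cumulative hazard written as a*t*phi(b*t) so the b->0 limit is smooth
    ch = a * t * _phi(b * t)
    s = np.exp(-ch)
    return float(s) if scalar else s


def gompertz_hazard(t, a: float, b: float):
    """Gompertz hazard (mortality risk) lambda(t) = a * e^{bt}."""
    _validate_ab(a, b)
    scalar = np.isscalar(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lam = a * np.exp(b * t)
    return float(lam) if scalar else lam


def gompertz_isf(s, a: float, b: float):
    """Inverse survival function: the time T at which S(T) = s.

    Used by the lifespan sampler (draw U ~ Uniform(0,1], return isf(U)), so
    plugging the sample back into :func:`gompertz_survival` returns the draw.
    """
    _validate_ab(a, b)
    scalar = np.isscalar(s)
    s = np.asarray(s, dtype=float)
    if np.any((s <= 0) | (s > 1)):
        raise ValueError("survival probability s must be in (0, 1]")
    if b == 0:
        t = -np.log(s) / a
    else:
        t = np.log1p(-(b / a) * np.log(s)) / b
    return float(t) if scalar else t


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate as a right-continuous step function.

    ``times`` are the sorted unique observed times (deaths and censorings);
    ``survival`` holds S(t) just after each time; steps occur only at deaths.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    n: int
    all_censored: bool = False

    def evaluate(self, t) -> np.ndarray:
        """S(t) for arbitrary times (1 before the first event)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out

    def death_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Times with at least one death and S there (the fit support)."""
        mask = self.deaths > 0
        return self.times[mask], self.survival[mask]


def kaplan_meier(durations, event_observed=None) -> SurvivalCurve:
    """Kaplan–Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    ``d_i`` is the number of deaths at time ``t_i`` and ``n_i`` the number of
    cells still at risk; censored cells leave the risk set without a step.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.ndim != 1 or durations.size == 0:
        raise ValueError("durations must be a non-empty 1-d array")
    if np.any(durations < 0) or not np.all(np.isfinite(durations)):
        raise ValueError("durations must be finite and >= 0")
    if event_observed is None:
        event_observed = np.ones_like(durations, dtype=bool)
    event_observed = np.asarray(event_observed).astype(bool)
    if event_observed.shape != durations.shape:
        raise ValueError("event_observed must match durations in shape")

    all_censored = not event_observed.any()
    if all_censored:
        warnings.warn("all records censored: survival curve is flat at 1",
                      stacklevel=2)

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=event_observed)
    table = kmf.event_table
    # drop the synthetic t=0 entry row unless something was observed there
    observed = table["observed"].to_numpy()
    removed = table["removed"].to_numpy()
    keep = removed > 0
    times = table.index.to_numpy(dtype=float)[keep]
    sf = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return SurvivalCurve(
        times=times,
        survival=sf,
        at_risk=table["at_risk"].to_numpy()[keep],
        deaths=observed[keep],
        n=int(durations.size),
        all_censored=all_censored,
    )


# ---------------------------------------------------------------------------
# Gompertz fitting
# ---------------------------------------------------------------------------

@dataclass
class GompertzFit:
    """Point estimates and bootstrap 95% confidence bounds for (a, b)."""

    a: float
    b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    method: str
    gof: float
    clock: str = "hours"
    n: int = 0
    n_deaths: int = 0
    b_at_boundary: bool = False


def fit_gompertz_curve(t, s, x0: tuple[float, float] | None = None
                       ) -> tuple[float, float, float]:
    """Least-squares Gompertz fit to survival values ``s`` observed at ``t``.

    Returns ``(a, b, rmse)``.  By default multi-starts over a small grid of
    aging rates to avoid the flat-likelihood valley between
    exponential-like and strongly aging solutions; passing ``x0 = (a, b)``
    warm-starts a single solve (used by the bootstrap).
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 curve points to fit the Gompertz law")
    if np.any((s <= 0) | (s > 1 + 1e-12)):
        raise ValueError("survival values must lie in (0, 1]")

    # exponential-rate moment start for a
    a0 = max(-np.log(max(s.min(), 1e-12)) / max(t.max(), 1e-12), 1e-8)

    def resid(p):
        a = np.exp(p[0])
        ch = a * t * _phi(p[1] * t)
        return np.exp(-ch) - s

    if x0 is not None:
        starts = [(np.log(max(x0[0], 1e-12)), max(x0[1], 0.0))]
    else:
        starts = [(np.log(a0), b0) for b0 in _B0_GRID]
    best = None
    for start in starts:
        try:
            sol = least_squares(
                resid, x0=list(start),
                bounds=([_LOG_A_BOUNDS[0], _B_BOUNDS[0]],
                        [_LOG_A_BOUNDS[1], _B_BOUNDS[1]]),
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ValueError("Gompertz least-squares fit failed to converge")
    a_hat = float(np.exp(best.x[0]))
    b_hat = float(best.x[1])
    rmse = float(np.sqrt(2 * best.cost / t.size))
    return a_hat, b_hat, rmse


def _fit_mle(durations: np.ndarray, observed: np.ndarray,
             x0: tuple[float, float] | None = None
             ) -> tuple[float, float, float]:
    """Censoring-aware Gompertz maximum likelihood; returns (a, b, -loglik/n)."""
    t = durations
    ev = observed
    t_ev = t[ev]
    a0 = max(ev.sum() / max(t.sum(), 1e-12), 1e-8)

    def nll(p):
        log_a, b = p
        a = np.exp(log_a)
        ch = a * t * _phi(b * t)
        ll = np.sum(log_a + b * t_ev) - np.sum(ch)
        return -ll

    if x0 is not None:
        starts = [(np.log(max(x0[0], 1e-12)), max(x0[1], 0.0))]
    else:
        starts = [(np.log(a0), b0) for b0 in _B0_GRID]
    best = None
    for start in starts:
        sol = minimize(nll, x0=list(start), method="L-BFGS-B",
                       bounds=[_LOG_A_BOUNDS, _B_BOUNDS])
        if best is None or sol.fun < best.fun:
            best = sol
    a_hat = float(np.exp(best.x[0]))
    b_hat = float(best.x[1])
    return a_hat, b_hat, float(best.fun / t.size)


def _point_fit(durations, observed, method: str,
               x0: tuple[float, float] | None = None
               ) -> tuple[float, float, float]:
    if method == "nls_on_km":
        curve = kaplan_meier(durations, observed)
        td, sd = curve.death_points()
        if td.size < 3:
            raise ValueError(
                "degenerate event table: need >= 3 distinct death times for "
                "the survival-curve fit")
        return fit_gompertz_curve(td, np.clip(sd, 1e-12, 1.0), x0=x0)
    if method == "mle":
        return _fit_mle(durations, observed, x0=x0)
    raise ValueError(f"unknown method {method!r}; use 'nls_on_km' or 'mle'")


class GompertzFitter(BaseEstimator):
    """Fit the Gompertz survival law to possibly right-censored lifespans.

    Parameters
    ----------
    method : {"nls_on_km", "mle"}
        ``nls_on_km`` (default) least-squares fits S(t;a,b) to the
        Kaplan–Meier curve; ``mle`` maximizes the censoring-aware likelihood.
    n_boot : int
        Bootstrap resamples (over cells) for the 95% percentile confidence
        bounds.  Set to 0 to skip the bootstrap.
    random_state : int or None
        Seed for the bootstrap resampling.
    clock : str
        Label for the time axis ("hours" or "generations"); carried on the
        fit so rate units are unambiguous.

    Attributes
    ----------
    a_, b_ : float
        Initial hazard and aging rate in 1/clock units.  ``b_`` is
        constrained >= 0; a fit pinned at the boundary sets
        ``b_at_boundary_``.
    ci95_a_, ci95_b_ : tuple of float
        Percentile bootstrap 95% confidence bounds.
    gof_ : float
        RMSE of survival residuals (nls) or mean negative log-likelihood (mle).
    """

    def __init__(self, method: str = "nls_on_km", n_boot: int = 1000,
                 random_state: int | None = None, clock: str = "hours"):
        self.method = method
        self.n_boot = n_boot
        self.random_state = random_state
        self.clock = clock

    def fit(self, durations, event_observed=None):
        durations = np.asarray(durations, dtype=float)
        if durations.ndim != 1 or durations.size == 0:
            raise ValueError("durations must be a non-empty 1-d array")
        if event_observed is None:
            event_observed = np.ones_like(durations, dtype=bool)
        event_observed = np.asarray(event_observed).astype(bool)
        if event_observed.shape != durations.shape:
            raise ValueError("event_observed must match durations in shape")
        if event_observed.sum() == 0:
            raise ValueError("need at least one observed death to fit")
        if np.unique(durations[event_observed]).size < 3:
            raise ValueError(
                "degenerate data: fewer than 3 distinct death times")

        self.a_, self.b_, self.gof_ = _point_fit(
            durations, event_observed, self.method)
        self.n_ = int(durations.size)
        self.n_deaths_ = int(event_observed.sum())
        self.b_at_boundary_ = self.b_ < 1e-9

        if self.n_boot and self.n_boot > 0:
            rng = np.random.default_rng(self.random_state)
            a_s, b_s = [], []
            n = durations.size
            for _ in range(self.n_boot):
                idx = rng.integers(0, n, n)
                try:
                    a_b, b_b, _ = _point_fit(
                        durations[idx], event_observed[idx], self.method,
                        x0=(self.a_, self.b_))
                except ValueError:
                    continue
                a_s.append(a_b)
                b_s.append(b_b)
            if len(a_s) < max(10, self.n_boot // 2):
                warnings.warn("bootstrap mostly failed; CIs unreliable",
                              stacklevel=2)
            if a_s:
                self.ci95_a_ = (float(np.percentile(a_s, 2.5)),
                                float(np.percentile(a_s, 97.5)))
                self.ci95_b_ = (float(np.percentile(b_s, 2.5)),
                                float(np.percentile(b_s, 97.5)))
            else:
                self.ci95_a_ = (np.nan, np.nan)
                self.ci95_b_ = (np.nan, np.nan)
        else:
            self.ci95_a_ = (np.nan, np.nan)
            self.ci95_b_ = (np.nan, np.nan)
        return self

    def predict_survival(self, t):
        return gompertz_survival(t, self.a_, self.b_)

    def predict_hazard(self, t):
        return gompertz_hazard(t, self.a_, self.b_)

    def to_fit(self) -> GompertzFit:
        return GompertzFit(
            a=self.a_, b=self.b_, ci95_a=self.ci95_a_, ci95_b=self.ci95_b_,
            method=self.method, gof=self.gof_, clock=self.clock,
            n=self.n_, n_deaths=self.n_deaths_,
            b_at_boundary=self.b_at_boundary_)


def fit_gompertz(durations, event_observed=None, method: str = "nls_on_km",
                 n_boot: int = 1000, seed: int | None = None,
                 clock: str = "hours") -> GompertzFit:
    """Functional wrapper around :class:`GompertzFitter`."""
    fitter = GompertzFitter(method=method, n_boot=n_boot, random_state=seed,
                            clock=clock)
    fitter.fit(durations, event_observed)
    return fitter.to_fit()


def event_table_from_lifespans(records: pd.DataFrame, clock: str = "hours",
                               event: str = "lysis") -> pd.DataFrame:
    """Turn a lifespan table into (duration, observed) pairs for fitting.

    ``event="lysis"`` uses PI entry (aRL + PRL) as the death event;
    ``event="arrest"`` uses the end of proliferation.  ``clock`` selects
    calendar hours or aRL generation counts (only meaningful for the arrest
    event).  Censored traces contribute right-censored durations.
    """
    if event not in ("lysis", "arrest"):
        raise ValueError("event must be 'lysis' or 'arrest'")
    if clock not in ("hours", "generations"):
        raise ValueError("clock must be 'hours' or 'generations'")
    observed = ~records["censored"].to_numpy(dtype=bool)
    if clock == "generations":
        durations = records["arl_generations"].to_numpy(dtype=float)
    elif event == "arrest":
        durations = records["arl_h"].to_numpy(dtype=float)
    else:
        durations = (records["arl_h"] + records["prl_h"]).to_numpy(dtype=float)
    out = pd.DataFrame({"duration": durations, "observed": observed})
    for col in ("strain", "medium", "phenotype", "cell_id"):
        if col in records.columns:
            out[col] = records[col].to_numpy()
    return out


def compare_groups(fits: Mapping[str, GompertzFit]) -> tuple[pd.DataFrame, list]:
    """Order groups by aging rate and flag pairs with disjoint b intervals.

    Returns the table (sorted by ``b``) and a list of flagged group pairs
    whose 95% bounds on the aging rate do not overlap.
    """
    if not fits:
        raise ValueError("no fits to compare")
    rows = []
    for name, f in fits.items():
        if f is None:
            rows.append({"group": name, "a": np.nan, "b": np.nan,
                         "b_lo": np.nan, "b_hi": np.nan, "clock": ""})
            continue
        rows.append({"group": name, "a": f.a, "b": f.b,
                     "b_lo": f.ci95_b[0], "b_hi": f.ci95_b[1],
                     "clock": f.clock})
    table = pd.DataFrame(rows).sort_values("b", na_position="last")
    table = table.reset_index(drop=True)
    flagged = []
    valid = table.dropna(subset=["b"])
    names = valid["group"].tolist()
    for i in range(len(valid)):
        for j in range(i + 1, len(valid)):
            lo_i, hi_i = valid.iloc[i][["b_lo", "b_hi"]]
            lo_j, hi_j = valid.iloc[j][["b_lo", "b_hi"]]
            if np.isfinite([lo_i, hi_i, lo_j, hi_j]).all() and (
                    hi_i < lo_j or hi_j < lo_i):
                flagged.append((names[i], names[j]))
    return table, flagged
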
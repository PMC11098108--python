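"""Three-compartment population model of proliferation, arrest and lysis.

A declared reconstruction linking the single-cell measurements to culture
growth: proliferating cells divide at rate ``r``; each proliferating cell
transitions to the post-replicative compartment at the age-dependent
Gompertz hazard ``a * exp(b * age)``; post-replicative cells lyse at rate
``mu``.  The "age" clock is configurable: under the default *lineage-age*
clock a division leaves the tracked (old-pole) cell's clock running and
starts the newborn daughter at age zero, matching the measured aRL; under
the *cell-age* clock both daughters inherit the mother's age.

The model is simulated exactly as a stochastic agent system
(Gillespie-style, with the time-dependent total arrest rate handled in
closed form because every cell ages at unit rate).  It makes no claim of
equivalence to any particular fitted culture model — it is the minimal
mechanism consistent with the measured division, arrest and lysis
statistics, and its apparent culture-level growth curve can be fed to the
growth-parameter extraction for qualitative comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .growth import GrowthCurve

__all__ = [
    "PopulationModelParams",
    "PopulationTrajectory",
    "simulate_population",
    "apparent_growth_curve",
    "trajectory_to_growth_curve",
    "extinction_probe",
]

_EXP_CAP = 700.0  # exp() overflow guard; unreachable before mass arrest


@dataclass(frozen=True)
class PopulationModelParams:
    """Rates in h^-1; ``arrest_a``/``arrest_b`` are the Gompertz hazard
    parameters acting on the configured age clock."""

    division_rate: float = np.log(2) / 0.5
    arrest_a: float = 0.01
    arrest_b: float = 0.2
    lysis_rate: float = 0.2
    initial_n: int = 100
    t_max: float = 10.0
    max_cells: int = 100_000
    age_clock: str = "lineage"
    seed: int = 0

    def __post_init__(self):
        if self.division_rate < 0:
            raise ValueError("division_rate must be >= 0")
        if self.arrest_a < 0 or self.arrest_b < 0 or self.lysis_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.initial_n < 1:
            raise ValueError("initial_n must be >= 1")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.max_cells < self.initial_n:
            raise ValueError("max_cells must be >= initial_n")
        if self.age_clock not in ("lineage", "cell"):
            raise ValueError("age_clock must be 'lineage' or 'cell'")


@dataclass
class PopulationTrajectory:
    """Counts per compartment at every event time, plus flow bookkeeping.

    At every recorded time, births - (proliferating - initial) - arrests = 0
    and arrests - postreplicative - lysed = 0 (exact, by construction).
    """

    times: np.ndarray
    n_proliferating: np.ndarray
    n_postreplicative: np.ndarray
    n_lysed: np.ndarray
    births: np.ndarray
    arrests: np.ndarray
    lyses: np.ndarray
    initial_n: int
    overflowed: bool = False
    arrest_times: np.ndarray = field(default=None, repr=False)

    @property
    def total_viable(self) -> np.ndarray:
        return self.n_proliferating + self.n_postreplicative

    @property
    def extinct(self) -> bool:
        return bool(self.total_viable[-1] == 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "proliferating": self.n_proliferating,
            "postreplicative": self.n_postreplicative,
            "lysed": self.n_lysed,
            "births": self.births,
            "arrests": self.arrests,
            "lyses": self.lyses,
        })


def _next_event_time(t: float, E: float, C: float, aW: float,
                     b: float, t_cap: float) -> float:
    """Solve the integrated total rate for the next event time.

    Total rate R(u) = C + aW * exp(b u) (C collects the constant division
    and lysis rates; the arrest term is exact because all ages advance at
    unit rate, so sum_i a e^{b age_i} = a e^{bt} sum_i e^{-b birth_i}).
    Returns a time > t_cap when no event fires before the cap.
    """
    if C <= 0 and aW <= 0:
        return np.inf
    if aW <= 0 or b == 0:
        return t + E / (C + aW)
    if C <= 0:
        # closed form: (aW/b)(e^{b tn} - e^{b t}) = E
        x = np.exp(min(b * t, _EXP_CAP)) + E * b / aW
        return np.log(x) / b

    def integrated(u):
        return C * (u - t) + (aW / b) * (
            np.exp(min(b * u, _EXP_CAP)) - np.exp(min(b * t, _EXP_CAP))) - E

    hi = t + E / C  # rate >= C, so the event fires no later than this
    if integrated(hi) <= 0:
        return hi
    return brentq(integrated, t, hi, xtol=1e-12)


def simulate_population(params: PopulationModelParams,
                        seed: int | None = None,
                        on_overflow: str = "error") -> PopulationTrajectory:
    """Exact stochastic simulation of the three-compartment model.

    ``on_overflow`` controls behaviour when the viable population exceeds
    ``max_cells``: "error" raises, "stop" ends the run early (the
    trajectory is flagged ``overflowed``).  Seed-reproducible.
    """
    if on_overflow not in ("error", "stop"):
        raise ValueError("on_overflow must be 'error' or 'stop'")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    r, a, b, mu = (params.division_rate, params.arrest_a,
                   params.arrest_b, params.lysis_rate)

    birth_times: list[float] = [0.0] * params.initial_n
    weights: list[float] = [1.0] * params.initial_n  # exp(-b * birth_i)
    n_pr = 0
    n_ly = 0
    births = arrests = lyses = 0
    t = 0.0
    overflowed = False

    rec_t = [0.0]
    rec = [(params.initial_n, 0, 0, 0, 0, 0)]
    arrest_times: list[float] = []

    def record():
        rec_t.append(t)
        rec.append((len(birth_times), n_pr, n_ly, births, arrests, lyses))

    while t < params.t_max and (birth_times or n_pr > 0):
        n_p = len(birth_times)
        C = n_p * r + n_pr * mu
        W = float(np.sum(weights)) if (a > 0 and n_p) else 0.0
        E = rng.exponential()
        tn = _next_event_time(t, E, C, a * W, b, params.t_max)
        if tn > params.t_max:
            break
        t = tn
        rate_div = n_p * r
        rate_lys = n_pr * mu
        rate_arr = a * np.exp(min(b * t, _EXP_CAP)) * W
        total = rate_div + rate_lys + rate_arr
        u = rng.random() * total
        if u < rate_div:
            idx = int(rng.integers(n_p))
            if params.age_clock == "lineage":
                birth_times.append(t)
                weights.append(np.exp(-min(b * t, _EXP_CAP)))
            else:
                birth_times.append(birth_times[idx])
                weights.append(weights[idx])
            births += 1
        elif u < rate_div + rate_lys:
            n_pr -= 1
            n_ly += 1
            lyses += 1
        else:
            w_arr = np.asarray(weights)
            cum = np.cumsum(w_arr)
            idx = int(np.searchsorted(cum, rng.random() * cum[-1]))
            idx = min(idx, n_p - 1)
            birth_times.pop(idx)
            weights.pop(idx)
            n_pr += 1
            arrests += 1
            arrest_times.append(t)
        record()
        if len(birth_times) + n_pr > params.max_cells:
            if on_overflow == "error":
                raise OverflowError(
                    f"population exceeded max_cells={params.max_cells} at "
                    f"t={t:.3f}; raise max_cells or use on_overflow='stop'")
            overflowed = True
            break

    if not overflowed and t < params.t_max:
        t = params.t_max
        record()
    elif not overflowed:
        # close the trajectory at t_max with the final state
        rec_t.append(params.t_max)
        rec.append(rec[-1])

    arr = np.asarray(rec, dtype=np.int64)
    return PopulationTrajectory(
        times=np.asarray(rec_t, dtype=float),
        n_proliferating=arr[:, 0],
        n_postreplicative=arr[:, 1],
        n_lysed=arr[:, 2],
        births=arr[:, 3],
        arrests=arr[:, 4],
        lyses=arr[:, 5],
        initial_n=params.initial_n,
        overflowed=overflowed,
        arrest_times=np.asarray(arrest_times, dtype=float))


def apparent_growth_curve(traj: PopulationTrajectory
                          ) -> tuple[np.ndarray, np.ndarray, bool]:
    """ln(viable / initial) vs time, truncated at extinction.

    Returns ``(times, log_ratio, extinct)``; the series ends just before
    the first time the viable count reaches zero.
    """
    viable = traj.total_viable
    if viable[0] <= 0:
        raise ValueError("trajectory starts with no viable cells")
    zero = np.flatnonzero(viable == 0)
    end = int(zero[0]) if zero.size else viable.size
    extinct = zero.size > 0
    times = traj.times[:end]
    logr = np.log(viable[:end] / viable[0])
    return times, logr, extinct


def trajectory_to_growth_curve(traj: PopulationTrajectory,
                               t_grid: np.ndarray | None = None,
                               strain: str = "model",
                               medium: str = "model") -> GrowthCurve:
    """Viable-count step function sampled on a grid, as a GrowthCurve.

    The result is directly feedable to
    :func:`bactaging.growth.extract_growth_params` (counts play the role
    of OD; the extraction works on ln(N/N0)).
    """
    if t_grid is None:
        t_grid = np.linspace(traj.times[0], traj.times[-1], 200)
    t_grid = np.asarray(t_grid, dtype=float)
    idx = np.clip(np.searchsorted(traj.times, t_grid, side="right") - 1,
                  0, traj.times.size - 1)
    viable = traj.total_viable[idx].astype(float)
    return GrowthCurve(strain=strain, medium=medium, times=t_grid,
                       od=np.maximum(viable, 1e-12))


def extinction_probe(params: PopulationModelParams,
                     b_grid: np.ndarray, n_replicates: int,
                     seed: int | None = None) -> pd.DataFrame:
    """Fraction of replicate populations extinct by ``t_max`` per aging
    rate ``b``.

    Populations that outgrow ``max_cells`` are stopped early and counted
    as surviving.  The fraction is non-decreasing in ``b`` up to
    Monte-Carlo error.
    """
    b_grid = np.asarray(b_grid, dtype=float)
    if b_grid.size == 0:
        raise ValueError("b_grid must be non-empty")
    if np.any(b_grid < 0):
        raise ValueError("aging rates must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    rows = []
    for b in b_grid:
        p = PopulationModelParams(
            division_rate=params.division_rate, arrest_a=params.arrest_a,
            arrest_b=float(b), lysis_rate=params.lysis_rate,
            initial_n=params.initial_n, t_max=params.t_max,
            max_cells=params.max_cells, age_clock=params.age_clock,
            seed=params.seed)
        n_ext = 0
        for child in ss.spawn(n_replicates):
            rng_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            traj = simulate_population(p, seed=rng_seed, on_overflow="stop")
            if traj.extinct and not traj.overflowed:
                n_ext += 1
        rows.append({"b": float(b), "extinct_fraction": n_ext / n_replicates,
                     "n": n_replicates})
    return pd.DataFrame(rows)
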
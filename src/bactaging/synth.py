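"""Synthetic mother-machine lineages and plate-reader growth curves.

Generates single-cell traces with known ground truth so every downstream
stage (division detection, EER/DR extraction, aRL/PRL decomposition,
phenotype classification, Gompertz fitting) has a parameter-recovery test
surface.  The generator emulates the observables of a trapped *E. coli*
mother cell:

* exponential elongation within each cycle at a per-cycle rate drawn
  lognormally around ln2 / mean doubling time (~0.5 h in rich medium),
  with division resetting length by a fixed ratio;
* a replicative lifespan drawn from the Gompertz law, after which the cell
  stops dividing and enters its post-replicative lifespan (PRL);
* a death phenotype planted per cell — Ia (chromosome signal lost in a
  single frame at the last division), Ib (signal retained, decaying
  gradually during the PRL), or II (replicative crisis: the final cycle
  elongates without division past the filamentation threshold);
* a viability-dye (PI) channel that steps up at lysis, one PRL after the
  last division;
* logistic population growth curves (OD600 vs time) with lag and noise.

Traces longer than the movie are truncated and their truth marked
right-censored, mirroring real mother-machine movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .growth import GrowthCurve
from .lineage import LineageTrace
from .survival import gompertz_isf

__all__ = [
    "PHENOTYPES",
    "LineageSimConfig",
    "GroundTruth",
    "sample_gompertz_lifespans",
    "simulate_lineage",
    "simulate_cohort",
    "simulate_growth_curve",
]

PHENOTYPES = ("Ia", "Ib", "II")

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class LineageSimConfig:
    """Study conditions for the lineage simulator.

    Durations in hours, lengths in micrometres, fluorescence in a.u.
    Defaults emulate wild-type *E. coli* in rich medium: ~30 min doubling
    time imaged every 3 min, Gompertz lifespans with initial hazard
    0.01 h^-1 and aging rate 0.2 h^-1, and PRLs of a few hours.
    """

    mean_doubling_time: float = 0.5
    elongation_noise_sd: float = 0.02
    birth_length_mean: float = 2.5
    division_ratio: float = 0.5
    sampling_interval: float = 0.05
    gompertz_a: float = 0.01
    gompertz_b: float = 0.2
    prl_duration_mean: float = 5.0
    prl_duration_sd: float = 2.0
    phenotype_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)
    filament_factor: float = 3.5
    gfp_baseline: float = 1000.0
    pi_baseline: float = 100.0
    signal_noise_sd: float = 20.0
    gfp_decay_halflife: float = 3.0
    crisis_eer_fraction: float = 0.5   # phenotype II grows this much slower
    last_gen_bl_factor: float = 1.0    # planted birth-length effect at gen 0
    width_mean: float = 1.0
    movie_length: float = 48.0
    strain: str = "wt"
    medium: str = "LB"
    seed: int = 0

    def __post_init__(self):
        pos = {"mean_doubling_time": self.mean_doubling_time,
               "birth_length_mean": self.birth_length_mean,
               "sampling_interval": self.sampling_interval,
               "gompertz_a": self.gompertz_a,
               "prl_duration_mean": self.prl_duration_mean,
               "gfp_baseline": self.gfp_baseline,
               "pi_baseline": self.pi_baseline,
               "gfp_decay_halflife": self.gfp_decay_halflife,
               "width_mean": self.width_mean,
               "movie_length": self.movie_length}
        for name, val in pos.items():
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {val}")
        nonneg = {"elongation_noise_sd": self.elongation_noise_sd,
                  "gompertz_b": self.gompertz_b,
                  "prl_duration_sd": self.prl_duration_sd,
                  "signal_noise_sd": self.signal_noise_sd}
        for name, val in nonneg.items():
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val}")
        if not 0 < self.division_ratio < 1:
            raise ValueError("division_ratio must be in (0, 1)")
        probs = np.asarray(self.phenotype_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("phenotype_probs must be 3 nonnegative values "
                             "summing to 1 within 1e-9")
        if self.sampling_interval > self.mean_doubling_time / 3:
            raise ValueError(
                "sampling_interval must be <= mean_doubling_time/3; coarser "
                "sampling cannot resolve division events")
        if self.filament_factor <= 3:
            raise ValueError("filament_factor must exceed 3 (the "
                             "filamentation threshold)")
        if not 0 < self.crisis_eer_fraction <= 1:
            raise ValueError("crisis_eer_fraction must be in (0, 1]")
        if self.last_gen_bl_factor <= 0:
            raise ValueError("last_gen_bl_factor must be > 0")
        if self.movie_length < self.sampling_interval:
            raise ValueError("movie shorter than one sampling interval")


@dataclass
class GroundTruth:
    """Planted per-cell truth for recovery tests.

    ``lifespan`` is the aRL end (time of the last completed division),
    ``lysis_time = lifespan + prl_duration`` and ``n_generations`` equals
    the number of completed cycles.
    """

    cell_id: str
    lifespan: float
    n_generations: int
    phenotype: str
    prl_duration: float
    lysis_time: float
    division_times: np.ndarray
    per_cycle_eer: np.ndarray
    censored: bool = False

    def __post_init__(self):
        self.division_times = np.asarray(self.division_times, dtype=float)
        self.per_cycle_eer = np.asarray(self.per_cycle_eer, dtype=float)
        if abs(self.lysis_time - (self.lifespan + self.prl_duration)) > 1e-9:
            raise ValueError("lysis_time must equal lifespan + prl_duration")
        if self.division_times.size and np.any(np.diff(self.division_times) <= 0):
            raise ValueError("division_times must be strictly increasing")
        if self.n_generations != self.division_times.size:
            raise ValueError("n_generations must equal completed divisions")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


def sample_gompertz_lifespans(a: float, b: float, n: int,
                              seed: int | None = None,
                              rng: np.random.Generator | None = None
                              ) -> np.ndarray:
    """Draw ``n`` Gompertz lifespans by inverse-CDF sampling.

    ``S(t) = exp(-(a/b)(e^{bt}-1))``; for b=0 this reduces to an
    exponential with rate ``a``.  Deterministic given the seed.
    """
    if not np.isfinite(a) or a <= 0:
        raise ValueError("a must be finite and > 0")
    if not np.isfinite(b) or b < 0:
        raise ValueError("b must be finite and >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = 1.0 - rng.random(int(n))  # uniform on (0, 1]
    return gompertz_isf(u, a, b)


def _draw_prl(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Truncated-normal (>0) PRL duration by resampling."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    return mean  # pragma: no cover - pathological sd/mean ratio


def simulate_lineage(config: LineageSimConfig, seed: int | None = None,
                     phenotype: str | None = None, cell_id: str = "cell0000",
                     rng: np.random.Generator | None = None
                     ) -> tuple[LineageTrace, GroundTruth]:
    """Simulate one mother cell's trace and its planted ground truth."""
    if phenotype is not None and phenotype not in PHENOTYPES:
        raise ValueError(f"phenotype must be one of {PHENOTYPES}")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)

    ph = phenotype
    if ph is None:
        ph = PHENOTYPES[rng.choice(3, p=np.asarray(config.phenotype_probs))]

    dt = config.sampling_interval
    base_rate = _LN2 / config.mean_doubling_time
    cycle_log = -np.log(config.division_ratio)  # ln-length gained per cycle
    sd = config.elongation_noise_sd

    def draw_eer():
        return base_rate * (np.exp(rng.normal(-0.5 * sd * sd, sd)) if sd > 0
                            else 1.0)

    # trapped cells are loaded while growing and always complete at least
    # one division before arresting, so the lifespan draw is conditioned on
    # covering the first cycle (truncates <1% of the mass at the defaults)
    eer0 = draw_eer()
    dur0 = cycle_log / eer0
    lifespan_draw = float(sample_gompertz_lifespans(
        config.gompertz_a, config.gompertz_b, 1, rng=rng)[0])
    for _ in range(1000):
        if lifespan_draw >= dur0 or dur0 > config.movie_length:
            break
        lifespan_draw = float(sample_gompertz_lifespans(
            config.gompertz_a, config.gompertz_b, 1, rng=rng)[0])

    # completed cycles: start time, eer; replication stops at the last
    # division at or before the sampled lifespan
    starts: list[float] = []
    eers: list[float] = []
    div_times: list[float] = []
    t = 0.0
    eer = eer0
    while True:
        dur = cycle_log / eer
        if t + dur > lifespan_draw:
            break
        starts.append(t)
        eers.append(eer)
        div_times.append(t + dur)
        t += dur
        if t >= config.movie_length:
            break
        eer = draw_eer()

    n_gen = len(div_times)
    t_last_div = div_times[-1] if div_times else 0.0

    prl = _draw_prl(rng, config.prl_duration_mean, config.prl_duration_sd)

    # lengths: each cycle starts at B (division returns length to its birth
    # value); the final completed cycle may carry a planted BL increase
    B = config.birth_length_mean
    birth_lengths = [B] * n_gen
    if n_gen and config.last_gen_bl_factor != 1.0:
        birth_lengths[-1] = B * config.last_gen_bl_factor
    # post-replicative birth length: the tracked cell keeps division_ratio of
    # the final length of the last cycle
    if n_gen:
        B_pr = birth_lengths[-1] * np.exp(eers[-1] * cycle_log / eers[-1]) \
            * config.division_ratio
    else:
        B_pr = B

    # phenotype II: crisis segment after the last division, elongating at a
    # reduced rate until the filamentation threshold, then arrested
    mean_len = B * (1.0 / config.division_ratio - 1.0) / cycle_log
    crisis_eer = config.crisis_eer_fraction * base_rate
    if ph == "II":
        target = config.filament_factor * mean_len
        grow_time = max(np.log(target / B_pr) / crisis_eer, 0.0)
        prl = max(prl, grow_time + 3 * dt)
    else:
        target = np.nan
        grow_time = 0.0

    lysis = t_last_div + prl

    times = np.arange(int(np.floor(config.movie_length / dt)) + 1) * dt
    n = times.size
    censored = lysis > times[-1] or (n_gen and div_times
                                     and t_last_div > times[-1])

    # piecewise-exponential length profile
    length = np.empty(n)
    seg_bounds = np.asarray(div_times, dtype=float)
    seg_idx = np.searchsorted(seg_bounds, times, side="right")
    for k in range(n_gen):
        mask = seg_idx == k
        if not mask.any():
            continue
        s = starts[k]
        length[mask] = birth_lengths[k] * np.exp(eers[k] * (times[mask] - s))
    post = seg_idx == n_gen
    if post.any():
        tp = times[post]
        if ph == "II":
            lp = np.where(
                tp < t_last_div + grow_time,
                B_pr * np.exp(crisis_eer * (tp - t_last_div)),
                B_pr * np.exp(crisis_eer * grow_time))
        else:
            lp = np.full(tp.shape, B_pr)
        length[post] = lp

    noise = (lambda: rng.normal(0.0, config.signal_noise_sd, n)
             if config.signal_noise_sd > 0 else np.zeros(n))

    # chromosome-label channel
    gfp = np.full(n, config.gfp_baseline)
    if ph == "Ia":
        gfp[times >= t_last_div - 1e-12] = 0.05 * config.gfp_baseline
    elif ph == "Ib":
        decay = times > t_last_div
        gfp[decay] = config.gfp_baseline * np.exp(
            -_LN2 * (times[decay] - t_last_div) / config.gfp_decay_halflife)
    gfp = gfp + noise()

    # viability-dye channel steps up at lysis
    pi_step = 0.5 * config.pi_baseline + 25.0 * config.signal_noise_sd
    pi = np.full(n, config.pi_baseline)
    pi[times >= lysis - 1e-12] += pi_step
    pi = pi + noise()

    width = np.full(n, config.width_mean)

    trace = LineageTrace(cell_id=cell_id, times=times, length=length,
                         width=width, gfp=gfp, pi=pi,
                         strain=config.strain, medium=config.medium)
    truth = GroundTruth(cell_id=cell_id, lifespan=t_last_div,
                        n_generations=n_gen, phenotype=ph,
                        prl_duration=prl, lysis_time=lysis,
                        division_times=np.asarray(div_times),
                        per_cycle_eer=np.asarray(eers),
                        censored=bool(censored))
    return trace, truth


def simulate_cohort(config: LineageSimConfig, n_cells: int,
                    seed: int | None = None
                    ) -> tuple[list[LineageTrace], list[GroundTruth]]:
    """Simulate independent lineages with per-cell derived seeds.

    Phenotypes are drawn independently per cell, so cohort fractions
    converge to ``config.phenotype_probs``.  Bit-reproducible given the
    seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    children = ss.spawn(int(n_cells))
    traces, truths = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        tr, gt = simulate_lineage(config, cell_id=f"cell{i:05d}", rng=rng)
        traces.append(tr)
        truths.append(gt)
    return traces, truths


def simulate_growth_curve(r: float, K: float, N0: float, lag: float = 0.0,
                          noise_sd: float = 0.0,
                          t_grid: Sequence[float] | None = None,
                          seed: int | None = None, strain: str = "sim",
                          medium: str = "sim", replicate: str = "r1",
                          floor: float = 1e-4) -> GrowthCurve:
    """Logistic OD600 curve with lag and additive Gaussian noise.

    ``N(t) = K / (1 + (K/N0 - 1) exp(-r (t - lag)))`` for t past the lag,
    flat at ``N0`` before it; readings are floored at a small positive OD.
    """
    if not np.isfinite(r) or r <= 0:
        raise ValueError("r must be finite and > 0")
    if not (0 < N0 < K):
        raise ValueError("require 0 < N0 < K")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if t_grid is None:
        t_grid = np.arange(0.0, 16.0 + 1e-9, 5.0 / 60.0)
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    te = np.clip(t - lag, 0.0, None)
    od = K / (1.0 + (K / N0 - 1.0) * np.exp(-r * te))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, od.size)
    od = np.maximum(od, floor)
    return GrowthCurve(strain=strain, medium=medium, replicate=replicate,
                       times=t, od=od)
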
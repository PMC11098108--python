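# Methods

`bactaging` implements a desk-scale pipeline for quantifying replicative
aging in bacteria from two data modalities: single-cell mother-machine
lineage traces and population OD600 growth curves. This note records the
models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic-data tests do and do not demonstrate.

## The aging model

Lifespans are modelled by the Gompertz survival law

    S(t) = exp(-(a/b) (e^{bt} - 1)),      lambda(t) = a e^{bt},

with `a` the initial hazard and `b` the aging (hazard-accumulation) rate,
both in inverse units of the chosen clock (hours, or aRL generation
counts). `b > 0` means mortality risk compounds exponentially — the
operational definition of aging; `b = 0` is the memoryless exponential
limit `S = exp(-a t)`, handled smoothly via the cumulative hazard
`a·t·phi(bt)` with `phi(x) = expm1(x)/x`. For a dividing population to
persist, `b` must stay well below 1 per clock unit.

Two fitting routes are provided and kept deliberately distinct:

* `nls_on_km` (default): least squares of the closed-form `S(t; a, b)`
  against the Kaplan–Meier product-limit curve evaluated at death times.
  This mirrors how survival curves are usually fit in figures and is the
  route used for the headline aging rates.
* `mle`: the censoring-aware likelihood
  `sum_deaths [ln a + b t_i] - sum_all (a/b)(e^{b t_i} - 1)`,
  preferable when movies end with many survivors.

Both optimize over `(ln a, b)` with `b >= 0` (L-BFGS-B / trust-region
bounds), multi-starting `b` on {0, 0.02, 0.1, 0.3, 1} because the
least-squares surface has a shallow valley connecting exponential-like
and strongly aging solutions. A fit pinned at `b = 0` is reported with an
explicit boundary flag rather than allowed to go negative. Confidence
bounds are percentile bootstrap over cells (default 1000 resamples,
seeded, warm-started at the point estimate); bootstrap-over-cells was
chosen over asymptotic covariance because mother-machine groups are small
(tens of cells). Kaplan–Meier estimation itself is delegated to
`lifelines`; the package's own brute-force product-limit computation
exists only inside the test suite as an independent oracle.

## Lineage segmentation

Divisions are frame-to-frame relative length drops of at least
`drop_fraction` (default 0.25: divisions roughly halve length, while
segmentation noise rarely produces 25% single-frame drops). Each
completed cycle yields birth length (BL, first frame), EER (least-squares
slope of ln length vs time over the cycle's frames — a fit, not an
endpoint ratio, so all frames contribute) and DR (inverse of the cycle
duration; `DR x duration = 1` identically). The first segment of every
trace is flagged partial (age at trap entry is unknowable) and the final
non-dividing segment is kept separately as the terminal segment; neither
enters population statistics. Interior segments shorter than 4 frames are
dropped and counted.

End-of-life alignment indexes each cell's cycles so that generation 0 is
the last cycle with EER above `eps_growth` (default 0.01 h^-1, the
operational "nonzero growth rate"); the population reference mean is
taken over all generations at index <= -3, i.e. excluding the last three,
so that end-of-life deviations do not contaminate their own baseline.

## Lifespan decomposition and phenotypes

Lysis is the first time the PI channel exceeds its own baseline mean by
`k_sigma` (default 5) standard deviations for at least `sustain_frames`
(default 2) consecutive frames — the sustained requirement rejects
single-frame speckle. The baseline is each cell's first 30 frames: with
only 10 frames the SD estimate falls below half its true value about 1%
of the time, which turns the nominal 5-sigma rule into an effective
2.5-sigma rule for those cells and produces spurious multi-hour-early
lysis calls over movie-length records; 30 frames keeps the estimate
tight while still preceding any plausible lysis. The aRL ends at the last
detected division (or the last growing frame when no division was seen);
the PRL runs from there to lysis, or to the movie end (lower bound,
censored) when the dye never entered.

Phenotype decision order: (i) *excluded* when the chromosome label drops
below 25% of baseline for 2 frames at a time earlier than the start of
the final cycle while divisions continue — the signature of plasmid loss
of the labelling construct, not of death; (ii) *II* when the maximum
length during the final cycle or PRL exceeds `filament_factor` (default
3) times the cohort mean length; (iii) *Ia* when the label collapses by
at least 50% in a single frame within one frame of the last division;
(iv) *Ib* otherwise — "gradual decay" needs no threshold because Ib is
the residual class. Censored cells are `I-unresolved` unless already
filamented. The filamentation reference (`cohort_mean_length`) averages
each cell's *replicative* frames only: post-replicative and filamented
frames would otherwise inflate the very reference that defines
filamentation. Filamentation is assessed in the final cycle/PRL only;
mid-life filaments that resume dividing do not trigger II.

## Synthetic-data generator

The generator plants known truth for every stage. Within a cycle, length
grows exponentially at a per-cycle rate `ln2/tau x lognormal(sd)` (mean
1; multiplicative noise keeps rates positive); division multiplies
length by `division_ratio` (default 0.5, so birth length is stationary).
Replication stops at the last division at or before a Gompertz-sampled
lifespan (inverse-CDF sampler, exact round trip through the survival
function); the PRL is truncated-normal (> 0). The lifespan draw is
conditioned on covering at least one completed cycle: trapped cells are
loaded while growing and always divide before arresting, and a
zero-division lineage could not display a last-division phenotype. This
truncates under 1% of the Gompertz mass at the defaults. Channels: GFP at baseline
with additive Gaussian noise, dropping to 5% in one frame at the last
division (Ia), decaying exponentially with a 3 h half-life during the
PRL (Ib), or retained (II); PI steps up at lysis by half its baseline
plus 25 noise SDs. Phenotype II adds a crisis segment after the last
division growing at half the nominal rate until 3.5x the replicative
mean length, with the PRL extended to contain it. Traces are truncated
at the movie end with censored truth.

Defaults are the study conditions and are not tuned per test: doubling
time 0.5 h (rich-medium wild type; 31 and 100 min correspond to the
moderate and poor media), sampling every 0.05 h (3 min), `a = 0.01 h^-1`,
`b = 0.2 h^-1`, PRL 5 +/- 2 h, phenotype probabilities (0.4, 0.3, 0.3),
movie 48 h (beyond the 99.9th lifespan percentile plus PRL, so censoring
is rare), elongation noise SD 0.02, fluorescence noise SD 20 a.u. on a
1000 a.u. baseline. The generator produces segmentation-level traces: no
per-frame length measurement error, no width dynamics, no old-pole/
new-pole asymmetry, no plasmid copy-number dynamics, no raw images.
Passing recovery tests therefore demonstrates correctness of the
analysis operations under this observation model, not robustness to
segmentation artifacts of real micrographs.

## Growth curves and the strain panel

All parameters are computed on `y = ln(N/N0)` with `N0` the mean of the
first three floored readings (robust to first-read noise; the OD floor
is 1e-4 and floored readings are counted in the output). MGR is the
maximum least-squares slope over sliding windows of 5 points; SPG the
maximum of a 3-point median-filtered `y`; AUC the trapezoidal integral
over the full record; Texp the union length of the time intervals
covered by windows whose slope is at least `exp_fraction` (default 0.5)
of MGR, and defined as 0 for curves that never grow. Window size and
`exp_fraction` are exposed because the literature algorithms they
approximate are not uniquely specified.

The panel pivots replicate-averaged parameters to a strain x
(parameter-medium) matrix, z-scores columns (zero-variance columns map
to zeros; a single-strain panel is rejected), decomposes by PCA (full
SVD of the centered matrix, so retaining all components reconstructs it
to machine precision), and clusters strains by average-linkage
agglomerative clustering on the first two component scores — matching
the "clusters based on the first two principal components" convention.
Missing strain x medium cells are an error, never imputed.

## Population model

A declared reconstruction, not a fitted model: proliferating cells
divide at rate `r`; each proliferating cell arrests at hazard
`a e^{b age}`; post-replicative cells lyse at rate `mu`. Under the
default lineage-age clock a division adds one age-zero daughter and
leaves the tracked cell's clock running (the mother-machine reading);
the cell-age alternative makes both daughters inherit the age. The
simulation is exact: because every age advances at unit rate, the total
arrest rate is `a e^{bt} sum_i e^{-b birth_i}` in closed form, so
waiting times solve a one-dimensional monotone equation (closed form
when there are no constant-rate channels, bracketed Brent otherwise) —
no thinning or discretization error. Flow bookkeeping
(`births - Delta proliferating - arrests = 0`,
`arrests - postreplicative - lysed = 0`) holds exactly at every event.
Populations exceeding `max_cells` either raise or stop early (flagged);
the extinction probe counts stopped runs as survivors. Limits used as
checks: `a = 0` reduces to a pure birth process with mean growth `e^{rt}`;
`r = 0` reduces to the survival module's Gompertz cohort.

## Problem sizes and tolerances

The test and acceptance workloads use 500-cell cohorts for lineage-stage
recovery, 2000 cells for phenotype fractions (binomial 99% bound ~0.026
at n=2000 motivates the +/-0.03 tolerance), 1000 lifespans x 100
replicates x 200 bootstrap resamples for aging-rate recovery and CI
coverage, 10^4 cells for the cohort-mode distributional check (KS <=
0.02), and 150–200 replicates for population-model means. These sizes
put Monte-Carlo error comfortably inside each stated tolerance while
keeping a full run to a few minutes on one core.

## Known limitations

* The Gompertz fits assume a homogeneous cohort; no frailty or
  competing-risk structure.
* The arrest-event definition ("lysis" vs "arrest", hours vs
  generations) changes the fitted rates; both are supported and the
  clock/event labels travel with every fit to keep units honest.
* Texp and MGR depend mildly on the window configuration; defaults are
  documented above rather than claimed canonical.
* The population model has no nutrient feedback, spatial structure, or
  growth-rate inheritance, and is not fit to data.
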
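# bactaging

Replicative-aging analysis for bacteria, from two kinds of raw data:
single-cell **mother-machine lineage traces** (time series of cell length
and fluorescence for one trapped cell per microchannel) and population
**OD600 growth curves** from plate readers. It is aimed at groups
quantifying how environmental or genetic stress changes bacterial aging —
e.g. comparing a wild-type strain against single-gene deletion mutants
across growth media.

## What it computes

**Aging rates.** Lifespans are summarized by the Kaplan–Meier
product-limit estimate S(t) = ∏ₜᵢ≤ₜ (1 − dᵢ/nᵢ) and fit with the Gompertz
survival law

S(t) = exp(−(a/b)(e^{bt} − 1)),  λ(t) = a·e^{bt},

where *a* is the initial hazard and *b* the aging rate (h⁻¹ or gen⁻¹):
an exponentially compounding mortality risk is the operational signature
of aging, and *b* = 0 recovers the memoryless exponential. Fits run
either as least squares on the KM curve or as censoring-aware maximum
likelihood, with bootstrap 95% bounds over cells.

**Single-cell division dynamics.** Traces are cut at division events
(large frame-to-frame length drops) into cell cycles with birth length
(BL), exponential elongation rate (EER, slope of ln length vs time) and
doubling rate (DR = 1/cycle duration); per-generation statistics are
aligned so that generation 0 is the last cycle with nonzero growth,
exposing end-of-life changes.

**Lifespan decomposition and death phenotypes.** The viability dye (PI)
marks lysis; each cell's record splits into its apparent replicative
lifespan (aRL) and post-replicative lifespan (PRL). Death phenotypes are
classified from morphology and the chromosome label (GFP-Fis): sudden
label loss at the last division (Ia), gradual decay with the chromosome
retained (Ib), or replicative crisis with filamentation beyond 3× the
cohort mean length (II), with plasmid-loss artifacts excluded.

**Growth curves.** Each OD600 curve yields MGR, SPG, AUC and Texp on the
ln(N/N₀) scale; a strain×medium panel of these parameters is z-scored,
decomposed by PCA and clustered (average linkage on the first two
component scores) to sort mutants into growth-profile classes.

**Population model.** A three-compartment stochastic model (proliferating
→ post-replicative at age-dependent Gompertz hazard → lysed) links the
single-cell rates to culture-level growth and extinction.

A synthetic-data generator (`bactaging.synth`) emulates all of the above
with planted ground truth, so every stage has a parameter-recovery test.

## Worked example

```python
import bactaging as ba

cfg = ba.LineageSimConfig()                      # wild-type-like, rich medium
traces, truths = ba.simulate_cohort(cfg, 200, seed=7)
records, extractions = ba.analyze_cohort(traces)

print(ba.phenotype_fractions(records).round(3))

events = ba.event_table_from_lifespans(records, clock="hours", event="lysis")
fit = ba.fit_gompertz(events["duration"], events["observed"],
                      n_boot=500, seed=7)
print(f"aging rate b = {fit.b:.3f} 1/h "
      f"(95% CI {fit.ci95_b[0]:.3f}-{fit.ci95_b[1]:.3f})")
```

prints

```
               frac_Ia  frac_Ib  frac_II  frac_I-unresolved      n  n_excluded
strain medium
wt     LB         0.41     0.31     0.28                0.0  200.0         0.0
aging rate b = 0.212 1/h (95% CI 0.187-0.251)
```

The phenotype fractions recover the generator's planted (0.4, 0.3, 0.3)
mixture, and the fitted aging rate recovers the planted b = 0.2 h⁻¹
within its confidence bounds. The same functions accept real trace
tables (`bactaging.io.read_traces`) with columns
`cell_id, time_h, length_um, width_um, gfp_au, pi_au`.

The `bactaging` command exposes the pipeline as subcommands
(`simulate`, `growth`, `lineages`, `lifespan`, `survival`, `popmodel`);
see `bactaging --help`.

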
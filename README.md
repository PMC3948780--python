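# nebkha

Spatial point-pattern inference for patchy dryland vegetation.

Nebkhas — phytogenic mounds that build up where wind-blown sand accumulates
under desert shrubs — form strikingly patchy landscapes. Whether that
patchiness comes from seed limitation, from vegetation-independent
(allogenic) habitat patchiness, or from competition and facilitation among
the shrubs themselves is a question about *process*, and this package
implements a pattern-to-process inference pipeline for answering it from a
single mapped snapshot: a table of canopy patches (centroid, equivalent-
circle diameter) in a rectangular study window, split into five
diameter-defined cohorts (age classes) `UI`, `J_B`, `A_S`, `A_M`, `A_L`
with boundaries at 0.25 / 0.50 / 1.00 / 2.00 m.

It is aimed at spatial ecologists working with mapped shrub or nebkha
populations, and at methodologists who want a tested reference
implementation of edge-distance pair-correlation statistics with
constrained Monte Carlo null models.

## The statistics

**Edge-distance pair correlation functions.** For a cohort of `N`
non-overlapping canopy discs in a window of area `A`, the pair correlation
function is estimated as

    ghat(r) = A / (2 pi r N(N-1)) * sum_{i != j} k_h(r - d_ij) e_ij

where `d_ij` is the *patch-edge distance* (centroid distance minus both
radii), `k_h` an Epanechnikov kernel of half-width `h` (Stoyan rule
`h = 0.15 / sqrt(N/A)` by default), and `e_ij` the translation
edge-correction weight. Using edge distances removes the spurious
small-scale regularity that finite patch size imprints on hard-core
patterns. The cross-type version (PCCF) `ghat_12(r)` uses only pairs from
two different cohorts and detects attraction (facilitation) or repulsion
(competition); under independence it is ~1.

**Constrained null models.** Observed functions are compared with
envelopes over 499 Monte Carlo relocations of the analysed cohort:

* *univariate null* — centroids i.i.d. uniform (binomial process) with the
  same count and diameters, no overlap among themselves or with the fixed
  older cohorts; departures reveal within-cohort clustering;
* *bivariate null* — centroids drawn from a heterogeneous intensity
  obtained by smoothing the observed cohort with an isotropic 5 m-SD
  Gaussian kernel, same constraints; because the cohort's large-scale
  density surface is preserved, PCCF departures against the large adults
  isolate short-range interaction rather than shared clustering.

**Envelope + rank GoF testing.** Distance intervals where the observed
function leaves the pointwise min/max envelope of a first simulation batch
are re-tested on an independent second batch with the Loosmore–Ford
statistic `u = sum (f - fbar_loo)^2 dr`; the null is rejected for an
interval when the observed `u` ranks among the 5 highest or 5 lowest of
all 500 values (per-tail level 5/500 = 0.01; a reduced-cost run with 99
simulations and rank 1 preserves the level).

**Grid-plot correlation tests.** Square plots with sides five and ten
times the largest observed diameter carry two first-order tests: adult
cover vs recruit density (distance seed limitation, "Corr1") and the 10
pairwise cohort-density correlations (static vs dynamic large-scale
habitat patchiness, "Corr2").

**Decision framework.** The statistical outcomes map to seven recruitment
hypotheses — distance/density seed limitation, small-scale and
static/dynamic large-scale allogenic habitat patchiness, autogenic
facilitation and competition — reported as a `y`/`n` verdict table.

Because no field map ships with the package, `nebkha.synthetic` generates
multi-cohort landscapes with known ground truth (Thomas cluster processes
with shared or independent parents, a bimodal log-area size mixture,
imposed short-range facilitation/competition annuli) so the whole pipeline
is testable end to end.

## Worked example

Generate a clustered, interacting landscape at the default 125 m × 250 m
window and run the full pipeline at reduced Monte Carlo cost:

```bash
nebkha simulate --scenario paper_like --seed 7 --out landscape.csv
# wrote landscape.csv (980 patches) and landscape.truth.json
nebkha run-all landscape.csv --window 0 0 125 250 --seed 7 --n-sims 99 --gof-k 1 --outdir out
```

which prints

```
| SL_DIS | SL_DEN | HP_AL_SS | HP_AL_LS_STAT | HP_AL_LS_DYN | HP_AU_FA | HP_AU_CO |
|---|---|---|---|---|---|---|
| n | y | y | n | y | y | y |
```

Reading the verdict row: distance seed limitation is rejected (adult cover
does not predict recruit density), isolated recruits support density seed
limitation / small-scale habitat patchiness (the two are not separable by
pattern analysis alone), every cohort clusters at scales above 10 m while
cohort densities are mutually uncorrelated (0 of 10 pairs significant →
the large-scale habitat patchiness is *dynamic*), and the branched
juveniles' PCCF against large adults is significantly above its envelope
below ~1.5 m and below it at ~2–2.5 m — facilitation close to the adult
edge, competition just beyond. `out/report.json` holds the evidence trail
(for this run: recruit PCF above its envelope up to 26.8 m; the juvenile
PCCF intervals rank 1st of 100 in their respective tails).

The same analysis runs on any patch table CSV (`id,x,y,diameter[,cohort]`,
meters) via `nebkha run-all <table> --window x0 y0 x1 y1`.

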
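# Methods

This note documents the models, estimators, numerical conventions and
design choices behind the package, and what the synthetic-data tests do
and do not establish about real data.

## Data model

A landscape is a set of disc-shaped vegetation patches — centroid
coordinates in meters and an equivalent-circle diameter — inside an
axis-aligned rectangular window. Patches must lie wholly inside the window
and the union of all cohorts must be overlap-free (pairwise edge distance
≥ 0); both are validated on load and asserted for every simulated pattern.
Real sites are rarely exact rectangles and boundary patches would need
clipping upstream; both are documented limitations of the rectangular
window model. Cohort classification uses half-open diameter intervals
[0, 0.25), [0.25, 0.50), [0.50, 1.00), [1.00, 2.00), [2.00, ∞) m so that
every positive diameter maps to exactly one label; measured diameters
landing exactly on a boundary are measure-zero, so the choice of side is
inconsequential in practice.

## Estimators

The pair correlation function (PCF) and its cross-type variant (PCCF) are
kernel estimators on the *patch-edge distance* abscissa: the centroid
distance minus both radii. The classical normalization `A/(2πr·N(N−1))`
(or `A/(2πr·N_a·N_b)`) is kept on the edge-distance axis. This is not
exactly unbiased for sized discs — under randomness the expected pair
density at edge distance r is proportional to the centroid distance
2π(r + r̄) rather than 2πr, so the raw estimate of a random disc pattern
sits slightly above 1 at small r (about 13% at r = 5 m for the default
size mixture). The bias cancels in all inferences because observed and
null-model functions are computed with the identical estimator; no
patch-size-dependent denominator correction is applied.

Numerical conventions:

* Epanechnikov kernel, half-width `h`; kernel sums are computed with
  prefix sums over sorted pair distances (O(P log P + G) per evaluation),
  and a box-kernel variant reproduces the histogram (binned) estimator
  exactly, which the tests exploit as a brute-force oracle.
* Bandwidth: Stoyan's rule `h = 0.15/√λ̂` for the PCF. For the PCCF the
  pipeline default is a fixed 0.5 m: the interactions of interest sit at
  0–3 m (set by canopy sizes), and the Stoyan rule at realistic cohort
  densities (λ̂ ~ 0.003–0.02 m⁻²) yields h of 1–3 m, which both smears the
  signal and marks the whole interaction range unreliable.
* Edge correction: translation weights computed on centroid
  displacements (exact for rectangles); "none" is available since
  null-model comparison cancels first-order bias anyway.
* Values at r < h are computed but flagged unreliable and excluded from
  envelope interval detection; r = 0 is undefined (NaN).
* The analysis grid should be no finer than the kernel bandwidth — see
  "Error control" below. The pipeline default is 64 points from 0 to a
  quarter of the shorter window side.

## Null models

Both null models relocate the observed patches of one cohort — count and
diameter multiset are conserved exactly, hence cohort cover too — placing
discs sequentially from largest to smallest (ties by patch id) with
rejection sampling; a disc failing 10⁴ placement attempts triggers a full
restart, up to 100 restarts, after which a packing error names the
offending patch. Placement respects whole-disc containment and non-overlap
with already-placed discs and with all *older* cohorts, which stay fixed
(the conditioning set for the bivariate null is configurable to
large-adults-only).

The bivariate null draws centroids from the Gaussian-kernel intensity
(SD 5 m, lattice step 0.5 m) of the observed cohort, by a lattice-cell
inverse-CDF draw plus uniform within-cell jitter — exact up to lattice
resolution and cheap. The kernel surface is deliberately *not*
renormalized at window edges: the same uncorrected surface drives the
sampling, so envelopes are internally consistent. The 5 m SD preserves
large-scale cohort clustering in the null while leaving sub-3-m
attraction/repulsion detectable; much smaller kernels would absorb the
very interactions being tested (the simulations in the test suite show
this absorption is already noticeable at 5 m for strong imposed
facilitation).

All randomness flows from one root seed through named `SeedSequence`
spawns; identical inputs, configuration and seed reproduce every simulated
pattern bit-exactly.

## Envelopes, GoF testing and error control

Envelopes are pointwise min/max/mean over n = 499 simulations by default.
Candidate departures are maximal runs of grid points where the observed
function exits the band, discarding runs shorter than two grid steps; each
candidate is then re-tested on an independent second batch with the
Loosmore–Ford statistic (Δr-weighted squared deviation from the
leave-one-out mean). The observed u is ranked against the batch; rejection
requires rank ≤ k = 5 among the 500 values in either tail (ties counted in
the observed value's favor), a per-tail level of 0.01. The reduced-cost
pair (n, k) = (99, 1) preserves that level, and the calibration diagnostic
(`nebkha.diagnostics.gof_rank_calibration`) verifies it empirically: for a
*fixed* interval the rule is exactly calibrated by exchangeability.

Two error-control caveats are inherent to the interval-selection design
and documented rather than hidden:

* The per-tail level applies per tested interval; "five highest or five
  lowest" is two-sided at 0.02. Both per-tail ranks are reported.
* Intervals are *selected* for extremeness before being tested, and the
  same observed function is ranked against the second batch, so the
  procedure is anti-conservative for null data. The damage is governed by
  grid resolution: on grids much finer than the kernel bandwidth, adjacent
  points share one kernel window and the two-step width filter cannot
  suppress single-window noise (measured ~0.3 false confirmations per null
  PCCF at 99 simulations with a 0.25 m step and 0.5 m bandwidth). With the
  recommended step of about one bandwidth the rate drops to ~0.1 per
  function — the residual is the method's honest type I error and shows up
  as occasional false interaction verdicts in the null-scenario tests.

Cluster scale is read off as the end of the first significant
above-envelope PCF interval that starts within one grid step of the
smallest interpretable distance; deviation strength is the envelope's
displacement from the null line `g = 1` averaged over the interval,
relative to the envelope width (zero-width points skipped).

## Grid-plot tests

Square plots on a lattice anchored at the window's lower-left corner
(offset configurable; the placement is otherwise arbitrary), keeping only
cells wholly inside the window. Patches belong to the half-open cell
containing their centroid, and a disc's full area counts toward its
centroid's plot — at 21 m plots vs ≤ 4.2 m discs the attribution error is
small, and it keeps cover consistent with counts. Correlations are Pearson
with two-sided t p-values (a Spearman switch exists); no multiple-testing
correction is applied across the 10 cohort pairs by default. The
distance-seed-limitation verdict is "supported" when either plot size
yields p < 0.05, irrespective of sign; note a sufficiently strong negative
association (e.g. broad competition around adults) would also trigger it.
The static/dynamic call is "dynamic" when fewer than 5 of the 10 pairs are
significant; the threshold is configurable since only the qualitative rule
("the fewer, the more dynamic") is fixed. Spatially autocorrelated density
fields inflate the effective type I error of these plot-level correlations
somewhat above nominal — visible as the dominant failure mode in the
end-to-end recovery tests.

## Decision framework

The hypothesis map is a pure function of the evidence bundle: Corr1 →
distance seed limitation; isolated recruits → density seed limitation and
small-scale allogenic habitat patchiness jointly, with an explicit caveat
that pattern analysis cannot separate them (seed-addition experiments
would); any cohort PCF significantly above its envelope with cluster scale
> 10 m → large-scale allogenic habitat patchiness, split static/dynamic by
Corr2 (mutually exclusive by construction); any PCCF against the large
adults significantly above (below) its bivariate envelope → facilitation
(competition), aggregated over cohorts with an "any" rule.

Note that with hard-core generation, *any* non-empty recruit cohort is
almost surely isolated (edge distances are strictly positive), so the
isolation criterion is effectively an existence check for recruits; a
landscape with no isolation evidence is one with no unbranched recruits.

## Synthetic landscapes

`nebkha.synthetic` provides the generators and two canonical scenarios.
Diameters come from per-cohort truncated lognormals (medians 0.12 / 0.35 /
0.70 / 1.40 / 2.60 m), and the landscape-level mixture reproduces the
bimodal log-area histogram characteristic of such populations. Clustering
uses a Thomas process: Poisson parents on a 4σ-buffered window (so
boundary clusters are represented without bias; offspring falling outside
the window are discarded, and the closed-form PCF
`1 + exp(−r²/4σ²)/(4πκσ²)` is a test oracle), offspring displaced by
isotropic Gaussians and re-drawn on overlap. Interactions are imposed by
annulus thinning (competition) or by adding patches until the annulus
density reaches `(1 + strength · boost)` times background (facilitation).

The *clustered interacting* scenario runs at full field scale — a
125 × 250 m window with expected cohort counts 500/125/178/171/82 —
because below-envelope detection power collapses at desk-scale cross-pair
counts. Cohorts are clustered with independent parents (dynamic mode;
σ = 12 m for recruits whose clusters are widest, 6 m otherwise) except the
oldest cohort, which is completely random: clustering weakens with cohort
age in such populations, and spatially clustered adults would place a
juvenile facilitated by one adult inside the suppression band of its
neighbor, blurring the scale-dependent signal the scenario instantiates
(facilitation within 1.5 m of adult edges, suppression at 1.5–3.25 m for
juveniles; recruit suppression within 1.5 m). Fixed parent counts (scaled
to the buffered area) keep realized cohort sizes near the nominal ones.
The *all-CSR* scenario carries the same cohorts as independent random
patterns and no recruits, for the reason given above.

Passing the end-to-end tests therefore shows that the pipeline recovers
known ground truth for landscapes matching its assumptions — disc-shaped
patches, Thomas-type clustering, annulus-shaped interactions, a rectangular
window. It does not validate the ecological interpretation on real sites,
where patch shapes are irregular, boundaries are not rectangular, cluster
geometry is richer, and the static/dynamic and seed-limitation readings
rest on the framework's ecological assumptions.

## Problem sizes in the test suite

Monte Carlo tests run at the reduced (99, 1) GoF setting with a 0.5 m grid
step; stochastic calibrations use 150–1000 replicates and the detection-
power and recovery checks 15–20 replicates each, sizes chosen so the whole
suite completes in minutes while keeping binomial assertion bounds
meaningful. The GoF calibration diagnostic follows the stated design of
300 replicates of a 30-disc cohort in a 50 × 50 m window. All suite
randomness is fixed-seeded.

## Known limitations

* Rectangular windows only; no irregular site polygons or torus wrapping.
* No Gibbs/Strauss-type interaction null models; no global rank or
  studentized envelopes (the min/max envelope plus rank GoF follows the
  two-batch design described above, with its documented selection bias).
* The edge-abscissa normalization is uncorrected (absorbed by the null
  comparison, but raw `ghat` values of sized-disc patterns should not be
  read as absolute clustering strengths).
* Plot-level Pearson tests assume exchangeable plots; spatial
  autocorrelation makes them mildly anti-conservative.
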
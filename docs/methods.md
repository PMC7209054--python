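# Methods

## The problem

'Global' palaeodiversity curves built by counting fossil species per time
interval are not global measurements: the spatial footprint of the sampled
fossil record differs enormously between intervals, and in the terrestrial
record it expands roughly exponentially toward the present.  Richness
estimators that standardize *sampling intensity* (coverage-based rarefaction,
asymptotic extrapolators) do not correct this, because adding new regions adds
new species regardless of how thoroughly each region is sampled.  The approach
implemented here therefore standardizes *space* itself: diversity is estimated
only for palaeogeographical regions of approximately equal spatial extent, and
the time series of interest is built from those standardized regional
estimates rather than from the pooled worldwide record.

## Pipeline

1. **Ingest and clean.**  Occurrence tables (PBDB-dialect CSV) are validated
   and filtered: records are removed by higher-taxon tag (defaults: Aves,
   Pterosauromorpha, Chiroptera — flying tetrapods with an inadequate,
   Lagerstätten-dominated record), by environment (default: marine strings),
   and by identification rank (default: species and subspecies only, since
   the analysis counts species).
2. **Time binning.**  A record is assigned to the bin containing strictly
   more than 50 % of its stratigraphic age range [min_ma, max_ma]; records
   with no such bin are dropped and counted.  Zero-length ranges go to the
   containing bin, boundary ages to the older bin (the geological convention
   for boundary-aged dates).  The default bin table is contiguous 10-Myr
   bins; any non-overlapping table can be supplied.
3. **Spatial points.**  Collections are binned into ~100-km equal-area grid
   cells; a *spatial point* is a cell containing at least one occurrence.
   All distances are great-circle distances between cell centres on a sphere
   of radius 6371.0088 km.
4. **Region enumeration.**  For every possible starting point, a region
   grows by repeatedly absorbing the unincluded point with the smallest
   distance to the current member set (single linkage: minimum over current
   members).  Every intermediate member set of size ≥ 2 is saved; duplicate
   member sets from different starts are discarded; distance ties are broken
   uniformly at random with a seeded generator.  This yields all nested sets
   of adjacent spatial points — candidate palaeogeographical regions of
   every size.
5. **Characterization.**  Each region gets spatial metadata (total MST
   length over member cell centres — the measure of spatial extent — and
   its longest branch; occupied-cell counts at 100/200/500/1000/5000-km
   spacings), sampling metadata (occurrences, collections, distinct
   literature references, Good's u, the multiton ratio, estimated sample
   coverage), and richness estimates (observed species count; SQS at quorums
   0.4/0.6/0.8; Chao 2 on collection incidences; the 'squares' extrapolator;
   optionally grid-cell-rarefied SQS).
6. **Standardization.**  At each target scale (1000–4000 km MST length in
   500-km steps), regions are kept only if: MST length within ±10 % of the
   target; longest MST branch ≤ 40 % of the total (rejects disjoint locality
   clusters); ≥ 20 literature references (a research-effort floor); multiton
   ratio ≥ 0.25 (a completeness floor).  Regions mixing land masses that an
   active geographic barrier separates at the bin's midpoint age (defaults:
   South America–Africa after 120 Ma, Australia–New Zealand after 70 Ma,
   Europe–Africa after 66 Ma) are removed.
7. **Clustering.**  Because nested regions share points, surviving regions
   are grouped by single-linkage transitive closure of the overlap relation
   overlap(A,B) = |A∩B| / min(|A|,|B|) with threshold 0.25 (strict >).
   Connected components are exactly the transitive closure, so the partition
   is order-independent; labels are canonicalized by descending member count
   then lexicographic member ids.  Each cluster is summarized by per-variable
   medians and interquartile ranges (linear-interpolation quartiles).
8. **Model comparison.**  Cluster-median log richness is regressed on bin
   midpoint age under five least-squares models — intercept-only, time,
   time + phase, time × phase, phase-only, where phase indicates bins younger
   than a fixed boundary (default 66 Ma, the end-Cretaceous mass extinction).
   Models are ranked by AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with the
   residual variance counted in k (intercept-only k = 2), and Akaike weights
   are reported.  First-difference OLS regressions (Δlog y on Δlog x over
   consecutive bins, excluded bins dropping both adjacent differences) and
   exact-ML AR(1) generalized least squares (profile likelihood over the AR
   coefficient with Prais–Winsten whitening) support the bias analyses.

## Estimator details

For a frequency vector with counts X_i, n = ΣX_i, S_obs species, f1
singletons and f2 doubletons:

- Good's u = 1 − f1/n; multiton ratio = (S_obs − f1)/S_obs (species-based).
- Reference-sample coverage Ĉ = 1 − (f1/n)·A with
  A = (n−1)f1/((n−1)f1 + 2f2); when f2 = 0 and f1 > 1,
  A = (n−1)(f1−1)/((n−1)(f1−1) + 2); Ĉ = 1 when f1 = 0.
- SQS interpolation: Ŝ(m) = Σ_i [1 − C(n−X_i, m)/C(n, m)] and
  Ĉ(m) = 1 − Σ_i (X_i/n)·C(n−X_i, m)/C(n−1, m); extrapolation:
  Ŝ(n+m′) = S_obs + f̂0·[1 − (1 − f1/(n·f̂0 + f1))^m′] with
  f̂0 = ((n−1)/n)·f1²/(2f2) (or ((n−1)/n)·f1(f1−1)/2 when f2 = 0) and
  Ĉ(n+m′) = 1 − (f1/n)·A^(m′+1).  The target size at quorum q is found by
  monotone (binary) search on the coverage curve; fractional sizes are
  resolved by linear interpolation between adjacent integers.  Estimates
  needing extrapolation beyond 2n are flagged; all-singleton samples return
  a missing value with a flag.
- Chao 2 on per-species sampling-unit counts (units = collections):
  classical Ŝ = S_obs + ((m−1)/m)·q1²/(2q2) when doubletons exist, else the
  bias-corrected S_obs + ((m−1)/m)·q1(q1−1)/2, flagged.
- squares: Ŝ = S_obs + f1²·ΣX_i² / (n² − f1·S_obs); undefined (flagged
  missing) when every species is a singleton.
- Grid-cell rarefaction: quota = round(quota_per_1000km × MST_km/1000)
  occupied 200-km cells; regions with fewer occupied cells get a missing
  value; otherwise the mean SQS over 50 seeded draws of exactly the quota.

Estimator failures are data, not exceptions: missing values with flags
propagate into the standardization filters.

## The synthetic fossil record

The generator separates the world (true diversity) from sampling (the
record), so every stage can be checked against ground truth.

Species live in latent geographic pools around centres placed on a Fibonacci
lattice.  Pool sizes follow the scenario: `flat` (constant), `expansionist`
(size × exp(rate·Δt) per bin), or `constrained_with_shift` (constant with
one multiplicative jump at a boundary age).  Species identities persist with
15 % per-bin turnover; each species keeps a relative-abundance weight drawn
once from a log-series distribution (p = 0.95; the heavy singleton tail is
deliberate — it stresses the coverage estimators the way real occurrence
data do).  A lognormal alternative is available for evenness-sensitivity
work.

Collections are placed at a limited number of sites inside a spherical-cap
window around an anchor; the window radius can grow exponentially toward the
present.  Each collection draws a Poisson number of occurrences from the
pool of its nearest latent centre (10 % from the second-nearest — species
ranges overlap along pool boundaries).  Collections are grouped into
literature references (Poisson group sizes), given longitude-sector
continental codes, and age ranges with up to 20 % of a bin length of slop so
the majority-overlap binning rule is genuinely exercised.  A small fraction
of occurrences (3 %) carries an excluded-taxon tag so the cleaning stage has
work to do.  Identical configs give byte-identical tables; the true per-bin
pool sizes are exported as a sidecar the pipeline never sees.

Packaged scenarios (sizes chosen to keep a desk-scale run in seconds while
leaving every filter criterion binding):

- **bias_demo** — flat world, 400 pools of 20 species (a fine-grained
  mosaic: any 1000-km region averages several pools, so pool-level
  realization noise cancels); 10 × 10-Myr bins; 500 collections at 100 sites
  per bin; window growing 800 → ~5500 km; per-bin lognormal effort shocks
  (σ = 0.4) scaling sites and collections jointly.  This reproduces the
  artefact: the worldwide face-value curve tracks occupied grid cells, while
  standardized 1000-km regional diversity stays trendless.
- **constrained_shift** — 11 bins straddling 66 Ma, pools of 50 stepping
  ×2.5 at the boundary, constant 1200-km window.
- **expansionist** — same frame with pools growing at 0.008/Myr.
- **flat** — the null world.

What the generator does *not* emulate: plate motion (palaeocoordinates are
static), taphonomic or lithification gradients, taxonomic error, and
within-pool spatial abundance structure.  Passing tests therefore show that
the pipeline recovers known regimes under realistic sampling geometry and
abundance structure — not that any particular empirical dataset is unbiased.

## Numerical choices and degenerate inputs

- Accretion and clustering tie-breaks are explicit (seeded RNG; canonical
  sort orders), making every pipeline stage reproducible from the manifest.
- Distance ties in enumeration use an absolute 1e-9 km tolerance.
- The MST uses a dense-matrix Prim implementation so that exact-zero edges
  between coincident cell centres are kept.
- The grid is a latitude-ring equal-area construction: rings of height equal
  to the spacing, each split into round(ring area / spacing²) cells.  Cell
  areas stay within a few percent of the mean (±15 % guaranteed by test) and
  in-ring neighbour distances within ±20 % of the nominal spacing.  Grid
  orientation is fixed; downstream statistics depend only on approximate
  equal-area binning, so the realization is pluggable.
- AR(1) GLS profiles the likelihood over φ ∈ (−0.999, 0.999) with a bounded
  scalar optimizer (xatol 1e-8); φ = 0 reproduces OLS exactly.
- Models whose small-sample AICc correction is undefined (n − k − 1 ≤ 0) are
  skipped and flagged, never silently ranked.

## Design choices where the method description is open

- "Closest point to the set" is read as single linkage (minimum over
  members), consistent with measuring spread by MSTs; centroid linkage could
  accrete geometrically disconnected points.
- Cluster overlap uses the smaller region as denominator, so a small region
  nested in a large one is always absorbed; Jaccard is a config alternative.
- The multiton ratio is species-based (share of species seen ≥ 2 times);
  an occurrence-based variant is a config alternative.
- SQS operates on abundance-type frequency vectors of per-species occurrence
  counts, the usual practice for occurrence databases; incidence-mode SQS is
  out of scope.
- Chao 2 sampling units are collections (the natural replication unit).
- p-values from slope tests are descriptive; no multiple-testing correction.

## Problem sizes

Default test and acceptance runs use the scenario sizes above (~15–30 k
occurrences per world, ≤ ~150 spatial points per bin); region enumeration is
O(P³) per bin worst case and completes P = 200 well inside a minute.  Model
selection robustness is assessed over 100 seeded replicates per scenario.

## Known limitations

- The standardization criteria assume the reference-count and multiton
  floors are meaningful for the input database; sparse records yield empty
  standardized sets (reported, not an error).
- SQS extrapolation far beyond 2n is unreliable and flagged rather than
  suppressed.
- The region enumeration is exhaustive by design; for point sets far beyond
  ~300 per bin a heuristic subset of starting points would be needed (out of
  scope here).
- Interval slope tests treat cluster medians as independent observations;
  clusters within a bin share sampling conditions, so p-values are
  descriptive rather than strictly calibrated.
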
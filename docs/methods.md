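# Methods

`piosphere` analyses the multi-scale structure of invertebrate communities
sampled by pitfall traps along transects running away from a permanent water
source (a piosphere gradient).  This note describes the statistical
machinery, the choices made where the methods literature leaves latitude,
and what the synthetic-data generator does and does not emulate.

## Survey data model

The observation unit is one trap x season x morphospecies count inside a
fixed hierarchy: transects ⊃ distance categories ⊃ sample points ⊃ traps.
The default design is six transects with sample points at 0, 50, 100, 150,
250, 500 and 1,000 m from water, five sample points per distance category,
three traps per point, and wet/dry seasonal visits.  Input tables are
long-format CSV; validation rejects counts that are negative or
non-integer, distances outside the declared category set, identifiers
outside the design, and duplicate keys, reporting input line numbers.
Missing traps must be represented explicitly (the generator zero-fills; the
reader never invents rows).

Two derived containers feed the analyses:

* **Community matrix** — samples x morphospecies counts at trap,
  sample-point or distance-by-transect pooling.  Species never observed in
  the selection are dropped by default (they carry no information for
  per-season metrics); a flag retains the full species universe so paired
  wet/dry matrices can share one column set.
* **Interaction matrix** — per transect x season, morphospecies (rows) x
  distance categories (columns), counts pooled over points and traps;
  all-zero rows are removed.  Matrix totals always equal the totals of the
  records they summarize.

## Alpha diversity

Per sample: abundance (total individuals), richness (morphospecies with
count > 0) and the effective number of species, exp(H) with H the Shannon
entropy of relative abundances (Hill number of order 1; natural log — the
exponential makes the choice of base irrelevant).  Empty traps propagate a
missing effective-species value, never 0: exp(H) of an empty community is
undefined and a silent 0 would bias distance-category summaries downward.
Summaries report mean, SE = sd/sqrt(n) and n per distance category x
season.

## Beta diversity as multivariate dispersion

1. **Modified Gower dissimilarity** between trap samples: counts are
   transformed to log_b(x) + 1 for x > 0 and 0 for absence, and the
   dissimilarity is the mean absolute difference over species not absent
   from both samples.  The default base is 10, so a tenfold abundance
   change contributes exactly as much as a species gain/loss; the base is a
   flag for sensitivity analyses.  A pair of completely empty samples has
   an undefined dissimilarity, so empty traps are excluded before this step
   and the exclusion count is reported.
2. **Principal coordinates** of the dissimilarity matrix, from the
   Gower-centred matrix -D²/2.  Negative-eigenvalue axes are *retained* as
   imaginary coordinates: the signed identity
   d²(i,j) = ‖x_i−x_j‖² − ‖y_i−y_j‖² then reproduces the input
   dissimilarities exactly (to 1e-8 in tests).  Eigenvalues within 1e-10 of
   the largest magnitude are treated as zero.
3. **Distance to centroid**: for each sample, squared real-axis distance to
   its group centroid minus the squared imaginary-axis distance, clamped at
   zero (clamp events are counted and logged) and square-rooted — the
   standard correction used in homogeneity-of-dispersion analysis.
   Singleton groups give distance 0.

Dispersion is computed at four nested scales — transect, distance category
(pooled across transects), distance category within transect, and sample
point — all within one per-season ordination of trap samples, because the
comparison across scales is only meaningful in a common space.  No
homogeneity F-test is performed; the per-sample distances are exported as a
model-ready table for external mixed-model software.

## Weighted nestedness (WIN / WINE)

Rows and columns of an interaction matrix are sorted by decreasing marginal
totals (stable ties by original index), so the generalist corner sits at
(0,0).  Each cell gets a *corner affinity*: 1 minus its Euclidean distance
to the generalist corner after normalizing both index axes to [0,1]
(aspect-ratio invariance: a 150 x 7 matrix must weigh column position as
strongly as a square one).  WIN is the mean affinity weighted by
log10(1 + count) — the same order-of-magnitude abundance weighting the
modified Gower dissimilarity uses.  Two numerical facts drive these
choices and are easy to miss:

* A cell score *linear* in the indices (a Manhattan distance) makes the
  weighted mean a function of the margins alone, hence *identical* across a
  fixed-margin null ensemble — zero power by construction.  The curvature
  of the Euclidean distance carries the entire signal.
* Weights linear in raw counts let the few dominant-species cells swamp the
  occupancy pattern of the long species tail; the log compression restores
  the pattern the estimator is meant to see.

The normalized estimator is

    WINE = (WIN_obs − mean WIN_null) / (WIN_max − mean WIN_null)

with the null ensemble described below and WIN_max the WIN of the maximally
nested rearrangement of the observed matrix: after canonical sorting, each
row's positive values are slid against the generalist corner with their
relative order preserved (a pure occupancy repacking — values are not
re-sorted, so the reference stays achievable by rearranging presence
pattern alone).  WINE is ~0 for a matrix typical of its fixed-margin
ensemble, ~1 for a maximally packed one and negative for anti-nested
(checkerboard-like) structure; the significance outputs are
z = (WIN_obs − mean)/sd over the null and a one-tailed p (proportion of
null WINs ≥ observed).  For a matrix with no empty cells the repacking is a
no-op and the normalization is uninformative; WINE is then reported as NaN
with a flag while z and p remain valid.

## Weighted bipartite modularity

The objective is the weighted two-mode modularity

    Q = (1/F) Σ_ij [A_ij − k_i d_j / F] · 1{row i, column j share a module}

(F grand total, k row sums, d column sums).  Maximization is a simulated
annealing over joint row/column module assignments: single-node moves to a
random module under a geometric cooling schedule (T: 0.05 → 2e-4, factor
0.85, four proposals per node per temperature), followed by a greedy
best-move polish, with 10 independent restarts by default.  Module count is
capped at min(rows, columns).  The reported Q is recomputed from the
returned partition, so the recomputation identity holds by construction.
Against exhaustive search over all joint partitions (matrices with ≤ 8
nodes) the default settings recover the global optimum in effectively all
runs, and planted two-block 10x10 matrices are recovered essentially
always; both are asserted in the test suite.

## Null model and inference

All significance statements use ensembles of random integer matrices with
exactly the observed row and column totals, drawn by Patefield's algorithm
(via `scipy.stats.random_table`).  Matrices with a single row or column are
fully determined by their margins and are returned as-is.  The default
ensemble size is 1,000 draws per matrix.  Null modularity values are
optimized with the identical annealing budget as the observed matrix —
unequal search effort would bias the z-score.

Seasonal contrasts use D-values: for each statistic and season, D_i =
null_i − observed.  The wet and dry D-distributions are compared by a
two-sample permutation test on the difference of means, two-sided, with the
identity permutation included in numerator and denominator (so p = 1 when
the seasons are identical and the smallest attainable p is 1/(B+1); default
B = 9,999).  Families of nestedness and modularity p-values across
transect x season cells are adjusted by Benjamini–Hochberg step-up FDR
control (via statsmodels).  Type-I error of the permutation test is
verified by simulation to sit in [0.03, 0.07] at α = 0.05, with power ≥
0.99 at a five-null-SD separation.

## Synthetic surveys

The generator draws per trap x season x species counts from a negative
binomial (size 0.5 by default — pitfall catches are strongly aggregated)
around λ(season, distance, species) = base(species) ·
season_multiplier · exp(trend · distance/100 m) · structure_weight, with
the whole mean surface rescaled so the expected survey total matches a
target (default 55,000 individuals across 150 species, matching the scale
of a large semi-arid savanna survey).  Base abundances follow a log-series
(p = 0.995) by default.  Defaults plant a wet:dry abundance ratio of 2 and
log-linear declines of −0.05 (wet) and −0.15 (dry) per 100 m, the dry
season steeper because water limitation concentrates activity near the
source.

Planted structure is a weight matrix interpolated linearly between all-ones
and a fully structured 0/1 pattern (`structure_strength` in [0,1]):

* **nested** — the species of abundance rank i occupies the first b_i
  distance categories, with b_i shrinking from all categories to one as
  rank grows.  A variant with within-range geometric value decay was
  evaluated and rejected: it concentrates the column margins, which a
  fixed-margin null then absorbs, destroying detection power — an
  instructive property of margin-conditioned inference.
* **modular** — distance categories are partitioned into blocks (default
  {0,50,100} vs {150,250,500,1000}); species are assigned to blocks round-
  robin by abundance rank and occur only in their block at full strength.

`planted_truth` returns the planted ordering/partition/trends for recovery
tests.  Identical config + seed reproduce the table byte-for-byte.

The generator emulates the sampling hierarchy, overdispersion, seasonal and
distance effects, and nested/modular organisation.  It does *not* emulate
spatial autocorrelation beyond the hierarchy, trap-level heterogeneity in
capture efficiency, climate covariates, or species-level detection
differences — so passing recovery tests demonstrate correctness of the
estimators under the stated model, not robustness to those field realities.

## Problem sizes in the shipped checks

The test suite and the acceptance script run everything at reduced scale,
chosen as the smallest sizes at which the checked properties are stable:
single- to three-transect surveys of 40–100 species and 3,000–20,000
individuals, null ensembles of 120–1,000 draws, 10 annealing restarts, and
499–1,999 permutations.  The pipeline defaults remain at the full-survey
settings (1,000 null draws, 9,999 permutations).

## Known limitations

* WINE's normalization is undefined for matrices without empty cells
  (reported as NaN with a flag) and is sensitive to the choice of cell
  weighting; the z-score and p-value are the more robust outputs.
* The annealer offers no optimality guarantee beyond the tested regimes;
  very large sparse matrices may need more restarts.
* Mixed-model inference on the alpha/beta responses is intentionally out of
  scope; the pipeline exports a model-ready table instead.
* Dispersion distances are computed in a per-season ordination; comparing
  absolute magnitudes *between* seasons therefore compares different
  spaces, and only within-season contrasts are interpreted.
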
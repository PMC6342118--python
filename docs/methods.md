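# Methods

This note documents the models and numerical choices behind `landgen` —
what each procedure assumes, which knobs matter, what the simulator does
and does not emulate, and where the design was genuinely open.

## Genotype model and duplicate resolution

Genotypes are diploid codominant calls at L unlinked microsatellite loci,
stored as positive integer allele codes with 0 as the missing sentinel; a
half-missing call is coerced to fully missing on load, so every genotype is
either complete or absent. Comparisons are unordered (heterozygote AB equals
BA — codominant markers carry no phase).

Re-sampled individuals (e.g., repeated non-invasive collections) are
collapsed by `match_duplicates`: two samples link when they agree at
`min_matching_loci` (default 8 of 9) or more loci, a locus missing in
either sample counting as a non-match (conservative; an `ignore_missing`
mode lowers the threshold by the number of incomparable loci instead).
Linked samples are resolved by connected components, so chained
near-matches merge transitively. The representative is the member with the
fewest missing loci (ties: lowest input index) and takes the centroid of
the member coordinates. These three choices — strict missing handling,
transitive closure, centroid — are conventions; the alternatives are
defensible, and the mismatch histogram in the `MatchReport` lets a user
audit how aggressive the merge was. The planted-duplicate recovery
guarantee ("n_unique equals the planted count") holds for duplicate-free
base populations; under strong isolation by distance at low density the
simulator legitimately produces natural 8/9 kin matches, which the rule
merges as designed.

## Classical statistics

* Expected heterozygosity uses the unbiased small-sample factor
  `2n/(2n−1)`; allelic richness rarefies each locus to the smallest
  per-group count of complete genotypes (in genes) via the exact
  hypergeometric formula; multilocus F_IS = 1 − ΣH_o/ΣH_e with sums over
  loci, tested by permuting alleles among individuals within the group
  (two-sided).
* Pairwise F_ST is Weir & Cockerham's θ with variance components summed
  over alleles and loci before the ratio; significance permutes individuals
  between the two groups. Note θ of two identical groups is slightly
  *negative*, not zero — the estimator is unbiased, so a realization whose
  among-group variance is exactly zero sits below the null expectation.
* Hardy–Weinberg and linkage tests are Monte-Carlo probability tests: the
  HWE p-value is the conditional probability mass of genotype tables at
  most as probable as the observed one (tables sampled by shuffling the 2n
  allele list); the linkage statistic is the G-statistic of the two-locus
  genotype table with one locus permuted among individuals.
* All permutation p-values use the `(k+1)/(n_perm+1)` correction and
  therefore respect the resolution of the permutation count (default 999).
* Multiple testing uses Holm's step-down sequential Bonferroni.

## Mantel test and correlogram

Mantel r is the Pearson correlation of upper-triangle entries, with rows
and columns of the second matrix permuted simultaneously (one-sided by
default). Geographic distance is straight-line Euclidean in projected
meters; no log transform is applied by default (the relationship between
genetic distance and log distance can be examined by transforming the
off-diagonal entries, under which r is invariant only for *linear* maps).
The correlogram uses equal-frequency distance classes; per class, r is the
correlation of genetic distance with the complement of the within-class
indicator, so positive autocorrelation at short range appears as positive
r. Classes under 20 pairs merge downward (fewer than two surviving classes
is an error), and the sequential correction is progressive Bonferroni
(p·k in increasing-distance order).

## MEM construction and the spatial regression

The spatial basis is the PCNM lineage of Moran's eigenvector maps: given
any symmetric spatial distance matrix (straight-line or least-cost), the
truncation threshold t defaults to the longest minimum-spanning-tree edge
(the smallest t keeping the graph connected); entries beyond t become 4t;
the matrix −D*²/2 is Gower-centered and eigen-decomposed. Eigenvectors with
|eigenvalue| above 1e−10 of the maximum are retained and classed by
eigenvalue sign — positive = broad-scale, positively autocorrelated
patterns; negative = fine-scale alternation.

The response is the full set of positive principal coordinates of the Dps
genetic distance (no axis cap by default; `axis_cap` exists for speed).
Selection of eigenvectors, per sign class:

1. **Global gate.** The class-wide regression is tested by permutation of
   response rows; selection proceeds only if its p ≤ α. Without this gate
   the best-of-k candidate scan is anticonservative — on panmictic data the
   procedure would report spatial structure far more often than α.
2. **Stepwise max-test.** At each step, the candidate with the largest
   marginal contribution is tested against the *maximum* over remaining
   candidates under permutation of the current residual — the null of the
   statistic actually selected. A plain marginal test admitted several
   false eigenvectors per run.
3. **Adjusted-R² ceiling.** Selection stops once the cumulative
   Ezekiel-adjusted R² reaches the adjusted R² of the full-class model.
   The ceiling is a noisy, unbiased estimate of the same quantity the
   selected model estimates, so the *crossing* variable is kept and
   selection stops after it; dropping it instead was observed to discard
   genuinely constructed predictors in roughly half of replicates.

Negative-class eigenvectors are selected the same way and enter the model
only when their own global gate passes ('auto'; both classes can be
forced). The redundancy analysis itself is ordinary least squares of the
response on the selected (orthonormal) eigenvectors; the SVD of the fitted
values gives orthogonal spatial genetic axes ordered by eigenvalue, each
with its share of the explained variation. Reported R² is Ezekiel-adjusted
(`1−(1−R²)(n−1)/(n−m−1)`), with the raw value alongside; overall
significance permutes response rows with the selection held fixed.

## Landscape resistance and the IBD/IBR partition

Vector features rasterize onto a regular grid (default cell: 1/200 of the
larger bounding-box dimension, overridable — results at a given precision
depend on resolution, so `model_search` accepts an explicit grid). Roads
are buffered lines (500 m radius, i.e., a 1 km corridor); water and fire
polygons burn by cell-center containment; fire polygons are kept only for
ignition years 1964–2013 (a 50-year recency window). Costs are
multiplicative per-cell traversal factors on a background of exactly 1;
overlapping layers take the maximum (configurable). Scaling all costs by a
common factor scales distances and leaves every MEM basis and fraction
unchanged.

Least-cost distances are shortest paths on the cell graph with edge weight
= mean endpoint cost × cell size (×√2 diagonal). `cost_distance_matrix`
defaults to 8-connectivity; `mg_landscape` defaults to 16 directions
(knight moves weighted over the two traversed intermediate cells, so a
narrow corridor cannot be skipped), which cuts the worst-case metric
distortion of the grid approximation from ~8% to ~3%. A uniform cost-1
surface is the straight-line IBD model by definition, so `mg_landscape`
uses exact Euclidean distances for it rather than the grid approximation —
otherwise the truncation threshold reacts to the ~3% metric warp and a few
percent of spurious "landscape-specific" variation appears.

The partition follows the standard two-block adjusted-R² algebra
(`abc = adjR²(X1∪X2)`, `a = abc − adjR²(X2)`, `c = abc − adjR²(X1)`,
`b = ab + bc − abc`, `d = 1 − abc`), which satisfies `a+b+c=abc` and
`abc+d=1` identically; small negative adjusted fractions are reported as
computed. The full-model p-value permutes response rows; the partial
fractions use residualized-response permutation (rows of the residual on
the conditioning block are permuted and added back to its fitted values).
`model_search` screens each feature at costs {10, 50, 100}, keeps the
cost maximizing fraction [a] per feature (switchable to [abc] — the
original choice of ranking statistic is ambiguous), then runs the pairwise
and three-way combinations plus the flat IBD surface.

## MU scenario evaluation

The response is the first spatial genetic axis (an all-axes multivariate
mode exists). The MU block is full-rank treatment-coded membership
(reference: lexicographically first unit); point-in-polygon assignment
breaks boundary ties toward the lowest polygon index, with an optional
nearest-boundary fallback. The spatial block defaults to the coordinates
(a linear trend surface for "spatial proximity"): it must *not* be the
selected MEM eigenvectors themselves, because the spatial genetic axes are
fitted values of the regression on exactly those vectors — the spatial
block would then span the response and every unique MU fraction would be
identically zero, making scenarios indistinguishable. Scenarios are ranked
by fraction [a] (ties: larger [a]+[c]); ranking across different unit
counts is refused because no penalty for added dummy variables exists.

## The simulator

`simulate_population` is a minimal forward-time model producing genuine
spatial autocorrelation with known truth: n individuals at fixed
uniform-random sites; discrete non-overlapping generations; each site's
offspring draws two *distinct* parents with probability ∝
exp(−d_eff²/2σ²), where d_eff multiplies the straight-line distance by the
barrier factor when the segment crosses the barrier (panmixia: uniform
draws); one allele per parent per locus; stepwise ±1 mutation at rate μ
(default 5×10⁻⁴) reflecting at repeat sizes [5, 50]; founders at
Hardy–Weinberg with 10 equifrequent alleles per locus. Planted duplicates
(copies with one perturbed locus, jittered coordinates) exercise the
dedup rule.

What it does **not** emulate: individual movement (sites are fixed),
overlapping generations, sex-biased dispersal, selection, genotyping error
beyond the planted perturbation, and linked loci. Passing recovery tests
therefore shows the *analysis* responds correctly to clinal
autocorrelation, resistive barriers and panmixia — not that it handles
every artifact of real non-invasive data.

Two regime notes, relevant to interpreting tests:

* **Equilibration.** The clinal IBD signal needs σ√t comparable to the
  study extent and Wright neighborhood size 4πσ²n/extent² of order ≥ 1.
  Away from that regime (small σ, few sites, few generations) the
  population is a mosaic of inbred patches: the Mantel correlation is then
  *not* monotone in σ. The dispersal-gradient checks use n = 400 and 600
  generations, where the monotone decrease holds with a wide margin.
* **Local inbreeding.** Small neighborhoods produce genuinely homozygous
  kin clusters, which the 8/9 duplicate rule merges — as it should. Tests
  of exact planted-duplicate recovery therefore use panmictic populations.

## Problem sizes used by the validation suite

Oracle-equivalence checks run on ≤25-point fixtures at 1e−8. Type-I
control: 200 panmictic populations (n = 150, 9 loci) for the spatial
regression (significance rate ≤ 8% at α = 0.05) and 2000 independent
random-geometry pairs for the Mantel test (rate within the binomial 95%
band — the test is exact, so more replicates tighten the check). IBD
recovery: 30 replicates per dispersal level (2%, 5%, 20% of extent).
IBR and MU recovery: 100 replicates each at n = 120, 300 generations,
barrier factor 10, grid cells of 1 km. Adjusted-R² recovery: 100
two-eigenvector constructions at n = 150, target R² = 0.5. The suite
completes in roughly ten minutes on one CPU.

## Known limitations

* Fractions from adjusted R² can be slightly negative; they are reported,
  not clipped.
* The PCNM truncation step is discontinuous in the distances: near-threshold
  pairs can flip with tiny metric changes, which is why comparisons between
  bases built from *approximated* distance matrices need care (see the
  flat-surface shortcut above).
* GENEPOP parsing covers the 2- and 3-digit dialects with POP blocks; exotic
  variants (haploid blocks, mixed ploidy) are out of scope.
* The probability tests use Monte-Carlo sampling, not the original
  Markov-chain batching scheme of the classical software; p-values agree in
  distribution but not call-for-call.
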
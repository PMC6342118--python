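# landgen

Landscape genetics for continuously distributed populations: spatial
genetic regression on Moran's eigenvector maps (MEM), partitioning of
genetic variation into isolation-by-distance (IBD) and
isolation-by-resistance (IBR) components with least-cost-path landscape
models, and variation-partitioning comparison of management-unit (MU)
delineations.

## Who this is for

Conservation and population geneticists working with multilocus codominant
genotypes (microsatellites) from individuals sampled continuously across a
landscape — wide-ranging mammals, for instance — where discrete "population"
boundaries are an output of the analysis, not an input. The package answers
three questions:

1. **How much genetic variation is spatially structured, and at what
   scales?** Genetic dissimilarity between individuals i and j is
   `D_ps(i,j) = 1 − (shared alleles)/(2 × loci)`; its principal coordinates
   Y are regressed (redundancy analysis) on spatial eigenfunctions — the
   eigenvectors of the Gower-centered, truncated distance matrix (the
   PCNM/MEM construction, with distances beyond the minimum-spanning-tree
   threshold t replaced by 4t). Forward selection with permutation tests
   picks the significant eigenvectors; the orthogonal axes of the fitted
   values are the spatial genetic patterns, and the Ezekiel-adjusted R² is
   the proportion of genetic variation explained by space.

2. **Is the spatial structure shaped by the landscape (IBR) beyond plain
   distance (IBD)?** For a candidate resistance model (roads, water, recent
   wildfire rasterized at cost values 10/50/100 over a cost-1 background),
   MEM bases are built from least-cost-path distances and from straight-line
   distances, and the adjusted R² is partitioned:
   `[a]` landscape-specific, `[c]` coordinate-specific, `[b]` confounded,
   `[d] = 1 − [abc]` residual, with `[a]+[b]+[c] = [abc]` exactly.

3. **Which MU boundaries best capture the spatial genetic pattern?**
   Dummy-coded polygon membership is partitioned against spatial proximity
   for the first spatial genetic axis; scenarios are ranked by the
   boundary-specific fraction `[a]` — only scenarios with equal unit counts
   are comparable, since added dummy variables inflate R² with no penalty
   available.

A forward-time spatially explicit simulator (fixed sites, distance-limited
biparental mating, stepwise microsatellite mutation, optional resistive
barrier) generates populations with known truth for validating the whole
chain, plus GENEPOP and delimited-table readers for real data.

## Worked example

```python
import numpy as np
from landgen import (SimulationConfig, simulate_population, match_duplicates,
                     mgquick, mantel_test, dps_distance)
from scipy.spatial.distance import pdist, squareform

cfg = SimulationConfig(n_individuals=200, n_generations=400,
                       sigma=5_000.0, scenario="ibd", seed=7)
table, truth = simulate_population(cfg)

D_geo = squareform(pdist(table.xy))
D_gen = dps_distance(table).matrix
ibd = mantel_test(D_geo, D_gen, n_perm=999, random_state=7)
print(f"Mantel r = {ibd.r:.3f}, p = {ibd.p:.3f}, n = {ibd.n}")

res = mgquick(table, alpha=0.05, n_perm=999, random_state=7)
print(f"space explains {100*res.adj_r2:.1f}% of genetic variation "
      f"({res.n_axes} axes, first axis {100*res.axis_proportions[0]:.0f}%)")
```

prints

```
Mantel r = 0.517, p = 0.001, n = 200
space explains 44.1% of genetic variation (25 axes, first axis 38%)
```

— genetic similarity decays with distance (a strong clinal IBD signal at a
dispersal scale of 5% of the study extent), and a large share of the
individual genetic variation is attributable to spatial patterns, led by a
broad-scale cline. The same objects continue into the landscape
and MU analyses (`mg_landscape`, `model_search`, `mu_varpart`,
`compare_scenarios`), and everything is also reachable from the `landgen`
CLI (`simulate`, `dedup`, `stats`, `ibd`, `memgene`, `landscape`,
`mu-compare`, `pipeline`).

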
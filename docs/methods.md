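# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `mosaicopt`, in the spirit of a statistical software
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Landscape model

A landscape is a `rows × cols` raster of square parcels, each in exactly
one land state: grassland (G), forest (F), agriculture (Ag), or excluded
(X). Both urban and water map to the single X state: X parcels never
participate in exchanges, contribute nothing to any objective term, and
do not connect patches of the surrounding vegetation. Coordinates are
0-based `(row, col)`, row-major; exported files use the same convention.

A **patch** is a maximal von Neumann-connected (4-neighbour) component of
same-state parcels; diagonal contact does not connect. Patch extraction
delegates to `scipy.ndimage.label` with a plus-shaped structuring
element; the test suite cross-checks it against a naive pairwise
union-find written independently.

A **parcel exchange** swaps the states of two parcels of differing
vegetation states (G↔Ag, F↔Ag, G↔F). Exchanged parcels need not be
adjacent or co-owned unless an exchange rule says so; per-state counts
are conserved by construction. Non-equal state distributions are fully
supported.

## Objective

The mosaic richness index is

    B = Σ_L B_L,      B_L = N_L · c_j · (N_L · A)^{z_j},

the power-law SAR of each patch weighted by its parcel count `N_L`. The
weighting is what makes a connected set of N parcels score strictly
higher than the same parcels split into several patches: for `z > 0`,
`(N1+N2)^{z+1} > N1^{z+1} + N2^{z+1}` (Bernoulli's inequality), and by
induction fewer patches at fixed counts always score higher. This gives
a checkable global-optimality criterion under the pure index: a
landscape is a global maximum iff each vegetation state present forms a
single patch. The test suite verifies this against exhaustive
enumeration of all 1,680 arrangements of a 3×3 grid with three parcels
per state.

Defaults (`ObjectiveConfig()`): `c_G = 19.95` species/m², `z_G = z_F =
z_Ag = 0.51`, `c_F = 0.5·c_G`, `c_Ag = 0.05·c_G`, parcel area `A = 1`
(the 1 m² quadrat scale the calibration was done at; the framework is
scale-free in the sense that `B_L` scales by `s^z` when `A` is scaled by
`s`). Agriculture carries a SAR too (roughly one crop species per m²),
so Ag patches contribute to B.

### Optional extensions

Two alternative extensions blend into the objective with a weight
`w ∈ [0,1]` (`w·B + (1−w)·extra`); the analysis default is the pure
index (`w = 1`, no extensions), and they are mutually exclusive:

* **Patch architecture.** `P_A1` sums, for forest and grassland
  separately, each patch centroid's distance to its nearest same-state
  patch centroid (Euclidean, parcel side-length units) and adds the two
  reciprocals — rewarding same-state patches for being close. `P_A2`
  adds the reciprocals of the counts of forest and of grassland parcels
  adjacent to agriculture — penalizing vegetation–agriculture contact.
  `architecture_mode="both"` uses their sum.
* **Path costs.** `C` is the reciprocal of the accumulated cost of all
  individual parcel state changes along the exchange pathway (two
  changes per exchange), priced by an ordered-pair cost table with the
  six ledgers F→G, Ag→G, G→F, Ag→F, F→Ag, G→Ag.

**Degenerate reciprocals.** The reciprocal terms are undefined when a
state has fewer than two patches (`P_A1`), when no vegetation parcel
touches agriculture (`P_A2`), or when a pathway has zero cost (`C`).
These corners are mapped to configurable finite caps (defaults: 1 per
state for distance, 2 per state for adjacency, 1 for cost), chosen so
each term stays finite and monotone — fewer patches, less
agriculture contact, or lower cost never decreases the term. The caps
are a package design choice for corners the original formulation leaves
unspecified.

## SAR calibration

Accumulation curves are built by Scheiner-style **combination
averaging**: for each `k`, the mean over all `C(n,k)` quadrat subsets of
the distinct-species count of the subset union. The exact mean is
evaluated in closed form — a species present in `m` of `n` quadrats is
missed by a `k`-subset with probability `C(n−m,k)/C(n,k)` — which equals
the full enumeration average (the suite checks this against explicit
subset enumeration up to n = 6). When `C(n,k)` exceeds `exact_limit`
(default 2×10⁵, comfortably above C(15,7) = 6,435 so the 15-quadrat
study design is always exact), a seeded Monte-Carlo estimate over
`n_samples` subsets is used instead.

Cover values (Londo ordinal scale in the field data this emulates) are
reduced to presence: any value > 0 counts. Only richness enters the
model.

Power-law fitting defaults to OLS on `log S` vs `log Area` — the
standard deterministic SAR convention — with an optional
`scipy.optimize.curve_fit` refinement on the original scale seeded by
the log-log fit. The grassland calibration averages the three
subcategory curves (abandoned / grazed / recently-burned sampling sites)
pointwise *before* fitting, matching the convention of fitting the mean
empirical curve rather than averaging fitted parameters.

## Local search

At each step, every legal exchange is scored by its gain ΔB and one of
the argmax moves is applied; the search stops when no exchange improves
B. Strict improvement at every step guarantees termination.

* **Ties.** Gains within a relative tolerance of the maximum
  (`tie_tol = 1e-9`; exact float equality would be fragile, and
  symmetric landscapes must tie) form the tied set. `search_all_paths`
  expands every tied branch depth-first; each completed branch is one
  locally optimal path, and two orderings of the same exchanges are two
  distinct paths. `search_single` follows one branch (lexicographic
  first-move or seeded random tie-break).
* **Incremental ΔB.** Swapping parcels a and b only reshapes the patch
  structure of their two states. Removing a cell can split its patch
  into at most four fragments, found by a local flood fill confined to
  that patch; adding a cell merges the patches/fragments it touches.
  With per-landscape label caches each candidate costs O(patch size)
  once and O(1) thereafter. The suite validates every increment against
  full recomputation and the whole search against an independent
  brute-force recursive oracle on small grids.
* **Once-per-parcel rule.** Practical pathways should not change any
  parcel's state twice. Default `prune_in_search` excludes used parcels
  from later enumeration while branching (bounding the tree);
  `post_filter` searches unrestricted and drops offending completed
  paths (provided for fidelity comparisons); `off` disables the rule.
* **Budgets.** The tie tree can explode on large symmetric landscapes.
  A node budget (default 10⁶ expansions) either hard-fails
  (`PathExplosionError`, the default, so counts are never silently
  wrong) or truncates with a `cap_hit` flag in the result stats.
* **Exchange rules.** `unrestricted` (any pair), `intra_property`
  (same owner), `inter_property` (exactly one parcel from each of a
  designated owner pair). `cra_run` models a reserve-quota trade: a
  greedy inter-property run stopping after the negotiated number of
  exchanges (e.g. 10 parcels), reporting the net per-owner, per-state
  parcel transfer.

## Path taxonomy and ranking

Among all locally optimal paths: **minimal** paths have the fewest
exchanges; a **dominant minimal** path attains, at every step index, the
maximum richness over all minimal paths at that index (comparisons use
the search's `tie_tol`); **minimal deviants** are the non-dominant
minimal paths plus locally optimal paths exactly one exchange longer
than minimal — both criteria can be toggled independently. When
trajectories of minimal paths cross, no dominant path exists and the
deviants form the viable-candidate pool. Viable candidates are distinct
terminal landscapes (exact grid equality — mirror-image optima count
separately) of dominant and deviant paths after the once-per-parcel
filter. Ranking is a total order: dominant minimal first, then by
length, stepwise trajectory (descending, lexicographic), terminal value,
and finally the move list as a deterministic tiebreak.

## Synthetic data generator

* **Landscapes.** `random_landscape` assigns exact per-state counts
  uniformly at random (seeded); the default spec is the hypothetical
  study condition — a 6×6 grid with 12 parcels each of G, F, Ag —
  optionally partitioned into rectangular ownership blocks.
* **Quadrat tables.** `synth_quadrats` emulates the field sampling
  design: 15 quadrats of 1 m² whose combination-averaged curve follows a
  target power law (default the grassland calibration c = 19.95,
  z = 0.51). Each species occupies each quadrat independently
  (Bernoulli) with a species-specific probability; because the expected
  union curve is linear in the number of species at each occupancy
  level, the probability profile is solved by non-negative least
  squares over a grid of occupancy levels and rounded by largest
  remainder. Levels are bounded below at 0.05: rarer species inflate
  union-curve variance without improving the (already ≤ 0.1 species)
  fit residual. The default pool of 160 species accommodates the ≈130
  species the calibration curve requires.
* **What the generator does not emulate.** Real quadrat data has
  spatially autocorrelated composition, species co-occurrence structure,
  and subcategory-specific richness differences; the generator's
  subcategory replicates are exchangeable. Real landscapes have spatial
  autocorrelation of land cover; the generator's are uniform. Passing
  tests therefore demonstrate correctness of the machinery at the study
  conditions, not robustness to the structure of real field data.
* **Recovery study conventions.** A single 15-quadrat realization
  carries ≈0.02 sampling standard deviation in the fitted exponent and
  ≈0.8 in the fitted coefficient, so recovery checks are formulated
  statistically: the exponent is required within ±0.05 for each of 20
  generator seeds, and the three-subcategory calibration check compares
  the *mean* fit over 10 replicate sampling campaigns against the
  target (±0.5 on c, ±0.05 on z). These tolerances are fixed study
  tolerances, not fitted quantities.

## Fixtures

The two published hypothetical 6×6 initial landscapes exist only as
raster figures in the source article; no cell-by-cell transcription
could be verified, so none is packaged. `load_fixture("fig4a")` /
`("fig5a")` raise `FixtureUnavailableError` with a provenance message,
and clearly-labelled synthetic stand-ins (`fig4a_synthetic`,
`fig5a_synthetic`: random mosaics with the same shape and per-state
counts, generator seeds 0 and 1 fixed a priori) are shipped instead.
Path censuses — how many dominant minimal paths, how many deviants,
minimal path length — are properties of the exact initial grid, so
results on the stand-ins are not comparable to the published counts;
tests that require the published grids skip with an explicit provenance
warning rather than asserting against stand-in output.
`demo_two_owner` is an invented two-property grid for inter-property
trading demos.

## Problem sizes

The default test and acceptance runs use 6×6 landscapes (the
hypothetical study condition; full tie-tree searches finish in seconds
and stay well under the 10⁶-node budget), 3×3 grids for exhaustive
enumeration oracles (1,680 configurations), and 15-quadrat tables for
SAR work. The search machinery itself is size-agnostic; full move
enumeration is quadratic in parcel count, so landscape-scale rasters
should be run under intra- or inter-property restrictions, which is how
the bounded case-study scenarios are intended to be used.

## Known limitations

* Moore-neighbourhood connectivity, Shannon-entropy objectives, species
  dispersal kernels, multi-objective cost/re-establishment modelling,
  and geographic projections/shapefile ingestion are out of scope.
* The single-patch global-optimality test is only valid for the pure
  index; under architecture or cost extensions it raises.
* The cost term's accumulation is per parcel state change (two per
  exchange); treating it per exchange would halve all costs and leave
  rankings unchanged only for symmetric tables.
* Tie classification depends on `tie_tol`; pathologically near-tied
  gains (beyond float-sum noise) could flip a branch in or out of the
  tied set.
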
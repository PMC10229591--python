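# Methods

This note records the models, defaults and numerical choices behind
`florealm`, and what the synthetic tests do and do not demonstrate.

## Turnover index

All stages rest on the Simpson dissimilarity `1 - a/(a + min(b, c))`.
It measures turnover only: nested assemblages score 0, and richness
differences do not inflate it, which is why it is the standard index for
bioregionalization. In phylogenetic mode a branch is "present" in a GSU iff
at least one descendant tip occurs there, and a/b/c are branch-length sums
over the tree spanned by the two assemblages. The root carries no stem
branch: a stem shared by every assemblage would only inflate the shared
component uniformly. The index is undefined when `a + min(b, c) = 0`
(an empty assemblage); empty assemblages are rejected at I/O time rather
than patched downstream. Because the index is a ratio of branch lengths, it
is exactly invariant under global rescaling of the tree — the package
asserts this end to end (a doubled tree gives bit-equal beta matrices and
the same realms).

The full-matrix path computes one branch-incidence matrix per GSU set and
evaluates all pairs by matrix products; it is contractually equal (to
1e-12) to the per-pair set-arithmetic path, which the tests use as the
independent oracle.

## Realm delineation

GSUs are clustered agglomeratively on the beta matrix. Seven classical
linkages (single, complete, average/UPGMA, McQuitty/WPGMA, Ward, centroid,
median) can be compared on two axes: *performance* (the minimum number of
nested-cut clusters at which the explained turnover P_beta reaches 0.99;
fewer is better) and *accuracy* (Pearson correlation between input and
cophenetic distances). The selected method minimises the cluster count with
ties broken by accuracy, and a full tie falls back to UPGMA, the field's
default. P_beta of a partition is the between-cluster share of the total
pairwise beta; along one dendrogram's nested cut sequence it is
nondecreasing in k (the between-pair set only grows), so "the smallest k
with P_beta >= threshold" is well defined. Cuts use the dendrogram's nested
sequence — undoing the last k-1 merges in merge order — which for monotone
linkages equals cutting at descending height, with height ties broken
deterministically by merge order. Realms use threshold 0.80 and sub-realms
0.95; sub-realms are therefore refinements of realms by construction. A
two-cluster cut is exposed for super-realms without asserting a turnover
level for that rank.

Supporting diagnostics: NMDS (nonmetric MDS, Kruskal stress-1, 2-D, best of
100 random starts by default; an all-equal matrix yields a deterministic
circular layout with a warning); FANNY-style fuzzy c-means operating
directly on the dissimilarity matrix (fuzziness exponent 1.5 by default;
rows sum to 1; a vanishing within-cluster cost pins a GSU crisply);
silhouette widths on the beta matrix (singleton clusters score 0); and the
confinement statistic — the fraction of genera whose occupied GSUs all
carry one realm label.

## Chronology by time-slicing

Cutting the dated tree at depth t collapses every branch whose age interval
spans t (older end > t >= younger end, tips pinned to the present) into one
lineage; a lineage occupies a GSU iff any member tip does. Beta at a slice
uses branch lengths of the *truncated* tree only, so each slice is a
self-contained comparison of the floras as resolvable at that depth. The
t = 0 slice reproduces the present-day pipeline exactly. Slices at or
beyond the crown age collapse to the root's children and are reported as a
single realm. Slice clusters are matched to present realms by
maximum-overlap optimal assignment; a slice cluster whose best Jaccard
falls below 0.5 is labelled "ancestral" rather than force-matched. NMDS
configurations per slice are aligned to the present configuration by a full
similarity Procrustes (translation, scale, rotation/reflection) fitted on
shared GSUs.

Separation of two realms is scored by the majority slice-cluster of each
realm's GSUs, and dated as the oldest slice of the unbroken separated run
containing the present; transient "separations" at deeper slices, where few
lineages remain and clustering is noise-driven, are ignored. A split
planted at time s is typically first visible one grid step younger than s:
immediately after a split the sister lineages have accumulated almost no
distinguishing branch length, so Simpson turnover between them is near 0.
The dating error the acceptance script reports (about one 10-Ma step) is
this structural lag, not an implementation artefact.

## Drivers

Contemporary-climate effects are OLS fits of beta on pairwise Euclidean
climate distance (temperature and precipitation z-scored by default — the
units are incommensurable), reported within each realm and between each
realm pair, on raw scales. The time-resolved attribution uses the ln-ln
model: per 1-Ma step, ln(beta) of a realm pair's cross-GSU pairs is
regressed on ln(geographic isolation) and ln(historical climate distance);
hierarchical partitioning gives each predictor's independent R²,
`I1 = [R²(x1) + R²(full) - R²(x2)]/2`, whose sum equals the full-model R²
exactly (asserted at every call). Zero distances are offset by 1e-6 times
the vector's positive maximum before the log. Bins of 5 Ma are summarized
as mean and SE (SD/sqrt(n) over the steps in the bin).

Geographic isolation is the all-pairs least-cost route between GSU
centroids on a land/ocean/elevation raster: 8-neighbour moves, edge cost =
great-circle length between cell centers x mean friction of the two cells,
friction = 1 + k_elev * elevation/1000 m on land and k_ocean on ocean.
Defaults k_ocean = 10 and k_elev = 1 are configuration, not estimates: the
route-cost functional form is not canonical, so the constants are exposed
and documented rather than hidden. Costs come from Dijkstra on the cell
graph and therefore satisfy the triangle inequality by construction.
Centroids falling on ocean snap to the nearest land cell with a logged
warning. A surface series with repeated landscapes shares shortest-path
computations.

## Node divergence

For an internal node with descendant clades A and B, GND defaults to the
Simpson-type mismatch of the clades' occupied-GSU sets (identical ranges 0,
disjoint ranges 1); the metric slot is pluggable because no single formula
is canonical for "distributional mismatch". Nodes with GND strictly above
0.65 are screened. SOS per GSU standardises the observed count of clade-A
tips against a null that shuffles the A/B labels across the node's tips,
preserving clade sizes and each tip's range (200 shuffles by default,
seeded); a zero null SD gives SOS 0. Polytomies are scored as the two
largest children with the remainder logged. A clade's contribution to one
realm division is the ANOVA R² of its SOS against realm identity, which for
two realms equals the squared point-biserial correlation (the tests check
this algebraically).

## The synthetic world

The generator targets the statistical structure the analysis assumes — no
continental drift, speciation geography or niche evolution is simulated.

* **Geometry.** GSUs form a lattice (default 6x6, 4 deg per GSU, centered
  on the equator); realms are contiguous rectangular blocks, optionally
  with proportional band areas (`realm_weights`).
* **Phylogeny.** A backbone places realm divergences at planted split
  times; each realm carries a birth-death subtree whose crown is capped at
  0.8x the youngest backbone split, so the oldest disjoint clades of the
  finished tree are exactly the realm clades. Within-realm subtrees get an
  early-burst age transform (internal ages remapped by `(a/crown)^0.2`),
  concentrating divergences near the realm crown as in a radiation. This
  choice keeps tip-level turnover inside realms strong and stable across
  seeds; with tree shapes that bury most branch length in shared deep
  edges, within-realm turnover fluctuates enough that the 0.80 cut
  occasionally under-splits four equal blocks (merging one realm pair
  leaves an explained-turnover of about 405/486 ~ 0.83 when within-realm
  turnover vanishes — an arithmetic property of the cut, not of the data).
  Default splits are 60, 30, 30 Ma for four realms ("realms formed since
  the Paleogene" scale).
* **Ranges.** Each clade is mapped to its realm (largest clades to largest
  realms, ties by smallest tip label); a tip occurs in each home GSU with
  probability `affinity` (0.8) and in each foreign GSU with probability
  `leakage` (0.02). Options: nested range patches within realms
  (`patch_frac < 1`), and leakage decaying with lattice distance or climate
  similarity (`leakage_mode`), which plant distance-decay or
  climate-matched turnover for the driver analyses. Empty genera are
  redrawn; empty GSUs are re-sampled up to 100 rounds, then generation
  fails.
* **Climate and paleo-landscape.** Contemporary climate mixes a
  latitudinal gradient with realm-mean offsets (`gradient_align`) plus
  noise. Paleo rasters put 1-deg cells inside 4-deg GSUs; a one-cell ocean
  strip opens along a realm-pair boundary at times younger than the pair's
  split, so least-cost isolation rises after the split; elevation is a
  fixed random hill field. Paleoclimate is the gradient plus a fixed
  per-GSU microclimate, with realm offsets switching on after the split in
  climate-driven worlds.

Study worlds used by the acceptance checks (chosen once, as the package's
own study design): realm recovery uses the defaults above; the chronology
world uses three realms with splits {60, 30} Ma, leakage 0.002 and band
areas 3:2:1 (low leakage keeps deep slices informative — a collapsed
lineage of ~100 tips with 2% leakage would occupy ~90% of foreign GSUs and
erase the block signal, an intrinsic property of presence-absence
collapsing; unequal areas keep the explained-turnover cut from absorbing a
sibling merge); driver worlds use two realms split at 60 Ma and leakage
0.15 with distance- or climate-decay (uniform leakage leaves no explainable
variance in cross-realm turnover, making attribution a coin flip); the
node-contribution world uses leakage 0.002 (range unions at 2% leakage
saturate and no node clears the 0.65 screen). Problem sizes throughout
(200 genera, 36 GSUs, 10-Ma slice grids, 81-step driver series, 20-seed
replicates) are the package's test design.

What passing synthetic tests do *not* show about real data: real GSUs are
polygons of unequal area with coastlines; real ranges are shaped by
dispersal and climate jointly, not by a two-parameter occupancy; real
phylogenies have polytomies, sampling gaps and dating error; and real
paleo-landscapes move. The generator demonstrates that each stage recovers
the structure it is designed to detect when that structure is present — it
cannot validate the ecological assumptions themselves.

## Numerical conventions

Identifier order is lexicographic everywhere, making matrix indices and
cut tie-breaks deterministic. All randomness flows from one master seed
through named substreams (tree/ranges/climate/paleo), so stages are
individually reproducible. Beta matrices are written with 12 significant
digits; newick slicing uses 17 significant digits so a t = 0 slice is
bit-faithful. Dendrogram cut ties follow merge order. The grid origin
follows ESRI ASCII-grid semantics (cell (0,0) at the NW corner, centers
half a cell in from the lower-left corner). NODATA mask cells read as
ocean, logged.

## Known limitations

* The explained-turnover thresholds (0.80/0.95) are conventions; near the
  threshold the realm count is sensitive to within-realm turnover, as the
  equal-block arithmetic above makes explicit.
* Slice dating carries the one-step structural lag described under
  Chronology.
* The route-cost constants are not calibrated to any empirical dispersal
  process.
* The GND metric is one reasonable choice among several; the 0.65 screen
  is inherited as a convention, not re-derived.
* OLS fits ignore the non-independence of pairwise observations sharing a
  GSU; no spatial or matrix-permutation correction is applied.
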
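# florealm

Quantitative delineation of floristic realms from phylogenies and
distributions, with their divergence chronology and drivers.

`florealm` is for biogeographers who have (i) a dated genus-level phylogeny
(newick, branch lengths in Ma) and (ii) presence records of those genera
over a set of geographic standard units (GSUs), and who want to:

1. **Delineate nested floristic realms.** Pairwise assemblage turnover is
   the Simpson dissimilarity

       beta = 1 - a / (a + min(b, c)),

   computed taxonomically (a = shared genera, b/c = unique genera) or
   phylogenetically (a, b, c = shared/unique branch length of the phylogeny
   spanned by each assemblage). GSUs are clustered by UPGMA (linkage methods
   are compared by cophenetic correlation and by the number of clusters
   needed to explain 99% of turnover), and the dendrogram is cut at the
   smallest number of clusters whose explained turnover P_beta — the
   between-cluster share of total pairwise beta — reaches 80% (realms) and
   95% (sub-realms). NMDS ordinations, fuzzy c-means memberships, silhouette
   widths, and the fraction of genera confined to a single realm quantify
   how hard the boundaries are.
2. **Date the realm boundaries.** The phylogeny is cut at successive depths
   t; each branch crossing t becomes one collapsed lineage, assemblages are
   unioned accordingly, and the clustering is re-run on the truncated tree.
   Matching each slice's clusters to the present realms (optimal-assignment
   overlap) shows the depth at which each boundary appears; Procrustes-
   aligned NMDS configurations trace the growth of inter-realm
   dissimilarity.
3. **Attribute boundaries to isolation vs climate.** Per 1-Ma time step,
   ln(beta) for the cross-realm GSU pairs of a realm pair is regressed on
   ln(least-cost geographic isolation) over the paleo-landscape (Dijkstra on
   a land/ocean/elevation friction raster) and ln(paleoclimate distance);
   hierarchical partitioning splits the R² into independent contributions,
   summarized as mean ± SE per 5-Ma bin.
4. **Score clades' contributions.** Per internal node, a geographic node
   divergence (GND) score in [0, 1] measures the range mismatch of the two
   descendant clades; nodes with GND > 0.65 get per-GSU standardized
   overrepresentation scores (SOS) against a clade-label-shuffling null, and
   a clade's contribution to a realm division is the one-way ANOVA R² of SOS
   against realm identity.

A synthetic-world generator (`florealm.synthetic`) plants realms, split
times, climates and paleo-landscapes with known parameters so every stage
is testable against ground truth.

## Worked example

```python
from florealm import (
    simulate_world, pairwise_beta, regionalize, boundary_confinement,
    chronology_run, separation_time,
)

world = simulate_world(seed=11)          # 4 planted realms, 200 genera, 6x6 GSUs
beta = pairwise_beta(world.occurrences, tree=world.tree, mode="phylogenetic")
reg = regionalize(beta, linkage_method="auto")
print(reg.realms.k, round(reg.realm_pbeta, 3))
print(round(boundary_confinement(world.occurrences, reg.realms), 3))

# chronology on a low-leakage world with splits planted at 60 and 30 Ma
chrono = simulate_world(n_realms=3, leakage=0.002,
                        realm_weights=(3, 2, 1), seed=11)
slices = chronology_run(chrono.tree, chrono.occurrences,
                        [float(t) for t in range(0, 90, 10)])
print(separation_time(slices, chrono.truth.realm_partition(), 1, 3))
```

This prints:

```
4 0.941
0.59
50.0
```

i.e. the 80%-turnover cut finds the four planted realms (explained turnover
94.1%), 59% of genera never cross a realm boundary, and realms 1 and 3 —
planted to diverge 60 Ma — first appear as separate realms at the 50-Ma
slice, one 10-Ma step after their divergence (a split becomes visible only
once the lineages have accumulated distinguishing branches).

The same stages are available from the shell:

```
florealm simulate --out world/ --seed 11
florealm beta --occ world/occurrences.csv --tree world/tree.nwk --out beta.csv
florealm regionalize --beta beta.csv --gsu-table world/gsu_table.csv --out realms/
florealm chronology --tree world/tree.nwk --occ world/occurrences.csv --times 0:80:10 --out chron/
```

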
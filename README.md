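# micronet

A reverse-ecology toolkit for microbial ecologists who want to relate
observed co-occurrence patterns between microbes to the metabolic
capabilities encoded in their genome-scale metabolic models (GEMs).
Given a collection of GEMs, `micronet` identifies each organism's **seed
metabolites** — the minimal set of compounds it must acquire from its
environment — and from them computes pairwise **competition** and
**complementarity** indexes, **metabolic** and **taxonomic** distances,
and combines these with curated association tables into two per-query
scatter products: the *neighbourhood map* and the *metabolism
compatibility map*.

## The method

A GEM is turned into a directed metabolite graph: every internal or
transport reaction contributes an edge from each substrate to each
product (both directions when reversible); exchange reactions, which
describe boundary flow of a single extracellular compound, contribute no
edges. The graph is decomposed into strongly connected components with
Kosaraju's two-pass algorithm, and the seed metabolites are the members
of *source* components of the condensation — components with no incoming
edge but at least one outgoing edge. Writing `S_A` for the seed set of
organism A, `P_A` for its producible set (all network compounds outside
`S_A`) and `R_A` for its reaction set:

- competition index `C(A,B) = |S_A ∩ S_B| / |S_A|` — overlap of
  nutritional niches, normalised by the query's seed count (asymmetric);
- complementarity index `X(A→B) = |P_A ∩ S_B| / |S_B|` — the fraction of
  B's requirements that A can synthesise without itself requiring them
  (cross-feeding potential), normalised by the receiver's seed count;
- metabolic distance = Jaccard distance `1 − |R_A ∩ R_B| / |R_A ∪ R_B|`
  on reaction presence/absence;
- taxonomic distance = cophenetic path length on the NCBI-style ranked
  lineage tree (unit branches), normalised to [0, 1].

The neighbourhood map plots metabolic distance (x) against taxonomic
distance (y) for every taxon relative to a query; the compatibility map
plots mean two-directional complementarity (x) against one minus mean
two-directional competition (y). In both, the query sits at the origin
and points are coloured by the sign of the merged association weight.

## Worked example

Generate a small synthetic community with planted ground truth and run
the full query workflow:

```bash
python - <<'EOF'
from micronet.fixtures import simulate_community
simulate_community("community", n_models=5, rng_seed=1)
EOF
micronet run --models community --edges community/edges.tsv \
    --lineages community/lineages.tsv --query t0x0x0 --out results_demo
head -3 results_demo/neighborhood.tsv results_demo/compatibility.tsv
```

```
==> results_demo/neighborhood.tsv <==
target	x	y	association	n_pairs
t0x0x0	0	0	none	1
t0x0x1	0.666667	0.142857	none	1

==> results_demo/compatibility.tsv <==
target	x	y	association	n_pairs
t0x0x0	0	0	none	1
t0x0x1	0.0555556	0.388889	none	1
```

Reading the neighbourhood row for `t0x0x1`: its reaction repertoire is
67% dissimilar to the query's (Jaccard distance 0.667) while the two
taxa are congeneric (taxonomic distance 2/14 ≈ 0.143). In the
compatibility map the same taxon shows little cross-feeding potential
(mean complementarity 0.056) and shares on average 61% of seed
metabolites with the query (y = 1 − 0.611 = 0.389), i.e. it is a
potential competitor, not a partner. Individual analysis steps are also available as subcommands
(`micronet parse | graph | seeds | compat | taxdist | map | simulate`)
and as plain library functions.

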
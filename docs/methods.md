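# Methods

## Model representation and reaction classification

A GEM is held as metabolite and reaction inventories plus free-text
properties (gram stain, oxygen preference, ...) passed through verbatim.
Metabolite identity is `(base id, compartment)`, compared verbatim after
lowercasing; no cross-database harmonisation (KEGG/BIGG/MetaNetX) is
attempted — reconciling namespaces across model collections is a curation
task upstream of this toolkit, and an optional user-supplied synonym table
can be applied before comparison. Stoichiometric coefficients are parsed
and stored but ignored by every algorithm: the analysis is purely
topological.

Reactions are classified totally and idempotently:

- **exchange** — exactly one distinct participating metabolite, and it is
  extracellular (boundary flow);
- **transport** — participants span at least two compartments;
- **internal** — everything else. A metabolite appearing on both sides of
  an internal reaction is removed from both sides with a logged warning:
  such self-loops carry no reachability information and violate
  substrate/product disjointness.

A compartment counts as extracellular when its id is in a configurable set
(defaults cover the common `e`/`e0`/`extracellular` conventions) or its
declared name contains "extracellular". The model-level flag
`has_exchange_or_transport` is always recomputed, never trusted from
input.

SBML Level 3 is the canonical external format (Level 2 files also parse);
MATLAB `.mat` models are out of scope — conversion is upstream tooling. A
tabular reaction-list dialect (`rxn_id`, `equation`, optional `subsystem`)
is provided for fixtures and quick experiments; in it, one-sided equations
are only legal for reactions whose id carries the `ex_` exchange prefix,
so a truncated equation is a parse error rather than a silent boundary
reaction.

## Metabolite graph and SCC decomposition

Each internal (and, by default, transport) reaction contributes the
complete substrate × product bipartite edge expansion; reversible
reactions contribute both directions. This is the standard reverse-ecology
construction for seed detection. Two documented switches alter the graph:
`--no-transport-edges` restricts to within-compartment conversions, and an
explicit currency-metabolite exclusion list (shipped as
`data/currency_metabolites.txt`) deletes hub cofactors and their incident
edges. Currency exclusion is **off** by default because it materially
changes SCC structure and therefore must be a visible, user-controlled
choice.

The SCC decomposition is Kosaraju's two-pass algorithm, implemented
iteratively (explicit stacks) so graphs with >10⁴ metabolites do not hit
the recursion limit. Determinism: DFS roots and neighbours are visited in
sorted order and components are re-indexed by their smallest member id, so
the partition and condensation of a given graph are unique. Tests check
the implementation against both a brute-force pairwise-reachability oracle
and networkx's independent SCC routine.

## Seed metabolites

Seed metabolites are the members of condensation *sources*: components
with no incoming edge and at least one outgoing edge. Isolated metabolites
(no edges at all) fail the outgoing-edge clause and are reported in
diagnostics instead of being silently classified either way.

Two restrictions can be applied, and the applied configuration is recorded
in every result so outputs are self-describing:

- `require_exchange` — models without any exchange or transport reaction
  cannot represent uptake, so their result is flagged `not_evaluable`
  (with empty seeds) rather than reported as a seed set;
- an SCC size filter — `min_size`/`max_size` with threshold `k` keeps only
  qualifying source components.

The library default applies neither (mode `none`): seeds are exactly the
source-component members, which keeps the producibility property clean —
every non-seed metabolite is reachable from some seed, and any exception
(only possible via isolated components or filtering) is surfaced in an
`unreachable_nonseeds` diagnostic. The preset `paper_mode_config()`
applies `require_exchange` together with `min_size, k=5`. The min-size
reading discards the common singleton sources; because the opposite
reading (discarding giant components) is also ecologically defensible,
both filters are supported and neither is hard-wired. Seed confidence
weights (1/|SCC|) are deliberately not computed: the indexes below count
seed metabolites individually.

## Pairwise indexes

With seed set `S`, producible set `P` (graph nodes minus `S`) and reaction
set `R`:

- competition(A,B) = |S_A ∩ S_B| / |S_A| — normalised by the **query's**
  seed count; the reverse normalisation lives on the (B,A) record, and
  both denominators are reported;
- complementarity(A→B) = |P_A ∩ S_B| / |S_B| — normalised by the
  **receiver's** seed count;
- metabolic distance = Jaccard on reaction ids (lowercased, verbatim);
  a Dice variant is available behind `--distance dice`.

A model with an empty or not-evaluable seed set propagates
`evaluable=false` instead of NaN-as-data: 0 is a meaningful index value
and must stay distinguishable from "could not be computed". Self-pairs
obey competition 1, complementarity 0, distance 0 by construction, and
the pairwise table enumerates ordered pairs of distinct models.

## Taxonomic distance

Lineages use the seven canonical NCBI ranks; the tree is their prefix
trie with unit branch lengths, and the distance between two taxa is the
edge count through their most recent common ancestor divided by 2 × 7
(2 × 8 when any strain-level taxon is present — strains attach below
species with one extra unit branch). Two species in one genus are 2/14
apart; taxa sharing only the superkingdom are 12/14 apart. The
normalisation constant is configurable via the tree's `n_levels`.

Missing ranks must not shrink distances: shared-prefix scanning stops at
the first rank where the two lineages disagree *or where exactly one of
them is annotated*, and path lengths always count canonical rank levels.
Consequently a gap in one lineage makes the pair look more distant, never
closer — the conservative direction for incomplete annotation. Rank-node
consistency across lineages is enforced by comparing ancestor chains at
the ranks both annotate, so partial annotations merge rather than clash.
The Newick export attaches taxon leaves with zero-length branches to
their terminal rank node, making cophenetic path lengths in the exported
tree equal the unnormalised distances (verified against dendropy in the
tests).

## Association tables and the map products

Edges are stored with the canonical (lexicographic) taxon pair order.
Duplicates are merged per (pair, study context): weights and adjusted
P-values are arithmetically averaged, the merge count is recorded, and a
sign conflict among duplicates sets a flag that renders the association
as `none` downstream — averaging opposite-sign reports into a confident
call would be misleading. Method labels of merged duplicates are kept as
a sorted set; the method filter matches set membership. Filtering is
conjunctive (context, method, max adjusted P, min |weight|), and edges
lacking a P-value pass the significance filter only with
`keep_missing_p`.

Both maps are computed per query taxon over all other taxa with models.
"Mean pair-wise" is resolved as the mean of the two directions per model
pair, then the mean over strain pairs when several models map to one
taxon (`n_pairs` records the count); the per-direction values remain
available through the pairwise table so asymmetric cases stay
recoverable. Association colour pools every context of the merged table
by default; a `--context` option narrows it. `rank_complementarity`
reports where a chosen partner falls in the query's complementarity
distribution as a percentile, with no threshold hard-coded.

## Synthetic data

The fixture generators construct their ground truth rather than
recomputing it, so recovery tests are genuine oracles:

- `simulate_gem` plants source chains (heads are seeds, reachable through
  an exchange reaction on the extracellular head) and cycles feeding
  downstream chains (all members are seeds; the default cycle length 5
  makes them survive the min-size-5 preset). Distracting reactions are
  added only forward along a topological ordering and never into a
  planted source, so neither new cycles nor new sources can arise.
- `simulate_pair` plants exact seed-overlap and cross-feed counts between
  two models; expected indexes follow from the planted counts by closed
  form (integer set arithmetic, tested for exact equality).
- `simulate_association_table` injects duplicates at a set rate and
  records the expected post-merge table by direct arithmetic.
- `simulate_lineages` emits balanced lineages with closed-form distances.
- `simulate_community` ties these together into an on-disk fixture set
  (SBML + TSV, exercising the real I/O paths) and plants cross-feeding
  through one shared metabolite that even-indexed models produce and
  odd-indexed models require, so compatibility maps have non-trivial
  structure.

What the generators do **not** emulate: realistic reaction/metabolite
vocabularies and network sizes (real GEMs have thousands of reactions and
heavily shared cofactors), flux constraints, namespace divergence between
model collections, and noisy or conflicting lineage annotations. Passing
the recovery tests therefore demonstrates algorithmic correctness of the
pipeline on known topologies, not robustness to the curation issues of
real model collections.

Test and acceptance problem sizes — 200 random digraphs of ≤30 nodes for
the SCC oracle, 50 planted models and 50 planted pairs, communities of
5–6 models — were chosen as the smallest sets that exercise every code
path and structural case; all generators scale to larger sizes by
parameter.

## Workflow and determinism

The `micronet run` workflow (parse → seeds → pairwise indexes → maps)
writes TSV/JSON only; data files contain no timestamps, so repeated runs
are byte-identical. The manifest records the tool version, the exact
configuration, SHA-256 checksums of all inputs and the produced
artifacts, and is the only file carrying a timestamp. Stage failures
raise stage-named errors; completed outputs are retained and any
half-written file is renamed with a `.partial` suffix.

## Known limitations

- Seed detection is topological; it ignores stoichiometry, biomass
  objectives and flux feasibility, so a "producible" compound may not be
  producible at steady state.
- Verbatim id comparison makes cross-collection index values meaningful
  only after external namespace harmonisation.
- The taxonomic distance is a rank-count convention, not an evolutionary
  divergence estimate; alternative normalisations can be substituted via
  the configurable constant.
- Merging associations across methods and studies treats heterogeneous
  statistics as commensurable weights; the per-study records remain
  available before merging.
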
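"""Synthetic GEMs, lineages and association tables with planted truth.

Every generator here *constructs* its ground truth rather than recomputing
it with the code under test, so fixture-based tests are genuine oracles:

* :func:`simulate_gem` composes source chains and cycles (whose heads /
  members are the planted seed metabolites) plus distracting forward
  reactions that never point into a planted source, so the seed pipeline
  must recover the planted set exactly.
* :func:`simulate_pair` plants exact seed overlaps and cross-feeding
  counts between two models and reports the expected indexes from the
  planted counts by closed form.
* :func:`simulate_association_table` injects duplicates at a known rate
  and records the exact expected post-merge table.
* :func:`simulate_lineages` emits balanced 7-rank lineages whose pairwise
  taxonomic distances have a closed form.

All generators are deterministic functions of ``rng_seed`` and write real
on-disk files in the external formats (SBML / TSV) so I/O code is
exercised, not bypassed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compatibility import PairwiseIndex
from .gem_io import GEModel, Metabolite, Reaction, classify_reactions, write_sbml
from .taxonomy import CANONICAL_RANKS, TaxonLineage, write_lineage_table


class FixtureParameterError(ValueError):
    pass


@dataclass
class PlantedModel:
    model: GEModel
    planted_seed_metabolites: frozenset[str]
    planted_scc_structure: dict = field(default_factory=dict)

    def write_sbml(self, path: str | Path) -> None:
        write_sbml(self.model, path)


def _add_chain(model: GEModel, mets: list[str], rxn_prefix: str) -> None:
    for m in mets:
        if m not in model.metabolites:
            comp = m.rsplit("_", 1)[1] if "_" in m else "c"
            model.add_metabolite(Metabolite(met_id=m, compartment=comp))
    for j, (u, v) in enumerate(zip(mets, mets[1:])):
        model.add_reaction(Reaction(rxn_id=f"{rxn_prefix}{j}", substrates={u: 1.0}, products={v: 1.0}))


def _add_exchange(model: GEModel, met: str, suffix: str) -> None:
    model.add_reaction(Reaction(rxn_id=f"ex_{suffix}", substrates={met: 1.0}, products={}))


def simulate_gem(
    n_source_chains: int,
    n_cycles: int,
    cycle_len: int = 5,
    chain_len: int = 3,
    rng_seed: int = 0,
    model_id: str | None = None,
    n_distractors: int | None = None,
) -> PlantedModel:
    """Build a GEM whose seed metabolites are known by construction.

    ``n_source_chains`` linear chains of ``chain_len`` metabolites are
    planted (their extracellular heads are seeds, reached by an exchange
    reaction), plus ``n_cycles`` cycles of ``cycle_len`` metabolites each
    feeding a downstream chain (all cycle members are seeds).  Distracting
    forward reactions are added between non-source metabolites, strictly
    following a topological ordering so no new cycle or source can arise.
    """
    if n_source_chains < 0 or n_cycles < 0:
        raise FixtureParameterError("counts must be >= 0")
    if n_source_chains == 0 and n_cycles == 0:
        raise FixtureParameterError("parameters yield an empty graph")
    if n_source_chains > 0 and chain_len < 2:
        raise FixtureParameterError("chain_len must be >= 2 (a length-1 chain has no outgoing edge)")
    if n_cycles > 0 and cycle_len < 2:
        raise FixtureParameterError("cycle_len must be >= 2")

    rng = np.random.default_rng(rng_seed)
    model = GEModel(model_id=model_id or f"sim_gem_{rng_seed}")
    seeds: set[str] = set()
    position: dict[str, int] = {}  # topological position; cycle members share one
    pos = 0

    for i in range(n_source_chains):
        head = f"h{i}_e"
        mets = [head] + [f"c{i}x{j}_c" for j in range(1, chain_len)]
        _add_chain(model, mets, rxn_prefix=f"rc{i}x")
        _add_exchange(model, head, head)
        seeds.add(head)
        for m in mets:
            position[m] = pos
            pos += 1

    for i in range(n_cycles):
        cyc = [f"y{i}x0_e"] + [f"y{i}x{j}_c" for j in range(1, cycle_len)]
        for m in cyc:
            comp = m.rsplit("_", 1)[1]
            model.add_metabolite(Metabolite(met_id=m, compartment=comp))
            position[m] = pos  # whole cycle collapses to one position
        for j in range(cycle_len):
            u, v = cyc[j], cyc[(j + 1) % cycle_len]
            model.add_reaction(Reaction(rxn_id=f"ry{i}x{j}", substrates={u: 1.0}, products={v: 1.0}))
        _add_exchange(model, cyc[0], cyc[0])
        seeds.update(cyc)
        pos += 1
        down = [f"d{i}x{j}_c" for j in range(max(1, chain_len - 1))]
        _add_chain(model, [cyc[0]] + down, rxn_prefix=f"rd{i}x")
        for m in down:
            position[m] = pos
            pos += 1

    nonseed = sorted(set(model.metabolites) - seeds)
    if n_distractors is None:
        n_distractors = len(model.metabolites) // 3
    added = 0
    attempts = 0
    while added < n_distractors and attempts < 50 * max(1, n_distractors) and nonseed:
        attempts += 1
        v = nonseed[rng.integers(len(nonseed))]
        candidates = [u for u in model.metabolites if position[u] < position[v]]
        if not candidates:
            continue
        u = sorted(candidates)[rng.integers(len(candidates))]
        rid = f"dx{added}"
        if rid in model.reactions:
            added += 1
            continue
        model.add_reaction(Reaction(rxn_id=rid, substrates={u: 1.0}, products={v: 1.0}))
        added += 1

    classify_reactions(model)
    return PlantedModel(
        model=model,
        planted_seed_metabolites=frozenset(seeds),
        planted_scc_structure={
            "n_source_chains": n_source_chains,
            "n_cycles": n_cycles,
            "cycle_len": cycle_len,
            "chain_len": chain_len,
            "n_distractors": added,
        },
    )


def simulate_pair(
    overlap_seeds: int,
    cross_feed: int,
    rng_seed: int = 0,
    n_seeds_a: int = 3,
    n_seeds_b: int = 3,
) -> tuple[PlantedModel, PlantedModel, PairwiseIndex]:
    """Two models with planted seed overlap and cross-feeding.

    Model A has ``n_seeds_a`` two-metabolite source chains; model B has
    ``n_seeds_b``.  Exactly ``overlap_seeds`` seed metabolites are shared
    (same extracellular ids in both models) and exactly ``cross_feed`` of
    A's non-seed (producible) metabolites appear in B's seed set.  The
    expected indexes follow from the planted counts by closed form:

    * competition(A,B) = overlap / n_seeds_a (and /n_seeds_b reversed)
    * complementarity(A->B) = cross_feed / n_seeds_b; B->A is 0
    """
    if overlap_seeds < 0 or cross_feed < 0:
        raise FixtureParameterError("counts must be >= 0")
    if overlap_seeds > min(n_seeds_a, n_seeds_b):
        raise FixtureParameterError("overlap_seeds exceeds a model's seed count")
    if cross_feed > n_seeds_a:
        raise FixtureParameterError("cross_feed exceeds model A's producible count")
    if overlap_seeds + cross_feed > n_seeds_b:
        raise FixtureParameterError("overlap_seeds + cross_feed exceeds n_seeds_b")

    a = GEModel(model_id=f"sim_pair_a_{rng_seed}")
    b = GEModel(model_id=f"sim_pair_b_{rng_seed}")

    seeds_a: list[str] = []
    tails_a: list[str] = []
    for i in range(n_seeds_a):
        head = f"s{i}_e" if i < overlap_seeds else f"a{i}_e"
        tail = f"pa{i}_c"
        _add_chain(a, [head, tail], rxn_prefix=f"ra{i}x")
        _add_exchange(a, head, head)
        seeds_a.append(head)
        tails_a.append(tail)

    seeds_b: list[str] = []
    for i in range(n_seeds_b):
        if i < overlap_seeds:
            head = f"s{i}_e"
        elif i < overlap_seeds + cross_feed:
            head = tails_a[i - overlap_seeds]  # one of A's producible mets
        else:
            head = f"b{i}_e"
        tail = f"pb{i}_c"
        _add_chain(b, [head, tail], rxn_prefix=f"rb{i}x")
        if head.endswith("_e"):
            _add_exchange(b, head, head)
        seeds_b.append(head)

    classify_reactions(a)
    classify_reactions(b)

    # expected metabolic distance from the constructed reaction-id sets
    ra, rb = set(a.reactions), set(b.reactions)
    expected = PairwiseIndex(
        model_a=a.model_id,
        model_b=b.model_id,
        competition=overlap_seeds / n_seeds_a,
        complementarity_ab=cross_feed / n_seeds_b,
        complementarity_ba=0.0,
        metabolic_distance=1.0 - len(ra & rb) / len(ra | rb),
        evaluable=True,
        n_seeds_a=n_seeds_a,
        n_seeds_b=n_seeds_b,
    )
    pa = PlantedModel(a, frozenset(seeds_a), {"n_seeds": n_seeds_a})
    pb = PlantedModel(b, frozenset(seeds_b), {"n_seeds": n_seeds_b})
    return pa, pb, expected


# ---------------------------------------------------------------------------
# association tables


@dataclass
class SimulatedAssociations:
    table: pd.DataFrame          # raw rows, duplicates included
    expected_merged: pd.DataFrame  # one row per (pair, context) with mean weight

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def simulate_association_table(
    taxa: list[str],
    p_edge: float = 0.3,
    sign_bias: float = 0.7,
    dup_rate: float = 0.2,
    rng_seed: int = 0,
    context: str = "human_gut",
) -> SimulatedAssociations:
    """Random co-occurrence edges with duplicates injected at ``dup_rate``.

    ``sign_bias`` is the probability of a positive correlation.  The
    expected post-merge table is computed here, by direct arithmetic on
    the generated rows, independently of ``merge_duplicates``.
    """
    if len(taxa) < 2:
        raise FixtureParameterError("need at least 2 taxa")
    rng = np.random.default_rng(rng_seed)
    methods = ("pearson", "spearman", "sparcc", "flashweave")
    rows = []
    expected = []
    for ta, tb in itertools.combinations(sorted(taxa), 2):
        if rng.random() >= p_edge:
            continue
        sign = 1.0 if rng.random() < sign_bias else -1.0
        w = float(np.round(sign * rng.uniform(0.1, 0.9), 4))
        method = methods[rng.integers(len(methods))]
        p = float(np.round(rng.uniform(0.0, 0.2), 4))
        group = [w]
        rows.append({"taxon_a": ta, "taxon_b": tb, "weight": w, "method": method,
                     "context": context, "empo_level": "empo3", "study_id": "study1",
                     "adjusted_p": p})
        if rng.random() < dup_rate:
            w2 = float(np.round(np.clip(w + rng.uniform(-0.05, 0.05), -1.0, 1.0), 4))
            rows.append({"taxon_a": ta, "taxon_b": tb, "weight": w2,
                         "method": methods[rng.integers(len(methods))],
                         "context": context, "empo_level": "empo3",
                         "study_id": "study2", "adjusted_p": p})
            group.append(w2)
        expected.append({"taxon_a": ta, "taxon_b": tb, "context": context,
                         "weight": sum(group) / len(group), "n_merged": len(group)})
    return SimulatedAssociations(
        table=pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "weight", "method",
                                          "context", "empo_level", "study_id", "adjusted_p"]),
        expected_merged=pd.DataFrame(expected, columns=["taxon_a", "taxon_b", "context",
                                                        "weight", "n_merged"]),
    )


# ---------------------------------------------------------------------------
# lineages


def simulate_lineages(
    n_phyla: int,
    n_genera_per_phylum: int,
    n_species_per_genus: int,
    rng_seed: int = 0,
) -> list[TaxonLineage]:
    """Balanced synthetic 7-rank lineages (one class/order/family chain per
    phylum), so pairwise taxonomic distances have a closed form:
    same genus 2/14, same phylum (different genus) 4/14, different phyla
    12/14."""
    if min(n_phyla, n_genera_per_phylum, n_species_per_genus) < 1:
        raise FixtureParameterError("all counts must be >= 1")
    _ = np.random.default_rng(rng_seed)  # deterministic by construction
    out = []
    for i in range(n_phyla):
        for j in range(n_genera_per_phylum):
            for k in range(n_species_per_genus):
                names = (
                    "bacteria_sim", f"phy{i}", f"cls{i}", f"ord{i}",
                    f"fam{i}", f"gen{i}x{j}", f"sp{i}x{j}x{k}",
                )
                out.append(TaxonLineage(
                    taxon_id=f"t{i}x{j}x{k}",
                    ranks=dict(zip(CANONICAL_RANKS, names)),
                ))
    return out


def expected_lineage_distance(a: str, b: str) -> float:
    """Closed-form distance between two simulate_lineages taxon_ids."""
    ia = a.lstrip("t").split("x")
    ib = b.lstrip("t").split("x")
    if ia == ib:
        return 0.0
    if ia[0] != ib[0]:
        return 12 / 14
    if ia[1] != ib[1]:
        return 4 / 14
    return 2 / 14


# ---------------------------------------------------------------------------
# whole-community convenience used by the CLI and the acceptance script


def simulate_community(
    out_dir: str | Path,
    n_models: int = 5,
    rng_seed: int = 0,
) -> dict:
    """Write a self-consistent fixture set: one SBML model per taxon of a
    balanced lineage table, plus an association edge table.  Returns the
    written paths and the planted seed sets."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lineages = simulate_lineages(
        n_phyla=2, n_genera_per_phylum=2,
        n_species_per_genus=max(1, (n_models + 3) // 4),
        rng_seed=rng_seed,
    )[:n_models]
    model_paths = []
    planted = {}
    for i, lin in enumerate(lineages):
        pm = simulate_gem(
            n_source_chains=2 + i % 2, n_cycles=i % 2, cycle_len=5,
            chain_len=3, rng_seed=rng_seed * 1000 + i, model_id=lin.taxon_id,
        )
        # plant cross-feeding through the shared metabolite xfm_c: even
        # models produce it (downstream of chain 0, hence producible),
        # odd models require it (a fresh source chain, hence a seed)
        if i % 2 == 0:
            _add_chain(pm.model, ["c0x1_c", "xfm_c"], rxn_prefix=f"rxf{i}x")
        else:
            _add_chain(pm.model, ["xfm_c", f"xf{i}_c"], rxn_prefix=f"rxf{i}x")
            pm.planted_seed_metabolites = pm.planted_seed_metabolites | {"xfm_c"}
        classify_reactions(pm.model)
        pm.model.taxon_id = lin.taxon_id
        path = out_dir / f"{lin.taxon_id}.xml"
        pm.write_sbml(path)
        model_paths.append(str(path))
        planted[lin.taxon_id] = sorted(pm.planted_seed_metabolites)
    lineage_path = out_dir / "lineages.tsv"
    write_lineage_table(lineages, lineage_path)
    assoc = simulate_association_table(
        [l.taxon_id for l in lineages], p_edge=0.5, rng_seed=rng_seed,
    )
    edge_path = out_dir / "edges.tsv"
    assoc.write(edge_path)
    return {
        "models": model_paths,
        "lineages": str(lineage_path),
        "edges": str(edge_path),
        "planted_seeds": planted,
        "taxa": [l.taxon_id for l in lineages],
    }
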
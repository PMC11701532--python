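"""Seed-metabolite detection from the SCC condensation.

Seed metabolites are the minimal set of compounds an organism must acquire
exogenously to be able to produce every other compound in its metabolic
network.  Topologically they are the members of *source* components of the
SCC condensation: components with no incoming edge but at least one
outgoing edge.

Two filters can restrict the candidate components:

* ``require_exchange`` — seed detection is only meaningful for models in
  which uptake is represented at all; when set, models with neither
  exchange nor transport reactions are flagged ``not_evaluable`` instead
  of returning seeds.
* an SCC size filter — ``min_size``/``max_size`` with threshold ``k``
  keeps only source components of qualifying size.

The library default applies neither filter (mathematically clean seeds).
``paper_mode_config()`` returns the stricter preset (require_exchange and
min_size k=5).  Either way the applied configuration is recorded on the
result so outputs are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .gem_io import GEModel
from .metabolic_graph import (
    DirectedGraph,
    SCCPartition,
    build_metabolite_graph,
    condensation_sources,
    kosaraju_scc,
)

FilterMode = Literal["none", "min_size", "max_size"]


class SeedConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SeedFilterConfig:
    scc_size_filter: FilterMode = "none"
    k: int = 1
    require_exchange: bool = False

    def __post_init__(self) -> None:
        if self.scc_size_filter not in ("none", "min_size", "max_size"):
            raise SeedConfigError(f"unknown filter mode {self.scc_size_filter!r}")
        if self.k < 1:
            raise SeedConfigError(f"size threshold k must be >= 1, got {self.k}")

    def as_dict(self) -> dict:
        return {
            "scc_size_filter": self.scc_size_filter,
            "k": self.k,
            "require_exchange": self.require_exchange,
        }


def paper_mode_config() -> SeedFilterConfig:
    """Strict preset: require exchange/transport reactions and keep only
    source SCCs containing at least five metabolites."""
    return SeedFilterConfig(scc_size_filter="min_size", k=5, require_exchange=True)


@dataclass
class SeedSet:
    model_id: str
    seed_components: list[frozenset[str]]
    seed_metabolites: frozenset[str]
    nonseed_metabolites: frozenset[str]
    filter_config: SeedFilterConfig
    not_evaluable: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def evaluable(self) -> bool:
        return not self.not_evaluable and len(self.seed_metabolites) > 0

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "filter_config": self.filter_config.as_dict(),
            "not_evaluable": self.not_evaluable,
            "seed_components": [sorted(c) for c in self.seed_components],
            "seed_metabolites": sorted(self.seed_metabolites),
            "nonseed_metabolites": sorted(self.nonseed_metabolites),
            "diagnostics": {k: sorted(v) if isinstance(v, (set, frozenset)) else v
                            for k, v in self.diagnostics.items()},
        }


def _reachable_from(graph: DirectedGraph, starts: frozenset[str]) -> set[str]:
    seen = set(starts)
    stack = list(starts)
    while stack:
        u = stack.pop()
        for v in graph.successors(u):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def find_seed_set(
    graph: DirectedGraph,
    partition: SCCPartition,
    config: SeedFilterConfig | None = None,
    has_exchange_or_transport: bool | None = None,
    model_id: str = "",
) -> SeedSet:
    """Select seed components among the condensation sources.

    ``has_exchange_or_transport`` must be supplied (e.g. from the model
    flag) when ``config.require_exchange`` is set.

    Diagnostics reported rather than hidden:

    * ``isolated_nodes`` — nodes with neither in- nor out-edges; never
      seeds under the "at least one outgoing edge" rule.
    * ``unreachable_nonseeds`` — non-seed nodes not reachable from any
      seed; nonempty whenever filtering (or isolated components) breaks
      full producibility.
    """
    config = config or SeedFilterConfig()
    all_nodes = frozenset(graph.nodes)

    if config.require_exchange:
        if has_exchange_or_transport is None:
            raise SeedConfigError(
                "require_exchange is set but has_exchange_or_transport was not provided"
            )
        if not has_exchange_or_transport:
            return SeedSet(
                model_id=model_id,
                seed_components=[],
                seed_metabolites=frozenset(),
                nonseed_metabolites=all_nodes,
                filter_config=config,
                not_evaluable=True,
                diagnostics={"reason": "model has no exchange or transport reactions"},
            )

    sources = condensation_sources(partition)
    components = []
    for i in sorted(sources):
        comp = partition.components[i]
        if config.scc_size_filter == "min_size" and len(comp) < config.k:
            continue
        if config.scc_size_filter == "max_size" and len(comp) > config.k:
            continue
        components.append(comp)

    seeds = frozenset().union(*components) if components else frozenset()
    nonseeds = all_nodes - seeds

    isolated = {
        n for n in all_nodes
        if not graph.successors(n) and not graph.predecessors(n)
    }
    unreachable = nonseeds - _reachable_from(graph, seeds) if seeds else set(nonseeds)

    return SeedSet(
        model_id=model_id,
        seed_components=components,
        seed_metabolites=seeds,
        nonseed_metabolites=nonseeds,
        filter_config=config,
        diagnostics={
            "isolated_nodes": isolated,
            "unreachable_nonseeds": unreachable,
        },
    )


def producible_set(seed_set: SeedSet) -> frozenset[str]:
    """All network compounds outside the seed set (the organism's
    producible metabolites)."""
    return seed_set.nonseed_metabolites


def seeds_for_model(
    model: GEModel,
    config: SeedFilterConfig | None = None,
    exclude: list[str] | None = None,
    include_transport_edges: bool = True,
) -> SeedSet:
    """Convenience pipeline: graph -> Kosaraju SCC -> seed selection."""
    graph = build_metabolite_graph(
        model, exclude=exclude, include_transport_edges=include_transport_edges
    )
    partition = kosaraju_scc(graph)
    return find_seed_set(
        graph,
        partition,
        config=config,
        has_exchange_or_transport=model.has_exchange_or_transport,
        model_id=model.model_id,
    )
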
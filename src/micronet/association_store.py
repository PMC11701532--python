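"""Curated co-occurrence tables and the two per-query map products.

Association edges are pairwise abundance correlations (Pearson, Spearman,
SparCC, FlashWeave, ...) curated from published studies, each tagged with a
study context, an EMPO biospecimen level and optionally an adjusted
P-value.  Duplicated records for the same taxon pair within a context are
averaged; sign conflicts among duplicates are flagged and rendered as
``none`` rather than silently resolved.

Two map products summarise a query taxon against every other taxon:

* Neighbourhood map — x = metabolic distance, y = taxonomic distance.
* Metabolism compatibility map — x = mean two-directional complementarity,
  y = 1 − mean two-directional competition.

In both maps the query itself sits at the origin, and each point is
coloured by the sign of the merged association weight (positive /
negative / none).  When several strain-level models map to one taxon the
indexes are averaged over strain pairs and ``n_pairs`` records the count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compatibility import (
    ModelProfile,
    competition_index,
    complementarity_index,
    metabolic_distance,
    profile_model,
)
from .gem_io import GEModel
from .seed_finder import SeedFilterConfig
from .taxonomy import TaxonLineage, TaxonomyTree, build_taxonomy_tree, taxonomic_distance

logger = logging.getLogger(__name__)

VALID_METHODS = ("pearson", "spearman", "sparcc", "flashweave", "other")
MANDATORY_COLUMNS = ("taxon_a", "taxon_b", "weight", "method", "context")
OPTIONAL_COLUMNS = ("empo_level", "study_id", "adjusted_p")


class AssociationSchemaError(ValueError):
    pass


@dataclass
class AssociationEdge:
    taxon_a: str
    taxon_b: str
    weight: float
    method: str
    context: str
    empo_level: str = ""
    study_id: str = ""
    adjusted_p: float | None = None
    n_merged: int = 1
    sign_conflict: bool = False

    def __post_init__(self) -> None:
        if self.taxon_a == self.taxon_b:
            raise AssociationSchemaError(f"self-loop on taxon {self.taxon_a!r}")
        # canonical lexicographic pair order; weight sign is symmetric
        if self.taxon_b < self.taxon_a:
            self.taxon_a, self.taxon_b = self.taxon_b, self.taxon_a
        if self.adjusted_p is not None and not (0.0 <= self.adjusted_p <= 1.0):
            raise AssociationSchemaError(
                f"adjusted_p={self.adjusted_p} outside [0, 1] for pair "
                f"({self.taxon_a}, {self.taxon_b})"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.taxon_a, self.taxon_b)


def load_edges(path: str | Path) -> list[AssociationEdge]:
    """Load and validate an association edge TSV.

    Self-loop rows are dropped with a row-numbered warning; an out-of-range
    adjusted_p or a missing mandatory column raises.  Methods outside the
    known vocabulary are coerced to ``other`` with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"taxon_a": str, "taxon_b": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise AssociationSchemaError(f"{path}: missing mandatory columns {missing}")
    edges: list[AssociationEdge] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        if row["taxon_a"] == row["taxon_b"]:
            logger.warning("%s row %d: self-loop on %r dropped", path, rowno, row["taxon_a"])
            continue
        method = str(row["method"]).lower()
        if method not in VALID_METHODS:
            logger.warning("%s row %d: unknown method %r recorded as 'other'", path, rowno, method)
            method = "other"
        adj = row.get("adjusted_p")
        adj = None if adj is None or (isinstance(adj, float) and np.isnan(adj)) else float(adj)
        try:
            edges.append(
                AssociationEdge(
                    taxon_a=str(row["taxon_a"]),
                    taxon_b=str(row["taxon_b"]),
                    weight=float(row["weight"]),
                    method=method,
                    context=str(row["context"]),
                    empo_level=str(row.get("empo_level", "") or ""),
                    study_id=str(row.get("study_id", "") or ""),
                    adjusted_p=adj,
                )
            )
        except AssociationSchemaError as exc:
            raise AssociationSchemaError(f"{path} row {rowno}: {exc}") from exc
    return edges


def write_edges(edges: Sequence[AssociationEdge], path: str | Path) -> None:
    rows = [
        {
            "taxon_a": e.taxon_a, "taxon_b": e.taxon_b, "weight": e.weight,
            "method": e.method, "context": e.context, "empo_level": e.empo_level,
            "study_id": e.study_id,
            "adjusted_p": "" if e.adjusted_p is None else e.adjusted_p,
            "n_merged": e.n_merged, "sign_conflict": e.sign_conflict,
        }
        for e in edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def merge_duplicates(edges: Iterable[AssociationEdge]) -> list[AssociationEdge]:
    """Average duplicated records per (canonical pair, context).

    The merged weight (and adjusted_p, where present) is the arithmetic
    mean; ``n_merged`` counts the inputs and ``sign_conflict`` is set when
    duplicates disagree in sign.  Idempotent and permutation-invariant
    (output sorted by pair then context).
    """
    groups: dict[tuple[str, str, str], list[AssociationEdge]] = {}
    for e in edges:
        groups.setdefault((e.taxon_a, e.taxon_b, e.context), []).append(e)
    merged = []
    for (ta, tb, ctx), group in sorted(groups.items()):
        weights = [e.weight for e in group]
        signs = {np.sign(w) for w in weights if w != 0}
        pvals = [e.adjusted_p for e in group if e.adjusted_p is not None]
        methods = sorted({m for e in group for m in e.method.split(";")})
        merged.append(
            AssociationEdge(
                taxon_a=ta,
                taxon_b=tb,
                weight=float(np.mean(weights)),
                method=";".join(methods),
                context=ctx,
                empo_level=group[0].empo_level,
                study_id=";".join(sorted({e.study_id for e in group if e.study_id})),
                adjusted_p=float(np.mean(pvals)) if pvals else None,
                n_merged=sum(e.n_merged for e in group),
                sign_conflict=len(signs) > 1 or any(e.sign_conflict for e in group),
            )
        )
    return merged


def filter_edges(
    edges: Iterable[AssociationEdge],
    context: str | None = None,
    method: str | None = None,
    max_adjusted_p: float | None = None,
    min_abs_weight: float | None = None,
    keep_missing_p: bool = False,
) -> list[AssociationEdge]:
    """Conjunctive filtering.  Edges lacking adjusted_p pass the p filter
    only when ``keep_missing_p`` is set.  Method filtering matches any
    member of a merged edge's method set."""
    if method is not None and method.lower() not in VALID_METHODS:
        raise AssociationSchemaError(
            f"unknown method {method!r}; valid: {', '.join(VALID_METHODS)}"
        )
    out = []
    for e in edges:
        if context is not None and e.context != context:
            continue
        if method is not None and method.lower() not in e.method.split(";"):
            continue
        if max_adjusted_p is not None:
            if e.adjusted_p is None:
                if not keep_missing_p:
                    continue
            elif e.adjusted_p > max_adjusted_p:
                continue
        if min_abs_weight is not None and abs(e.weight) < min_abs_weight:
            continue
        out.append(e)
    return out


def association_sign(edges: Sequence[AssociationEdge], a: str, b: str) -> str:
    """Pooled association call for a pair over all contexts of merged
    edges: positive / negative / none (absent or sign-conflicted)."""
    pair = (min(a, b), max(a, b))
    hits = [e for e in edges if e.pair == pair]
    if not hits:
        return "none"
    if any(e.sign_conflict for e in hits):
        return "none"
    mean_w = float(np.mean([e.weight for e in hits]))
    if mean_w > 0:
        return "positive"
    if mean_w < 0:
        return "negative"
    return "none"


# ---------------------------------------------------------------------------
# map products


@dataclass
class MapPoint:
    target: str
    x: float
    y: float
    association: str  # positive | negative | none
    n_pairs: int = 1


def _group_models_by_taxon(models: Sequence[GEModel]) -> dict[str, list[GEModel]]:
    groups: dict[str, list[GEModel]] = {}
    for m in models:
        groups.setdefault(m.taxon_id or m.model_id, []).append(m)
    return groups


def neighborhood_map(
    query: str,
    models: Sequence[GEModel],
    lineages: Sequence[TaxonLineage],
    edges: Sequence[AssociationEdge],
    distance: str = "jaccard",
) -> list[MapPoint]:
    """Per-taxon scatter of metabolic distance (x) vs taxonomic distance
    (y) relative to a query taxon; the query itself is the origin point.

    ``query`` and targets are taxon_ids; models are grouped by their
    taxon_id, and the metabolic distance of a multi-strain taxon is the
    mean over strain-model pairs.
    """
    groups = _group_models_by_taxon(models)
    if query not in groups:
        raise KeyError(f"query taxon {query!r} has no model")
    tree = build_taxonomy_tree(list(lineages))
    merged = merge_duplicates(edges)

    points = [MapPoint(target=query, x=0.0, y=0.0, association="none",
                       n_pairs=len(groups[query]))]
    for taxon in sorted(groups):
        if taxon == query:
            continue
        dists = [
            metabolic_distance(a.reaction_ids(), b.reaction_ids(), method=distance)
            for a in groups[query]
            for b in groups[taxon]
        ]
        points.append(
            MapPoint(
                target=taxon,
                x=float(np.mean(dists)),
                y=taxonomic_distance(tree, query, taxon),
                association=association_sign(merged, query, taxon),
                n_pairs=len(dists),
            )
        )
    return points


def compatibility_map(
    query: str,
    models: Sequence[GEModel],
    edges: Sequence[AssociationEdge],
    config: SeedFilterConfig | None = None,
) -> list[MapPoint]:
    """Per-taxon scatter of mean pairwise complementarity (x) vs
    1 − mean pairwise competition (y) relative to a query taxon.

    Per target the two directions are averaged; for multi-strain taxa the
    mean additionally runs over strain pairs (``n_pairs`` records the
    count).  Targets whose seeds are not evaluable are omitted with a
    logged diagnostic; a non-evaluable query raises.
    """
    groups = _group_models_by_taxon(models)
    if query not in groups:
        raise KeyError(f"query taxon {query!r} has no model")
    profiles: dict[str, list[ModelProfile]] = {
        taxon: [profile_model(m, config=config) for m in ms]
        for taxon, ms in groups.items()
    }
    q_profiles = [p for p in profiles[query] if p.evaluable]
    if not q_profiles:
        raise ValueError(f"query taxon {query!r}: seed set not evaluable")
    merged = merge_duplicates(edges)

    points = [MapPoint(target=query, x=0.0, y=0.0, association="none",
                       n_pairs=len(q_profiles))]
    for taxon in sorted(profiles):
        if taxon == query:
            continue
        t_profiles = [p for p in profiles[taxon] if p.evaluable]
        if not t_profiles:
            logger.warning("compatibility map: target %r omitted (seeds not evaluable)", taxon)
            continue
        comp_vals, compl_vals = [], []
        for q, t in itertools.product(q_profiles, t_profiles):
            comp_vals.append(np.mean([
                competition_index(q.seeds, t.seeds),
                competition_index(t.seeds, q.seeds),
            ]))
            compl_vals.append(np.mean([
                complementarity_index(q.producible, q.seeds, t.seeds),
                complementarity_index(t.producible, t.seeds, q.seeds),
            ]))
        points.append(
            MapPoint(
                target=taxon,
                x=float(np.mean(compl_vals)),
                y=1.0 - float(np.mean(comp_vals)),
                association=association_sign(merged, query, taxon),
                n_pairs=len(comp_vals),
            )
        )
    return points


def map_frame(points: Sequence[MapPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"target": p.target, "x": p.x, "y": p.y,
          "association": p.association, "n_pairs": p.n_pairs} for p in points]
    )


def write_map_tsv(points: Sequence[MapPoint], path: str | Path) -> None:
    map_frame(points).to_csv(path, sep="\t", index=False, float_format="%.6g")


def rank_complementarity(points: Sequence[MapPoint], partner: str) -> float:
    """Percentile (0-100) of a partner's complementarity (map x value)
    within the distribution over all non-query targets; 100 means the
    partner has the highest complementarity with the query."""
    values = [p.x for p in points[1:]]  # points[0] is the query origin
    match = [p for p in points[1:] if p.target == partner]
    if not match:
        raise KeyError(f"partner {partner!r} not on the map")
    v = match[0].x
    return 100.0 * sum(1 for x in values if x <= v) / len(values)


def plot_map(points: Sequence[MapPoint], path: str | Path, kind: str = "neighborhood") -> None:
    """Optional scatter rendering (matplotlib imported lazily so headless
    pipelines never require it)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"positive": "tab:blue", "negative": "tab:orange", "none": "0.7"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for p in points[1:]:
        ax.scatter(p.x, p.y, c=colors[p.association], s=18,
                   label=p.association, zorder=2)
    ax.scatter([points[0].x], [points[0].y], c="red", s=40, zorder=3, label="query")
    if kind == "neighborhood":
        ax.set_xlabel("metabolic distance")
        ax.set_ylabel("taxonomic distance")
    else:
        ax.set_xlabel("complementarity")
        ax.set_ylabel("1 - competition")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def association_graphml(edges: Sequence[AssociationEdge], path: str | Path) -> None:
    """Export a filtered/merged association network as GraphML."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_edge(
            e.taxon_a, e.taxon_b, weight=e.weight, method=e.method,
            context=e.context, n_merged=e.n_merged, sign_conflict=e.sign_conflict,
        )
    nx.write_graphml(g, str(path))
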
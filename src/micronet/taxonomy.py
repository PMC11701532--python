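"""Taxonomy trees from ranked lineages and normalised taxonomic distances.

Lineages follow the NCBI-style seven canonical ranks (superkingdom, phylum,
class, order, family, genus, species), optionally extended with a strain
below species.  The tree is the prefix trie of the lineages with unit
branch lengths; the distance between two taxa is the cophenetic path
length (edge count through their most recent common ancestor) divided by
twice the number of rank levels, so it lies in [0, 1].

Missing ranks do not shrink distances: a lineage with a gap skips the node
in the tree, but path lengths always count the canonical number of rank
levels between the deepest shared rank and each leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CANONICAL_RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")
STRAIN_RANK = "strain"


class LineageError(ValueError):
    pass


@dataclass
class TaxonLineage:
    taxon_id: str
    ranks: dict[str, str]  # rank name -> taxon name; canonical order, gaps allowed
    strain: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.ranks) - set(CANONICAL_RANKS)
        if unknown:
            raise LineageError(f"{self.taxon_id}: unknown ranks {sorted(unknown)}")
        # normalise to canonical order, dropping empty names
        self.ranks = {
            r: self.ranks[r] for r in CANONICAL_RANKS if self.ranks.get(r)
        }

    def name_at(self, rank: str) -> str | None:
        return self.ranks.get(rank)


@dataclass
class TaxonomyTree:
    """Prefix trie over lineages; leaves are taxon_ids, internal nodes are
    shared lineage prefixes, all branches unit length."""

    lineages: dict[str, TaxonLineage] = field(default_factory=dict)
    has_strain: bool = False

    @property
    def n_levels(self) -> int:
        """Rank levels below the root: 7 canonical, 8 when any strain is
        present.  The normalisation constant is 2 * n_levels."""
        return len(CANONICAL_RANKS) + (1 if self.has_strain else 0)

    @property
    def leaves(self) -> list[str]:
        return sorted(self.lineages)


def build_taxonomy_tree(lineages: list[TaxonLineage]) -> TaxonomyTree:
    """Assemble the trie, checking that no named rank node claims two
    different parents (e.g. one genus under two families)."""
    if not lineages:
        raise LineageError("need at least one lineage")
    # known ancestor chain (rank -> name) per named rank node; two lineages
    # clash only if they disagree at a rank both annotate, so a gap in one
    # lineage is tolerated
    ancestors: dict[tuple[str, str], dict[str, str]] = {}
    tree = TaxonomyTree()
    for lin in lineages:
        if lin.taxon_id in tree.lineages:
            raise LineageError(f"duplicate taxon_id {lin.taxon_id!r}")
        chain: dict[str, str] = {}
        for rank in CANONICAL_RANKS:
            name = lin.name_at(rank)
            if name is None:
                continue
            key = (rank, name)
            if key in ancestors:
                known = ancestors[key]
                for r in known.keys() & chain.keys():
                    if known[r] != chain[r]:
                        raise LineageError(
                            f"rank node {rank}:{name} claimed under both "
                            f"{r}:{known[r]} and {r}:{chain[r]}"
                        )
                known.update(chain)
            else:
                ancestors[key] = dict(chain)
            chain[rank] = name
        tree.lineages[lin.taxon_id] = lin
        if lin.strain:
            tree.has_strain = True
    return tree


def _shared_depth(a: TaxonLineage, b: TaxonLineage) -> int:
    """Deepest canonical rank index (0-based) at which the two lineages are
    known to coincide; -1 when nothing is shared.

    Scanning stops at the first rank where the names differ, or where
    exactly one lineage is annotated (deeper sharing cannot be confirmed);
    ranks missing in both are skipped.
    """
    depth = -1
    for i, rank in enumerate(CANONICAL_RANKS):
        na, nb = a.name_at(rank), b.name_at(rank)
        if na is None and nb is None:
            continue
        if na is None or nb is None or na != nb:
            break
        depth = i
    return depth


def taxonomic_distance(tree: TaxonomyTree, a: str, b: str) -> float:
    """Normalised cophenetic distance between two leaves, in [0, 1]."""
    for t in (a, b):
        if t not in tree.lineages:
            raise KeyError(f"unknown taxon_id {t!r}")
    if a == b:
        return 0.0
    la, lb = tree.lineages[a], tree.lineages[b]
    species_level = len(CANONICAL_RANKS) - 1  # leaf depth index for species
    depth_a = species_level + (1 if la.strain else 0)
    depth_b = species_level + (1 if lb.strain else 0)
    shared = _shared_depth(la, lb)
    if shared == species_level and (la.strain or lb.strain) and la.strain == lb.strain:
        shared += 1  # identical strains below a shared species
    edges = (depth_a - shared) + (depth_b - shared)
    return edges / (2 * tree.n_levels)


def distance_matrix(tree: TaxonomyTree) -> pd.DataFrame:
    taxa = tree.leaves
    mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            d = taxonomic_distance(tree, a, b)
            mat.loc[a, b] = d
            mat.loc[b, a] = d
    return mat


# ---------------------------------------------------------------------------
# I/O


def read_lineage_table(path: str | Path) -> list[TaxonLineage]:
    """Read a lineage TSV with columns taxon_id, superkingdom..species
    (and optionally strain); empty cells are recorded as gaps."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "taxon_id" not in df.columns:
        raise LineageError(f"{path}: missing mandatory column 'taxon_id'")
    missing = [r for r in CANONICAL_RANKS if r not in df.columns]
    if missing:
        raise LineageError(f"{path}: missing rank columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            TaxonLineage(
                taxon_id=row["taxon_id"],
                ranks={r: row[r] for r in CANONICAL_RANKS if row[r]},
                strain=row["strain"] if "strain" in df.columns and row.get("strain") else None,
            )
        )
    return out


def write_lineage_table(lineages: list[TaxonLineage], path: str | Path) -> None:
    has_strain = any(l.strain for l in lineages)
    cols = ["taxon_id", *CANONICAL_RANKS] + (["strain"] if has_strain else [])
    rows = []
    for l in lineages:
        row = {"taxon_id": l.taxon_id, **{r: l.ranks.get(r, "") for r in CANONICAL_RANKS}}
        if has_strain:
            row["strain"] = l.strain or ""
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def to_newick(tree: TaxonomyTree) -> str:
    """Newick serialisation of the trie with unit branch lengths; taxon
    leaves attach to their terminal rank node with a zero-length branch so
    that cophenetic leaf-to-leaf path lengths in the written tree equal
    the (unnormalised) distances computed by :func:`taxonomic_distance`."""

    # nested dict keyed by (rank, name); leaves stored under a sentinel
    root: dict = {}
    for tid in tree.leaves:
        lin = tree.lineages[tid]
        node = root
        for rank in CANONICAL_RANKS:
            name = lin.name_at(rank)
            if name is None:
                continue
            node = node.setdefault((rank, name), {})
        if lin.strain:
            node = node.setdefault((STRAIN_RANK, lin.strain), {})
        node.setdefault("__leaves__", []).append(tid)

    def render(node: dict, label: str) -> str:
        children = []
        for key in sorted(k for k in node if k != "__leaves__"):
            children.append(render(node[key], key[1]))
        children.extend(f"{tid}:0" for tid in sorted(node.get("__leaves__", [])))
        if not children:
            return f"{label}:1"
        inner = ",".join(children)
        return f"({inner}){label}:1" if label else f"({inner});"

    return render(root, "")


def write_newick(tree: TaxonomyTree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
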
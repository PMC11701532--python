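"""Pairwise competition / complementarity indexes and metabolic distance.

Given seed sets S_A, S_B and producible sets P_A (network compounds outside
the organism's own seeds):

* competition(A, B) = |S_A ∩ S_B| / |S_A| — nutritional-niche overlap,
  normalised by the *query's* seed count, hence generally asymmetric.
* complementarity(A -> B) = |P_A ∩ S_B| / |S_B| — the fraction of B's seed
  requirements that A can produce without itself requiring them;
  cross-feeding potential, normalised by the *receiver's* seed count.
* metabolic distance = Jaccard distance 1 − |R_A ∩ R_B| / |R_A ∪ R_B| on
  reaction-id presence/absence (a Dice variant is available).

Models with empty (or not-evaluable) seed sets propagate
``evaluable=False`` rather than NaN: zero is a meaningful index value and
must not be conflated with "could not be computed".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .gem_io import GEModel
from .seed_finder import SeedFilterConfig, SeedSet, producible_set, seeds_for_model

NOT_EVALUABLE = float("nan")


class PairwiseError(ValueError):
    pass


@dataclass
class PairwiseIndex:
    """Ordered-pair record; ``competition`` is normalised by model_a's
    seed count (the b-normalised value lives on the (b, a) record)."""

    model_a: str
    model_b: str
    competition: float
    complementarity_ab: float
    complementarity_ba: float
    metabolic_distance: float
    evaluable: bool
    n_seeds_a: int = 0
    n_seeds_b: int = 0


def competition_index(seeds_a: Iterable[str], seeds_b: Iterable[str]) -> float:
    """|S_A ∩ S_B| / |S_A|; NaN (not evaluable) when S_A is empty."""
    sa, sb = set(seeds_a), set(seeds_b)
    if not sa:
        return NOT_EVALUABLE
    return len(sa & sb) / len(sa)


def complementarity_index(
    producible_a: Iterable[str],
    seeds_a: Iterable[str],
    seeds_b: Iterable[str],
) -> float:
    """|P_A ∩ S_B| / |S_B|; NaN when S_B is empty.

    ``producible_a`` is expected to exclude A's own seeds; any overlap is
    removed defensively so the definition always holds.
    """
    pa = set(producible_a) - set(seeds_a)
    sb = set(seeds_b)
    if not sb:
        return NOT_EVALUABLE
    return len(pa & sb) / len(sb)


def metabolic_distance(
    reactions_a: Iterable[str],
    reactions_b: Iterable[str],
    method: str = "jaccard",
) -> float:
    """Presence/absence distance on reaction-id sets (ids compared after
    lowercasing); NaN when both sets are empty."""
    ra = {r.lower() for r in reactions_a}
    rb = {r.lower() for r in reactions_b}
    if not ra and not rb:
        return NOT_EVALUABLE
    inter = len(ra & rb)
    if method == "jaccard":
        return 1.0 - inter / len(ra | rb)
    if method == "dice":
        return 1.0 - 2.0 * inter / (len(ra) + len(rb))
    raise ValueError(f"unknown distance method {method!r}; use 'jaccard' or 'dice'")


@dataclass
class ModelProfile:
    """Cached per-model pipeline products used by all pairwise indexes."""

    model_id: str
    taxon_id: str | None
    seed_set: SeedSet
    reaction_ids: frozenset[str]

    @property
    def seeds(self) -> frozenset[str]:
        return self.seed_set.seed_metabolites

    @property
    def producible(self) -> frozenset[str]:
        return producible_set(self.seed_set)

    @property
    def evaluable(self) -> bool:
        return self.seed_set.evaluable


def profile_model(
    model: GEModel,
    config: SeedFilterConfig | None = None,
    exclude: list[str] | None = None,
    include_transport_edges: bool = True,
) -> ModelProfile:
    seed_set = seeds_for_model(
        model, config=config, exclude=exclude, include_transport_edges=include_transport_edges
    )
    return ModelProfile(
        model_id=model.model_id,
        taxon_id=model.taxon_id,
        seed_set=seed_set,
        reaction_ids=frozenset(r.lower() for r in model.reactions),
    )


def pair_index(a: ModelProfile, b: ModelProfile, distance: str = "jaccard") -> PairwiseIndex:
    evaluable = a.evaluable and b.evaluable
    if evaluable:
        comp = competition_index(a.seeds, b.seeds)
        c_ab = complementarity_index(a.producible, a.seeds, b.seeds)
        c_ba = complementarity_index(b.producible, b.seeds, a.seeds)
    else:
        comp = c_ab = c_ba = NOT_EVALUABLE
    return PairwiseIndex(
        model_a=a.model_id,
        model_b=b.model_id,
        competition=comp,
        complementarity_ab=c_ab,
        complementarity_ba=c_ba,
        metabolic_distance=metabolic_distance(a.reaction_ids, b.reaction_ids, method=distance),
        evaluable=evaluable,
        n_seeds_a=len(a.seeds),
        n_seeds_b=len(b.seeds),
    )


def pairwise_table(
    models: Sequence[GEModel],
    config: SeedFilterConfig | None = None,
    distance: str = "jaccard",
    exclude: list[str] | None = None,
    include_transport_edges: bool = True,
) -> list[PairwiseIndex]:
    """Run the full pipeline (graph -> SCC -> seeds -> indexes) for every
    ordered pair of distinct models.  Non-evaluable pairs are flagged,
    never dropped."""
    if len(models) < 2:
        raise PairwiseError("pairwise_table needs at least 2 models")
    ids = [m.model_id for m in models]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise PairwiseError(f"duplicate model ids: {sorted(dupes)}")
    profiles = [
        profile_model(m, config=config, exclude=exclude,
                      include_transport_edges=include_transport_edges)
        for m in models
    ]
    out = []
    for a in profiles:
        for b in profiles:
            if a.model_id == b.model_id:
                continue
            out.append(pair_index(a, b, distance=distance))
    return out


def pairwise_frame(records: Sequence[PairwiseIndex]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_a": r.model_a,
                "model_b": r.model_b,
                "competition": r.competition,
                "complementarity_ab": r.complementarity_ab,
                "complementarity_ba": r.complementarity_ba,
                "metabolic_distance": r.metabolic_distance,
                "evaluable": r.evaluable,
                "n_seeds_a": r.n_seeds_a,
                "n_seeds_b": r.n_seeds_b,
            }
            for r in records
        ]
    )


def write_pairwise_tsv(records: Sequence[PairwiseIndex], path: str | Path) -> None:
    pairwise_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")


def index_matrix(records: Sequence[PairwiseIndex], field: str) -> pd.DataFrame:
    """Square matrix of one index over all models; the diagonal carries the
    self-pair identity (competition 1, complementarity 0, distance 0)."""
    ids = sorted({r.model_a for r in records} | {r.model_b for r in records})
    diag = {"competition": 1.0, "complementarity_ab": 0.0,
            "complementarity_ba": 0.0, "metabolic_distance": 0.0}
    if field not in diag:
        raise ValueError(f"unknown index field {field!r}")
    mat = pd.DataFrame(math.nan, index=ids, columns=ids)
    for i in ids:
        mat.loc[i, i] = diag[field]
    for r in records:
        mat.loc[r.model_a, r.model_b] = getattr(r, field)
    return mat
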
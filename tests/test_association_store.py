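"""Association-table loading, merging, filtering and the two map products."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micronet.association_store import (
    AssociationEdge,
    AssociationSchemaError,
    association_sign,
    compatibility_map,
    filter_edges,
    load_edges,
    map_frame,
    merge_duplicates,
    neighborhood_map,
    rank_complementarity,
    write_edges,
)
from micronet.fixtures import simulate_association_table
from micronet.gem_io import read_model
from micronet.taxonomy import read_lineage_table


def edge(a="t1", b="t2", w=0.5, method="sparcc", context="gut", p=None, study="s1"):
    return AssociationEdge(taxon_a=a, taxon_b=b, weight=w, method=method,
                           context=context, adjusted_p=p, study_id=study)


class TestLoadEdges:
    def _write(self, tmp_path, rows):
        path = tmp_path / "edges.tsv"
        header = "taxon_a\ttaxon_b\tweight\tmethod\tcontext\tempo_level\tstudy_id\tadjusted_p"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_fixture_table_loads_all_rows(self, tmp_path):
        sim = simulate_association_table([f"t{i}" for i in range(10)],
                                         p_edge=0.8, dup_rate=0.0, rng_seed=4)
        path = tmp_path / "e.tsv"
        sim.write(path)
        assert len(load_edges(path)) == len(sim.table)

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        path = self._write(tmp_path, ["t1\tt1\t0.5\tsparcc\tgut\te\ts\t0.01",
                                      "t1\tt2\t0.5\tsparcc\tgut\te\ts\t0.01"])
        with caplog.at_level("WARNING"):
            edges = load_edges(path)
        assert len(edges) == 1
        assert "self-loop" in caplog.text

    def test_out_of_range_adjusted_p_rejected(self, tmp_path):
        path = self._write(tmp_path, ["t1\tt2\t0.5\tsparcc\tgut\te\ts\t1.5"])
        with pytest.raises(AssociationSchemaError, match="adjusted_p"):
            load_edges(path)

    def test_missing_mandatory_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon_a\ttaxon_b\tweight\nt1\tt2\t0.5\n")
        with pytest.raises(AssociationSchemaError, match="method"):
            load_edges(path)

    def test_pair_stored_in_canonical_order_sign_preserved(self, tmp_path):
        path = self._write(tmp_path, ["zeb\tant\t-0.4\tpearson\tgut\te\ts\t0.01"])
        (e,) = load_edges(path)
        assert e.pair == ("ant", "zeb")
        assert e.weight == -0.4

    def test_round_trip_through_write_edges(self, tmp_path):
        edges = [edge(w=0.3, p=0.02), edge(a="t3", b="t4", w=-0.7)]
        path = tmp_path / "rt.tsv"
        write_edges(edges, path)
        again = load_edges(path)
        assert [(e.pair, e.weight, e.method) for e in again] == [
            (e.pair, e.weight, e.method) for e in edges]


class TestMergeDuplicates:
    def test_mean_of_duplicates(self):
        merged = merge_duplicates([edge(w=0.4), edge(w=0.6, study="s2")])
        assert len(merged) == 1
        assert merged[0].weight == pytest.approx(0.5)
        assert merged[0].n_merged == 2
        assert not merged[0].sign_conflict

    def test_sign_cancellation_flagged(self):
        merged = merge_duplicates([edge(w=0.3), edge(w=-0.3)])
        assert merged[0].weight == pytest.approx(0.0)
        assert merged[0].sign_conflict

    def test_no_duplicates_is_identity(self):
        edges = [edge(), edge(a="t3", b="t4")]
        merged = merge_duplicates(edges)
        assert [(e.pair, e.weight, e.n_merged) for e in merged] == [
            (e.pair, e.weight, 1) for e in edges]

    def test_distinct_contexts_not_merged(self):
        merged = merge_duplicates([edge(context="gut"), edge(context="soil")])
        assert len(merged) == 2

    def test_idempotent(self):
        edges = [edge(w=0.4), edge(w=0.6), edge(a="t3", b="t4", w=-0.2)]
        once = merge_duplicates(edges)
        twice = merge_duplicates(once)
        assert [(e.pair, e.context, e.weight, e.n_merged) for e in once] == [
            (e.pair, e.context, e.weight, e.n_merged) for e in twice]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.permutations(list(range(6))))
    def test_permutation_invariant(self, order):
        edges = [edge(w=0.1), edge(w=0.5), edge(a="t3", b="t4", w=-0.2),
                 edge(a="t3", b="t4", w=0.4, context="soil"),
                 edge(a="t1", b="t5", w=0.9), edge(w=0.3)]
        base = merge_duplicates(edges)
        permuted = merge_duplicates([edges[i] for i in order])
        assert [(e.pair, e.context, e.weight) for e in base] == [
            (e.pair, e.context, e.weight) for e in permuted]

    def test_generator_expected_table_reproduced(self):
        sim = simulate_association_table([f"t{i}" for i in range(12)],
                                         p_edge=0.6, dup_rate=0.5, rng_seed=9)
        loaded = [
            AssociationEdge(taxon_a=r.taxon_a, taxon_b=r.taxon_b, weight=r.weight,
                            method=r.method, context=r.context, adjusted_p=r.adjusted_p)
            for r in sim.table.itertuples()
        ]
        merged = {(e.taxon_a, e.taxon_b): (e.weight, e.n_merged)
                  for e in merge_duplicates(loaded)}
        for row in sim.expected_merged.itertuples():
            w, n = merged[(row.taxon_a, row.taxon_b)]
            assert w == pytest.approx(row.weight)
            assert n == row.n_merged


class TestFilterEdges:
    edges = [
        edge(w=0.5, method="sparcc", p=0.01),
        edge(a="t3", b="t4", w=0.2, method="sparcc", p=0.2),
        edge(a="t5", b="t6", w=-0.8, method="sparcc"),
        edge(a="t7", b="t8", w=0.4, method="spearman", p=0.03),
        edge(a="t9", b="ta", w=0.1, method="spearman", p=0.04, context="soil"),
    ]

    def test_method_filter_counts(self):
        assert len(filter_edges(self.edges, method="sparcc")) == 3
        assert len(filter_edges(self.edges, method="spearman")) == 2

    def test_default_significance_cutoff(self):
        kept = filter_edges(self.edges, max_adjusted_p=0.05)
        assert {e.pair for e in kept} == {("t1", "t2"), ("t7", "t8"), ("t9", "ta")}

    def test_missing_p_needs_keep_flag(self):
        with_flag = filter_edges(self.edges, max_adjusted_p=0.05, keep_missing_p=True)
        assert ("t5", "t6") in {e.pair for e in with_flag}

    def test_empty_criteria_is_identity(self):
        assert filter_edges(self.edges) == self.edges

    def test_unknown_method_errors_listing_valid(self):
        with pytest.raises(AssociationSchemaError, match="pearson"):
            filter_edges(self.edges, method="secom")

    def test_output_subset_and_commutative_composition(self):
        a = filter_edges(filter_edges(self.edges, method="sparcc"), max_adjusted_p=0.05)
        b = filter_edges(filter_edges(self.edges, max_adjusted_p=0.05), method="sparcc")
        assert a == b
        assert set(e.pair for e in a) <= set(e.pair for e in self.edges)

    def test_min_abs_weight(self):
        kept = filter_edges(self.edges, min_abs_weight=0.45)
        assert {e.pair for e in kept} == {("t1", "t2"), ("t5", "t6")}


class TestAssociationSign:
    def test_positive_negative_none(self):
        merged = merge_duplicates([edge(w=0.4), edge(a="t3", b="t4", w=-0.2)])
        assert association_sign(merged, "t1", "t2") == "positive"
        assert association_sign(merged, "t4", "t3") == "negative"
        assert association_sign(merged, "t1", "t9") == "none"

    def test_sign_conflict_renders_none(self):
        merged = merge_duplicates([edge(w=0.3), edge(w=-0.3)])
        assert association_sign(merged, "t1", "t2") == "none"


class TestMaps:
    def _load(self, community):
        models = [read_model(p) for p in community["models"]]
        lineages = read_lineage_table(community["lineages"])
        edges = load_edges(community["edges"])
        return models, lineages, edges

    def test_neighborhood_query_at_origin_one_point_per_taxon(self, community):
        models, lineages, edges = self._load(community)
        query = community["taxa"][0]
        points = neighborhood_map(query, models, lineages, edges)
        assert points[0].target == query
        assert (points[0].x, points[0].y) == (0.0, 0.0)
        assert len(points) == len(community["taxa"])
        for p in points:
            assert 0.0 <= p.x <= 1.0 and 0.0 <= p.y <= 1.0
            assert p.association in ("positive", "negative", "none")
            assert p.n_pairs >= 1

    def test_neighborhood_association_labels_match_edge_table(self, community):
        models, lineages, edges = self._load(community)
        query = community["taxa"][0]
        points = neighborhood_map(query, models, lineages, edges)
        expected = {t: association_sign(merge_duplicates(edges), query, t)
                    for t in community["taxa"][1:]}
        assert {p.target: p.association for p in points[1:]} == expected

    def test_neighborhood_unknown_query_errors(self, community):
        models, lineages, edges = self._load(community)
        with pytest.raises(KeyError):
            neighborhood_map("ghost", models, lineages, edges)

    def test_compatibility_axes_and_ranges(self, community):
        models, _, edges = self._load(community)
        query = community["taxa"][0]
        points = compatibility_map(query, models, edges)
        assert (points[0].x, points[0].y) == (0.0, 0.0)
        assert len(points) == len(community["taxa"])
        for p in points[1:]:
            assert 0.0 <= p.x <= 1.0 and 0.0 <= p.y <= 1.0

    def test_identical_seed_target_lands_at_y_zero(self, community):
        """A target whose seed set equals the query's has competition 1 in
        both directions, hence y = 1 - 1 = 0."""
        models, _, edges = self._load(community)
        import copy

        query = models[0]
        twin = copy.deepcopy(query)
        twin.model_id = "twin"
        twin.taxon_id = "twin"
        points = compatibility_map(query.model_id, models + [twin], edges)
        twin_point = next(p for p in points if p.target == "twin")
        assert twin_point.y == pytest.approx(0.0)
        assert twin_point.x == pytest.approx(0.0)  # producible excludes own seeds

    def test_strain_pair_averaging(self, community):
        """Two strain models for one target taxon: map values are means
        over the strain pairs and n_pairs records the count."""
        models, _, edges = self._load(community)
        from micronet.compatibility import (
            competition_index,
            complementarity_index,
            profile_model,
        )
        import copy

        query = models[0]
        s1, s2 = models[1], copy.deepcopy(models[2])
        s2.taxon_id = s1.model_id  # second strain of the same taxon
        s2.model_id = "strain2"
        points = compatibility_map(query.model_id, [query, s1, s2], edges)
        target = next(p for p in points if p.target == s1.model_id)
        assert target.n_pairs == 2
        pq, p1, p2 = (profile_model(m) for m in (query, s1, s2))
        expected_x = sum(
            (complementarity_index(pq.producible, pq.seeds, pt.seeds)
             + complementarity_index(pt.producible, pt.seeds, pq.seeds)) / 2
            for pt in (p1, p2)
        ) / 2
        assert target.x == pytest.approx(expected_x)

    def test_rank_complementarity_percentile(self, community):
        models, _, edges = self._load(community)
        points = compatibility_map(community["taxa"][0], models, edges)
        best = max(points[1:], key=lambda p: p.x)
        assert rank_complementarity(points, best.target) == pytest.approx(100.0)
        with pytest.raises(KeyError):
            rank_complementarity(points, "ghost")

    def test_map_frame_schema(self, community):
        models, lineages, edges = self._load(community)
        frame = map_frame(neighborhood_map(community["taxa"][0], models, lineages, edges))
        assert list(frame.columns) == ["target", "x", "y", "association", "n_pairs"]
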
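import math

import networkx as nx
import pandas as pd
import pytest

import reference_impl as ref
from herbprox.combination import (
    AdmetTable,
    CombinationLandscape,
    FilterSpec,
    LandscapeEdge,
    admet_filter,
    build_combination_graph,
    build_disease_landscape,
    detect_modules,
    disease_module_members,
    formula_synergy_scan,
    recommend,
)
from herbprox.core import CatalogError, load_catalog
from herbprox.significance import NullModel


def make_null(values=(1.0, 2.0, 3.0, 2.0, 2.0), level="ingredient_ingredient"):
    return NullModel(values=list(values), strategy="random_pairs", level=level, seed=0)


@pytest.fixture()
def path_formula_catalog():
    return load_catalog(
        formula_herb=[("F1", "H1"), ("F1", "H2")],
        herb_ingredient=[("H1", "ia"), ("H1", "ib"), ("H2", "ic")],
        ingredient_target=[("ia", "v1"), ("ib", "v1"), ("ic", "v5")],
    )


class TestFormulaSynergyScan:
    def test_counts_all_pairs_and_flags_close_ones(self, path_graph,
                                                   path_formula_catalog):
        # 3 usable ingredients -> C(3,2)=3 pairs evaluated; ia-ib share v1
        null = make_null(values=(2.0, 3.0, 4.0, 3.0))
        hits = formula_synergy_scan("F1", path_formula_catalog, path_graph, null)
        assert all(h.p < 0.05 for h in hits)
        shared = [h for h in hits if {h.source, h.target} == {"ia", "ib"}]
        assert shared and shared[0].distance == 0.0
        assert hits == sorted(hits, key=lambda e: e.distance)

    def test_too_few_ingredients_errors(self, path_graph):
        catalog = load_catalog(
            formula_herb=[("F1", "H1")],
            herb_ingredient=[("H1", "ia")],
            ingredient_target=[("ia", "v1")],
        )
        with pytest.raises(CatalogError, match="<2 ingredients"):
            formula_synergy_scan("F1", catalog, path_graph, make_null())

    def test_planted_pair_flagged_background_not(self, default_scenario):
        """At fixed seed, planted proximal pairs are flagged by the scan
        while pairs in an all-background formula mostly are not."""
        from herbprox.proximity import DistanceEngine
        from herbprox.significance import sample_null

        catalog, graph, truth = default_scenario
        eng = DistanceEngine(graph)
        ings = sorted(catalog.ingredient_ids)
        universe = [(a, b) for i, a in enumerate(ings) for b in ings[i + 1:]]
        null = sample_null(universe, "ingredient_ingredient", catalog, eng,
                           n=500, seed=7)

        # the first formula holds all planted ingredients
        planted_formula = "FOR_001"
        assert set(catalog.ingredients_of_formula(planted_formula)) == set(truth.planted)
        hits = formula_synergy_scan(planted_formula, catalog, eng, null)
        flagged = {frozenset((h.source, h.target)) for h in hits}
        planted_rate = sum(frozenset(p) in flagged
                           for p in truth.planted_pairs) / len(truth.planted_pairs)

        background_formula = "FOR_002"
        bg_ings = catalog.ingredients_of_formula(background_formula)
        assert not set(bg_ings) & set(truth.planted)
        bg_hits = formula_synergy_scan(background_formula, catalog, eng, null)
        bg_rate = len(bg_hits) / (len(bg_ings) * (len(bg_ings) - 1) / 2)

        assert planted_rate >= 0.5
        assert bg_rate < 0.1
        assert planted_rate > bg_rate


class TestRecommend:
    def test_ingredient_pair_pattern(self, path_graph, path_formula_catalog):
        nulls = {"ing-ing": make_null()}
        ls = recommend("ingredient+ingredient", ["ia", "ic"],
                       path_formula_catalog, path_graph, nulls)
        assert set(ls.nodes) == {"ia", "ic"}
        assert len(ls.edges) == 1
        assert ls.edges[0].distance == 4.0  # v1 to v5 on the path

    def test_identical_singleton_herbs_zero(self, path_graph):
        catalog = load_catalog(
            formula_herb=[("F1", "HA"), ("F1", "HB")],
            herb_ingredient=[("HA", "ia"), ("HB", "ib")],
            ingredient_target=[("ia", "v3"), ("ib", "v3")],
        )
        nulls = {"herb-herb": make_null(level="herb_herb")}
        ls = recommend("herb+herb", ["HA", "HB"], catalog, path_graph, nulls)
        assert ls.edges[0].distance == 0.0

    def test_disease_pattern_zero_edges_when_covered(self, path_graph):
        catalog = load_catalog(
            formula_herb=[("F1", "H1")],
            herb_ingredient=[("H1", "ia"), ("H1", "ib")],
            ingredient_target=[("ia", "v4"), ("ia", "v5"), ("ib", "v4"), ("ib", "v5")],
            disease_target=[("D1", "v4"), ("D1", "v5")],
        )
        nulls = {"ing-ing": make_null(),
                 "ing-disease": make_null(level="ingredient_disease")}
        ls = recommend("ingredient+ingredient+disease", ["ia", "ib", "D1"],
                       catalog, path_graph, nulls)
        dis_edges = [e for e in ls.edges if e.relation == "ing-disease"]
        assert len(dis_edges) == 2
        assert all(e.distance == 0.0 for e in dis_edges)

    def test_unknown_pattern_errors(self, path_graph, path_formula_catalog):
        with pytest.raises(ValueError, match="unknown pattern"):
            recommend("herb+disease", ["H1", "D1"], path_formula_catalog,
                      path_graph, {})

    def test_missing_disease_errors(self, path_graph, path_formula_catalog):
        with pytest.raises(ValueError, match="expects 3 inputs"):
            recommend("herb+herb+disease", ["H1", "H2"], path_formula_catalog,
                      path_graph, {"herb-herb": make_null(level="herb_herb")})

    def test_prescription_pattern_cross_pairs(self, path_graph):
        catalog = load_catalog(
            formula_herb=[("F1", "HA"), ("F2", "HB")],
            herb_ingredient=[("HA", "ia"), ("HB", "ib")],
            ingredient_target=[("ia", "v1"), ("ib", "v3")],
            disease_target=[("D1", "v5")],
        )
        nulls = {
            "ing-ing": make_null(),
            "herb-herb": make_null(level="herb_herb"),
            "ing-disease": make_null(level="ingredient_disease"),
            "herb-disease": make_null(level="herb_disease"),
        }
        ls = recommend("prescription+prescription+disease", ["F1", "F2", "D1"],
                       catalog, path_graph, nulls)
        relations = sorted(e.relation for e in ls.edges)
        assert relations == ["herb-disease", "herb-disease", "herb-herb",
                             "ing-disease", "ing-disease", "ing-ing"]
        ii = next(e for e in ls.edges if e.relation == "ing-ing")
        assert ii.distance == 2.0  # v1 to v3

    def test_landscape_serialization_reproducible(self, path_graph,
                                                  path_formula_catalog):
        nulls = {"ing-ing": make_null()}
        a = recommend("ingredient+ingredient", ["ia", "ic"],
                      path_formula_catalog, path_graph, nulls)
        b = recommend("ingredient+ingredient", ["ia", "ic"],
                      path_formula_catalog, path_graph, nulls)
        assert a.to_json() == b.to_json()


class TestCombinationGraph:
    def landscape(self):
        ls = CombinationLandscape(nodes={"a": "ingredient", "b": "ingredient",
                                         "c": "ingredient"})
        ls.add_edge(LandscapeEdge("a", "b", "ing-ing", 0.0, -3.0, 0.001))
        ls.add_edge(LandscapeEdge("b", "c", "ing-ing", 1.0, -2.0, 0.02))
        ls.add_edge(LandscapeEdge("a", "c", "ing-ing", 3.0, 1.0, 0.8))
        return ls

    def test_weight_transform(self):
        g = build_combination_graph(self.landscape(), significant_only=False)
        assert g["a"]["b"]["weight"] == 1.0
        assert g["b"]["c"]["weight"] == pytest.approx(math.exp(-1.0))
        # monotone: smaller distance -> larger weight
        assert g["a"]["b"]["weight"] > g["b"]["c"]["weight"] > g["a"]["c"]["weight"]

    def test_significant_only_filter(self):
        g = build_combination_graph(self.landscape(), significant_only=True)
        assert g.number_of_edges() == 2
        assert not g.has_edge("a", "c")

    def test_no_surviving_edges_errors(self):
        ls = CombinationLandscape(nodes={"a": "ingredient", "b": "ingredient"})
        ls.add_edge(LandscapeEdge("a", "b", "ing-ing", 2.0, 1.0, 0.9))
        with pytest.raises(ValueError, match="no surviving"):
            build_combination_graph(ls, significant_only=True)


class TestDetectModules:
    def two_cliques(self):
        g = nx.Graph()
        for base in ("a", "b"):
            clique = [f"{base}{i}" for i in range(4)]
            for i, u in enumerate(clique):
                for v in clique[i + 1:]:
                    g.add_edge(u, v, weight=1.0)
        g.add_edge("a0", "b0", weight=1.0)  # bridge
        return g

    def test_two_clique_partition_matches_bruteforce(self):
        g = self.two_cliques()
        labels = detect_modules(g, seed=0)
        got = {frozenset(n for n, l in labels.items() if l == lab)
               for lab in set(labels.values())}
        best = ref.best_partition_bruteforce(g)
        assert got == {frozenset(c) for c in best}
        assert got == {frozenset({"a0", "a1", "a2", "a3"}),
                       frozenset({"b0", "b1", "b2", "b3"})}

    def test_single_clique_one_community(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        labels = detect_modules(g, seed=0)
        assert len(set(labels.values())) == 1

    def test_same_seed_identical(self):
        g = self.two_cliques()
        assert detect_modules(g, seed=3) == detect_modules(g, seed=3)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="empty"):
            detect_modules(nx.Graph())


class TestDiseaseModuleMembers:
    def test_members_of_disease_community(self):
        labels = {"D": 0, "i1": 0, "i2": 0, "i3": 1}
        assert disease_module_members(labels, "D") == ["i1", "i2"]

    def test_isolated_disease_empty(self):
        labels = {"D": 0, "i1": 1, "i2": 1}
        assert disease_module_members(labels, "D") == []

    def test_absent_disease_errors(self):
        with pytest.raises(ValueError):
            disease_module_members({"i1": 0}, "D")

    def test_two_clique_fixture_membership(self):
        g = TestDetectModules().two_cliques()
        labels = detect_modules(g, seed=0)
        labels["D"] = labels["a1"]  # disease co-labelled inside clique A
        assert disease_module_members(labels, "D") == ["a0", "a1", "a2", "a3"]


class TestAdmetFilter:
    def table(self):
        rows = pd.DataFrame(
            {
                "HIA": ["+", "+", "-", "+"],
                "OB": [40.0, 20.0, 50.0, 35.0],
                "BBB": ["+", "+", "+", "-"],
            },
            index=pd.Index(["i1", "i2", "i3", "i4"], name="ingredient_id"),
        )
        return AdmetTable(rows=rows)

    def test_worked_conjunction(self):
        spec = FilterSpec.parse("HIA eq +\nOB ge 30\nBBB eq +\n")
        assert admet_filter(self.table(), spec, ["i1", "i2", "i3", "i4"]) == ["i1"]

    def test_empty_spec_keeps_all(self):
        spec = FilterSpec.parse("")
        assert admet_filter(self.table(), spec, ["i1", "i2"]) == ["i1", "i2"]

    def test_missing_property_value_excludes(self):
        table = self.table()
        table.rows.loc["i1", "OB"] = float("nan")
        spec = FilterSpec.parse("OB ge 30")
        assert admet_filter(table, spec, ["i1", "i3", "i4"]) == ["i3", "i4"]

    def test_unknown_property_errors(self):
        spec = FilterSpec.parse("LOGP ge 2")
        with pytest.raises(ValueError, match="unknown ADMET property"):
            admet_filter(self.table(), spec, ["i1"])

    def test_antitone_in_spec(self):
        base = FilterSpec.parse("HIA eq +")
        tighter = FilterSpec.parse("HIA eq +\nOB ge 30")
        ids = ["i1", "i2", "i3", "i4"]
        assert set(admet_filter(self.table(), tighter, ids)) <= \
            set(admet_filter(self.table(), base, ids))

    def test_parse_rejects_bad_comparator(self):
        with pytest.raises(ValueError, match="line 1"):
            FilterSpec.parse("HIA gt +")


class TestDiseaseLandscapeRecovery:
    def test_planted_module_recovery(self, default_scenario):
        from herbprox.proximity import DistanceEngine
        from herbprox.significance import sample_null

        catalog, graph, truth = default_scenario
        eng = DistanceEngine(graph)
        ings = sorted(catalog.ingredient_ids)
        ii_univ = [(a, b) for i, a in enumerate(ings) for b in ings[i + 1:]]
        id_univ = [(i, truth.disease_id) for i in ings]
        ii_null = sample_null(ii_univ, "ingredient_ingredient", catalog, eng,
                              n=500, seed=11)
        id_null = sample_null(id_univ, "ingredient_disease", catalog, eng,
                              n=500, seed=12)
        ls = build_disease_landscape(truth.disease_id, ings, catalog, eng,
                                     ii_null, id_null)
        g = build_combination_graph(ls, significant_only=True)
        labels = detect_modules(g, seed=0)
        members = disease_module_members(labels, truth.disease_id)
        recovered = len(set(members) & set(truth.planted)) / len(truth.planted)
        assert recovered >= 0.8
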
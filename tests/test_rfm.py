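import copy
import random

import networkx as nx
import pytest

from diseasechain.core_model import (
    AbnormalState,
    CausalGraph,
    CausalLink,
    Disease,
    DiseaseOntology,
    state_subsumes,
)
from diseasechain.errors import ArgumentError, UnknownIdentifierError
from diseasechain.rfm import (
    chain_graph,
    chain_included_in,
    core_causal_chain,
    disease_is_super_of,
    diseases_containing,
    downstream_closure,
    effective_states,
    general_graph,
    infer_isa_hierarchy,
    upstream_closure,
    validate_core_against_subclasses,
)

from oracles import brute_force_included, random_graph, random_hierarchy_ontology

DIABETES_CORE = {"deficiency_of_insulin", "elevated_glucose_in_blood"}
TYPE_I_CORE = DIABETES_CORE | {"destruction_of_pancreatic_beta_cells", "lack_of_insulin_in_blood"}


class TestEffectiveStates:
    def test_type_i_aggregates_inherited_core(self, diabetes):
        assert effective_states("type_I_diabetes", "core", diabetes) == TYPE_I_CORE

    def test_diabetes_core_is_printed_pair(self, diabetes):
        assert effective_states("diabetes", "core", diabetes) == DIABETES_CORE

    def test_empty_disease(self):
        ontology = DiseaseOntology()
        ontology.add_disease(Disease(id="d"))
        assert effective_states("d", "all", ontology) == set()

    def test_unknown_disease(self, diabetes):
        with pytest.raises(UnknownIdentifierError):
            effective_states("nope", "core", diabetes)

    def test_bad_which(self, diabetes):
        with pytest.raises(ArgumentError):
            effective_states("diabetes", "wrong", diabetes)


class TestChainGraph:
    def test_type_i_is_four_node_path(self, diabetes):
        graph = chain_graph("type_I_diabetes", "all", diabetes)
        assert graph.states == TYPE_I_CORE
        assert len(graph.links) == 3
        nxg = graph.to_networkx()
        assert nx.is_directed_acyclic_graph(nxg)
        order = list(nx.topological_sort(nxg))
        assert order[0] == "destruction_of_pancreatic_beta_cells"
        assert order[-1] == "elevated_glucose_in_blood"

    def test_diabetes_core_two_nodes_one_link(self, diabetes):
        graph = chain_graph("diabetes", "core", diabetes)
        assert graph.states == DIABETES_CORE
        assert graph.links == {CausalLink("deficiency_of_insulin", "elevated_glucose_in_blood")}

    def test_states_without_links(self):
        ontology = DiseaseOntology()
        ontology.add_state(AbnormalState(id="a", level=1))
        ontology.add_state(AbnormalState(id="b", level=1))
        ontology.add_disease(Disease(id="d", core_states=("a", "b")))
        graph = chain_graph("d", "all", ontology)
        assert graph.states == {"a", "b"} and not graph.links


class TestChainInclusion:
    def test_diabetes_core_in_type_i_chain(self, diabetes):
        a = chain_graph("diabetes", "core", diabetes)
        b = chain_graph("type_I_diabetes", "all", diabetes)
        witness = chain_included_in(a, b, diabetes, mode="path")
        assert witness is not None
        # identity node map: the aggregated chain contains the same states
        assert witness.node_map == {s: s for s in a.states}

    def test_empty_graph_vacuously_included(self, diabetes):
        empty = CausalGraph()
        target = chain_graph("diabetes", "all", diabetes)
        for mode in ("path", "strict"):
            witness = chain_included_in(empty, target, diabetes, mode=mode)
            assert witness is not None
            assert witness.node_map == {} and witness.edge_map == {}

    def test_witness_invariants(self, rng):
        ontology = random_hierarchy_ontology(rng, 10)
        for _ in range(60):
            a = random_graph(rng, ontology, 4)
            b = random_graph(rng, ontology, 8)
            for mode in ("path", "strict"):
                witness = chain_included_in(a, b, ontology, mode=mode)
                if witness is None:
                    continue
                # injectivity
                assert len(set(witness.node_map.values())) == len(witness.node_map)
                for general, specific in witness.node_map.items():
                    sa, sb = ontology.states[general], ontology.states[specific]
                    if sa.is_unknown or sb.is_unknown:
                        assert sa.is_unknown and sb.is_unknown
                    else:
                        assert state_subsumes(general, specific, ontology)
                for link, path in witness.edge_map.items():
                    assert path, "edge paths must be nonempty"
                    assert path[0].cause == witness.node_map[link.cause]
                    assert path[-1].effect == witness.node_map[link.effect]
                    for left, right in zip(path, path[1:]):
                        assert left.effect == right.cause
                    if mode == "strict":
                        assert len(path) == 1

    def test_agrees_with_brute_force(self, rng):
        ontology = random_hierarchy_ontology(rng, 10)
        for _ in range(60):
            a = random_graph(rng, ontology, 4)
            b = random_graph(rng, ontology, 7)
            for mode in ("path", "strict"):
                expected = brute_force_included(a, b, ontology, mode)
                actual = chain_included_in(a, b, ontology, mode=mode) is not None
                assert actual == expected

    def test_reflexive_and_transitive(self, rng):
        ontology = random_hierarchy_ontology(rng, 8, p_unknown=0.0)
        graphs = [random_graph(rng, ontology, 5) for _ in range(6)]
        for mode in ("path", "strict"):
            for g in graphs:
                assert chain_included_in(g, g, ontology, mode=mode) is not None
            for g1 in graphs:
                for g2 in graphs:
                    for g3 in graphs:
                        if (
                            chain_included_in(g1, g2, ontology, mode=mode) is not None
                            and chain_included_in(g2, g3, ontology, mode=mode) is not None
                        ):
                            assert chain_included_in(g1, g3, ontology, mode=mode) is not None

    def test_monotone_under_growth(self, rng):
        ontology = random_hierarchy_ontology(rng, 10)
        extra = sorted(ontology.states)
        for _ in range(40):
            a = random_graph(rng, ontology, 4)
            b = random_graph(rng, ontology, 6)
            for mode in ("path", "strict"):
                if chain_included_in(a, b, ontology, mode=mode) is None:
                    continue
                grown_states = set(b.states) | set(rng.sample(extra, 2))
                grown_links = set(b.links)
                nodes = sorted(grown_states)
                for _ in range(3):
                    u, v = rng.sample(nodes, 2)
                    grown_links.add(CausalLink(u, v))
                grown = CausalGraph(states=grown_states, links=grown_links)
                assert chain_included_in(a, grown, ontology, mode=mode) is not None

    def test_strict_implies_path(self, rng):
        ontology = random_hierarchy_ontology(rng, 10)
        for _ in range(50):
            a = random_graph(rng, ontology, 4)
            b = random_graph(rng, ontology, 7)
            if chain_included_in(a, b, ontology, mode="strict") is not None:
                assert chain_included_in(a, b, ontology, mode="path") is not None

    def test_deterministic_witness(self, rng):
        ontology = random_hierarchy_ontology(rng, 10)
        for _ in range(20):
            a = random_graph(rng, ontology, 4)
            b = random_graph(rng, ontology, 8)
            w1 = chain_included_in(a, b, ontology)
            w2 = chain_included_in(a, b, ontology)
            assert (w1 is None) == (w2 is None)
            if w1 is not None:
                assert w1.node_map == w2.node_map and w1.edge_map == w2.edge_map


class TestDiseaseIsSuperOf:
    def test_diabetes_over_type_i(self, diabetes):
        assert disease_is_super_of("diabetes", "type_I_diabetes", diabetes, mode="path")

    def test_diabetes_over_steroid_with_elision(self, diabetes):
        assert disease_is_super_of("diabetes", "steroid_diabetes", diabetes, mode="path")

    def test_not_reversed(self, diabetes):
        assert not disease_is_super_of("type_I_diabetes", "diabetes", diabetes, mode="path")

    def test_self_comparison_rejected(self, diabetes):
        with pytest.raises(ArgumentError):
            disease_is_super_of("diabetes", "diabetes", diabetes)


class TestInferIsa:
    def test_diabetes_family(self, diabetes):
        result = infer_isa_hierarchy(diabetes)
        expected = {
            ("type_I_diabetes", "diabetes"),
            ("steroid_diabetes", "diabetes"),
            ("diabetes_caused_blindness", "diabetes"),
        }
        assert result.pairs == expected
        assert result.reduced_pairs == expected
        assert not result.equivalences
        assert not result.discrepancies

    def test_single_disease(self):
        ontology = DiseaseOntology()
        ontology.add_state(AbnormalState(id="a", level=1))
        ontology.add_disease(Disease(id="d", core_states=("a",)))
        result = infer_isa_hierarchy(ontology)
        assert not result.pairs and not result.reduced_pairs

    def test_equivalent_chains_not_cycles(self):
        ontology = DiseaseOntology()
        ontology.add_state(AbnormalState(id="a", level=1))
        ontology.add_state(AbnormalState(id="b", level=1))
        ontology.add_link("a", "b")
        ontology.add_disease(Disease(id="d1", core_states=("a", "b")))
        ontology.add_disease(Disease(id="d2", core_states=("a",), derived_states=("b",)))
        result = infer_isa_hierarchy(ontology)
        assert result.equivalences == {frozenset({"d1", "d2"})}
        assert not result.pairs
        dag = nx.DiGraph(result.pairs)
        assert nx.is_directed_acyclic_graph(dag)

    def test_closure_of_reduction_is_pairs(self, rng):
        from diseasechain.synthetic_data import GeneratorConfig, generate

        ontology, _ = generate(GeneratorConfig(n_diseases=15, p_refine=0.3, seed=7))
        result = infer_isa_hierarchy(ontology)
        dag = nx.DiGraph()
        dag.add_nodes_from(ontology.diseases)
        dag.add_edges_from(result.reduced_pairs)
        closure = set()
        for node in dag.nodes:
            for desc in nx.descendants(dag, node):
                closure.add((node, desc))
        assert closure == result.pairs
        assert result.reduced_pairs <= result.pairs

    def test_declared_pairs_always_confirmed_under_aggregation(self, diabetes):
        # a declared subclass aggregates its super's chain, so every
        # declared pair is confirmed by the inclusion test by construction
        ontology = copy.deepcopy(diabetes)
        ontology.diseases["type_I_diabetes"] = Disease(
            id="type_I_diabetes",
            label="Type-I diabetes",
            core_states=ontology.diseases["type_I_diabetes"].core_states,
            supers=frozenset({"diabetes_caused_blindness"}),
        )
        result = infer_isa_hierarchy(ontology)
        assert ("type_I_diabetes", "diabetes_caused_blindness") in result.pairs
        assert not result.discrepancies


class TestCoreCausalChain:
    def test_diabetes_core_is_exactly_printed_chain(self, diabetes):
        graph = core_causal_chain("diabetes", diabetes)
        assert graph.states == DIABETES_CORE
        assert graph.links == {CausalLink("deficiency_of_insulin", "elevated_glucose_in_blood")}

    def test_leaf_falls_back_to_declared_core(self, diabetes):
        graph = core_causal_chain("type_I_diabetes", diabetes)
        assert graph == chain_graph("type_I_diabetes", "core", diabetes)

    def test_perturbed_subclass_filters_states_and_links(self, diabetes):
        # standalone-authored subclass chains (explicit subclass list):
        # one subclass lacks elevated_glucose -> only deficiency survives
        ontology = copy.deepcopy(diabetes)
        ontology.add_disease(Disease(
            id="perturbed",
            core_states=("destruction_of_pancreatic_beta_cells", "lack_of_insulin_in_blood", "deficiency_of_insulin"),
        ))
        graph = core_causal_chain("diabetes", ontology, subclasses=["perturbed", "steroid_diabetes"])
        assert graph.states == {"deficiency_of_insulin"}
        assert not graph.links

    def test_validate_core_against_subclasses_clean(self, diabetes):
        assert validate_core_against_subclasses("diabetes", diabetes) == []

    def test_validate_core_perturbed(self, diabetes):
        ontology = copy.deepcopy(diabetes)
        ontology.add_disease(Disease(id="perturbed", core_states=("deficiency_of_insulin",)))
        violations = validate_core_against_subclasses("diabetes", ontology, subclasses=["perturbed"])
        assert ("perturbed", "elevated_glucose_in_blood") in violations

    def test_no_subclasses_no_violations(self, diabetes):
        assert validate_core_against_subclasses("type_I_diabetes", diabetes) == []


class TestClosures:
    def test_downstream_reaches_blindness(self, diabetes):
        graph = general_graph(diabetes)
        closure = downstream_closure("deficiency_of_insulin", graph)
        assert {"elevated_glucose_in_blood", "loss_of_sight"} <= closure.states
        assert "destruction_of_pancreatic_beta_cells" not in closure.states

    def test_upstream_reaches_both_etiologies(self, diabetes):
        graph = general_graph(diabetes)
        closure = upstream_closure("deficiency_of_insulin", graph)
        assert {"destruction_of_pancreatic_beta_cells", "long_term_steroid_treatment"} <= closure.states
        assert "loss_of_sight" not in closure.states

    def test_isolated_state(self):
        graph = CausalGraph(states={"solo"})
        assert downstream_closure("solo", graph).states == {"solo"}
        assert upstream_closure("solo", graph).states == {"solo"}

    def test_cycle_terminates(self):
        links = {CausalLink("a", "b"), CausalLink("b", "c"), CausalLink("c", "a")}
        graph = CausalGraph(states={"a", "b", "c"}, links=links)
        down = downstream_closure("a", graph)
        assert down.states == {"a", "b", "c"} and down.links == links
        up = upstream_closure("a", graph)
        assert up.states == {"a", "b", "c"}

    def test_max_depth(self, diabetes):
        graph = general_graph(diabetes)
        one_step = downstream_closure("deficiency_of_insulin", graph, max_depth=1)
        assert one_step.states == {"deficiency_of_insulin", "elevated_glucose_in_blood"}

    def test_seed_not_in_graph(self, diabetes):
        with pytest.raises(UnknownIdentifierError):
            downstream_closure("nope", general_graph(diabetes))


class TestGeneralGraph:
    def test_diabetes_single_component(self, diabetes):
        graph = general_graph(diabetes)
        assert nx.number_weakly_connected_components(graph.to_networkx()) == 1
        assert graph.states == set(diabetes.states)

    def test_empty_ontology(self):
        graph = general_graph(DiseaseOntology())
        assert not graph.states and not graph.links

    def test_isolated_state_kept(self, diabetes):
        ontology = copy.deepcopy(diabetes)
        ontology.add_state(AbnormalState(id="isolated", level=1))
        graph = general_graph(ontology)
        assert "isolated" in graph.states
        assert graph.to_networkx().degree("isolated") == 0


class TestDiseasesContaining:
    def test_deficiency_in_all_four(self, diabetes):
        assert diseases_containing("deficiency_of_insulin", diabetes) == [
            "diabetes", "diabetes_caused_blindness", "steroid_diabetes", "type_I_diabetes",
        ]

    def test_unreferenced_state(self, diabetes):
        ontology = copy.deepcopy(diabetes)
        ontology.add_state(AbnormalState(id="orphan", level=1))
        assert diseases_containing("orphan", ontology) == []

    def test_descendant_flag_is_superset(self, stenosis):
        ontology = copy.deepcopy(stenosis)
        ontology.add_disease(Disease(id="cad", core_states=("coronary_artery_stenosis",)))
        without = diseases_containing("vascular_stenosis", ontology, include_state_descendants=False)
        with_flag = diseases_containing("vascular_stenosis", ontology, include_state_descendants=True)
        assert set(without) <= set(with_flag)
        assert without == []
        assert with_flag == ["cad"]
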
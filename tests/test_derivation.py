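from __future__ import annotations

import numpy as np
import pytest

from conftest import random_tripartite
from dcdnet.derivation import (
    DerivedBipartite,
    DerivedEdge,
    common_complexes,
    derive_drug_disease,
    derived_weight,
    fallback_weight,
)
from dcdnet.io_tables import EntityId, GeneSetMap
from dcdnet.tripartite import TripartiteNetwork, build_tripartite

T = EntityId("drug", "t")
D = EntityId("disease", "d")


def naive_derived_weight(t, d, net: TripartiteNetwork) -> float | None:
    """Straight-line re-implementation of the shared-complex score.

    Scans every complex explicitly; returns None when the pair has no
    shared complex neighbor.
    """
    w_t = {p: net.drug_complex.weight(t, p) for p in net.complexes}
    w_d = {p: net.complex_disease.weight(p, d) for p in net.complexes}
    c = [p for p in net.complexes if w_t[p] > 0 and w_d[p] > 0]
    if not c:
        return None
    g_t_c = sum(w_t[p] for p in c)
    g_d_c = sum(w_d[p] for p in c)
    g_t = sum(w_t.values())
    g_d = sum(w_d.values())
    return (g_t_c / g_t) * (g_d_c / g_d)


def naive_derive(net: TripartiteNetwork) -> dict:
    """Brute-force over all (drug, disease) pairs, including the fallback."""
    edges = {}
    for t in net.drugs:
        for d in net.diseases:
            w = naive_derived_weight(t, d, net)
            if w is not None:
                edges[(t, d)] = ("via_complexes", w)
            else:
                shared = net.drugs.genes(t) & net.diseases.genes(d)
                if shared:
                    a, b = net.drugs.genes(t), net.diseases.genes(d)
                    edges[(t, d)] = (
                        "direct_fallback",
                        len(shared) ** 2 / (len(a) * len(b)),
                    )
    return edges


class TestCommonComplexes:
    def test_intersection_of_neighborhoods(self, worked_tripartite):
        assert common_complexes(T, D, worked_tripartite) == frozenset(
            {EntityId("complex", "p1"), EntityId("complex", "p2")}
        )

    def test_disjoint_neighborhoods_give_empty_set(self):
        net = build_tripartite(
            GeneSetMap.from_dict("drug", {"t": [1]}),
            GeneSetMap.from_dict("complex", {"p1": [1], "p2": [2]}),
            GeneSetMap.from_dict("disease", {"d": [2]}),
        )
        assert common_complexes(T, D, net) == frozenset()

    def test_unknown_entity_raises_lookup_error(self, worked_tripartite):
        with pytest.raises(LookupError):
            common_complexes(EntityId("drug", "nope"), D, worked_tripartite)
        with pytest.raises(LookupError):
            common_complexes(T, EntityId("disease", "nope"), worked_tripartite)

    def test_full_adjacency_matches_brute_force_scan(self):
        net = build_tripartite(
            GeneSetMap.from_dict("drug", {"t": [1, 2, 3, 4]}),
            GeneSetMap.from_dict("complex", {"p1": [1, 9], "p2": [2, 9], "p3": [3, 9], "p4": [4, 9]}),
            GeneSetMap.from_dict("disease", {"d": [9]}),
        )
        expected = {
            p for p in net.complexes
            if net.drug_complex.weight(T, p) > 0 and net.complex_disease.weight(p, D) > 0
        }
        assert len(expected) == 4
        assert common_complexes(T, D, net) == frozenset(expected)


class TestDerivedWeight:
    def test_saturated_pair_scores_one(self):
        # without p3 the shared complexes exhaust both neighborhoods
        net = build_tripartite(
            GeneSetMap.from_dict("drug", {"t": [1, 2]}),
            GeneSetMap.from_dict("complex", {"p1": [1, 3], "p2": [2, 4, 5]}),
            GeneSetMap.from_dict("disease", {"d": [3, 4]}),
        )
        assert derived_weight(T, D, net) == pytest.approx(1.0)

    def test_drug_only_complex_dilutes_weight(self, worked_tripartite):
        # g_T(t,C)=0.25+1/6, g(t) adds w_T(t,p3)=0.125 -> (5/12)/(13/24)
        assert derived_weight(T, D, worked_tripartite) == pytest.approx(
            (0.25 + 1 / 6) / (0.25 + 1 / 6 + 0.125), abs=1e-12
        )
        assert derived_weight(T, D, worked_tripartite) == pytest.approx(0.7692, abs=1e-4)

    def test_empty_support_is_domain_error(self):
        net = build_tripartite(
            GeneSetMap.from_dict("drug", {"t": [1]}),
            GeneSetMap.from_dict("complex", {"p1": [1], "p2": [2]}),
            GeneSetMap.from_dict("disease", {"d": [2]}),
        )
        with pytest.raises(ValueError, match="fallback"):
            derived_weight(T, D, net)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        net = random_tripartite(rng)
        for t in net.drugs:
            for d in net.diseases:
                expected = naive_derived_weight(t, d, net)
                if expected is None:
                    continue
                assert derived_weight(t, d, net) == pytest.approx(expected, abs=1e-12)


class TestFallbackWeight:
    def test_worked_example(self):
        drugs = GeneSetMap.from_dict("drug", {"t": [1, 2]})
        diseases = GeneSetMap.from_dict("disease", {"d": [2, 5, 6]})
        assert fallback_weight(T, D, drugs, diseases) == pytest.approx(1 / 6)

    def test_identical_sets_give_one(self):
        drugs = GeneSetMap.from_dict("drug", {"t": [1, 2]})
        diseases = GeneSetMap.from_dict("disease", {"d": [1, 2]})
        assert fallback_weight(T, D, drugs, diseases) == 1.0

    def test_disjoint_sets_give_no_edge(self):
        drugs = GeneSetMap.from_dict("drug", {"t": [1]})
        diseases = GeneSetMap.from_dict("disease", {"d": [2]})
        with pytest.raises(ValueError, match="no edge"):
            fallback_weight(T, D, drugs, diseases)


class TestDeriveDrugDisease:
    def test_via_complex_edge_with_support(self):
        net = build_tripartite(
            GeneSetMap.from_dict("drug", {"t": [1, 2]}),
            GeneSetMap.from_dict("complex", {"p1": [1, 9], "p2": [2, 8]}),
            GeneSetMap.from_dict("disease", {"d": [8]}),
        )
        derived = derive_drug_disease(net)
        edge = derived.edges[(T, D)]
        assert edge.provenance == "via_complexes"
        assert edge.support == frozenset({EntityId("complex", "p2")})

    def test_fallback_edge_when_no_shared_complex(self):
        net = build_tripartite(
            GeneSetMap.from_dict("drug", {"t": [1, 7]}),
            GeneSetMap.from_dict("complex", {"p1": [1, 9]}),
            GeneSetMap.from_dict("disease", {"d": [7]}),
        )
        derived = derive_drug_disease(net)
        edge = derived.edges[(T, D)]
        assert edge.provenance == "direct_fallback"
        assert edge.support == frozenset()
        assert edge.weight == pytest.approx(0.5)

    def test_unrelated_pair_gets_no_edge(self):
        net = build_tripartite(
            GeneSetMap.from_dict("drug", {"t": [1]}),
            GeneSetMap.from_dict("complex", {"p1": [1, 9]}),
            GeneSetMap.from_dict("disease", {"d": [2]}),
        )
        assert derive_drug_disease(net).n_edges == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_over_all_pairs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        net = random_tripartite(rng)
        derived = derive_drug_disease(net)
        expected = naive_derive(net)
        assert set(derived.edges) == set(expected)
        for pair, (provenance, weight) in expected.items():
            assert derived.edges[pair].provenance == provenance
            assert derived.edges[pair].weight == pytest.approx(weight, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_weights_bounded(self, seed):
        rng = np.random.default_rng(2000 + seed)
        derived = derive_drug_disease(random_tripartite(rng))
        for edge in derived.edges.values():
            assert 0.0 < edge.weight <= 1.0

    def test_enlarging_support_never_decreases_weight(self, worked_tripartite):
        partial = derived_weight(
            T, D, worked_tripartite, support=frozenset({EntityId("complex", "p1")})
        )
        full = derived_weight(T, D, worked_tripartite)
        assert full >= partial


class TestDerivedEdgeInvariants:
    def test_via_complexes_requires_support(self):
        with pytest.raises(ValueError):
            DerivedEdge(drug=T, disease=D, weight=0.5, provenance="via_complexes")

    def test_fallback_forbids_support(self):
        with pytest.raises(ValueError):
            DerivedEdge(
                drug=T, disease=D, weight=0.5, provenance="direct_fallback",
                support=frozenset({EntityId("complex", "p")}),
            )

    def test_weight_must_be_positive(self):
        with pytest.raises(ValueError):
            DerivedEdge(drug=T, disease=D, weight=0.0, provenance="direct_fallback")


class TestDerivedBipartiteIO:
    def test_tsv_round_trip_preserves_edges_and_provenance(self, tmp_path):
        rng = np.random.default_rng(17)
        derived = derive_drug_disease(random_tripartite(rng))
        path = tmp_path / "dd.tsv"
        derived.write_tsv(path)
        back = DerivedBipartite.read_tsv(path)
        assert set(back.edges) == set(derived.edges)
        for pair, edge in derived.edges.items():
            other = back.edges[pair]
            assert other.weight == pytest.approx(edge.weight, abs=1e-12)
            assert other.provenance == edge.provenance
            assert other.support == edge.support

    def test_restrict_to_disease_case_folded(self, worked_tripartite):
        derived = derive_drug_disease(worked_tripartite)
        sub = derived.restrict_to_disease("D")
        assert set(sub.edges) == {(T, D)}
        with pytest.raises(LookupError):
            derived.restrict_to_disease("unknown disease")
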
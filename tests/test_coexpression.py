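"""Species networks, conserved intersection, and candidate prioritization."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ksdev import synthetic as syn
from ksdev.coexpression import (
    OrthologMap,
    build_species_network,
    conserve_network,
    extract_connected,
    prioritize_candidates,
    reference_neighbor_counts,
)
from ksdev.matrix import ExpressionMatrix


@pytest.fixture(scope="module")
def compendium():
    return syn.gen_compendium_pair(seed=17)


def _net(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def test_orthomap_must_be_injective():
    with pytest.raises(ValueError):
        OrthologMap((("a1", "b1"), ("a1", "b2")))
    with pytest.raises(ValueError):
        OrthologMap((("a1", "b1"), ("a2", "b1")))


def test_perfectly_correlated_pair_gets_edge():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    vals = pd.DataFrame(
        {f"s{i}": [x[i], x[i] * 2.0, rng.normal()] for i in range(20)},
        index=["g1", "g2", "g3"],
    )
    net = build_species_network(ExpressionMatrix(vals), top_k=1, min_abs_rho=0.5)
    assert net.has_edge("g1", "g2")
    assert net.edges["g1", "g2"]["weight"] == pytest.approx(1.0)


def test_constant_gene_has_no_edges():
    rng = np.random.default_rng(1)
    vals = pd.DataFrame(rng.normal(size=(5, 30)), index=[f"g{i}" for i in range(5)])
    vals.loc["g0"] = 3.14
    with pytest.warns(UserWarning, match="constant"):
        net = build_species_network(ExpressionMatrix(vals), top_k=3, min_abs_rho=0.0)
    assert net.degree("g0") == 0
    with pytest.raises(ValueError):
        build_species_network(ExpressionMatrix(vals.iloc[:, :2]))


def test_planted_module_density(compendium):
    comp_a, _, _, truth = compendium
    net = build_species_network(comp_a)
    for module in truth.planted_modules + truth.decoy_modules:
        members = sorted(module)
        n_possible = math.comb(len(members), 2)
        n_edges = sum(net.has_edge(u, v) for u, v in itertools.combinations(members, 2))
        assert n_edges / n_possible > 0.8
    # cross-module / background edges are rare
    background = [g for g in net.nodes if not any(g in m for m in
                  truth.planted_modules + truth.decoy_modules)]
    cross = sum(net.degree(g) for g in background)
    assert cross / max(len(background), 1) < 0.5


def test_conserved_network_keeps_modules_drops_decoys(compendium):
    comp_a, comp_b, orthomap, truth = compendium
    net_a = build_species_network(comp_a)
    net_b = build_species_network(comp_b)
    conserved = conserve_network(net_a, net_b, orthomap)
    for module in truth.planted_modules:
        members = sorted(module)
        n_possible = math.comb(len(members), 2)
        n_edges = sum(
            conserved.has_edge(u, v) for u, v in itertools.combinations(members, 2)
        )
        assert n_edges / n_possible > 0.8
    for decoy in truth.decoy_modules:
        for u, v in itertools.combinations(sorted(decoy), 2):
            assert not conserved.has_edge(u, v)


def test_conserve_identity_and_intersection_semantics():
    identity = OrthologMap((("a", "a"), ("b", "b"), ("c", "c")))
    net = _net([("a", "b"), ("b", "c")])
    same = conserve_network(net, net, identity)
    assert set(same.edges) == set(net.edges)
    only_a = _net([("a", "b"), ("a", "c")])
    only_b = _net([("a", "b")])
    inter = conserve_network(only_a, only_b, identity)
    assert set(map(frozenset, inter.edges)) == {frozenset(("a", "b"))}
    with pytest.raises(ValueError):
        conserve_network(net, net, OrthologMap(()))


def test_conserve_symmetric_under_species_swap(compendium):
    comp_a, comp_b, orthomap, _ = compendium
    net_a = build_species_network(comp_a)
    net_b = build_species_network(comp_b)
    ab = conserve_network(net_a, net_b, orthomap)
    inverted = OrthologMap(tuple((b, a) for a, b in orthomap.pairs))
    ba = conserve_network(net_b, net_a, inverted)
    a2b = orthomap.a_to_b
    mapped = {frozenset((a2b[u], a2b[v])) for u, v in ab.edges}
    assert mapped == set(map(frozenset, ba.edges))


def test_reference_neighbor_counts_hand_drawn():
    # star with reference center plus a 2-ref triangle
    net = _net(
        [("ref1", "x"), ("ref1", "y"), ("ref1", "z"), ("ref2", "w"), ("ref3", "w")],
        nodes=["lonely"],
    )
    refs = {"ref1", "ref2", "ref3"}
    k = reference_neighbor_counts(net, refs)
    assert k["x"] == k["y"] == k["z"] == 1
    assert k["w"] == 2
    assert k["lonely"] == 0
    assert extract_connected(net, refs, 1) == {"x", "y", "z", "w"}
    assert extract_connected(net, refs, 2) == {"w"}
    with pytest.raises(ValueError):
        extract_connected(net, refs, 0)


def test_extract_counts_nonincreasing_in_min_k(compendium):
    comp_a, comp_b, orthomap, truth = compendium
    conserved = conserve_network(
        build_species_network(comp_a), build_species_network(comp_b), orthomap
    )
    counts = [
        len(extract_connected(conserved, truth.reference_genes, k)) for k in range(1, 7)
    ]
    assert counts == sorted(counts, reverse=True)


def test_prioritize_enumeration_oracle_small_network():
    """Hypergeometric neighborhood p equals exhaustive enumeration on an
    11-node toy network."""
    nodes = [f"n{i}" for i in range(10)] + ["cand"]
    refs = {"n0", "n1", "n2", "n3"}
    net = _net([("cand", r) for r in ("n0", "n1", "n2")] + [("cand", "n5"), ("n6", "n7")],
               nodes=nodes)
    scored = prioritize_candidates({"cand"}, net, refs)
    s = scored[0]
    assert s.n_ref_neighbors == 3 and s.degree == 4
    # enumerate all C(10, 4) neighbor draws from the other nodes
    others = [n for n in nodes if n != "cand"]
    draws = list(itertools.combinations(others, 4))
    exact = sum(1 for d in draws if len(set(d) & refs) >= 3) / len(draws)
    assert s.p == pytest.approx(exact, rel=1e-9)


def test_prioritize_isolated_and_out_of_network_genes_rank_last():
    net = _net([("cand", "ref1"), ("other", "x")], nodes=["isolated"])
    scored = prioritize_candidates({"cand", "isolated", "ghost"}, net, {"ref1"})
    by_gene = {s.gene: s for s in scored}
    assert by_gene["ghost"].p == 1.0 and not by_gene["ghost"].in_network
    assert by_gene["isolated"].p == 1.0
    assert scored[0].gene == "cand"
    assert prioritize_candidates(set(), net, {"ref1"}) == []


def test_planted_disease_genes_rank_top_decile(compendium):
    comp_a, comp_b, orthomap, truth = compendium
    conserved = conserve_network(
        build_species_network(comp_a), build_species_network(comp_b), orthomap
    )
    candidates = set(conserved.nodes) - truth.reference_genes
    scored = prioritize_candidates(candidates, conserved, truth.reference_genes)
    decile = max(len(scored) // 10, 1)
    top = {s.gene for s in scored[:decile]}
    frac = len(top & truth.disease_genes) / len(truth.disease_genes)
    assert frac >= 0.8


def test_permuted_references_destroy_enrichment(compendium):
    """With randomly relabelled reference genes the planted disease genes
    rank no better than chance."""
    comp_a, comp_b, orthomap, truth = compendium
    conserved = conserve_network(
        build_species_network(comp_a), build_species_network(comp_b), orthomap
    )
    rng = np.random.default_rng(5)
    module_genes = {g for m in truth.planted_modules for g in m}
    non_module = sorted(set(conserved.nodes) - module_genes)
    fake_refs = set(rng.choice(non_module, size=len(truth.reference_genes), replace=False))
    scored = prioritize_candidates(
        set(conserved.nodes) - fake_refs, conserved, fake_refs
    )
    disease = [s for s in scored if s.gene in truth.disease_genes]
    assert all(s.adj_p > 0.1 for s in disease)
    assert {s.n_ref_neighbors for s in disease} == {0}
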
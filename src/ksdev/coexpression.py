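"""Conserved co-expression networks and disease-gene prioritization.

Per-species co-expression graphs are built with a reciprocal top-k
correlation rule; the conserved network keeps the edges present in both
species after one-to-one ortholog mapping. Candidate disease genes are
prioritized by guilt-by-association: how many known disease ("reference")
genes sit among a candidate's conserved-network neighbors, tested with a
hypergeometric tail and Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ksdev.matrix import ExpressionMatrix
from ksdev.stats import bh_adjust, hypergeom_overlap


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one ortholog pairs between species A and B."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("ortholog map must be injective in both directions")

    @property
    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    @property
    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    @classmethod
    def read_tsv(cls, path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], comment="#")
        return cls(tuple(zip(df["a"], df["b"])))


@dataclass
class CandidateScore:
    gene: str
    n_ref_neighbors: int
    degree: int
    p: float
    adj_p: float = 1.0
    rank: int = 0
    in_network: bool = True


def build_species_network(
    comp: ExpressionMatrix,
    method: str = "spearman",
    top_k: int = 10,
    min_abs_rho: float = 0.5,
) -> nx.Graph:
    """Reciprocal top-k correlation graph.

    Edge (i, j) exists iff j is among i's ``top_k`` strongest partners by
    |rho| AND vice versa AND |rho| >= ``min_abs_rho``. Constant genes have
    undefined correlations and get no edges.
    """
    n_samples = len(comp.sample_ids)
    if n_samples < 3:
        raise ValueError("need at least three samples to correlate")
    if n_samples < 10:
        warnings.warn(f"only {n_samples} samples; correlations will be noisy")
    values = comp.values
    variable = values.std(axis=1) > 0
    if not variable.all():
        warnings.warn(f"{(~variable).sum()} constant gene(s) excluded from the network")
    sub = values.loc[variable]
    rho = sub.T.corr(method=method)
    np.fill_diagonal(rho.to_numpy(), 0.0)
    absrho = rho.abs().to_numpy()
    genes = list(rho.index)
    n = len(genes)
    k = min(top_k, n - 1)
    # top-k partner mask per row
    order = np.argsort(-absrho, axis=1, kind="stable")
    topmask = np.zeros_like(absrho, dtype=bool)
    rows = np.repeat(np.arange(n), k)
    topmask[rows, order[:, :k].ravel()] = True
    keep = topmask & topmask.T & (absrho >= min_abs_rho)
    g = nx.Graph(species=getattr(comp, "species", None))
    g.add_nodes_from(values.index)  # constant genes stay isolated
    ii, jj = np.nonzero(np.triu(keep, 1))
    g.add_edges_from(
        (genes[i], genes[j], {"weight": float(rho.iat[i, j])}) for i, j in zip(ii, jj)
    )
    return g


def conserve_network(net_a: nx.Graph, net_b: nx.Graph, orthomap: OrthologMap) -> nx.Graph:
    """Edges present in both species layers, on species-A gene ids.

    Nodes are the ortholog-mapped genes present in both layers; an edge is
    conserved iff both endpoints map and the mapped edge exists in the
    other species' network.
    """
    if not orthomap.pairs:
        raise ValueError("empty ortholog map")
    a2b = orthomap.a_to_b
    conserved = nx.Graph()
    conserved.add_nodes_from(a for a in net_a.nodes if a in a2b and a2b[a] in net_b)
    for u, v, data in net_a.edges(data=True):
        bu, bv = a2b.get(u), a2b.get(v)
        if bu is None or bv is None:
            continue
        if net_b.has_edge(bu, bv):
            conserved.add_edge(
                u, v, rho_a=data.get("weight"), rho_b=net_b.edges[bu, bv].get("weight")
            )
    return conserved


def reference_neighbor_counts(net: nx.Graph, refs: set[str]) -> pd.Series:
    """k(g) = number of reference genes adjacent to g, for every node."""
    present = refs & set(net.nodes)
    missing = refs - present
    if missing:
        warnings.warn(f"{len(missing)} reference gene(s) absent from the network: "
                      f"{sorted(missing)[:5]}...")
    counts = {g: sum(1 for nb in net.neighbors(g) if nb in present) for g in net.nodes}
    return pd.Series(counts, name="n_ref_neighbors").sort_index()


def extract_connected(net: nx.Graph, refs: set[str], min_k: int) -> set[str]:
    """Non-reference genes adjacent to at least ``min_k`` reference genes."""
    if min_k < 1:
        raise ValueError("min_k must be >= 1")
    k = reference_neighbor_counts(net, refs)
    return {g for g, kk in k.items() if kk >= min_k and g not in refs}


def prioritize_candidates(
    deg_list: set[str], net: nx.Graph, refs: set[str], alpha: float = 0.05
) -> list[CandidateScore]:
    """Rank candidate genes by reference-gene enrichment in their
    conserved-network neighborhood.

    For candidate g with degree d and k reference neighbors, p is the
    hypergeometric upper tail of drawing >= k references among d neighbors
    from the |nodes|−1 other genes, of which |refs ∩ nodes| are references.
    p-values are BH-adjusted across the candidate list; ranking is adj_p
    ascending, then k descending, then gene id. Genes absent from the
    network are reported with p = 1.
    """
    if not deg_list:
        return []
    nodes = set(net.nodes)
    present_refs = refs & nodes
    N = len(nodes) - 1
    scores: list[CandidateScore] = []
    for gene in sorted(deg_list):
        if gene not in nodes:
            scores.append(CandidateScore(gene, 0, 0, p=1.0, in_network=False))
            continue
        neighbors = set(net.neighbors(gene))
        k = len(neighbors & present_refs)
        d = len(neighbors)
        K = len(present_refs - {gene})
        p = 1.0 if d == 0 else hypergeom_overlap(k=k, n=d, K=K, N=N).p_upper
        scores.append(CandidateScore(gene, k, d, p=float(p)))
    adj = bh_adjust([s.p for s in scores])
    for s, a in zip(scores, adj):
        s.adj_p = float(a)
    scores.sort(key=lambda s: (s.adj_p, -s.n_ref_neighbors, s.gene))
    for i, s in enumerate(scores, 1):
        s.rank = i
    return scores


def network_to_tsv(net: nx.Graph, path) -> None:
    rows = [
        {"gene_a": u, "gene_b": v, "rho_a": d.get("rho_a", d.get("weight")), "rho_b": d.get("rho_b")}
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho_a", "rho_b"]).to_csv(
        path, sep="\t", index=False
    )
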
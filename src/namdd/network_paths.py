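"""Tripartite association network and site-gene-disease path ranking.

Sites, genes and the single disease node form a directed tripartite graph;
an edge is present when its stability score reaches the threshold phi.  A
path is a length-2 chain site -> gene -> disease and its score is the sum
of its two edge scores, so every path score lies in [2 phi, 2].  Paths are
enumerated exhaustively (exact in this tripartite setting) and the K
highest-scoring ones reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core_io import ValidationError
from .stability import EdgeScoreSet

__all__ = ["PathAssociation", "build_network", "top_k_paths", "DISEASE_NODE"]

DISEASE_NODE = "disease"


@dataclass(frozen=True)
class PathAssociation:
    site_id: str
    gene_id: str
    mg_score: float
    gd_score: float

    @property
    def path_score(self) -> float:
        return self.mg_score + self.gd_score


def build_network(edges: EdgeScoreSet, phi: float | None = None) -> nx.DiGraph:
    """Directed graph with exactly the edges whose score is >= phi.

    Node attribute ``layer`` is one of {"site", "gene", "disease"}; edge
    attribute ``score`` carries the stability score.
    """
    phi = edges.phi if phi is None else phi
    mg = np.asarray(edges.mg_scores)
    gd = np.asarray(edges.gd_scores)
    P, Q = mg.shape
    site_ids = edges.site_ids or [f"site{p}" for p in range(P)]
    gene_ids = edges.gene_ids or [f"gene{q}" for q in range(Q)]
    g = nx.DiGraph()
    g.add_nodes_from(site_ids, layer="site")
    g.add_nodes_from(gene_ids, layer="gene")
    g.add_node(DISEASE_NODE, layer="disease")
    rows, cols = np.nonzero(mg >= phi)
    g.add_edges_from(
        (site_ids[p], gene_ids[q], {"score": float(mg[p, q])})
        for p, q in zip(rows, cols)
    )
    g.add_edges_from(
        (gene_ids[q], DISEASE_NODE, {"score": float(gd[q])})
        for q in np.flatnonzero(gd >= phi)
    )
    return g


def top_k_paths(network: nx.DiGraph, K: int) -> list[PathAssociation]:
    """Up to K highest-scoring site -> gene -> disease paths.

    Every (site, gene) pair with both the site-gene edge and the gene's
    disease edge present forms a path; its score is the sum of the two edge
    scores.  Sorted by descending score, ties broken by (gene_id, site_id)
    lexicographically.  Empty list when no path exists.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    paths: list[PathAssociation] = []
    for gene, _, gd_score in network.in_edges(DISEASE_NODE, data="score"):
        for site, _, mg_score in network.in_edges(gene, data="score"):
            if network.nodes[site].get("layer") != "site":
                continue
            paths.append(PathAssociation(site, gene, float(mg_score), float(gd_score)))
    paths.sort(key=lambda p: (-p.path_score, p.gene_id, p.site_id))
    return paths[:K]
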
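"""Disease semantic similarity from MeSH-style disease DAGs.

Each disease ``D`` is described by a directed acyclic graph whose nodes
are ``D`` itself plus its ancestor terms, with edges stored
child -> parent.  Every term ``d`` in the DAG contributes to ``D``'s
semantic value with a score that decays by a factor ``delta`` per level
of separation:

    Contribution_D(D) = 1
    Contribution_D(d) = delta * max{ Contribution_D(d') : d' child of d }

where the children of ``d`` are the DAG-internal nodes one level closer
to ``D``.  The semantic value DV(D) is the sum of all contributions, and
the similarity of two diseases is the contribution mass of their shared
terms relative to their total semantic values:

    SD(d_i, d_j) = sum_{t in T_i ∩ T_j} (C_i(t) + C_j(t)) / (DV_i + DV_j)

which lies in [0, 1], equals 1 for identical DAGs and 0 for disjoint
node sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .containers import SimilarityMatrix
from .data_io import DagEdgeList

__all__ = [
    "SemanticParams",
    "contributions",
    "semantic_value",
    "semantic_similarity",
    "semantic_similarity_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SemanticParams:
    """Parameters of the semantic contribution recursion.

    delta is the per-level decay of a term's contribution; the
    conventional value is 0.5.
    """

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie strictly between 0 and 1")


def contributions(
    disease: str,
    edges: list[tuple[str, str]],
    params: SemanticParams = SemanticParams(),
) -> dict[str, float]:
    """Contribution of every DAG term to the disease's semantic value.

    Terms not reachable from the disease via child->parent edges are
    not ancestors; they are excluded with a warning.
    """
    g = nx.DiGraph(edges)
    g.add_node(disease)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError(f"DAG for disease {disease!r} contains a cycle")
    reachable = {disease} | nx.descendants(g, disease)
    dropped = set(g.nodes) - reachable
    if dropped:
        logger.warning(
            "disease %r: %d term(s) unreachable from the disease term "
            "excluded: %s", disease, len(dropped), sorted(dropped)[:5],
        )
    sub = g.subgraph(reachable)
    contrib: dict[str, float] = {}
    # child->parent edges point away from the disease, so a topological
    # order of the subgraph visits each term after all of its children
    for term in nx.topological_sort(sub):
        if term == disease:
            contrib[term] = 1.0
        else:
            children = [c for c, _ in sub.in_edges(term)]
            contrib[term] = params.delta * max(contrib[c] for c in children)
    return contrib


def semantic_value(contribs: dict[str, float]) -> float:
    """Semantic value DV = sum of all term contributions (>= 1)."""
    if not contribs:
        raise ValueError("empty contribution map")
    return float(sum(contribs.values()))


def semantic_similarity(
    disease_i: str,
    edges_i: list[tuple[str, str]],
    disease_j: str,
    edges_j: list[tuple[str, str]],
    params: SemanticParams = SemanticParams(),
) -> float:
    """Semantic similarity between two diseases from their DAGs."""
    ci = contributions(disease_i, edges_i, params)
    cj = contributions(disease_j, edges_j, params)
    shared = set(ci) & set(cj)
    if not shared:
        return 0.0
    num = sum(ci[t] + cj[t] for t in shared)
    return float(num / (semantic_value(ci) + semantic_value(cj)))


def semantic_similarity_matrix(
    dags: DagEdgeList, params: SemanticParams = SemanticParams()
) -> SimilarityMatrix:
    """Pairwise disease semantic similarity matrix (role disease_semantic)."""
    if not dags:
        raise ValueError("no disease DAGs supplied")
    diseases = list(dags)
    maps = {d: contributions(d, dags[d], params) for d in diseases}
    dvs = {d: semantic_value(maps[d]) for d in diseases}
    n = len(diseases)
    sd = np.eye(n)
    for a in range(n):
        ca = maps[diseases[a]]
        for b in range(a + 1, n):
            cb = maps[diseases[b]]
            shared = set(ca) & set(cb)
            if shared:
                num = sum(ca[t] + cb[t] for t in shared)
                sd[a, b] = sd[b, a] = num / (dvs[diseases[a]] + dvs[diseases[b]])
    return SimilarityMatrix(sd, diseases, "disease_semantic")
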
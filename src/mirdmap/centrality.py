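"""Weighted centrality measures and consensus hub identification.

Seven centrality measures are computed on the edge-weighted undirected
enrichment network: degree (sum of incident weights), betweenness and
closeness (shortest paths under distance = 1/weight, so stronger enrichment
means closer), eigenvector (principal eigenvector of the weighted adjacency
by power iteration), network centrality (sum of edge clustering
coefficients over incident edges), local average connectivity (mean
neighbourhood-internal degree of a node's neighbours), and information
centrality (current-flow closeness with weights as conductances).

A node's consensus support is the number of measures whose top-T list
contains it; nodes supported by at least ``min_agreement`` measures are the
consensus hubs. Optionally, Monte-Carlo edge-percolation centrality scores
a node's expected connectivity under random edge retention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .network import EdgeRecord, read_edges

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "CentralityReport",
    "build_graph",
    "centrality_suite",
    "epc",
    "consensus",
    "rank_scores",
    "hubs_from_edge_file",
]

MEASURES = (
    "degree",
    "betweenness",
    "closeness",
    "eigenvector",
    "network",
    "local_average",
    "information",
)


def build_graph(
    edges: Iterable[EdgeRecord | tuple[str, str, float]],
    inf_policy: str = "max-finite",
) -> nx.Graph:
    """Build a simple undirected weighted graph from edge records.

    Weights must be positive; non-finite weights (the odds-ratio ``Inf``
    sentinel) are replaced by the maximum finite weight in the input
    (``inf_policy='max-finite'``, the default) or by a caller-supplied
    constant when ``inf_policy`` is a number. Self-loops are rejected,
    parallel edges keep the larger weight.
    """
    triples: list[tuple[str, str, float]] = []
    for e in edges:
        if isinstance(e, EdgeRecord):
            triples.append((e.u, e.v, e.weight))
        else:
            u, v, w = e
            triples.append((u, v, float(w)))
    finite = [w for _, _, w in triples if math.isfinite(w)]
    if inf_policy == "max-finite":
        fill = max(finite) if finite else 1.0
    else:
        fill = float(inf_policy)
    g = nx.Graph()
    for u, v, w in triples:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        if not math.isfinite(w):
            w = fill
        if w <= 0:
            raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
        if g.has_edge(u, v):
            w = max(w, g[u][v]["weight"])
        g.add_edge(u, v, weight=w, dist=1.0 / w)
    return g


def _eigenvector(g: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000) -> dict[str, float]:
    """Principal eigenvector of the weighted adjacency, power iteration.

    Non-negative, normalised to unit max-norm; concentrates on the dominant
    component of a disconnected graph.
    """
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    x = np.ones(len(nodes))
    for _ in range(max_iter):
        y = a @ x
        norm = np.max(np.abs(y))
        if norm == 0:
            break
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    m = x.max()
    if m > 0:
        x = x / m
    return dict(zip(nodes, x.tolist()))


def _edge_clustering(g: nx.Graph, u: str, v: str) -> float:
    """Edge clustering coefficient: triangles through (u,v), weighted by the
    geometric mean of the three edge weights, over min(deg_u, deg_v) − 1.

    Zero when the smaller endpoint degree is 1 (no triangle is possible
    through a pendant edge, so numerator and fallback agree at 0).
    """
    denom = min(g.degree(u), g.degree(v)) - 1
    if denom <= 0:
        return 0.0
    common = set(g[u]) & set(g[v])
    wuv = g[u][v]["weight"]
    tri = sum(
        (wuv * g[u][w]["weight"] * g[v][w]["weight"]) ** (1.0 / 3.0) for w in common
    )
    return tri / denom


def _network_centrality(g: nx.Graph) -> dict[str, float]:
    """NC(v) = sum of edge clustering coefficients of v's incident edges."""
    return {
        v: sum(_edge_clustering(g, v, u) for u in g[v]) for v in g.nodes
    }


def _local_average(g: nx.Graph) -> dict[str, float]:
    """LAC(v): mean degree of v's neighbours within the subgraph they induce."""
    out: dict[str, float] = {}
    for v in g.nodes:
        nbrs = list(g[v])
        if not nbrs:
            out[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        out[v] = sum(sub.degree(u) for u in nbrs) / len(nbrs)
    return out


def _information(g: nx.Graph) -> dict[str, float]:
    """Current-flow closeness per connected component; isolated nodes score 0."""
    scores = {v: 0.0 for v in g.nodes}
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        scores.update(nx.information_centrality(sub, weight="weight"))
    return scores


def centrality_suite(g: nx.Graph) -> dict[str, dict[str, float]]:
    """All seven weighted centrality score vectors, keyed by measure name."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    suite = {
        "degree": {v: float(d) for v, d in g.degree(weight="weight")},
        "betweenness": nx.betweenness_centrality(g, weight="dist", normalized=False),
        "closeness": nx.closeness_centrality(g, distance="dist"),
        "eigenvector": _eigenvector(g),
        "network": _network_centrality(g),
        "local_average": _local_average(g),
        "information": _information(g),
    }
    return {m: {v: float(s) for v, s in sc.items()} for m, sc in suite.items()}


def epc(
    g: nx.Graph, reps: int = 1000, seed: int = 0, retain: float = 0.5
) -> dict[str, float]:
    """Monte-Carlo edge-percolation centrality.

    Each replicate retains every edge independently with probability
    ``retain · w_e / max(w)`` — proportional to the max-normalised weight,
    scaled by a base retention probability so that even the heaviest edge
    can fail. A node's score is its mean connectivity — the number of
    other nodes in its percolated component — across replicates.
    Deterministic given (graph, reps, seed, retain).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 < retain <= 1.0:
        raise ValueError("retain must lie in (0, 1]")
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v], d["weight"]) for u, v, d in g.edges(data=True)]
    if not edges:
        return {v: 0.0 for v in nodes}
    w = np.array([e[2] for e in edges])
    retain_p = retain * w / w.max()
    eu = np.array([e[0] for e in edges])
    ev = np.array([e[1] for e in edges])
    rng = np.random.default_rng(seed)
    n = len(nodes)
    totals = np.zeros(n)

    parent = np.empty(n, dtype=np.int64)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for _ in range(reps):
        keep = rng.random(len(edges)) < retain_p
        parent[:] = np.arange(n)
        for a, b in zip(eu[keep], ev[keep]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
        sizes = np.bincount(roots, minlength=n)
        totals += sizes[roots] - 1
    return dict(zip(nodes, (totals / reps).tolist()))


def rank_scores(scores: Mapping[str, float]) -> dict[str, int]:
    """Ranks 1..N by score descending, ties broken by node name."""
    ordered = sorted(scores.items(), key=lambda it: (-it[1], it[0]))
    return {v: r for r, (v, _) in enumerate(ordered, start=1)}


@dataclass(frozen=True)
class CentralityReport:
    """Per-measure scores and ranks, agreement counts, and the consensus list."""

    scores: dict[str, dict[str, float]]
    ranks: dict[str, dict[str, int]]
    agreement: dict[str, int]
    consensus: list[str]
    top_t: int
    min_agreement: int


def consensus(
    scores: Mapping[str, Mapping[str, float]],
    top_t: int = 100,
    min_agreement: int = 5,
) -> CentralityReport:
    """Consensus hubs: nodes in the top-T of at least ``min_agreement`` measures.

    Per measure the top-T nodes are taken with ties broken by name; a node's
    agreement is the number of measures listing it. The consensus list is
    sorted by agreement descending, then name.
    """
    if top_t < 1:
        raise ValueError("top_t must be >= 1")
    measures = sorted(scores)
    if min_agreement > len(measures):
        raise ValueError(
            f"min_agreement={min_agreement} exceeds the {len(measures)} measures given"
        )
    ranks = {m: rank_scores(scores[m]) for m in measures}
    agreement: dict[str, int] = {}
    for m in measures:
        for v, r in ranks[m].items():
            if r <= top_t:
                agreement[v] = agreement.get(v, 0) + 1
    hubs = sorted(
        (v for v, c in agreement.items() if c >= min_agreement),
        key=lambda v: (-agreement[v], v),
    )
    return CentralityReport(
        scores={m: dict(scores[m]) for m in measures},
        ranks=ranks,
        agreement=agreement,
        consensus=hubs,
        top_t=top_t,
        min_agreement=min_agreement,
    )


def hubs_from_edge_file(
    path: str | Path,
    top_t: int = 100,
    min_agreement: int = 5,
    with_epc: bool = False,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[CentralityReport, dict[str, float] | None]:
    """Convenience: read an exported edge TSV and run the consensus analysis."""
    g = build_graph(read_edges(path))
    report = consensus(centrality_suite(g), top_t=top_t, min_agreement=min_agreement)
    epc_scores = epc(g, reps=reps, seed=seed) if with_epc else None
    return report, epc_scores
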
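"""Pairwise overlap-enrichment networks.

Every unordered pair of miRNAs (or diseases) is scored for overlap of their
association sets against the full opposite universe with the one-sided
Fisher exact test: for miRNAs u, v over D_N diseases,
a = |D(u) ∩ D(v)|, b = |D(u)| − a, c = |D(v)| − a, d = D_N − a − b − c.
p-values are Benjamini–Hochberg-corrected across all scored pairs, edges
with q ≤ alpha are retained, ranked by −log10 p, and the top-k kept as a
weighted edge list (weight = odds ratio) importable by Cytoscape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .enrichment import ContingencyTable, adjust_pvalues, fisher_pvalue, odds_ratio
from .mapping import AssociationDB, AssociationMap

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeRecord",
    "NetworkResult",
    "pair_score",
    "build_network",
    "export_edges",
    "read_edges",
]

NEG_LOG10_CAP = 320.0  # −log10 p for p that underflows double precision


@dataclass(frozen=True)
class EdgeRecord:
    """One retained pair: nodes (u < v), p, q, odds-ratio weight, rank score."""

    u: str
    v: str
    p: float
    q: float
    weight: float
    neg_log10_p: float


@dataclass(frozen=True)
class NetworkResult:
    """Retained edge list plus the bookkeeping of the full pairwise scan."""

    edges: list[EdgeRecord]
    n_nodes: int
    n_tests: int
    n_significant: int

    def node_names(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.u)
            out.add(e.v)
        return out


def _mode_map(db: AssociationDB, mode: str) -> tuple[AssociationMap, int]:
    m = mode.lower()
    if m in ("mirna", "mir"):
        return db.forward, db.n_diseases
    if m == "disease":
        return db.inverse, db.n_mirnas
    raise ValueError(f"mode must be 'mirna' or 'disease', got {mode!r}")


def pair_score(
    db: AssociationDB, u: str, v: str, mode: str = "mirna"
) -> tuple[ContingencyTable, float, float]:
    """Overlap-enrichment score of one node pair: (table, p, odds ratio).

    Symmetric up to the a↔a, b↔c relabelling, so p and the odds ratio are
    identical for (u, v) and (v, u).
    """
    amap, universe = _mode_map(db, mode)
    for node in (u, v):
        if node not in amap:
            raise KeyError(f"unknown {mode} node {node!r}")
    if u == v:
        raise ValueError("pair nodes must differ")
    su, sv = amap[u], amap[v]
    a = len(su & sv)
    b = len(su) - a
    c = len(sv) - a
    t = ContingencyTable(a=a, b=b, c=c, d=universe - a - b - c)
    return t, fisher_pvalue(t), odds_ratio(t)


def _neg_log10(p: float) -> float:
    if p <= 0.0 or -math.log10(p) > NEG_LOG10_CAP:
        return NEG_LOG10_CAP
    return -math.log10(p)


def build_network(
    db: AssociationDB,
    mode: str = "mirna",
    top_k: int = 10_000,
    alpha: float = 0.05,
) -> NetworkResult:
    """Score all unordered node pairs and keep the top-k significant edges.

    All N·(N−1)/2 pairs are tested; BH correction runs across the full
    family of scored pairs. Edges with q ≤ alpha are sorted by −log10 p
    descending (ties: p ascending, then odds ratio descending among
    underflowed p, then node names) and truncated to ``top_k``.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    amap, universe = _mode_map(db, mode)
    nodes = sorted(amap.keys())
    if len(nodes) < 2:
        raise ValueError(f"need at least 2 {mode} nodes, have {len(nodes)}")

    sizes = {n: len(amap[n]) for n in nodes}
    pairs = list(combinations(nodes, 2))
    a_arr = np.fromiter(
        (len(amap[u] & amap[v]) for u, v in pairs), dtype=np.int64, count=len(pairs)
    )
    su = np.fromiter((sizes[u] for u, _ in pairs), dtype=np.int64, count=len(pairs))
    sv = np.fromiter((sizes[v] for _, v in pairs), dtype=np.int64, count=len(pairs))
    ps = hypergeom.sf(a_arr - 1, universe, su, sv)
    ps = np.clip(ps, np.nextafter(0, 1), 1.0)
    qs = adjust_pvalues(ps, method="bh")

    edges: list[EdgeRecord] = []
    for (u, v), a, n1, n2, p, q in zip(pairs, a_arr, su, sv, ps, qs):
        if q > alpha:
            continue
        t = ContingencyTable(
            a=int(a), b=int(n1 - a), c=int(n2 - a), d=int(universe - n1 - n2 + a)
        )
        edges.append(
            EdgeRecord(
                u=u, v=v, p=float(p), q=float(q),
                weight=odds_ratio(t), neg_log10_p=_neg_log10(float(p)),
            )
        )

    def key(e: EdgeRecord):
        # -log10 p descending == p ascending; among underflow-capped p,
        # fall back to odds ratio descending, then lexicographic names
        w = e.weight if not math.isnan(e.weight) else -math.inf
        return (-e.neg_log10_p, e.p, -w, e.u, e.v)

    edges.sort(key=key)
    n_significant = len(edges)
    edges = edges[:top_k]
    if not n_significant:
        logger.warning("no significant %s pairs at alpha=%g", mode, alpha)
    logger.info(
        "%s network: %d nodes, %d tests, %d significant, %d retained",
        mode, len(nodes), len(pairs), n_significant, len(edges),
    )
    return NetworkResult(
        edges=edges,
        n_nodes=len(nodes),
        n_tests=len(pairs),
        n_significant=n_significant,
    )


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "Inf"
    if math.isnan(x):
        return "NA"
    return repr(x)


def export_edges(edges: list[EdgeRecord], path: str | Path) -> Path:
    """Write the edge list as a Cytoscape-importable TSV, order preserved."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tweight\tp\tq\tneg_log10_p\n")
        for e in edges:
            fh.write(
                f"{e.u}\t{e.v}\t{_fmt(e.weight)}\t{_fmt(e.p)}\t{_fmt(e.q)}\t"
                f"{_fmt(e.neg_log10_p)}\n"
            )
    return path


def _parse(x: str) -> float:
    if x == "Inf":
        return math.inf
    if x == "NA":
        return math.nan
    return float(x)


def read_edges(path: str | Path) -> list[EdgeRecord]:
    """Read back an edge TSV written by :func:`export_edges`."""
    edges: list[EdgeRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["source", "target"]:
            raise ValueError(f"unexpected edge-table header in {path}: {header}")
        for line in fh:
            u, v, w, p, q, nlp = line.rstrip("\n").split("\t")
            edges.append(
                EdgeRecord(
                    u=u, v=v, p=_parse(p), q=_parse(q),
                    weight=_parse(w), neg_log10_p=_parse(nlp),
                )
            )
    return edges
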
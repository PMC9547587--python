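"""Disease enrichment of a miRNA list.

For every disease in the database a 2×2 contingency table is built from the
input miRNA list against the disease's associated-miRNA set, over the full
miRNA universe:

====================  =======================  ===========================
..                    associated with disease  not associated with disease
====================  =======================  ===========================
miRNAs in input       a                        b
miRNAs not in input   c                        d
====================  =======================  ===========================

Significance is the one-sided upper-tail hypergeometric probability
P(X ≥ a) — identical to the one-sided Fisher exact test — and effect size
is the sample odds ratio (a·d)/(b·c), with an ``inf`` sentinel when every
input miRNA is associated with the disease (b = 0) and ``nan`` when the
ratio is the indeterminate 0/0. p-values are corrected across all tested
diseases (Bonferroni, Holm, or Benjamini–Hochberg, the default) and records
passing the adjusted-significance threshold are returned sorted by q-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mapping import AssociationDB

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentRecord",
    "build_contingency",
    "fisher_pvalue",
    "odds_ratio",
    "adjust_pvalues",
    "enrich",
]

_METHODS = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}


@dataclass(frozen=True)
class ContingencyTable:
    """The four cell counts of the 2×2 enrichment table."""

    a: int  # in input and associated
    b: int  # in input, not associated
    c: int  # not in input, associated
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell count in {self}")
        if self.n == 0:
            raise ValueError("contingency table must have a positive total")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentRecord:
    """One tested disease: contingency counts, raw p, adjusted q, effect size."""

    target: str
    table: ContingencyTable
    p: float
    q: float
    odds_ratio: float

    @property
    def log2_odds_ratio(self) -> float:
        """log2 effect size; propagates the inf/nan sentinels of the ratio."""
        if math.isnan(self.odds_ratio):
            return math.nan
        if self.odds_ratio == 0.0:
            return -math.inf
        return math.log2(self.odds_ratio)


def build_contingency(
    db: AssociationDB, input_set: Iterable[str], disease: str
) -> ContingencyTable:
    """Contingency counts for one disease against a db-resident input set."""
    inp = set(input_set)
    if not inp:
        raise ValueError("no input miRNAs found in database")
    unknown = sorted(m for m in inp if m not in db.forward)
    if unknown:
        raise KeyError(f"input miRNAs not in database: {unknown}")
    if disease not in db.inverse:
        raise KeyError(f"unknown disease {disease!r}")
    assoc = db.inverse[disease]
    a = len(inp & assoc)
    b = len(inp) - a
    c = len(assoc) - a
    d = db.n_mirnas - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def fisher_pvalue(t: ContingencyTable) -> float:
    """One-sided upper-tail p: P(X ≥ a), X ~ Hypergeom(n, a+c, a+b)."""
    return float(np.clip(hypergeom.sf(t.a - 1, t.n, t.a + t.c, t.a + t.b), 0.0, 1.0))


def odds_ratio(t: ContingencyTable) -> float:
    """Sample cross-product ratio (a·d)/(b·c) with explicit sentinels.

    ``inf`` when a·d > 0 and b·c = 0 (in particular b = 0: the whole input
    list is contained in the disease's miRNA set); 0 when a·d = 0 and
    b·c > 0; ``nan`` for the indeterminate 0/0. No continuity correction.
    """
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def adjust_pvalues(ps: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjusted q-values, in the input order.

    ``bonferroni``: min(1, m·p). ``holm``: step-down with running max.
    ``bh``: Benjamini–Hochberg step-up. All satisfy q ≥ p.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.ndim != 1 or ps.size < 1:
        raise ValueError("ps must be a non-empty 1-d sequence")
    if np.any((ps <= 0.0) | (ps > 1.0)) or np.any(np.isnan(ps)):
        raise ValueError("p-values must lie in (0, 1]")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}, got {method!r}")
    return multipletests(ps, method=_METHODS[method])[1]


def resolve_mirnas(db: AssociationDB, mirnas: Iterable[str]) -> tuple[set[str], list[str]]:
    """Match input names to db miRNA keys case-insensitively.

    Returns the resolved db-key set and the sorted list of rejects.
    """
    lower = {}
    for key in db.forward.keys():
        lower.setdefault(key.lower(), key)
    resolved: set[str] = set()
    rejects: list[str] = []
    for name in mirnas:
        name = name.strip()
        if not name:
            continue
        hit = lower.get(name.lower())
        if hit is None:
            rejects.append(name)
        else:
            resolved.add(hit)
    return resolved, sorted(set(rejects))


def _sort_key(rec: EnrichmentRecord):
    # q ascending, then odds ratio descending (nan last), then name
    orx = rec.odds_ratio if not math.isnan(rec.odds_ratio) else -math.inf
    return (rec.q, -orx, rec.target)


def enrich(
    db: AssociationDB,
    mirnas: Iterable[str],
    alpha: float = 0.05,
    method: str = "bh",
) -> list[EnrichmentRecord]:
    """Test every disease in the database for enrichment of a miRNA list.

    Unknown input names are dropped with a warning; at least one must
    resolve. The hypothesis family is all D_N diseases. Records with
    q ≤ alpha are returned sorted ascending by q, ties broken by descending
    odds ratio then disease name.
    """
    resolved, rejects = resolve_mirnas(db, mirnas)
    if rejects:
        logger.warning("dropping %d input miRNAs not in database: %s", len(rejects), rejects)
    if not resolved:
        raise ValueError(f"no input miRNAs found in database; rejects: {rejects}")

    diseases = db.diseases()
    tables = [build_contingency(db, resolved, d) for d in diseases]
    a = np.array([t.a for t in tables])
    draws = np.array([t.a + t.b for t in tables])
    succ = np.array([t.a + t.c for t in tables])
    ps = np.clip(hypergeom.sf(a - 1, db.n_mirnas, succ, draws), np.nextafter(0, 1), 1.0)
    qs = adjust_pvalues(ps, method=method)
    records = [
        EnrichmentRecord(target=d, table=t, p=float(p), q=float(q), odds_ratio=odds_ratio(t))
        for d, t, p, q in zip(diseases, tables, ps, qs)
    ]
    records = [r for r in records if r.q <= alpha]
    records.sort(key=_sort_key)
    return records
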
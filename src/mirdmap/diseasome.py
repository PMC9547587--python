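"""Diseasome selection and miRNA abundance profiling.

A diseasome is a user-defined set of related diseases, given either as an
explicit name list or as a keyword/regex over disease names (e.g. every
disease containing "neoplasm"). The abundance profile counts, for each
miRNA, in how many diseasome diseases it occurs; miRNAs passing a count
threshold are candidate shared regulators of the disease set. This is pure
occurrence counting — significance testing lives in the enrichment module.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .mapping import AssociationDB

logger = logging.getLogger(__name__)

__all__ = ["AbundanceRecord", "select_diseasome", "abundance", "multi_keyword_table"]


@dataclass(frozen=True)
class AbundanceRecord:
    mirna: str
    occurrence: int


def select_diseasome(
    db: AssociationDB,
    keyword: str | None = None,
    diseases: Iterable[str] | None = None,
) -> set[str]:
    """Resolve a diseasome from a keyword pattern or an explicit name list.

    Keyword mode applies a case-insensitive unanchored regex over disease
    names. Explicit mode resolves names case-insensitively; unknown names
    are reported and skipped. An empty result is a hard error.
    """
    if (keyword is None) == (diseases is None):
        raise ValueError("give exactly one of keyword= or diseases=")
    if keyword is not None:
        try:
            rx = re.compile(keyword, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(
                f"invalid keyword for the Python 're' regex dialect: {keyword!r} ({exc})"
            ) from exc
        selected = {d for d in db.inverse.keys() if rx.search(d)}
        if not selected:
            raise ValueError(f"no disease matches keyword {keyword!r}")
        return selected
    lower = {}
    for d in db.inverse.keys():
        lower.setdefault(d.lower(), d)
    selected = set()
    unknown = []
    for name in diseases:
        name = name.strip()
        if not name:
            continue
        hit = lower.get(name.lower())
        if hit is None:
            unknown.append(name)
        else:
            selected.add(hit)
    if unknown:
        logger.warning("diseasome names not in database: %s", sorted(set(unknown)))
    if not selected:
        raise ValueError(f"no diseasome disease resolved from {sorted(set(unknown))}")
    return selected


def abundance(
    db: AssociationDB, diseasome: Iterable[str], min_count: int = 1
) -> list[AbundanceRecord]:
    """Count diseasome occurrences per miRNA and threshold at ``min_count``.

    occurrence(m) = number of diseasome diseases whose miRNA set contains m.
    Records are sorted descending by occurrence, ties by miRNA name.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    diseasome = set(diseasome)
    unknown = sorted(d for d in diseasome if d not in db.inverse)
    if unknown:
        raise KeyError(f"diseasome diseases not in database: {unknown}")
    counts: dict[str, int] = {}
    for d in diseasome:
        for m in db.inverse[d]:
            counts[m] = counts.get(m, 0) + 1
    records = [
        AbundanceRecord(mirna=m, occurrence=c)
        for m, c in counts.items()
        if c >= min_count
    ]
    records.sort(key=lambda r: (-r.occurrence, r.mirna))
    return records


def multi_keyword_table(
    db: AssociationDB,
    keywords: Sequence[str],
    min_count: int = 1,
    rank_by: str | None = None,
) -> list[dict]:
    """Cross-keyword abundance report: one occurrence column per keyword.

    Rows are the miRNAs passing ``min_count`` under the ranking keyword
    (the first by default), ordered by that keyword's abundance; a keyword
    column holds ``None`` where the miRNA falls below threshold there.
    """
    if not keywords:
        raise ValueError("at least one keyword required")
    rank_by = rank_by or keywords[0]
    if rank_by not in keywords:
        raise ValueError(f"rank_by {rank_by!r} not among keywords")
    per_kw = {
        kw: {r.mirna: r.occurrence for r in abundance(db, select_diseasome(db, keyword=kw), min_count)}
        for kw in keywords
    }
    rows = []
    ranked = sorted(per_kw[rank_by].items(), key=lambda it: (-it[1], it[0]))
    for rank, (mirna, occ) in enumerate(ranked, start=1):
        row = {"rank": rank, "mirna": mirna, rank_by: occ}
        for kw in keywords:
            if kw != rank_by:
                row[kw] = per_kw[kw].get(mirna)
        rows.append(row)
    return rows
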
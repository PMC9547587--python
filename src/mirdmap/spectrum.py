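"""Disease and miRNA spectrum widths.

The disease spectrum width of a miRNA is the fraction of all database
diseases it is associated with, DSW(i) = d_i / D_N; a high DSW flags a
putative master-regulator miRNA. Symmetrically, the miRNA spectrum width
of a disease, MSW(j) = m_j / M_N, flags multifactorial pathologies touched
by a large share of the miRNA-ome. Denominators are always the merged
database universes, never the source-database sizes.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .mapping import AssociationDB

__all__ = ["SpectrumRecord", "dsw", "msw", "rank_spectrum", "format_width"]


@dataclass(frozen=True)
class SpectrumRecord:
    """One entity's spectrum width: associated-entity count over universe size."""

    name: str
    count: int
    width: float


def _unknown(name: str, kind: str, universe) -> KeyError:
    near = difflib.get_close_matches(name, universe, n=5, cutoff=0.5)
    hint = f"; nearest matches: {', '.join(near)}" if near else ""
    return KeyError(f"unknown {kind} {name!r}{hint}")


def dsw(db: AssociationDB, mirna: str) -> SpectrumRecord:
    """Disease spectrum width of one miRNA: |diseases(m)| / D_N."""
    if mirna not in db.forward:
        raise _unknown(mirna, "miRNA", db.forward.keys())
    count = len(db.forward[mirna])
    return SpectrumRecord(name=mirna, count=count, width=count / db.n_diseases)


def msw(db: AssociationDB, disease: str) -> SpectrumRecord:
    """miRNA spectrum width of one disease: |miRNAs(d)| / M_N."""
    if disease not in db.inverse:
        raise _unknown(disease, "disease", db.inverse.keys())
    count = len(db.inverse[disease])
    return SpectrumRecord(name=disease, count=count, width=count / db.n_mirnas)


def rank_spectrum(db: AssociationDB, by: str = "dsw", top: int = 10) -> list[SpectrumRecord]:
    """Top entities by spectrum width, descending; ties broken by name.

    ``by`` selects DSW (rank miRNAs) or MSW (rank diseases). Returns
    ``min(top, universe size)`` records.
    """
    if top < 1:
        raise ValueError("top must be >= 1")
    kind = by.lower()
    if kind == "dsw":
        records = [dsw(db, m) for m in db.forward.keys()]
    elif kind == "msw":
        records = [msw(db, d) for d in db.inverse.keys()]
    else:
        raise ValueError(f"by must be 'dsw' or 'msw', got {by!r}")
    records.sort(key=lambda r: (-r.width, r.name))
    return records[:top]


def format_width(width: float, places: int = 2) -> str:
    """Report-style half-up rounding of a width (internal values stay exact)."""
    q = Decimal(1).scaleb(-places)
    return str(Decimal(repr(width)).quantize(q, rounding=ROUND_HALF_UP))
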
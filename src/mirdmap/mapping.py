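"""Association maps, the merged bidirectional database, and regex queries.

The core data structure is :class:`AssociationMap`, a multimap from source
names to sets of target names. Two source maps (miRNA→genes, gene→diseases)
are joined on the shared gene key with :func:`merge_on_key`; the result and
its transpose form an :class:`AssociationDB`, the bidirectional
miRNA↔disease store every analysis operates on.

Name identity is exact string match after stripping surrounding whitespace:
gene symbols, miRNA names and disease names are used verbatim, with no case
folding or Unicode normalisation of stored keys. Queries, by contrast, are
case-insensitive unanchored regular expressions (Python :mod:`re` dialect).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMap",
    "AssociationDB",
    "read_mapping",
    "merge_on_key",
    "invert",
    "build_db",
    "query",
    "write_db",
    "read_db",
]


class AssociationMap:
    """Directed multimap from source names to non-empty sets of target names.

    Sources whose target set would be empty are dropped at construction;
    the number dropped is available as :attr:`n_dropped_empty`. Names are
    stored exactly as given except for surrounding whitespace.
    """

    __slots__ = ("entries", "n_dropped_empty")

    def __init__(self, entries: Mapping[str, Iterable[str]] | None = None) -> None:
        self.entries: dict[str, set[str]] = {}
        self.n_dropped_empty = 0
        if entries:
            for source, targets in entries.items():
                cleaned = {t.strip() for t in targets if t.strip()}
                source = source.strip()
                if source and cleaned:
                    self.entries.setdefault(source, set()).update(cleaned)
                else:
                    self.n_dropped_empty += 1

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationMap":
        m = cls()
        for s, t in pairs:
            s, t = s.strip(), t.strip()
            if s and t:
                m.entries.setdefault(s, set()).add(t)
        return m

    def pairs(self) -> set[tuple[str, str]]:
        """The set of distinct (source, target) pairs."""
        return {(s, t) for s, ts in self.entries.items() for t in ts}

    def n_pairs(self) -> int:
        return sum(len(ts) for ts in self.entries.values())

    def keys(self):
        return self.entries.keys()

    def items(self):
        return self.entries.items()

    def get(self, key: str, default=None):
        return self.entries.get(key, default)

    def __getitem__(self, key: str) -> set[str]:
        return self.entries[key]

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AssociationMap):
            return NotImplemented
        return self.entries == other.entries

    def __repr__(self) -> str:
        return (
            f"AssociationMap({len(self.entries)} sources, "
            f"{self.n_pairs()} pairs)"
        )


@dataclass(frozen=True)
class AssociationDB:
    """Bidirectional miRNA↔disease association store.

    ``forward`` maps each miRNA to its disease set; ``inverse`` is the exact
    transpose. ``n_mirnas`` and ``n_diseases`` are the universe sizes used
    as spectrum-width denominators and contingency-table totals.
    """

    forward: AssociationMap
    inverse: AssociationMap = field(repr=False)

    @property
    def n_mirnas(self) -> int:
        return len(self.forward)

    @property
    def n_diseases(self) -> int:
        return len(self.inverse)

    def mirnas(self) -> list[str]:
        return sorted(self.forward.keys())

    def diseases(self) -> list[str]:
        return sorted(self.inverse.keys())


def _sniff_delimiter(path: Path) -> str:
    """Tab by default; fall back to comma when the first line has no tab."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_mapping(
    path: str | Path,
    source_col: int | str = 0,
    target_col: int | str = 1,
    delimiter: str | None = None,
    header: bool | None = None,
) -> AssociationMap:
    """Read a two-column association table into an :class:`AssociationMap`.

    Parameters
    ----------
    path
        Delimited text file (TSV default; CSV when the first line contains
        no tab and no delimiter is given explicitly).
    source_col, target_col
        Column selectors: 0-based integer position or header name.
    delimiter
        Field separator; ``None`` sniffs tab-vs-comma from the first line.
    header
        Whether the first row is a header. ``None`` infers ``True`` when
        either selector is a header name.

    Duplicate (source, target) rows collapse to a single pair; rows with an
    empty source or target are skipped and counted in the log.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"mapping file not found: {path}")
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    if header is None:
        header = isinstance(source_col, str) or isinstance(target_col, str)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if header else None,
            dtype=str,
            keep_default_na=False,
            skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:
        raise ValueError(
            f"malformed row for delimiter {delimiter!r} in {path}: {exc}"
        ) from exc

    def resolve(col: int | str, role: str) -> pd.Series:
        if isinstance(col, str):
            if col not in df.columns:
                raise KeyError(
                    f"{role} column {col!r} not found in header "
                    f"{list(df.columns)} of {path}"
                )
            return df[col]
        if not -df.shape[1] <= col < df.shape[1]:
            raise KeyError(
                f"{role} column index {col} out of range for "
                f"{df.shape[1]}-column file {path}"
            )
        return df.iloc[:, col]

    src = resolve(source_col, "source").astype(str).str.strip()
    tgt = resolve(target_col, "target").astype(str).str.strip()
    keep = (src != "") & (tgt != "")
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("%s: skipped %d rows with empty source/target", path, n_skipped)
    m = AssociationMap.from_pairs(zip(src[keep], tgt[keep]))
    logger.info(
        "%s: read %d sources, %d distinct pairs", path, len(m), m.n_pairs()
    )
    return m


def merge_on_key(
    a: AssociationMap, b: AssociationMap
) -> tuple[AssociationMap, list[str]]:
    """Join two maps X→K and K→Y on the shared key K, giving X→Y.

    ``x→y`` is present iff some key ``k`` satisfies ``k ∈ a[x]`` and
    ``y ∈ b[k]``. Sources of ``a`` whose resulting target set is empty are
    dropped; the sorted list of dropped sources is returned alongside the
    merged map (the handful of miRNAs whose target genes carry no disease
    annotation fall out here).
    """
    merged: dict[str, set[str]] = {}
    dropped: list[str] = []
    for x, keys in a.items():
        targets: set[str] = set()
        for k in keys:
            ts = b.get(k)
            if ts:
                targets.update(ts)
        if targets:
            merged[x] = targets
        else:
            dropped.append(x)
    dropped.sort()
    if dropped:
        logger.info("merge dropped %d sources with no mapped targets", len(dropped))
    out = AssociationMap()
    out.entries = merged
    return out, dropped


def invert(m: AssociationMap) -> AssociationMap:
    """Transpose a map: ``invert(invert(m)) == m``."""
    inv: dict[str, set[str]] = {}
    for s, ts in m.items():
        for t in ts:
            inv.setdefault(t, set()).add(s)
    out = AssociationMap()
    out.entries = inv
    return out


def build_db(forward: AssociationMap) -> AssociationDB:
    """Populate both directions of the association store from the forward map."""
    if len(forward) == 0:
        raise ValueError("cannot build a database from an empty forward map")
    return AssociationDB(forward=forward, inverse=invert(forward))


def query(
    db: AssociationDB, pattern: str, by: str = "disease"
) -> list[tuple[str, set[str]]]:
    """Case-insensitive unanchored regex search over miRNA or disease names.

    Returns ``(name, associated-set)`` pairs sorted by name; zero matches is
    an empty list, not an error. The pattern uses the Python :mod:`re`
    dialect.
    """
    side = by.lower()
    if side in ("mirna", "mir"):
        m = db.forward
    elif side == "disease":
        m = db.inverse
    else:
        raise ValueError(f"by must be 'mirna' or 'disease', got {by!r}")
    try:
        rx = re.compile(pattern, re.IGNORECASE)
    except re.error as exc:
        raise ValueError(
            f"invalid pattern for the Python 're' regex dialect: {pattern!r} ({exc})"
        ) from exc
    return [(name, m[name]) for name in sorted(m.keys()) if rx.search(name)]


def _write_pairs(m: AssociationMap, path: Path, header: tuple[str, str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{header[0]}\t{header[1]}\n")
        for s, t in sorted(m.pairs()):
            fh.write(f"{s}\t{t}\n")


def write_db(db: AssociationDB, outdir: str | Path) -> tuple[Path, Path]:
    """Persist the database as two sorted, byte-stable TSV files.

    ``mirna2disease.tsv`` holds one miRNA→disease association per row;
    ``disease2mirna.tsv`` the transpose.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fwd = outdir / "mirna2disease.tsv"
    inv = outdir / "disease2mirna.tsv"
    _write_pairs(db.forward, fwd, ("miRNA", "disease"))
    _write_pairs(db.inverse, inv, ("disease", "miRNA"))
    return fwd, inv


def read_db(source: str | Path) -> AssociationDB:
    """Load a database from ``mirna2disease.tsv`` (a file or its directory)."""
    path = Path(source)
    if path.is_dir():
        path = path / "mirna2disease.tsv"
    forward = read_mapping(path, source_col=0, target_col=1, delimiter="\t", header=True)
    return build_db(forward)
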
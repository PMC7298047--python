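"""Assembly of disease gene sets from multiple evidence sources.

A disease gene list is typically the union of several evidence sources:
Mendelian-disease databases, GWAS hits, phenotype-ranking tools, and
differential-expression studies.  This module merges such lists into a
single deduplicated :class:`GeneSet` while keeping per-symbol provenance
(which sources contributed each gene).

Normalization is purely lexical: whitespace is stripped and symbols are
upper-cased.  No alias or synonym resolution is attempted — that would
require an external gene-nomenclature database and would make the merge
irreproducible across database versions.  Iteration order of a
:class:`GeneSet` is lexicographic by symbol so that every downstream
output is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GeneRecord",
    "GeneSet",
    "normalize_symbol",
    "merge_gene_sources",
    "set_overlap",
    "read_gene_file",
    "write_gene_set",
]


@dataclass(frozen=True)
class GeneRecord:
    """A normalized gene symbol together with its evidence sources."""

    symbol: str
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("GeneRecord symbol must be nonempty")
        if not self.sources:
            raise ValueError(f"GeneRecord {self.symbol!r} has no sources")


class GeneSet:
    """Deduplicated collection of :class:`GeneRecord`, ordered by symbol.

    Parameters
    ----------
    records
        Gene records; symbols must be unique.
    label
        Free-text name of the set (e.g. ``"genetic_factors"``).
    """

    def __init__(self, records: Iterable[GeneRecord], label: str = "") -> None:
        self.label = label
        self._records: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.symbol in self._records:
                raise ValueError(f"duplicate symbol in GeneSet: {rec.symbol!r}")
            self._records[rec.symbol] = rec

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], label: str = "",
                     source: str = "unspecified") -> "GeneSet":
        """Build a set from raw symbols, normalizing and deduplicating."""
        return merge_gene_sources([(source, list(symbols))], label=label)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(sorted(self._records))

    def record(self, symbol: str) -> GeneRecord:
        return self._records[symbol]

    def __contains__(self, symbol: object) -> bool:
        return symbol in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        for symbol in sorted(self._records):
            yield self._records[symbol]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSet):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return f"GeneSet(label={self.label!r}, n={len(self)})"


def normalize_symbol(raw: str) -> str:
    """Lexically normalize a gene symbol.

    Strips surrounding whitespace and upper-cases the token.  Returns the
    empty string for all-whitespace input; callers decide how to treat it.
    """
    return raw.strip().upper()


def merge_gene_sources(
    sources: Sequence[tuple[str, Iterable[str]]],
    label: str = "merged",
) -> GeneSet:
    """Union several labelled symbol lists into one provenance-tracked set.

    Parameters
    ----------
    sources
        ``(source_label, raw_symbols)`` pairs; labels must be unique.
    label
        Name given to the merged set.

    Returns
    -------
    GeneSet
        One record per distinct normalized symbol; each record's
        ``sources`` lists every contributing label.  Empty and duplicate
        raw entries collapse.

    Raises
    ------
    ValueError
        If no sources are given, labels repeat, or nothing survives
        normalization.
    """
    if not sources:
        raise ValueError("at least one gene source is required")
    labels = [lab for lab, _ in sources]
    if len(set(labels)) != len(labels):
        raise ValueError(f"source labels must be unique, got {labels}")

    by_symbol: dict[str, set[str]] = {}
    for src_label, raw_symbols in sources:
        for raw in raw_symbols:
            symbol = normalize_symbol(raw)
            if not symbol:
                continue
            by_symbol.setdefault(symbol, set()).add(src_label)

    if not by_symbol:
        raise ValueError("no genes after normalization")
    records = [
        GeneRecord(symbol=s, sources=frozenset(srcs))
        for s, srcs in by_symbol.items()
    ]
    return GeneSet(records, label=label)


def set_overlap(a: GeneSet, b: GeneSet) -> tuple[int, int, int]:
    """Return ``(intersection, a_only, b_only)`` sizes for two gene sets."""
    sa, sb = set(a.symbols), set(b.symbols)
    inter = len(sa & sb)
    return inter, len(sa) - inter, len(sb) - inter


def read_gene_file(path: str | Path) -> list[tuple[str, str | None]]:
    """Read a gene-list file.

    Two layouts are accepted: one raw symbol per line, or a two-column
    tab-separated layout ``symbol<TAB>source``.  Lines starting with
    ``#`` and blank lines are ignored.  Returns ``(raw_symbol, source)``
    pairs with ``source`` ``None`` for the one-column layout.
    """
    out: list[tuple[str, str | None]] = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" in line:
            fields = line.split("\t")
            out.append((fields[0], fields[1].strip() or None))
        else:
            out.append((line, None))
    return out


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    """Write a gene set as two-column TSV: symbol, comma-joined sources."""
    lines = ["symbol\tsources"]
    for rec in gene_set:
        lines.append(f"{rec.symbol}\t{','.join(sorted(rec.sources))}")
    Path(path).write_text("\n".join(lines) + "\n")


def gene_set_from_files(
    named_files: Mapping[str, str | Path], label: str = "merged"
) -> GeneSet:
    """Merge several gene-list files, one source label per file."""
    collected: dict[str, list[str]] = {}
    for src_label, path in named_files.items():
        for raw, src in read_gene_file(path):
            # a per-symbol source column (if present) refines the file label
            collected.setdefault(src if src is not None else src_label, []).append(raw)
    return merge_gene_sources(sorted(collected.items()), label=label)
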
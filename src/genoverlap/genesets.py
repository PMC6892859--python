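"""Named collections of normalized gene symbols.

A :class:`GeneSet` is the basic currency of the overlap analyses: a named,
deduplicated set of uppercase gene symbols, optionally tagged with the size
of the gene universe it was drawn from.  Lists are read and written as plain
one-symbol-per-line UTF-8 text with ``#`` comment lines, the format in which
curated disease and reference lists are usually exchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = ["GeneSet", "normalize_symbol", "read_gene_list", "write_gene_list"]


def normalize_symbol(raw: str) -> Optional[str]:
    """Normalize a raw gene symbol: trim whitespace, uppercase.

    Returns ``None`` (absence) rather than an empty string when nothing
    remains after trimming, so callers can filter with a simple truth test.
    """
    sym = raw.strip().upper()
    return sym or None


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated collection of normalized gene symbols.

    Parameters
    ----------
    name
        Human-readable label (e.g. ``"CAG"`` for cancer-associated genes).
    members
        Set of gene symbols; normalized on construction via
        :func:`from_iterable` or validated if passed directly.
    universe_size
        Optional size of the gene universe the set was drawn from.
    """

    name: str
    members: frozenset[str] = field(default_factory=frozenset)
    universe_size: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        for m in self.members:
            if not m or m != m.strip().upper():
                raise ValueError(f"non-normalized member {m!r} in GeneSet {self.name!r}")
        if self.universe_size is not None and self.universe_size <= 0:
            raise ValueError("universe_size must be positive")

    @classmethod
    def from_iterable(
        cls, name: str, symbols: Iterable[str], universe_size: Optional[int] = None
    ) -> "GeneSet":
        """Build a set from raw symbols, normalizing and dropping empties."""
        members = {s for s in (normalize_symbol(x) for x in symbols) if s}
        return cls(name=name, members=frozenset(members), universe_size=universe_size)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def intersection(self, other: "GeneSet", name: Optional[str] = None) -> "GeneSet":
        return GeneSet(
            name=name or f"{self.name}&{other.name}",
            members=self.members & other.members,
            universe_size=self.universe_size,
        )

    def union(self, other: "GeneSet", name: Optional[str] = None) -> "GeneSet":
        return GeneSet(
            name=name or f"{self.name}|{other.name}",
            members=self.members | other.members,
            universe_size=self.universe_size,
        )


def read_gene_list(path: str | Path, name: Optional[str] = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; ``#`` lines are comments."""
    path = Path(path)
    symbols = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(line)
    return GeneSet.from_iterable(name or path.stem, symbols)


def write_gene_list(gene_set: GeneSet, path: str | Path) -> None:
    """Write a gene set as sorted one-symbol-per-line text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# {gene_set.name} ({len(gene_set)} genes)\n")
        for sym in sorted(gene_set.members):
            fh.write(sym + "\n")
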
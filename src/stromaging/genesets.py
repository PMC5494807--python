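"""Named gene sets and GMT serialisation.

A :class:`GeneSet` is a named collection of HGNC-style gene symbols with
optional free-text provenance and a subset of *provisional* members —
symbols whose membership in the programme is uncertain (in the curated
senescence-secretome set, CCL3 is carried this way).  Provisional members
are kept in the set definition but excluded from scoring by default.

Serialisation uses the standard GMT layout (one set per line:
name, description, then member symbols, all tab-separated).  Provisional
symbols are written parenthesised, ``(CCL3)``, so the flag round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class GMTParseError(ValueError):
    """Raised for a malformed GMT line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int) -> None:
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols.

    Parameters
    ----------
    name : str
        Set identifier (no tabs).
    symbols : tuple of str
        Unique, upper-case, whitespace-free member symbols, in a stable
        order.  Includes provisional members.
    description : str
        Free-text provenance (citations, notes).
    provisional : frozenset of str
        Subset of `symbols` flagged as uncertain members.
    """

    name: str
    symbols: tuple[str, ...]
    description: str = ""
    provisional: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")
        if "\t" in self.name:
            raise ValueError(f"gene set name contains a tab: {self.name!r}")
        seen: set[str] = set()
        for s in self.symbols:
            if not s or s != s.strip() or any(c.isspace() for c in s):
                raise ValueError(f"bad symbol {s!r} in set {self.name!r}")
            if s != s.upper():
                raise ValueError(f"symbol not upper-case normalised: {s!r}")
            if s in seen:
                raise ValueError(f"duplicate symbol {s!r} in set {self.name!r}")
            seen.add(s)
        unknown = self.provisional - seen
        if unknown:
            raise ValueError(
                f"provisional symbols not in set {self.name!r}: {sorted(unknown)}"
            )

    def members(self, include_provisional: bool = False) -> frozenset[str]:
        """Symbols used for scoring; provisional members opt-in."""
        if include_provisional:
            return frozenset(self.symbols)
        return frozenset(self.symbols) - self.provisional

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of uniquely named :class:`GeneSet` objects."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names in collection")

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        return cls(tuple(sets))

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sets)

    def as_dict(self, include_provisional: bool = False) -> Mapping[str, frozenset[str]]:
        return {s.name: s.members(include_provisional) for s in self.sets}


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; provisional members parenthesised."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            cells = [s.name, s.description]
            cells.extend(
                f"({sym})" if sym in s.provisional else sym for sym in s.symbols
            )
            fh.write("\t".join(cells) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; ``(SYM)`` members are marked provisional.

    Raises
    ------
    GMTParseError
        If a non-empty line has fewer than three tab-separated fields.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise GMTParseError(
                    f"expected >= 3 tab-separated fields, got {len(cells)}", lineno
                )
            name, description = cells[0], cells[1]
            symbols: list[str] = []
            provisional: set[str] = set()
            for cell in cells[2:]:
                cell = cell.strip()
                if not cell:
                    continue
                if cell.startswith("(") and cell.endswith(")"):
                    cell = cell[1:-1]
                    provisional.add(cell)
                symbols.append(cell)
            sets.append(
                GeneSet(
                    name=name,
                    symbols=tuple(symbols),
                    description=description,
                    provisional=frozenset(provisional),
                )
            )
    return GeneSetCollection(tuple(sets))
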
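"""Gene-set collections and GMT parsing.

A :class:`GeneSetCollection` holds named gene sets together with the
*background universe* — the non-redundant union of all genes appearing in the
retained sets. The background is the universe of the per-cell hypergeometric
test: ``N`` is its size and ``K[s]`` the size of set ``s`` restricted to it.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GeneSetCollection",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "membership_matrix",
    "read_background",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT input (line number included in the message)."""


def _open_text(path, mode: str = "rt"):
    """Open plain or gzip-compressed text transparently."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the shared background universe.

    Parameters
    ----------
    set_names
        Unique, non-empty identifiers, in file order.
    set_descriptions
        Free-text description per set (GMT column 2).
    members
        One frozen set of gene identifiers per set; always a subset of
        ``background``.
    background
        Union of all members across sets (size ``N``), or a user-supplied
        universe the members were intersected with.
    """

    set_names: tuple[str, ...]
    set_descriptions: tuple[str, ...]
    members: tuple[frozenset[str], ...]
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.set_names) != len(set(self.set_names)):
            raise ValueError("duplicate set names in collection")
        if any(not name for name in self.set_names):
            raise ValueError("empty set name in collection")
        if len(self.set_descriptions) != len(self.set_names) or len(
            self.members
        ) != len(self.set_names):
            raise ValueError("set_names, set_descriptions, members length mismatch")
        for name, mem in zip(self.set_names, self.members):
            if not mem <= self.background:
                raise ValueError(f"set {name!r} has members outside the background")
        if len(self.set_names) and not self.background:
            raise ValueError("non-empty collection requires a non-empty background")

    @classmethod
    def from_sets(
        cls,
        names: Sequence[str],
        members: Sequence[Iterable[str]],
        descriptions: Sequence[str] | None = None,
        background: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        """Build a collection; background defaults to the union of members.

        When an explicit ``background`` is given, members are intersected
        with it (genes outside the universe never enter the test).
        """
        members = [frozenset(m) for m in members]
        if background is None:
            bg = frozenset().union(*members) if members else frozenset()
        else:
            bg = frozenset(background)
            members = [m & bg for m in members]
        if descriptions is None:
            descriptions = [""] * len(names)
        return cls(tuple(names), tuple(descriptions), tuple(members), bg)

    @property
    def n_sets(self) -> int:
        return len(self.set_names)

    @property
    def n_background(self) -> int:
        """The hypergeometric population size N."""
        return len(self.background)

    @property
    def set_sizes(self) -> np.ndarray:
        """Per-set size K after restriction to the background."""
        return np.array([len(m) for m in self.members], dtype=np.int64)

    def restrict_to(self, background: Iterable[str]) -> "GeneSetCollection":
        """Return a copy with members intersected with a user-supplied universe."""
        return GeneSetCollection.from_sets(
            self.set_names, self.members, self.set_descriptions, background
        )


def read_gmt(
    path,
    min_set_size: int = 1,
    max_set_size: int | None = None,
) -> GeneSetCollection:
    """Parse a Broad/MSigDB-dialect GMT file.

    Each line is ``name TAB description TAB gene TAB gene ...``; gene
    identifiers are trimmed of surrounding whitespace and deduplicated,
    compared case-sensitively. Sets whose deduplicated size falls outside
    ``[min_set_size, max_set_size]`` are dropped; the background is the union
    of the retained sets' genes.

    Raises
    ------
    GmtParseError
        On a line with fewer than three fields, a duplicate set name, or if
        no set survives the size filter.
    """
    if min_set_size < 1:
        raise ValueError("min_set_size must be >= 1")
    names: list[str] = []
    descriptions: list[str] = []
    members: list[frozenset[str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            # trailing empty fields (e.g. from Excel exports) are ignored
            while fields and fields[-1].strip() == "":
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            name = fields[0].strip()
            if not name:
                raise GmtParseError(f"{path}: line {lineno}: empty set name")
            if name in seen:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            size = len(genes)
            if size < min_set_size or (max_set_size is not None and size > max_set_size):
                continue
            seen.add(name)
            names.append(name)
            descriptions.append(fields[1])
            members.append(genes)
    if not names:
        raise GmtParseError(f"{path}: no gene set retained after size filtering")
    return GeneSetCollection.from_sets(names, members, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection in GMT format (genes sorted for determinism)."""
    with _open_text(path, "wt") as fh:
        for name, desc, mem in zip(
            collection.set_names, collection.set_descriptions, collection.members
        ):
            fh.write("\t".join([name, desc, *sorted(mem)]) + "\n")


def read_background(path) -> frozenset[str]:
    """Read a user-supplied background universe, one gene per line."""
    with _open_text(path) as fh:
        genes = frozenset(line.strip() for line in fh if line.strip())
    if not genes:
        raise ValueError(f"{path}: empty background list")
    return genes


def membership_matrix(
    collection: GeneSetCollection, gene_order: Sequence[str]
) -> sp.csr_matrix:
    """Binary sets × genes membership matrix B over a given gene ordering.

    ``B[s, g] = 1`` iff ``gene_order[g]`` belongs to set ``s``. Genes absent
    from the background yield all-zero columns; row sums over
    background-restricted columns therefore equal ``set_sizes``.
    """
    gene_order = list(gene_order)
    if len(gene_order) != len(set(gene_order)):
        raise ValueError("gene_order contains duplicate identifiers")
    col_of = {g: j for j, g in enumerate(gene_order)}
    rows: list[int] = []
    cols: list[int] = []
    for s, mem in enumerate(collection.members):
        for g in mem:
            j = col_of.get(g)
            if j is not None:
                rows.append(s)
                cols.append(j)
    shape = (collection.n_sets, len(gene_order))
    B = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=shape
    )
    return B
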
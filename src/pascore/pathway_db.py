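"""Pathway knowledge-base structures.

A pathway is a flat set of member genes, each carrying an activator/repressor
role (ARR) weight that encodes how the gene product influences signal
transduction through that pathway: +1 activator, -1 repressor, +/-0.5 for
"rather an activator/repressor", 0 for genes that can act as both.  The
scoring model deliberately ignores pathway topology, so this is all the
structure the knowledge base needs.

The on-disk format is a 4-column tab-separated table with header
``pathway_id  pathway_name  gene  arr``, one (pathway, gene, role) per row.
Gene symbols are canonicalized (trimmed, uppercased) on the way in; alias
resolution is out of scope and should happen upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping

__all__ = [
    "ARR_VALUES",
    "ArrRole",
    "Pathway",
    "PathwayDB",
    "PathwayDBError",
    "canonical_gene",
    "read_pathway_db",
    "write_pathway_db",
    "coverage",
]

#: The five admissible activator/repressor role weights.
ARR_VALUES = (-1.0, -0.5, 0.0, 0.5, 1.0)


class PathwayDBError(ValueError):
    """Raised for malformed pathway definitions or files."""


class ArrRole(float):
    """Activator/repressor role weight; only the five canonical values exist.

    Subclasses :class:`float` so roles participate in arithmetic directly.
    """

    __slots__ = ()

    def __new__(cls, value: float) -> "ArrRole":
        try:
            v = float(value)
        except (TypeError, ValueError):
            raise PathwayDBError(f"invalid ARR value {value!r}") from None
        if v not in ARR_VALUES:
            raise PathwayDBError(
                f"invalid ARR value {value!r}: must be one of {ARR_VALUES}"
            )
        return super().__new__(cls, v)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ArrRole({float(self):+.1f})"


def canonical_gene(symbol: str) -> str:
    """Canonicalize a gene symbol: trim surrounding whitespace, uppercase.

    Raises :class:`PathwayDBError` if the result is empty or still contains
    whitespace (inner whitespace means a malformed symbol, not a fixable one).
    """
    s = str(symbol).strip().upper()
    if not s:
        raise PathwayDBError(f"empty gene symbol {symbol!r}")
    if any(c.isspace() for c in s):
        raise PathwayDBError(f"gene symbol {symbol!r} contains whitespace")
    return s


@dataclass
class Pathway:
    """One signaling pathway: an id, a display name and an ARR-weighted gene set."""

    id: str
    name: str
    members: Dict[str, ArrRole]

    def __post_init__(self) -> None:
        if not self.id or not str(self.id).strip():
            raise PathwayDBError("pathway id must be non-empty")
        self.id = str(self.id).strip()
        if not self.members:
            raise PathwayDBError(f"pathway {self.id!r} has no members")
        canon: Dict[str, ArrRole] = {}
        for gene, role in self.members.items():
            g = canonical_gene(gene)
            if g in canon:
                raise PathwayDBError(
                    f"duplicate gene {g!r} in pathway {self.id!r} (after canonicalization)"
                )
            canon[g] = role if isinstance(role, ArrRole) else ArrRole(role)
        self.members = canon

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PathwayDB:
    """Ordered collection of pathways; iteration follows insertion/file order."""

    pathways: List[Pathway] = field(default_factory=list)
    version: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pathways:
            if p.id in seen:
                raise PathwayDBError(f"duplicate pathway id {p.id!r}")
            seen.add(p.id)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def ids(self) -> List[str]:
        return [p.id for p in self.pathways]

    def gene_universe(self) -> set:
        """All gene symbols appearing in any pathway."""
        out: set = set()
        for p in self.pathways:
            out.update(p.members)
        return out


_HEADER = ["pathway_id", "pathway_name", "gene", "arr"]


def read_pathway_db(path: str | Path) -> PathwayDB:
    """Read a pathway database from its tab-separated file format.

    Errors name the offending line number / gene / pathway so that hand-edited
    tables are debuggable.
    """
    path = Path(path)
    order: List[str] = []
    names: Dict[str, str] = {}
    members: Dict[str, Dict[str, ArrRole]] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise PathwayDBError(
                f"{path}: bad header {header!r}, expected {_HEADER!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise PathwayDBError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            pid, pname, gene, arr = parts
            pid = pid.strip()
            if not pid:
                raise PathwayDBError(f"{path}:{lineno}: empty pathway id")
            try:
                g = canonical_gene(gene)
                role = ArrRole(arr)
            except PathwayDBError as exc:
                raise PathwayDBError(f"{path}:{lineno}: {exc}") from None
            if pid not in members:
                order.append(pid)
                names[pid] = pname
                members[pid] = {}
            if g in members[pid]:
                raise PathwayDBError(
                    f"{path}:{lineno}: duplicate gene {g!r} in pathway {pid!r}"
                )
            members[pid][g] = role
    db = PathwayDB(
        pathways=[Pathway(id=pid, name=names[pid], members=members[pid]) for pid in order]
    )
    return db


def write_pathway_db(db: PathwayDB, path: str | Path) -> None:
    """Write a pathway database; ``read_pathway_db`` round-trips it exactly.

    ARR weights are rendered with one decimal place so round-trips are
    bit-stable.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for p in db:
            for gene, role in p.members.items():
                fh.write(f"{p.id}\t{p.name}\t{gene}\t{float(role):.1f}\n")


def coverage(db: PathwayDB, gene_universe: Iterable[str]) -> Dict[str, float]:
    """Per-pathway fraction of member genes present in ``gene_universe``.

    Used to report how much of each pathway an expression dataset covers;
    scores for poorly covered pathways should be interpreted with care.
    """
    universe = {canonical_gene(g) for g in gene_universe}
    return {
        p.id: len(set(p.members) & universe) / len(p.members) for p in db
    }
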
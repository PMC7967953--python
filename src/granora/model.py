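"""Pathway databases, gene universes, and query gene sets.

A pathway database is a named collection of gene sets over a declared gene
universe.  The enrichment convention throughout this package is that the
background total ``N`` counts *pathway-assigned* genes (the union of all
pathway gene sets), not the genome or the declared universe; a declared
universe may be larger and is only used for validation unless explicitly
requested.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "Pathway",
    "PathwayDatabase",
    "AnnotationSummary",
    "load_gmt",
    "write_gmt",
    "load_gene_list",
    "summarize",
    "normalize_gene_id",
]


class GmtParseError(ValueError):
    """Raised for a malformed GMT line or duplicate pathway identifier."""


def normalize_gene_id(gene: str) -> str:
    """Optional identifier normalizer: strip whitespace and uppercase.

    Gene identifiers are otherwise treated as opaque, case-sensitive
    strings; cross-database reconciliation is the caller's responsibility.
    """
    return gene.strip().upper()


@dataclass(frozen=True)
class Pathway:
    """A single pathway: stable identifier, free-text name, member genes."""

    id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has an empty gene set")

    @property
    def size(self) -> int:
        """Number of genes assigned to the pathway (symbol n)."""
        return len(self.genes)


@dataclass(frozen=True)
class AnnotationSummary:
    """Database-level annotation totals used in enrichment corrections.

    ``n_pathways`` is the Bonferroni multiplier m; ``n_assigned_genes`` is
    the background total N (union of all pathway gene sets).
    """

    n_pathways: int
    n_assigned_genes: int
    size_distribution: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("database must contain at least one pathway")
        if self.size_distribution and self.n_assigned_genes < max(self.size_distribution):
            raise ValueError("assigned-gene total smaller than the largest pathway")


@dataclass
class PathwayDatabase:
    """Named collection of pathways over an optional declared universe."""

    name: str
    pathways: list[Pathway]
    universe: frozenset[str] | None = None
    _by_id: dict[str, Pathway] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate pathway identifiers: {sorted(dupes)}")
        if self.universe is not None:
            if not self.universe and self.pathways:
                raise ValueError("declared universe is empty but pathways are not")
            stray = self.assigned_genes() - self.universe
            if stray:
                raise ValueError(
                    f"{len(stray)} pathway genes outside the declared universe "
                    f"(e.g. {sorted(stray)[:3]})"
                )
        self._by_id = {p.id: p for p in self.pathways}

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def assigned_genes(self) -> frozenset[str]:
        """Union of all pathway gene sets (the background total N)."""
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)

    @property
    def n_assigned(self) -> int:
        return len(self.assigned_genes())


def summarize(db: PathwayDatabase) -> AnnotationSummary:
    """Annotation totals: m pathways, N assigned genes, size multiset."""
    if not db.pathways:
        raise ValueError("cannot summarize an empty database")
    return AnnotationSummary(
        n_pathways=len(db.pathways),
        n_assigned_genes=db.n_assigned,
        size_distribution=tuple(sorted(p.size for p in db.pathways)),
    )


def load_gmt(
    path: str | Path,
    name: str | None = None,
    universe: set[str] | None = None,
    normalize: bool = False,
) -> PathwayDatabase:
    """Read a GMT file (tab-separated: id, description, genes...).

    The second column is a description and is never parsed as a gene.
    Duplicate genes within a line are deduplicated with a warning;
    duplicate pathway identifiers or lines with fewer than three fields
    raise :class:`GmtParseError` naming the line number.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            if normalize:
                genes = [normalize_gene_id(g) for g in genes]
            if pid in seen:
                raise GmtParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            if len(set(genes)) < len(genes):
                logger.warning(
                    "%s:%d: %d duplicate gene(s) in pathway %s deduplicated",
                    path, lineno, len(genes) - len(set(genes)), pid,
                )
            pathways.append(Pathway(id=pid, name=desc, genes=frozenset(genes)))
    return PathwayDatabase(
        name=name or path.stem,
        pathways=pathways,
        universe=frozenset(universe) if universe is not None else None,
    )


def write_gmt(db: PathwayDatabase, path: str | Path) -> None:
    """Write a database in GMT format; genes sorted for reproducibility."""
    path = Path(path)
    with path.open("w") as fh:
        for p in db.pathways:
            fh.write("\t".join([p.id, p.name, *sorted(p.genes)]) + "\n")


def load_gene_list(path: str | Path, normalize: bool = False) -> frozenset[str]:
    """Read a plain-text gene list: one identifier per line, ``#`` comments.

    Returns a deduplicated, order-insensitive set; an effectively empty
    file is an error.
    """
    path = Path(path)
    genes: set[str] = set()
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(normalize_gene_id(line) if normalize else line)
    if not genes:
        raise ValueError(f"{path}: no gene identifiers found")
    return frozenset(genes)
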
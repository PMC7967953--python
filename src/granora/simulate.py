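"""Synthetic dual-granularity pathway databases.

Emulates the structural contrast between a fine-grained annotation
(small, mostly disjoint single-process pathways, EcoCyc-style) and a
coarse annotation of the same gene universe (large "mosaic" pathways,
each the union of several fine ones, KEGG-map-style), plus
significant-gene sets concentrated in perturbed pathways with uniform
background.

The default scenario keeps the fine annotation's statistical scale
realistic for a bacterial genome: 354 fine pathways with sizes uniform on
3..13 over a 4288-gene universe (the E. coli K-12 protein-coding gene
count), giving roughly 2800 pathway-assigned genes, and a grouping factor
of 3 so the coarse side has 118 mosaic pathways whose matched-pair size
ratio averages about 3.5.  All sampling flows through one explicit seeded
generator; no global random state.

What the generator does NOT emulate: real annotations overlap heavily
(pathway variants share genes), gene-to-pathway assignment is not
uniform, and coarse databases are not exact unions of fine ones.  Green
tests on these fixtures establish the statistical machinery, not
agreement with any real database's contents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Pathway, PathwayDatabase

__all__ = [
    "SyntheticScenario",
    "PerturbationSpec",
    "CoarsenResult",
    "generate_fine_db",
    "coarsen_db",
    "sample_significant_genes",
    "mosaic_significant_set",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the stated synthetic world."""

    universe_size: int = 4288
    n_fine_pathways: int = 354
    fine_size_range: tuple[int, int] = (3, 13)
    grouping_factor: int = 3
    overlap_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fine_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid fine_size_range")
        if self.grouping_factor < 1:
            raise ValueError("grouping_factor must be >= 1")
        if not (0.0 <= self.overlap_noise <= 1.0):
            raise ValueError("overlap_noise must be in [0, 1]")


def _gene_names(universe_size: int) -> list[str]:
    width = len(str(universe_size - 1))
    return [f"g{i:0{width}d}" for i in range(universe_size)]


def generate_fine_db(s: SyntheticScenario) -> PathwayDatabase:
    """Generate the fine-grained database; deterministic given the seed.

    Pathway sizes are drawn uniformly from ``fine_size_range``; genes are
    assigned disjointly from a shuffled universe, then ``overlap_noise``
    replaces that fraction of each pathway's genes with genes already
    assigned elsewhere (creating cross-pathway sharing).
    """
    rng = np.random.default_rng(s.seed)
    lo, hi = s.fine_size_range
    sizes = rng.integers(lo, hi + 1, size=s.n_fine_pathways)
    budget = int(s.universe_size * (1.0 + s.overlap_noise))
    if int(sizes.sum()) > budget:
        raise ValueError(
            f"infeasible packing: total pathway genes {int(sizes.sum())} exceed "
            f"universe_size*(1+overlap_noise) = {budget}"
        )
    genes = _gene_names(s.universe_size)
    order = rng.permutation(s.universe_size)
    width = len(str(s.n_fine_pathways - 1))
    pathways: list[Pathway] = []
    cursor = 0
    for i, size in enumerate(sizes):
        members = [genes[j] for j in order[cursor : cursor + int(size)]]
        cursor += int(size)
        pathways.append(
            Pathway(id=f"F{i:0{width}d}", name=f"fine pathway {i}", genes=frozenset(members))
        )
    if s.overlap_noise > 0:
        assigned = sorted({g for p in pathways for g in p.genes})
        noisy = []
        for p in pathways:
            members = set(p.genes)
            for g in sorted(p.genes):
                if rng.random() < s.overlap_noise:
                    pool = [x for x in assigned if x not in members]
                    if pool:
                        members.discard(g)
                        members.add(pool[int(rng.integers(len(pool)))])
            noisy.append(Pathway(id=p.id, name=p.name, genes=frozenset(members)))
        pathways = noisy
    return PathwayDatabase(
        name=f"synthetic-fine-seed{s.seed}",
        pathways=pathways,
        universe=frozenset(genes),
    )


@dataclass(frozen=True)
class CoarsenResult:
    """A coarse database plus its ground-truth containment mapping."""

    db: PathwayDatabase
    fine_to_coarse: dict[str, str] = field(hash=False)
    coarse_members: dict[str, tuple[str, ...]] = field(hash=False)


def coarsen_db(
    fine: PathwayDatabase, grouping_factor: int, seed: int = 0
) -> CoarsenResult:
    """Union random disjoint groups of fine pathways into mosaic pathways.

    Fine pathways are shuffled and chunked into groups of
    ``grouping_factor`` (the last group may be smaller); each coarse
    pathway is the union of its group's gene sets.  The fine-to-coarse
    mapping is returned as ground truth for recovery tests.
    """
    if not (1 <= grouping_factor <= len(fine.pathways)):
        raise ValueError("grouping_factor must be in 1..n_fine_pathways")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(fine.pathways))
    groups = [
        [fine.pathways[j] for j in order[i : i + grouping_factor]]
        for i in range(0, len(order), grouping_factor)
    ]
    width = len(str(len(groups) - 1)) if len(groups) > 1 else 1
    coarse_pathways, fine_to_coarse, coarse_members = [], {}, {}
    for i, group in enumerate(groups):
        cid = f"C{i:0{width}d}"
        union: set[str] = set()
        for p in group:
            union |= p.genes
            fine_to_coarse[p.id] = cid
        coarse_members[cid] = tuple(p.id for p in group)
        coarse_pathways.append(
            Pathway(
                id=cid,
                name="mosaic of " + ", ".join(p.id for p in group),
                genes=frozenset(union),
            )
        )
    db = PathwayDatabase(
        name=fine.name.replace("fine", "coarse"),
        pathways=coarse_pathways,
        universe=fine.universe,
    )
    return CoarsenResult(db=db, fine_to_coarse=fine_to_coarse, coarse_members=coarse_members)


@dataclass(frozen=True)
class PerturbationSpec:
    """How the significant-gene set is constructed."""

    perturbed_fine_ids: tuple[str, ...]
    within_pathway_fraction: float = 1.0
    background_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_pathway_fraction <= 1.0):
            raise ValueError("within_pathway_fraction must be in [0, 1]")
        if self.background_count < 0:
            raise ValueError("background_count must be >= 0")


def sample_significant_genes(db: PathwayDatabase, p: PerturbationSpec) -> frozenset[str]:
    """Significant set: a fraction of each perturbed pathway plus background.

    Background genes are drawn uniformly without replacement from the
    declared universe (or the assigned genes when none is declared) minus
    all perturbed pathways' genes.  Deterministic given the seed; an
    empty result is an error.
    """
    rng = np.random.default_rng(p.seed)
    perturbed_genes: set[str] = set()
    chosen: set[str] = set()
    for pid in p.perturbed_fine_ids:
        if pid not in db:
            raise KeyError(f"pathway {pid!r} not in database {db.name!r}")
        members = sorted(db[pid].genes)
        perturbed_genes.update(members)
        n_sig = int(round(p.within_pathway_fraction * len(members)))
        if n_sig:
            idx = rng.choice(len(members), size=n_sig, replace=False)
            chosen.update(members[i] for i in idx)
    pool = sorted((db.universe or db.assigned_genes()) - perturbed_genes)
    if p.background_count:
        if p.background_count > len(pool):
            raise ValueError("background_count exceeds available background genes")
        idx = rng.choice(len(pool), size=p.background_count, replace=False)
        chosen.update(pool[i] for i in idx)
    if not chosen:
        raise ValueError("perturbation produced an empty significant set")
    return frozenset(chosen)


def mosaic_significant_set(
    fine_db: PathwayDatabase,
    coarsened: CoarsenResult,
    coarse_id: str | None = None,
    seed: int = 0,
) -> tuple[frozenset[str], str]:
    """The mosaic false-positive construction.

    Picks one gene from each fine pathway inside a single coarse mosaic
    pathway: individually no fine pathway is meaningfully perturbed, yet
    their union — the coarse pathway — accumulates every hit.  Returns the
    significant set and the targeted coarse pathway id.
    """
    rng = np.random.default_rng(seed)
    if coarse_id is None:
        # the mosaic with the most members, ties broken by id
        coarse_id = max(
            coarsened.coarse_members, key=lambda c: (len(coarsened.coarse_members[c]), c)
        )
    chosen: set[str] = set()
    for fid in coarsened.coarse_members[coarse_id]:
        members = sorted(fine_db[fid].genes)
        chosen.add(members[int(rng.integers(len(members)))])
    return frozenset(chosen), coarse_id
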
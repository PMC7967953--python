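"""Cross-database analogous-pathway matching.

Two pathway databases annotating the same organism rarely share pathway
identifiers, so analogous pathways are identified from the gene sets
alone: a pair is a candidate when its gene-set overlap is significantly
larger than random draws from the joint universe would produce, and
candidates are resolved one-to-one by preferring stronger overlaps and,
at comparable significance and identical overlap, the pair with the
smallest combined gene count.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median, quantiles

from .comparison import round_sig
from .model import PathwayDatabase
from .stats import EnrichmentQuery, bonferroni, enrichment_pvalue

__all__ = [
    "PathwayPair",
    "MatchConfig",
    "overlap_pvalue",
    "match_pathways",
    "size_ratio_summary",
]


def overlap_pvalue(set_a: frozenset | set, set_b: frozenset | set, universe_size: int) -> float:
    """Hypergeometric tail probability of >= the observed overlap.

    Draws of |B| genes from a ``universe_size``-gene pool containing the
    |A| genes of the first set: P(|A ∩ draw| >= |A ∩ B|).
    """
    if universe_size < len(set_a | set_b):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(set_a & set_b)
    return float(
        enrichment_pvalue(
            EnrichmentQuery(k=k, K=len(set_a), n=len(set_b), N=universe_size)
        )
    )


@dataclass(frozen=True)
class PathwayPair:
    fine_id: str
    coarse_id: str
    n_fine: int
    n_coarse: int
    overlap: int
    overlap_p: float

    @property
    def size_ratio(self) -> float:
        return self.n_coarse / self.n_fine

    @property
    def combined_size(self) -> int:
        return self.n_fine + self.n_coarse


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters.

    ``overlap_alpha`` is the significance cutoff for "highly significant"
    overlap; with ``bonferroni_candidates`` on (default) it applies after
    Bonferroni correction over all scored candidate pairs.  ``uniqueness``
    enforces one-to-one matching; ``tie_sig_figs`` defines "comparable"
    p-values for the smallest-combined-size tie-break.
    """

    min_fine_genes: int = 3
    overlap_alpha: float = 0.05
    uniqueness: bool = True
    bonferroni_candidates: bool = True
    tie_sig_figs: int = 2

    def __post_init__(self) -> None:
        if self.min_fine_genes < 1:
            raise ValueError("min_fine_genes must be >= 1")
        if not (0 < self.overlap_alpha <= 1):
            raise ValueError("overlap_alpha must be in (0, 1]")


def match_pathways(
    fine_db: PathwayDatabase,
    coarse_db: PathwayDatabase,
    cfg: MatchConfig | None = None,
) -> list[PathwayPair]:
    """Analogous pathway pairs between a fine and a coarse database.

    The joint universe is the union of both databases' assigned genes.
    Candidates require a non-empty overlap, fine size >= min_fine_genes,
    and overlap significance at ``cfg.overlap_alpha``.  With uniqueness
    on, candidates are sorted by (rounded overlap p, combined size,
    identifiers) and accepted greedily while both endpoints are unused —
    a deterministic total order with no hash dependence.
    """
    cfg = cfg or MatchConfig()
    joint = fine_db.assigned_genes() | coarse_db.assigned_genes()
    if not (fine_db.assigned_genes() & coarse_db.assigned_genes()):
        raise ValueError("databases share no gene identifiers")
    N = len(joint)
    candidates: list[PathwayPair] = []
    for f in fine_db.pathways:
        if f.size < cfg.min_fine_genes:
            continue
        for c in coarse_db.pathways:
            overlap = len(f.genes & c.genes)
            if overlap == 0:
                continue
            candidates.append(
                PathwayPair(
                    fine_id=f.id,
                    coarse_id=c.id,
                    n_fine=f.size,
                    n_coarse=c.size,
                    overlap=overlap,
                    overlap_p=overlap_pvalue(f.genes, c.genes, N),
                )
            )
    n_tests = len(candidates)
    if cfg.bonferroni_candidates and n_tests:
        significant = [
            p for p in candidates if bonferroni(p.overlap_p, n_tests) <= cfg.overlap_alpha
        ]
    else:
        significant = [p for p in candidates if p.overlap_p <= cfg.overlap_alpha]
    significant.sort(
        key=lambda p: (
            round_sig(p.overlap_p, cfg.tie_sig_figs),
            p.combined_size,
            p.fine_id,
            p.coarse_id,
        )
    )
    if not cfg.uniqueness:
        return significant
    used_fine: set[str] = set()
    used_coarse: set[str] = set()
    accepted = []
    for p in significant:
        if p.fine_id in used_fine or p.coarse_id in used_coarse:
            continue
        accepted.append(p)
        used_fine.add(p.fine_id)
        used_coarse.add(p.coarse_id)
    return accepted


def size_ratio_summary(pairs: list[PathwayPair]) -> dict[str, float]:
    """Mean, median and quartiles of coarse/fine size ratios."""
    if not pairs:
        raise ValueError("no pairs to summarize")
    ratios = sorted(p.size_ratio for p in pairs)
    if len(ratios) == 1:
        q1 = q3 = ratios[0]
    else:
        q1, _, q3 = quantiles(ratios, n=4)
    return {
        "n_pairs": len(ratios),
        "mean": sum(ratios) / len(ratios),
        "median": median(ratios),
        "q1": q1,
        "q3": q3,
    }
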
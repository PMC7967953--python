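"""Critical subset sizes: the inverse enrichment problem.

For a fixed adjusted significance threshold and a sample of K significant
genes, the *critical subset size* of a pathway is the minimum number of
its genes that must appear in the sample for the pathway to be called
enriched.  Dividing by pathway size gives the *representation rate*: the
fraction of a pathway that must be perturbed to reach significance.

Because the upper-tail p-value is strictly decreasing in k (at fixed K,
n, N), the minimum is found by binary search; a sentinel marks pathways
that cannot reach the threshold even when every sampled gene is theirs.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

from .model import PathwayDatabase
from .stats import EnrichmentQuery, ThresholdSpec, enrichment_pvalue

__all__ = [
    "UNREACHABLE",
    "Unreachable",
    "CriticalSubsetProfile",
    "ProfileRatio",
    "critical_subset_size",
    "profile_database",
    "ratio_profiles",
]


class Unreachable:
    """Typed sentinel: significance unreachable at any k <= min(n, K)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNREACHABLE"

    def __bool__(self) -> bool:
        return False


UNREACHABLE = Unreachable()


def critical_subset_size(
    n: int, N: int, K: int, threshold: float
) -> int | Unreachable:
    """Smallest k in 1..min(n, K) with P(X >= k) <= threshold.

    Exploits tail monotonicity in k for a binary search; returns
    :data:`UNREACHABLE` when even k = min(n, K) is not significant.
    """
    if not (1 <= n <= N and 1 <= K <= N):
        raise ValueError(f"need 1 <= n <= N and 1 <= K <= N; got n={n}, N={N}, K={K}")
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1); got {threshold}")

    def pval(k: int) -> float:
        return float(enrichment_pvalue(EnrichmentQuery(k=k, K=K, n=n, N=N)))

    hi = min(n, K)
    if pval(hi) > threshold:
        return UNREACHABLE
    lo = 1
    while lo < hi:  # invariant: pval(hi) <= threshold
        mid = (lo + hi) // 2
        if pval(mid) <= threshold:
            hi = mid
        else:
            lo = mid + 1
    return hi


@dataclass(frozen=True)
class CriticalSubsetProfile:
    """Per-pathway critical subset sizes across a sample-size grid."""

    pathway_id: str
    n: int
    sample_sizes: tuple[int, ...]
    critical_k: tuple[int | Unreachable, ...]

    @property
    def representation_rate(self) -> tuple[float | Unreachable, ...]:
        """critical_k / pathway size, per grid point."""
        return tuple(
            ck / self.n if not isinstance(ck, Unreachable) else UNREACHABLE
            for ck in self.critical_k
        )


def profile_database(
    db: PathwayDatabase,
    sample_sizes: Sequence[int],
    alpha: float = 0.05,
    rank: int = 1,
    threshold: ThresholdSpec | None = None,
) -> list[CriticalSubsetProfile]:
    """Critical-subset profile for every pathway in a database.

    The raw-scale cutoff defaults to the rank-``rank`` Benjamini-Hochberg
    step-up bound alpha*rank/m with m the database's pathway count (rank 1
    coincides with Bonferroni); pass an explicit :class:`ThresholdSpec`
    to override.
    """
    N = db.n_assigned
    if threshold is None:
        threshold = ThresholdSpec(
            alpha=alpha, correction="bh_rank1", m=len(db.pathways), rank=rank
        )
    cutoff = threshold.raw_cutoff()
    grid = tuple(int(K) for K in sample_sizes)
    for K in grid:
        if not (1 <= K <= N):
            raise ValueError(f"sample size {K} outside 1..{N}")
    profiles = []
    for p in db.pathways:
        ks = tuple(critical_subset_size(p.size, N, K, cutoff) for K in grid)
        profiles.append(
            CriticalSubsetProfile(
                pathway_id=p.id, n=p.size, sample_sizes=grid, critical_k=ks
            )
        )
    return profiles


@dataclass(frozen=True)
class ProfileRatio:
    """Coarse/fine critical-subset ratios for one matched pathway pair."""

    pair_id: str
    sample_sizes: tuple[int, ...]
    ratios: tuple[float, ...]  # only grid points where both sides reachable

    @property
    def median_ratio(self) -> float:
        return median(self.ratios)


def ratio_profiles(
    fine: CriticalSubsetProfile, coarse: CriticalSubsetProfile
) -> ProfileRatio:
    """Elementwise coarse/fine critical-subset ratios on a shared grid.

    Grid points where either side is unreachable are excluded; an empty
    overlap is an error.
    """
    if fine.sample_sizes != coarse.sample_sizes:
        raise ValueError("profiles computed on different sample-size grids")
    kept_sizes, kept_ratios = [], []
    for K, kf, kc in zip(fine.sample_sizes, fine.critical_k, coarse.critical_k):
        if isinstance(kf, Unreachable) or isinstance(kc, Unreachable):
            continue
        kept_sizes.append(K)
        kept_ratios.append(kc / kf)
    if not kept_ratios:
        raise ValueError(
            f"no sample size where both {fine.pathway_id} and {coarse.pathway_id} "
            "reach significance"
        )
    return ProfileRatio(
        pair_id=f"{fine.pathway_id}|{coarse.pathway_id}",
        sample_sizes=tuple(kept_sizes),
        ratios=tuple(kept_ratios),
    )
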
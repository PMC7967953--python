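# Methods

## The statistical model

A pathway database assigns genes to named pathways. For enrichment the
background ("universe") is the set of *pathway-assigned* genes — the
union of all gene sets, of size N — not the genome: genes no pathway
claims carry no information for a pathway-level test, and the annotation
totals of interest (e.g. 1096 assigned genes across 354 pathways for a
fine-grained E. coli annotation versus 1686 across 119 pathways for a
coarse one) are what make cross-database comparisons non-trivial. A
declared universe, when supplied, is used for validation and can be
opted into as the background (`enrich(..., use_declared_universe=True)`).

Given K significant genes of which k fall in a pathway of size n, the
enrichment statistic is the one-tailed upper hypergeometric probability
of *k or more* pathway genes:

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

Only this enrichment tail is computed — no depletion (two-tailed) test
and no mid-p adjustment; the plain tail is the simplest, most tractable
form and is what the bundled reference values use. Descriptions of this
statistic sometimes typeset the summation with its bounds reversed; the
implementation follows the words "k or more", which is also the only
reading that reproduces the reference grids. P(X >= 0) is returned as
exactly 1.

Two analytic facts drive everything downstream, and both are enforced as
randomized property tests:

- **Size monotonicity.** At fixed (N, K, k), P(X >= k) is strictly
  increasing in pathway size n (outside the saturated support region
  k <= n + K - N, where both tails equal 1). A smaller pathway covering
  the same observed genes is always more significant, and the advantage
  grows with k.
- **Tail dominance.** At fixed (K, n, N), P(X >= k) is strictly
  decreasing in k (again outside saturation).

## Multiple-testing corrections

`bonferroni(p, m)` is min(1, p·m) with m the pathway count of the
database (not any class-hierarchy count — the multiplier is a parameter
and defaults to `len(db)`, overridable). `bh_adjust` is the standard
Benjamini-Hochberg step-up procedure (delegated to
`statsmodels.stats.multitest`). For threshold-style questions where the
rank of a hypothetical hit is unknown (the critical-subset analysis),
the rank-1 BH bound alpha/m is used: BH always penalizes the smallest
p-value by the full factor m, so rank 1 coincides with Bonferroni. The
rank is exposed (`ThresholdSpec(rank=...)`, cutoff alpha·rank/m) for
sensitivity analyses.

## Reference grids and their verification

`granora.comparison` ships six fine/coarse pathway pairings (sizes 3/34,
12/18, 4/17, 9/16, 10/78, 13/51 over backgrounds 1096/1686 with
multipliers 354/119) together with reference p-value grids transcribed
from the enrichment literature. All grid values arise in the K = k
regime — every significant gene lies in the pathway — which collapses
the tail to its single top term; this regime is hard-coded into
`build_comparison` and is the correct reading of the reference rows
(verified numerically cell by cell).

The verifier rounds each computed value to the printed precision of its
cell (2 significant figures for the four amino-acid pairings, 3 for the
two nucleotide pairings) and requires equality; bit-exact string
comparison across typography is meaningless. Three cells are annotated
`discrepant` in the bundled data: exact big-integer-rational
recomputation (independently confirmed by `scipy.stats.hypergeom`) gives
7.094e-9 / 8.442e-7 for the selenocysteine pairing at k=4 (coarse side)
and 9.490e-3 for the valine pairing at k=1 (coarse side), while the
transcribed values read 7.2e-9 / 8.5e-7 / 9.4e-3 — about one unit in the
last printed digit. For these cells the verifier requires agreement
within 1.5 units of the last printed digit instead of digit equality;
loosening is deliberately confined to the annotated cells.

One further ambiguity in the source material: the coarse-side grids are
described in places as recomputed against the fine background of 1096
genes, but the corrected columns are only consistent with the native
N = 1686 and m = 119. The background is therefore an explicit parameter
(`PairComparisonSpec.N_coarse`), and the bundled specs use the values
that actually reproduce the grids.

## Critical subset sizes

`critical_subset_size(n, N, K, threshold)` is the smallest k in
1..min(n, K) with P(X >= k) <= threshold. Tail dominance makes the
predicate monotone in k, so a binary search suffices; it is verified
against a naive full scan on randomized tuples. Unreachability (even
k = min(n, K) is not significant — common for 3-gene pathways at
Bonferroni-corrected thresholds once K is large, because the tail at
full coverage, C(K,n)-driven, grows with K) is reported as a typed
falsy sentinel `UNREACHABLE`, never 0 or n+1, so downstream medians can
exclude those grid points explicitly.

`profile_database` evaluates every pathway over a sample-size grid
(default 50..500 step 50 — the step is a package choice; only the range
is externally motivated). `ratio_profiles` forms elementwise
coarse/fine ratios where both sides are reachable. Because the
averaging procedure for a single summary number is genuinely ambiguous
(over pathways? over grid points?), the report emits both the
per-pair median ratios and their median, rather than privileging one.

## Analogous-pathway matching

No test for "these two pathways from different databases are the same
process" is canonical; the package quantifies overlap with the same
hypergeometric machinery: for fine set A and coarse set B in a joint
universe of size N_J (the union of both databases' assigned genes),
`overlap_pvalue` is P(|A ∩ draw| >= |A ∩ B|) for a random |B|-subset.
Candidates need a non-empty overlap and fine size >= 3 (configurable);
"highly significant" defaults to p <= 0.05 after Bonferroni over all
scored candidates (conservative; both the cutoff and the correction are
parameters, and ground-truth recovery tests run with raw p <= 1e-4).
One-to-one resolution sorts by (p rounded to 2 significant figures,
combined size, identifiers) and accepts greedily — "comparable
p-values" tie-break to the smallest combined gene count, and the total
order makes the output deterministic with no hash dependence. Gene
identifier reconciliation across databases is the caller's
responsibility: identifiers are opaque, case-sensitive strings, with an
optional trim+uppercase normalizer that is off by default.

## The synthetic dual-granularity world

The generator emulates the *structure* the analysis depends on: many
small single-process pathways, mostly disjoint, unioned in groups into
large mosaic pathways; significant-gene sets concentrated in perturbed
pathways over a uniform background; and the mosaic false-positive
construction (one hit per member process). Defaults, chosen once:

- `universe_size=4288` — the E. coli K-12 protein-coding gene count. A
  1096-gene universe cannot hold 354 *disjoint* pathways of mean size 8
  (the real annotation overlaps heavily; the zero-noise synthetic one
  cannot), so the universe is genome-sized and the *assigned* total
  comes out near 2900, keeping test magnitudes comparable to the
  reference grids while preserving exact disjointness for ground truth.
- `n_fine_pathways=354`, `fine_size_range=(3, 13)` — the fine-annotation
  scale of the bundled pairings.
- `grouping_factor=3` — 118 coarse mosaics (cf. 119), and because the
  per-pair ratio E[coarse size / fine size] ≈ g·E[size]·E[1/size] ≈
  1.2·g for sizes uniform on 3..13, matched pairs average a ≈3.5x size
  ratio.
- `overlap_noise=0.0` — pathways pairwise disjoint, so fine-to-coarse
  containment is exact ground truth; noise > 0 replaces that fraction
  of each pathway's genes with genes assigned elsewhere.

All sampling flows through one explicit `numpy` generator per call; no
global random state.

What the generator does **not** emulate: real annotations share genes
across pathway variants, assignment is far from uniform, coarse maps are
not exact unions of fine pathways, and identifier namespaces differ
between databases. A green test on this world therefore establishes the
machinery (solver correctness, recovery, the direction and rough
magnitude of granularity effects), not the literal statistics of any
real database pair — in particular the published per-pair counts (69
analogous pairs, "3.5x larger", "1.3-2.0x as many genes") require the
real membership files, which are accepted as optional user-supplied
input but never bundled or asserted.

## Numerics

- Default evaluation is in log space: `scipy.special.gammaln` for log
  binomials, `logsumexp` over tail terms, accurate to ~1e-11 relative
  even at p ~ 1e-40 (tested against the exact path at 1e-6, typically
  far better).
- `exact=True` switches to big-integer `Fraction` arithmetic
  (`math.comb`) — slow, bit-true, used by oracles and available for
  verification at any magnitude.
- `log=True` returns the natural-log tail without exponentiating.
  Double precision cannot represent p closer to 1 than ~1e-16 or
  smaller than ~1e-308; order comparisons in extreme regimes should
  compare log upper tails when p < 0.5 and log *lower* tails (also
  provided) when p is near 1.
- Printed-precision comparison uses decimal significant-figure rounding
  (`float(f"{x:.{s-1}e}")`, round-half-even).
- Degenerate inputs are rejected at construction (`EnrichmentQuery`
  validates 0 <= k <= min(n, K), n <= N, K <= N; empty pathways, empty
  gene lists, and infeasible packings raise immediately with the
  violated constraint named).

## Known limitations

- The enrichment background convention (pathway-assigned genes) makes
  p-values across databases with different assignment totals directly
  comparable only in the sense the comparison module formalizes; users
  wanting genome-wide backgrounds must declare a universe explicitly.
- `enrich` treats the significant set as unordered input, as ORA
  requires; no rank-based (GSEA-style) statistics are provided.
- The matching test's joint-universe hypergeometric is a modeling
  choice, not a community standard; its defaults are conservative and
  every knob is exposed.
- Reported BH-adjusted values in `enrich` are computed across the
  pathways of one database scan; combining scans requires re-adjustment
  by the caller.
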
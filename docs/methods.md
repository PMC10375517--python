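# Methods

## Model

A hetnet is represented by one 0/1 adjacency matrix per metaedge, bound to a
fixed node ordering per metanode (the HetMat directory layout). The package
assumes simple typed graphs: no self-edges at the node level, no multi-edges
within a metaedge, undirected self-typed metaedges stored symmetrically.
The zero-diagonal assumption is load-bearing — every duplicate-node
correction treats the diagonal of a same-type product as the walks that
revisit a node, which is only exact when single edges cannot do so.

### Degree-weighted path counts

For an oriented metaedge traversal, the degree-weighted matrix is
`W = diag(d_row^−w) · A · diag(d_col^−w)`, with degrees taken per metaedge
(row and column sums of the oriented adjacency). Zero-degree nodes get
weight 0 rather than raising an error: they lie on no path, so their
contribution is vacuously zero. The DWPC matrix of a metapath sums the path
degree product over duplicate-free paths; at w = 0 it is the plain path
count.

The damping exponent `w` (dimensionless, default 0.5) controls how strongly
paths through hub nodes are discounted: w = 0 ignores degree entirely,
w = 1 fully normalizes each edge by its endpoint degrees. The 0.5 default
takes square roots of degrees, a middle ground that keeps high-degree
evidence without letting hubs dominate. It is configurable per call.

### Duplicate-node corrections and the order of operations

Walk products overcount because they revisit nodes. The dispatcher:

1. reads the metanode sequence of the metapath and finds all types that
   occur more than once;
2. merges overlapping occurrence intervals into repeat groups; stretches
   between groups are plain matrix products;
3. classifies each group and routes it:
   - one type, 2–3 occurrences (inserted nonrepeated types allowed):
     chain the between-occurrence products, zeroing the main diagonal after
     every return to the repeated type;
   - two types in nested order `X…Y…Y…X` with the outer type exactly twice:
     resolve the interior recursively, then zero the outer diagonal;
   - two types in overlapping order `X…Y…X…Y`, each twice: the
     inclusion–exclusion identity
     `D1·D2·D3 − diag(D1·D2)·D3 − D1·diag(D2·D3) + D1 ⊙ D2ᵀ ⊙ D3`,
     where each Di may itself be a composite product over inserted
     nonrepeated types;
   - anything else (a type occurring ≥4 times, three-plus interleaved
     repeated types such as ABCABC): exact path enumeration
     (`dwpc_general`).
4. multiplies the factor matrices left to right.

The recursion covers hierarchical patterns like `C(BABA)C XYZ`. Exactness of
every route is enforced by the oracle-equivalence property suite: on random
hetnets, the dispatcher must agree with `dwpc_general` to 1e−8 relative
tolerance at w = 0.5 and exactly (integer path counts) at w = 0, for every
metapath of length ≤ 4 in the fixture metagraph.

One deliberate categorization choice: a metapath like *DrDaGaDrD* has four
occurrences of the Disease metanode, so it is classified as a long repeat
and routed to enumeration; the inserted Gene requires no treatment of its
own, but the 4-fold repeat is beyond the closed-form corrections.

Two approximations are provided for comparison only and never used by the
dispatcher: `dwpc_approx` corrects only the first repeat inside complex
groups, and `dwpc_mayers` zeroes the diagonal at every occurrence of the
first repeated metanode.

### Caching

Segment and full-metapath results are cached by (abbreviation, damping) in
memory and, for disk-backed stores, under `path-counts/dwpc-<w>/`. A cache
hit returns the identical array, so results are bit-identical regardless of
cache state; the reverse orientation is served as a transpose view.

## Permutation null

XSwap randomizes each metaedge independently: each attempt draws two edges
(a,b), (c,d) — endpoint roles flipped uniformly for undirected edges — and
proposes (a,d), (c,b), rejecting self-edges and duplicates. Attempts default
to 10× the edge count; rejected proposals count as attempts and are not
retried (the standard formulation; whether the original tooling retried is
not documented, and retrying would only change mixing speed, not the
stationary distribution). Undirected self-typed metaedges are swapped as
unordered pairs and re-symmetrized, which preserves degrees exactly; for
bipartite metaedges the two endpoint namespaces are kept disjoint so a row
index can never be mistaken for a column index. Per-metaedge sub-seeds are
derived from the user seed and a CRC of the metaedge abbreviation, making
permutation reproducible and independent of iteration order. The default of
200 permutations matches the precompute pipeline's expectations; both count
and multiplier are configurable.

## Degree grouping and the gamma-hurdle null

Because permutation preserves only degree, null DWPCs for all node pairs
with the same (source degree, target degree) are exchangeable and are pooled
per degree pair. Each group keeps five running totals — N, n nonzero, Σx,
Σx², number of permutations — which are additive across permutations
(`merge_stats` is a commutative monoid) and sufficient for inference.
Degrees are those of the metapath's first metaedge (source side) and last
metaedge (target side).

Nonzero nulls are modeled as Gamma(α, rate β) behind a hurdle λ = P(X > 0).
Method-of-moments estimates from the summaries: λ̂ = n/N, m = Σx/n,
v = (Σx² − n·m²)/(n−1), α̂ = m²/v, β̂ = m/v. Note the estimator labels are
fixed by the density convention `f(x) ∝ x^(α−1)·e^(−βx)` (so mean = α/β):
m²/v estimates the shape and m/v the rate. The parameter-recovery suite
(27-point grid, 10⁵ draws, λ within ±0.01, α and β within ±5%) pins this
convention down empirically.

The tail probability of an observed DWPC t > 0 is computed as
`p = λ · Q(α, βt)` with Q the regularized upper incomplete gamma
(numerically stable for large α). The λ factor makes the hurdle and gamma
components sum to a coherent probability — P(X ≥ t) for the full mixture —
and yields calibrated p-values when observations come from the same
mixture (verified by simulation: fraction of p ≤ 0.05 equals 0.05 ± 0.01
over 10⁴ replicates). A conditional-on-nonzero variant (no λ factor) is
exposed via `hurdle_weighted=False` but is not the default.

Empirical fallbacks, computable from summaries alone, apply when the fit is
unavailable: t = 0 → p = 1; all nulls zero and t > 0 → p = 0; zero-spread
nonzero nulls with common value v → p = 0 if t > v, else n/N. "Fit
unavailable" is operationalized as n < 2 or zero variance — the minimal
workable rule, since Bessel correction needs n ≥ 2.

## Multiple testing and storage prioritization

P-values are Bonferroni-multiplied by the number of metapaths sharing the
query's source metanode, target metanode, and length. The precompute
pipeline retains rows with nonzero DWPC that pass a metapath-specific
threshold: everything for length-1 metapaths (users always want direct
edges), and adjusted p < 5·(n_source·n_target)^(−0.3) for longer ones, which
penalizes metapaths with enormous DWPC matrices. On tiny fixtures this
threshold exceeds 1 and retains every nonzero row — expected behavior of
the formula at small metanode sizes, not a bug.

Canonical orientation economy: only the lexicographically smaller of
{metapath, reverse} is enumerated, computed, and stored; queries in either
direction are answered via the transpose law DWPC(reverse m) = DWPC(m)ᵀ,
with degree-group keys swapped accordingly. When a queried pair's degree
group is absent from the null statistics, the p-value is reported as
missing rather than extrapolated, since every degree realized in the store
is guaranteed a group by construction — absence signals a store mismatch.

## Synthetic data

`generate_hetnet` samples each metaedge independently at a requested
density (Bernoulli per cell, diagonal zeroed, undirected self metaedges
symmetrized from the upper triangle), or by stub matching when an explicit
degree sequence is given. The default random fixture uses three metanodes
and five metaedges — an undirected self metaedge, a directed self metaedge,
and three bipartite metaedges forming typed cycles — because that is the
smallest schema whose length-≤4 metapaths exercise every repeat-pattern
class (short, interleaved, nested, overlapping, long, disjoint, complex).

What the generator does *not* emulate: heavy-tailed degree distributions,
degree–degree correlations, modular or clustered structure, and the scale
of real knowledge graphs. Passing tests on these fixtures therefore
establish algorithmic correctness (path counting, degree preservation,
estimator behavior), not biological performance of connectivity search on
any particular real network.

Two hand-built toys anchor worked values: toy-GiG (genes g0–g1–g2; the one
*GiGiG* path has PDP 0.5 at w = 0.5) and toy-CD (treats edges c0–d0, c0–d1,
c1–d0; the one duplicate-free *CtDtCtD* path c1–d0–c0–d1 has PDP 0.25,
while every c0→d0 walk repeats a node).

## Numerical choices

- Path counts are 64-bit unsigned integers; DWPCs are 64-bit floats.
  Intermediate arithmetic runs in float64 even at w = 0, because the
  inclusion–exclusion corrections subtract before they add back; counts are
  re-cast after rounding (exact below 2⁵³).
- Stored matrices use the density rule: ≥ 0.7 dense `.npy`, else compressed
  sparse `.sparse.npz`. In-memory computation densifies matrices — at the
  problem sizes this package targets for testing and examples, dense BLAS
  products are faster than sparse dispatch, and sparse/dense inputs are
  required by the test-suite to agree exactly.
- Correction algebra can leave round-off of order 1e−16 in exactly-zero
  cells; magnitudes below 1e−12 are snapped to zero before the matrix is
  returned.
- Sorting tie-breaks are lexicographic on metapath abbreviation; paths with
  equal scores order by node identifiers. Tables are therefore byte-stable
  across runs with the same seed.
- An empirical p of exactly 0 gives a path score of +∞ (−log₁₀ 0); such
  rows sort first, which is the intended reading ("more surprising than any
  null sample").

## Problem sizes used by the test and acceptance suites

Chosen as the package's own desk-scale study conditions: random fixtures of
14 nodes per metanode at densities 0.08–0.35 (seeds 0–9) for the
dispatcher-vs-oracle sweeps; 25 nodes at density 0.2 for the 200-permutation
degree-preservation check; 10⁵ draws per grid point for parameter recovery;
10⁴ replicates × 10³ nulls for calibration; 20–50 permutations for pipeline
fixtures. Hetionet-scale quantities (node-pair counts, degree-pair counts,
storage thresholds, metapath enumeration) are computed exactly from the
schema and the published node counts, which require no network data.

## Known limitations

- The dispatcher's closed forms cover single-type repeats up to three
  occurrences and two-type nested/overlapping patterns; everything else
  routes to path enumeration, which is exponential in metapath length and
  practical only at small scale. This mirrors the intended division of
  labor but means very long complex metapaths on large networks are slow.
- DWPC transformation for cross-metapath comparability (e.g., inverse
  hyperbolic sine style compaction) is exposed as a post-processing hook
  only; p-values are always computed on raw DWPCs.
- The family-wise Bonferroni adjustment is conservative; no
  false-discovery-rate procedure is provided, since FDR methods want all
  p-values at once and a uniform null — neither holds here.
- XSwap mixing is not verified beyond degree preservation and
  edge-identity destruction; very sparse or rigid metaedges (like the
  3-edge toy) can be invariant under permutation, making every null
  degenerate and every p-value 1.
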
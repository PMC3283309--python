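# Methods

## Data model and coordinate conventions

All genomic intervals are 0-based, half-open `[start, end)`.  SAM/BAM input
(1-based) is converted at the reader boundary; the plain-text ESP dialect
(`id, chrom, left read interval + orientation, right read interval +
orientation, quality`) is native.  "Insert size" always means the outer
span of the pair *including* both reads — SAM `TLEN` conventions differ, so
the reader recomputes it from the alignment coordinates.

A properly oriented pair (leftmost read forward, mate reverse) is
*concordant* when its insert lies within `[min_len, max_len]` and
*deletion-indicating* when the insert exceeds `max_len`.  Everything else —
wrong orientation, insert below `min_len` (possible insertion),
inter-chromosomal pairs, overlapping reads (empty breakpoint region) — is
labeled `other` and excluded: only deletions are modeled.  Very small
deletions (≲ 10 bases), detectable inside single reads, are out of scope by
construction of the paired-end signal.

Cutoffs are estimated as nearest-rank quantiles (value at 1-based rank
`ceil(q·n)`) of the insert sizes of properly oriented pairs, by default the
0.1% and 99.9% quantiles with a mapping-quality floor of 20.  Nearest rank
keeps the cutoffs on observed integer values and is deterministic; the
quantile levels, the quality floor, and whether a sample's cutoffs are
estimated or supplied are all exposed as parameters.

## Clustering

Cluster validity (one deletion length compatible with every member, fitting
inside the shared breakpoint region) is *hereditary*: subsets of valid
clusters are valid.  Maximal valid clusters are therefore enumerated by a
Bron–Kerbosch-style branch-and-extend in which the candidate and excluded
sets are re-filtered with the full multi-way validity check at every
extension.  This is exact — the pairwise-compatibility graph alone is not,
because the deletion-length constraint couples all members through the
breakpoint-region intersection; the test suite contains pairwise-compatible
triples that are jointly invalid, and checks equivalence with exhaustive
subset enumeration on random instances.

Mappings are pre-partitioned into connected components of span overlap
(clusters cannot cross them), clusters are reported in `(chrom, br.start,
br.end, support)` order, and a chromosome whose cluster count exceeds
`max_clusters` (default 10⁶) is skipped with a diagnostic while the others
are still processed — maximal-cluster counts can explode combinatorially on
dense discordant data.  Singleton clusters are admitted: on real data many
singletons are genuine deletions that simply lack coverage.

## Conflicts

A cluster node blocks its whole read hull (leftmost read start to rightmost
read end) and demands `del_min` free bases within its breakpoint region; a
concordant mapping is a demand-zero node blocking its span.  The blocked
region deliberately includes the cluster's own putative deletion gap: the
model assumes each cluster explains exactly one deletion, so configurations
that would require threading a second deletion through another cluster's
span are treated as conflicting.

Minimal conflicting sets are found by testing overlap-connected pairs and
triples with the consistency oracle.  For cluster-only nodes this is
complete (minimal conflicting sets cannot exceed three elements — verified
empirically by exhaustive enumeration in the acceptance suite).  With
concordant nodes the same pair/triple search is used; triples with two or
more demand-zero nodes are skipped, since two pure blockers can only both be
essential through configurations (one cluster starved by several disjoint
concordant spans) that the pair/triple procedure does not claim to cover.
This is a known, deliberate limitation of the procedure.

Diploid consistency is 2-colorability of the conflict hypergraph.  The
exact backtracking solver refuses instances above 20 constrained nodes
(the problem is NP-hard even with edges of size 2–3); beyond that, the
pairwise-conflicting-triplet certificate gives a sound lower bound on the
number of conflicting clusters, deliberately missing exotic non-pairwise
configurations that require at least six mutually arranged clusters.
Pipeline summaries count a cluster as conflicting when it appears in such a
certified triplet.

## Four-copy assignment

Each overlapping component couples one normal deletion cluster `c` with the
tumor discordant mappings overlapping `br(c)` directly or transitively via
span overlap (span overlap is the default membership test; breakpoint-region
overlap is available as an option).  Components that are not independent —
sharing a tumor mapping, or built on normal clusters with overlapping
breakpoint regions — are dropped and reported rather than solved jointly.

Per component, with all deletions assumed heterozygous:

1. Concordant tumor mappings are explained on the normal chromosome copy
   that does not carry the deletion, where they constrain nothing.  A
   stricter mode (`--concordant-constrain`) places them as blockers on both
   tumor copies instead.
2. The *maximum supporting subset* is the largest mapping set that merges
   with `c` into one valid cluster.  It is computed exactly by a candidate
   sweep: an optimal deleted-segment placement `[x, x+d)` can be normalized
   so `x` is some breakpoint-region start and `d` some member's minimal
   deletion length, leaving O(n²) placements to score; ties are broken by
   the lexicographically smallest id set.  Support is assigned greedily and
   never reconsidered for tumor clusters — re-assignment is an explicit
   non-goal, so reported tumor-specific support counts are lower bounds.
3. The remaining mappings are assigned by branch-and-bound to valid
   clusters on the two tumor copies, with the refined cluster `c′`
   occupying one of them (tumor cells inherit the patient deletion), such
   that each copy is haploid-consistent and the discard count is minimal.
   Branching per mapping (in `(br.start, br.end, id)` order): join an open
   cluster, open a new cluster on either copy — the copy without `c′`
   first, which avoids splitting one true deletion across copies — or
   discard.  Inconsistent partial states are pruned (consistency is
   monotone under growth), the incumbent comes from the greedy-first
   descent, and the lower bound adds a greedy matching over pairs of
   remaining mappings that provably cannot both be kept.  The search stops
   early when the incumbent meets the root bound, and honors a
   per-component time budget (default 600 s); budget-limited results are
   labeled `time_limited`.  Only the discard count is optimized; among
   equal-discard solutions the deterministic branch order fixes the result.

Refinement ratios compare `c` to `c′`: deletion-size-range width ratio and
breakpoint-region length ratio, both ≤ 1 by construction (a zero-width
initial range maps to 1).

## Simulator

The generator emulates the assumed data-generating process, not sequencing:
a single reference chromosome; heterozygous patient deletions on normal
copy 2 (inherited by tumor copy 2); tumor-specific deletions on tumor
copy 1, planted adjacent to patient deletions (gap of 1–3 read lengths)
with probability `proximity_bias`, otherwise far from everything; fragments
drawn per copy with lengths ~ Normal(`frag_mean`, `frag_sd`) truncated at
twice the read length; the tumor sample mixes normal and tumor copies
according to the contamination fraction.  Mapping coordinates are computed
from the truth; fragments whose reads would cross a deletion junction
(split reads) are dropped.  Not modeled: sequencing errors, chimeric
fragments, repeat-induced mismapping, multi-mapping reads — so passing
recovery tests demonstrates correctness of the combinatorial machinery
under the model's assumptions, not robustness to mapping noise.

Default conditions: 0.5 Mb reference, 10 patient + 5 tumor-specific
deletions of 500–2000 bases, 300 ± 30 insert with 50-base reads, 20×
physical coverage (normal) and 40× (tumor, mirroring the roughly
four-fold-deeper tumor sequencing such studies use), contamination 0.3,
`proximity_bias` 1.0 (the tumor-near-normal case is exactly the situation
the method exists for).  The deletion sizes are kept well above the
fragment-length spread so every deletion-spanning pair is unambiguously
discordant; deletions are planted ≥ 4 fragment lengths apart so distinct
components stay disjoint.  With cutoffs at the true fragment-length
extremes, every truth-matched cluster brackets its planted deletion size.

## Verification strategy

Every nontrivial algorithm is checked against an independent brute-force
oracle on randomized small instances: consistency vs. enumeration of every
integer deletion placement; maximal clusters vs. exhaustive subset search;
hypergraph 2-coloring vs. exhaustive two-copy assignment; the support step
vs. exhaustive subset search; and the branch-and-bound discard count vs.
feasibility-pruned exhaustive partition enumeration.  Exhaustive
enumeration over thousands of random haploid configurations confirms the
2-or-3 bound on minimal conflicting set cardinality.  Noise-free
simulations at the default conditions must recover every planted
tumor-specific deletion with zero discarded mappings, and components whose
tumor mappings jointly support the normal deletion must produce no
tumor-specific call (the pooled-analysis consistency property).

## Known limitations

Homozygous deletions, loss of heterozygosity and copy-number abnormalities
are not modeled (all deletions heterozygous, exactly four copies).
Deletion splitting (one cluster explaining several smaller deletions) is
excluded by assumption.  Complete diploid conflict detection at scale is
intractable; the triplet certificate undercounts.  Support assignment is
greedy with no re-assignment pass.  Multi-location read mappings and SV
types other than deletions are out of scope.
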
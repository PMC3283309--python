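# condel — consistency-based detection of tumor-specific deletions

`condel` analyzes **matched normal/tumor paired-end mapping data** to find
deletions that are specific to the tumor genome, with a focus on the hard
case: tumor-specific deletions that overlap or lie close to inherited
(patient-specific) deletions, in a tumor specimen that is **contaminated
with normal cells**.

## The model

A paired-end mapping *m* places both reads of a sequenced fragment on the
reference.  Let *span(m)* run from the left end of the left read to the
right end of the right read, and let the insert size of concordant fragments
lie in \[*minLen*, *maxLen*\] (estimated as low/high quantiles of the
insert-size distribution).  A properly oriented mapping with
|*span(m)*| > *maxLen* indicates a deletion of size between

```
delMin(m) = |span(m)| − maxLen      and      delMax(m) = |span(m)| − minLen
```

located inside the *breakpoint region* *br(m)* between the inner read ends.
A set *c* of such mappings is a **valid cluster** when one deletion length
*delLen* ≤ |*br(c)*| (with *br(c)* = ∩ *br(m)*) satisfies every member's
bracket; `condel` enumerates all inclusion-**maximal** valid clusters.

On one chromosome copy, each cluster must place a deleted segment of at
least *delMin(c)* inside its breakpoint region, avoiding every position
covered by reads of other clusters or concordant mappings.  Sets of
clusters/mappings for which this fails are **conflicting**; in a haploid
genome every *minimal* conflicting set has exactly two or three elements, so
all conflicts are found from overlapping pairs and triples.  For a diploid
genome, consistency is equivalent to 2-colorability of the hypergraph whose
hyperedges are the minimal conflicting sets (NP-hard; `condel` provides an
exact backtracking solver for small instances and the polynomial
pairwise-conflicting-triplet certificate in general).

A contaminated tumor sample yields reads from **four chromosome copies**
(diploid normal + diploid tumor).  For each normal deletion cluster *c* and
the tumor mappings overlapping it (an *overlapping component*), `condel`
solves: partition the mappings into a support set merged into *c* (giving a
refined cluster *c′*), valid tumor-specific clusters *T₁…Tₗ* placed on the
two tumor copies consistently with *c′*, concordant sets, and a **discard
set D of minimal size** — by branch-and-bound with a per-component time
budget.  All deletions are treated as heterozygous.

## Worked example

Simulate a matched pair (0.5 Mb reference, 10 patient deletions, 5
tumor-specific deletions planted next to patient ones, 30% normal-cell
contamination) and run the full pipeline:

```bash
condel simulate --seed 1 --out-prefix demo/
# normal_mappings   33295
# tumor_mappings    66578

condel pipeline --normal demo/normal.esp --tumor demo/tumor.esp \
    --lib 174,432 --out demo/run
# normal_clusters           9
# normal_conflicting        0
# components                9
# tumor_subset_mappings     172
# supporting_mappings       126
# discarded_mappings        0
# refined_normal_clusters   9
# tumor_specific_clusters   5
```

Reading the output: the normal sample yields 9 conflict-free deletion
clusters (one planted deletion received no spanning read pairs at this
seed).  172 tumor discordant mappings fall into the 9 overlapping
components; 126 of them support and refine the patient deletions, the rest
form 5 tumor-specific clusters — one per planted tumor deletion — and **no
mapping had to be discarded** to reach a conflict-free four-copy
explanation.  `demo/run/tumor_specific.tsv` lists the calls, e.g.

```
cluster_id   chrom  br_start  br_end  del_min  del_max  support
comp_c1.t1   chr1   73445     74301   692      910      5
comp_c3.t1   chr1   205445    206201  611      770      11
```

each breakpoint region and size bracket containing the planted truth.
Other subcommands: `estimate` (insert-size cutoffs), `cluster`,
`conflicts`, `assign`; SAM/BAM input is supported via `--format`.

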
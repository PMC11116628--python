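# Methods

## Signature model

The caller treats every read-level observation of a deletion as a signature
`(chr, start, svlen, end)` in 0-based half-open coordinates and never
re-examines bases: all downstream reasoning is on positions and lengths.
Two extraction rules produce signatures.

**CIGAR deletions.** After dropping unmapped records, secondary alignments,
and records with MAPQ < `min_mapq` (default 20), every `D` run strictly
longer than `min_cigar_del` (default 30 bp) becomes a signature; its start
is the record start plus the reference length consumed by the preceding
operations (`M/D/N/=/X`). `N` is treated as reference-consuming bookkeeping
only, never as deletion evidence. Same-read, same-chromosome signatures are
then merged left-to-right whenever the gap `start₂ − end₁` is in
`(0, max_merge_gap]` (default 30 bp), cascading, because a single deletion
in a noisy read is often reported as two or three nearby runs. The merged
signature keeps `svlen = svlen₁ + svlen₂` and `end = end₂`; the gap bases
are deliberately *not* added to `svlen`, so for merged (and split, below)
signatures `end − start` can exceed `svlen`. `svlen` is the deletion length
everywhere downstream; `end` is only a span bound (used by the depth
profile). Overlapping same-read signatures (gap ≤ 0) are kept separate —
the conservative choice, since a negative gap usually means messy local
alignment rather than two real events.

**Split alignments.** A read's primary + supplementary records (secondary
records are excluded; supplementaries *are* the split evidence; an `SA` tag
parser exists for files that lack supplementary records) are projected to
segments with query intervals in original-read orientation — reverse-strand
records are flipped using the full read length including hard clips — and
sorted along the read. For each read-adjacent pair on one chromosome and
strand, `Distance = ref_gap − read_gap`; a value in
`[min_split_del, max_split_del]` = [50, 100 000] is a deletion whose start
is the reference-leftmost segment's end. For reverse-strand reads the
segments descend on the reference, so the reference gap is taken between
the reference-ordered pair while the read gap stays in read order; for
forward reads this is the identical formula. Only read-adjacent pairs are
examined: with three or more segments, non-adjacent pairings would
double-count the intervening segment's span.

A per-record MAPQ filter (rather than per-read) means a low-quality
supplementary is dropped even when its primary passes; the surviving single
segment then simply produces no split signature.

## Layer-1 clustering: loci

Signatures are split at `size_split` = 2000 bp (ties to the large side, so
borderline events get the positionally tighter method).

*Large* sites are swept with a `window` = 1500 bp sliding window over start
positions: a window opens at the first unclustered site's start and
captures every site starting inside it; the follow-on window begins at the
previous window's end and, if nonempty, extends the *same* cluster; an
empty window closes the cluster. The alternative reading — each nonempty
window starts a new cluster — would split sites 101 bp apart across a
window boundary; it is kept behind the `window_extension=False` ablation
hook.

*Small* sites use an evidence-depth profile: each span `[start, end)`
increments per-base depth, and each maximal run of depth ≥ 1 (a "peak") is
one cluster. Depth threshold 1 is the weakest assumption and makes the
procedure exactly the connected components of the span-overlap graph
(touching spans connect), which is how the tests verify it. The
implementation sweeps the sorted span endpoints instead of materialising a
chromosome-length array, which is outcome-identical and keeps memory
bounded on real chromosomes; spans beyond the chromosome end are clipped
with a warning.

Both methods, and all chromosomes, are independent; `layer1` may run
chromosomes on a thread pool and sorts its output so results are
byte-identical to serial execution.

## Layer-2 clustering: allele lengths

One locus can carry two different-length deletion alleles (one per
homologous chromosome). Within each layer-1 cluster, every signature starts
as a singleton; a cluster's length is the mean of its members' `svlen`; the
pair with the smallest absolute mean difference merges, repeatedly, until
two clusters remain (1-D centroid-linkage agglomeration). The two survivors
merge into one candidate cluster iff their length-difference rate
`|len₁ − len₂| / max(len₁, len₂)` is strictly below `rate_threshold` = 0.20
(exactly 0.20 stays split). Ties in the minimum difference break by smaller
combined size, then smaller mean, then smaller earliest start, making the
procedure deterministic under input permutation. Position never enters the
layer-2 distance — layer 1 already constrained it. At most two candidate
clusters can emerge (two haplotypes); clusters of size ≤ 2 skip straight to
the rate test. `layer2_enabled=False` bypasses the split and exists to
demonstrate its effect (one merged, wrong-length call per heterozygous
locus).

## Filtering and calling

Support is the candidate cluster's signature count (a `unique_reads` option
deduplicates by read name; default off, since each signature is one
independent observation and one read rarely observes a deletion twice after
intra-read merging). The two-case filter keeps a lone candidate at
`support ≥ min_support` and each of two candidates at
`support ≥ min_support / 2` — real-valued half, no rounding. The reported
call is the member minimising `|start − mean_start| + |svlen − mean_len|`
(ties: smaller start, then svlen, then read name). L1 was chosen because it
weighs a base of positional error equal to a base of length error and never
synthesises unobserved coordinates; the metric is a design choice, as is
reporting `svlen` (not `end − start`) as the deletion length, consistent
with the merge rule above. Calls from different loci are never post-merged.

Output is VCF 4.2 with symbolic `<DEL>` alleles: POS is the 1-based anchor
base before the deletion (0-based start `s` ⇒ POS `s`; a deletion at
position 0 falls back to POS 1 with REF `N`), `SVLEN` negative, `END` the
1-based inclusive end, `SUPPORT` the support count, REF from the FASTA when
given else `N`, and a `./.` genotype placeholder — the caller does not
genotype.

## Simulator

The generator emits alignments constructed directly from known implants —
no aligner — so fixtures are hermetic and byte-reproducible from the seed.
The reference is i.i.d. uniform ACGT (the caller has no sequence-level
logic, so content is irrelevant). Deletions are placed one per
equal-length slot with jitter, guaranteeing ≥ `min_spacing` (4500 bp, three
layer-1 windows) plus a read length between loci so no read spans two.
Lengths cycle through the bands [50,200), [200,500), [500,1000),
[1000,2000), [2000,10000). Reads of `read_length` = 8000 bp (matching
deep noisy long-read runs, average ≈ 7.9 kb) tile each haplotype at half
the total `coverage` with interleaved phases; alternate reads carry the
reverse-strand flag. A spanning read shows a deletion below
`split_rep_threshold` = 2000 bp as one `D` op — or, with probability
`frag_prob`, as two `D` ops (⌊L/2⌋ and L − ⌊L/2⌋ − 10) separated by a 10 bp
spurious match, emulating error-driven fragmentation — and a larger
deletion as a primary + supplementary pair with `SA` tags whose implied
`Distance` equals the implanted length. MAPQ is 60 throughout; a `noise`
option duplicates a fraction of reads at MAPQ 10 to exercise the filter.
Truth is written as TSV and as a VCF using the same anchor convention as
the caller, so the evaluator compares like with like.

What the simulation does **not** contain: base-level sequencing errors and
the alignment noise they cause (breakpoint jitter, clipped edges, chimeric
artifacts), SNVs/insertions, repeats and low-complexity sequence, mapping
ambiguity, or coverage fluctuation. Perfect scores on these fixtures
therefore validate the *logic* — extraction arithmetic, clustering
behaviour, filter cases, coordinate conventions — not performance on real
data, where support thresholds and the clustering tolerances do the heavy
lifting.

## Evaluator

Matching is the convention of SV benchmarking tools: same chromosome, start
within `refdist` = 500 bp, smaller/larger length ratio ≥ `pctsize` = 0.7,
greedy one-to-one with the closest-start call winning; a heterozygous
locus with two allele lengths counts as two truth entries. Reciprocal
overlap and genotype options of full benchmarking suites are deliberately
not emulated. Per-band reports assign each call/truth to the half-open band
containing its length, with the last band open-ended. Precision with zero
calls (and recall with zero truths) is reported as null rather than 0.

## Numerical and testing choices

All thresholds above are exposed in the CLI with the defaults shown.
Problem sizes in the test-suite and acceptance scenarios — 2 Mb
chromosomes, 20 deletions, 10–30× coverage — were chosen as the smallest
sizes at which every length band, both evidence classes, both filter cases,
and the heterozygous geometry all occur with double-digit supporting reads.
Clustering correctness is checked against independent brute-force oracles
(interval-graph components, a window-index re-derivation of the sweep, and
an exhaustive greedy agglomeration) on hundreds of random instances, and
pipeline determinism is checked byte-for-byte across repeat runs, thread
counts, and shuffled input record order.

Known limitations: no genotyping, no non-deletion SV types, no
inter-chromosomal events, no local realignment or breakpoint refinement,
and no more than two alleles per locus.
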
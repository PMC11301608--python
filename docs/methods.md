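# Methods

## Text model and coordinates

A collection is the concatenation of reference genomes in tree
(left-to-right) order, each terminated by one `$`. All offsets are
0-based; intervals `[lo..hi]` are inclusive. Genome (document) indices
are 0-based: the document of text position p is the number of `$`
strictly before p. Before suffix sorting an implicit sentinel smaller
than every symbol is appended, so a text of length n has n+1 suffixes
and the whole-text BWT interval is `[0, n]`. Symbol order is
`sentinel < $ < # < A < C < G < T` (digest modes:
`sentinel < $ < run-symbol < dense codes ascending`).

Degenerate IUPAC codes in references are resolved to a compatible base by
a generator seeded from the record name (CRC32), keeping the alphabet at
four bases while staying reproducible and order-independent. This is a
package decision; curated rRNA databases contain such codes and any fixed
resolution policy is defensible.

## Augmented FM-index

Components: suffix array (prefix doubling over `np.lexsort`,
O(n log² n)); BWT and per-symbol occurrence lists (rank/select by binary
search); LCP by Kasai's inversion with `LCP[0] = -1`; sparse tables for
leftmost-arg-min/max over LCP and SA; precomputed previous/next
*strictly* smaller value arrays over LCP (monotonic stacks — note that
popping on equality in a single combined scan silently computes
next-smaller-*or-equal*, which breaks contraction; the implementation
uses two independent scans and the test-suite pins the strict semantics
against linear scans). Plain arrays are used throughout rather than
succinct structures: at the scales this package targets the logarithmic
query bounds are met trivially, and the test surface is exact
equivalence with naive scans, not space.

Serialization writes text/BWT at one byte per symbol (alphabets < 255),
SA/LCP as little-endian int32, the separator bitvector packed 8
positions per byte, plus JSON metadata. `serialized_size_bytes` sums
these components without writing; only *relative* sizes between modes
are meaningful, since any absolute size depends on the chosen widths.

## Matching statistics and MEMs

MS[i] is the length of the longest prefix of `read[i..]` occurring in
the text. Computed right to left: extend by backward step; on failure,
contract. Contraction with character c finds the nearest BWT copies of c
before position `lo` (at p) and after `hi` (at q); the candidate depths
are `min LCP[p+1..lo]` and `min LCP[hi+1..q]`; the larger wins, with
ties broken toward the p-side (both sides denote the same prefix, so the
depth is identical either way); the enclosing interval of the winning
prefix is `[PSV(t), NSV(t)-1]` at the leftmost arg-min t. If c is absent
from the BWT entirely, the state resets to the whole interval at depth 0.
Each contraction strictly decreases the depth, so the loop terminates.

MEMs start where MS[i] ≥ min_mem_length (default 1; the classifier's
longest-MEM rule makes short MEMs irrelevant unless *all* MEMs are
short) and MS[i−1] ≤ MS[i]. Read symbols outside the index alphabet
yield MS 0 at their positions and break matches. In digest modes MEM
lengths are counted in digest characters.

## KATKA kernels

A position survives iff it lies in the first or last whole-collection
occurrence of some `$`-free kmax-mer, or is a `$`, or belongs to a
genome shorter than kmax (kept verbatim, preserving k-mer fidelity for
every k up to the genome length). Maximal omitted runs become a single
`#`; runs adjacent to a `$` — or to the start or end of the text, which
bound matches the same way — are dropped outright. First/last
occurrences are found in one hashing pass over all kmax-mers, then
intervals are painted. For every k ≤ kmax the kernel has exactly the
collection's k-mer set, and each k-mer's first/last kernel occurrence
lies in the same document as in the collection; both properties are
enforced by randomized tests against brute-force enumeration.

## Minimizer digests

Scheme: minimizer width k (default 3), window w (default 10) in k-mer
positions, affine hash `h(x) = (a·x + b) mod m` with defaults a=2544,
b=3937, m=8863 on the base-4 value x of the k-mer (A=0..T=3). Position j
is selected iff it is the *leftmost* hash minimum of some window of w
consecutive k-mer positions containing j. A sequence with fewer than w
k-mers uses one window over all of them (the window definition is vacuous
there, but every non-empty sequence must digest deterministically); a
sequence shorter than k digests to nothing. With the defaults the hash
is injective on the 64 possible 3-mers (gcd(a, m) = 1, 4^k ≤ m; checked
at scheme construction).

A caveat on partial patterns: a substring of a genome can select a
*boundary* minimizer (its first or last window is truncated) that the
full genome's digest did not select, so the document-range guarantees of
digest matching hold exactly for full-genome patterns (tested) and only
heuristically for arbitrary substrings; the evaluation treats any
resulting misses as ordinary classification errors.

Digest characters are dense ranks of the selected k-mer values over the
set present in the collection — not raw hashes — so character identity is
collision-free for any k; the hash only drives selection. Pattern
digests use the same scheme; pattern k-mers never selected in the
collection map to a reserved non-matching code. The ASCII rendering
(codes 37..100 for k=3, ordered by k-mer value) is cosmetic and
round-trips through `parse_ascii`.

Two consecutive selected positions are at most w apart (window
guarantee, property-tested), so a pair of adjacent digest characters
stands for a source substring between k+1 = 4 and roughly w+k source
characters; the acceptance script measures the minimum (4) by randomized
search.

Per-genome digests are joined by `$` into the collection digest; empty
digests still contribute their `$`, keeping document numbering intact.
Kernels of digests run the identical kernelization over digest tokens
with a dedicated run symbol outside the dense alphabet.

## Classification

A MEM's document range is the inclusive integer interval
[first_doc, last_doc]. Against source genome g: TP iff [g, g]; FP iff
non-empty and g outside; VP iff g inside with company; FN iff empty.
The range may overstate the true occurrence set — documents strictly
between first and last need not contain the MEM — which is faithful to
how the ranges are meant to be read. A read is a true positive iff its
MEM table is non-empty and every longest MEM is a TP. Reads whose digest
produces no MEM at all (possible when substitutions disrupt every
minimizer) count as not-true-positive with diagnostic label FN. The LCA
of the first/last leaves (depth-aligned pointer walking; trees here are
small) gives the reported subtree.

## Synthetic data

The fixture generator emulates the shape of a large curated rRNA
collection at reduced scale: a random bifurcating topology, a uniform
random root sequence, and per-branch per-site substitution at a fixed
divergence rate (default 0.05), so sequence similarity decays with tree
distance — the property that makes vague positives possible. It does
*not* model indels, rearrangements, varying sequence lengths, multiple
sequences per taxon, or database-specific taxon sampling; conclusions
from passing tests are about the matching and classification machinery,
not about accuracy on any real database.

Reads: uniform start within one genome (never straddling a separator),
fixed length (default 200), and exactly `round(error_rate × length)`
distinct substituted positions (default 1% → 2) rather than per-base
Bernoulli draws — a fixed mutation load per read makes results easier to
reason about and reproduce. Qualities are not modeled.

The standard evaluation fixture is 50 taxa × 1000 bp, divergence 0.05,
20 reads per taxon, fixed seeds — about 1/1000 the scale of a full rRNA
database experiment, chosen so the whole sweep runs in seconds. At this
scale genomes are well separated and absolute true-positive rates sit
near 1; the tested claims are therefore *orderings* (full ≥ digest;
higher kernel order ≥ lower; digest-based indexes smaller than full),
which are scale-stable, rather than absolute rates.

## Numerical and degenerate-input choices

* Equal-hash ties in a window: strictly leftmost minimum.
* Contraction ties: p-side preferred (intervals may differ momentarily,
  depths never do; the MEM oracle test covers both paths).
* Sparse-table arg-min returns the leftmost position on value ties.
* Empty patterns, patterns shorter than k (digest modes), and reads with
  no alphabet overlap yield empty MEM tables, classified FN.
* `min_mem_length` filters at emission only; matching statistics are
  always complete.
* Query timing in evaluation reports is informational and never
  asserted.

## Known limitations

* Suffix construction is O(n log² n) and in-memory; fine to a few
  megabases, not for full databases.
* No reverse-complement canonicalization: reads are matched on the given
  strand only.
* Digest-mode source-offset reporting is approximate (per-MEM spans via
  recorded minimizer positions), for reporting only.
* The O(1)-per-character / O(log n)-per-MEM complexity of the underlying
  technique is a contract about correctness here, not about measured
  constants.
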
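# Methods

## Model

A read length `k` and a genome (ordered chromosomes over `{A,C,G,T,N}`)
define, per chromosome, a binary vector `X` of chromosome length:
`X_i = 1` iff the k-mer starting at 0-based position `i` is uniquely
mappable. Mappability is defined through exact matching only: the k-mer
`S` at `i` is unique iff

```
hits(S) = #{forward occurrences of S} + #{forward occurrences of rc(S)} = 1
```

summed over all chromosomes. This is equivalent, by construction, to the
number of alignments an exact-match aligner searching both strands would
report, so no alignment step is needed. Exact matching gives the
baseline: a region not uniquely mappable under exact matching stays
ambiguous no matter how deep the sequencing; mismatch-tolerant
mappability is out of scope. Positions `i > L − k` have no k-mer and are
structurally 0. The same mask describes both strands: the reverse
complement of a unique k-mer is unique at the same locus, anchored at
`L − k − i` on the other strand.

Two conventions follow from the hit-count definition rather than from
any aligner's documented behaviour, and are therefore stated explicitly:

* **Palindromes.** A k-mer equal to its own reverse complement at a
  single locus has `hits = 2` (one forward, one reverse alignment at the
  same place) and is never unique.
* **N bases.** Any k-mer containing N is never unique, and N-containing
  reference k-mers are never counted as hits; exact matching cannot
  place ambiguous sequence. Sanitation maps every IUPAC ambiguity code
  and soft-masked (lowercase) base to N / uppercase respectively —
  masking status carries no information about uniqueness of the actual
  sequence.

### Bisulfite mode

Complete bisulfite conversion of unmethylated cytosine is simulated on
both strands: C→T on the plus strand, G→A on the minus strand (the two
never co-occur on one read). The converted reference set contains, per
chromosome `c`, `C→T(c)` and `C→T(revcomp(c))`. Conversion is applied
*after* reverse complementation: both strands are converted
simultaneously and nothing replicates new complements afterwards, so
`revcomp(C→T(c))` would be the wrong object (the two differ whenever `c`
contains a C or G). Matching is forward-only — complement search is
disabled because the minus strand is already explicit in the reference
set. For the forward interval `[i, i+k)` with unconverted sequence `s`,
the plus-strand read is `C→T(s)` and the minus-strand read is
`C→T(revcomp(s))`; each is unique iff it occurs exactly once in the
reference multiset (equal strings from different genomic origins count
separately — each is a distinct alignment target). Both strand masks are
anchored at the forward start coordinate, so they are positionwise
comparable; the combined (AND) mask is the both-strand convention used
for multi-read tracks, while single-read tracks are also useful per
strand. Because conversion is many-to-one on sequences, converted hit
counts are never smaller than unconverted ones: the bisulfite masks are
pointwise ≤ the unmodified mask, per strand.

Assumed: complete conversion (no methylation-state dependence, no
partial conversion) and a haploid reference without variants.

### Merged read-length range

For a sorted range `K = {k₁ < … < k_m}`, the merged integer vector holds
at each position the smallest `k ∈ K` whose mask is 1 there, else 0.
This compaction is licensed by monotonicity: an exact-match superstring
of a unique string is itself unique, so `mask_k[i] = 1` implies
`mask_k'[i] = 1` for every `k' > k` that stays in bounds. The value `v`
at `i` therefore reads: "any read of length ≥ v starting at `i` maps
uniquely".

### Scores

With regions as 0-based half-open `[start, end)` of length
`l = end − start`:

* single-read per base: 1 iff any unique k-mer overlaps the base (any
  overlap suffices, wherever the base falls within the k-mer); per
  region: mean over bases.
* multi-read per base: number of unique k-mers overlapping the base,
  divided by `k`. The denominator is fixed at `k` even within `k − 1`
  bases of a chromosome edge, where fewer k-mers physically fit.
* multi-read per region: unique k-mer starts in `[start − k + 1, end)`
  divided by `l − 1 + k` (with inclusive endpoints `i..j` this is
  `j − i + k`; a 1000-bp region at k = 100 has 1099 overlapping
  k-mers). Starts outside `[0, L − k]` count in the denominator but can
  never be unique, keeping the printed formula exact at edges. An
  alternative per-base-average aggregation (mean of the per-base track
  over the region) is exposed behind a flag; the two differ only through
  edge handling and weighting, and the region formula is the default.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` (read length, nt) | 24, 36, 50, 100 | the read lengths of common short-read assays; any positive set is accepted |
| mode | unmodified | `unmodified` or bisulfite (strand-specific + combined) |
| strand strategy | `both_strands` | combination rule for bisulfite masks (`both_strands` AND; `plus_only` / `minus_only` pass-through) |
| wiggle dialect | write all bases | `skip_zero_edges` omits leading/trailing zero runs |
| `threads` | 1 | concurrent per-k work units; output byte-identical for any value |

## Engine

Sequences are encoded 2 bits/base; each k-mer window is packed into
`ceil(k/32)` uint64 chunks (N packed as 0 but N-containing windows
flagged invalid and excluded from both counting and querying, so the
packing collision is unreachable). Occurrence counting is one
`np.unique(return_counts=True)` over the packed rows of all reference
sequences, queried by binary search — exact for every k, no hashing, and
bit-identical to a naive dictionary count (the engine-vs-oracle suite
asserts this at zero-mismatch tolerance). Reverse-complement hit counts
reuse the packed windows of the reverse-complemented chromosome,
re-anchored by reversal, instead of per-k-mer arithmetic. Memory is
`O(total length × ceil(k/32))` words; genomes are assumed to fit in
memory (chunked prefix-partitioned counting would be an internal
optimization, not an interface change).

Masks and merged vectors persist in a small versioned binary container
(8-byte magic, JSON header carrying k or k-range, mode, chromosome names
and lengths, dtype; then raw little-endian vectors). Round-tripping is
exact and tested.

## Synthetic genomes and the oracle

The generator draws i.i.d. background at a specified GC fraction
(default 0.41, human-like) and plants features with known mappability
consequences: dispersed/tandem/inverted repeat copies (interior k-mers
non-unique for k up to the copy length; junction-spanning k-mers may
remain unique and are asserted via the oracle, not assumed), N-runs, and
cytosine-dense blocks (A/C/G/T at 0.04/0.55/0.08/0.33). The block
composition is a deliberate desk-scale stand-in for the CpG-island
regime: real islands lose bisulfite mappability partly because a
genome-scale pool of conversion-collapsed collision partners exists,
which a 10–100 kb simulation cannot reproduce; a cytosine-dense block
instead collapses internally (C→T leaves a low-entropy T-rich sequence),
producing the same qualitative unmodified-vs-bisulfite gap locally.
Consequently, passing tests demonstrate correctness of the definitions
and engine on genomes with planted structure — they do not calibrate
absolute mappability percentages of real assemblies, which depend on the
real repeat landscape.

The oracle recomputes masks the slow, obvious way — string slices into a
`collections.Counter` over the appropriate reference set — sharing no
code with the engine, guarded to genomes ≤ 1 Mb (it is `O(L·k)`). Every
engine/oracle discrepancy is a release blocker.

## Problem sizes

The test suite verifies engine-oracle equivalence over 100 seeded 50-kb
genomes × k ∈ {12, 24, 36} × three modes (≈ 45 M positions), plus
property suites (monotonicity in k, bisulfite ⊆ unmodified per strand,
single-read ⇔ positive multi-read, strand symmetry under genome reverse
complementation, BED/wiggle round-trips, thread-count determinism) on
smaller seeded genomes. `scripts/acceptance.py` uses 10 × 20-kb genomes
for the oracle comparison and a structured 2 × 100-kb genome (planted
repeats, cytosine-dense blocks, an N-run) for the mappability summary —
sizes chosen so the whole script is a desk-scale run while every number
is still computed from scratch.

## Limitations

* Exact-match uniqueness only; no mismatch/quality-aware or gapped
  mappability.
* Complete bisulfite conversion assumed; partial methylation and
  strain/variant genomes are out of scope.
* Plain-text BED/wiggle output; bigBed/bigWig require an external
  converter.
* The published both-strand AND convention is implemented for combined
  bisulfite multi-read tracks; for combined single-read tracks no single
  convention is canonical, so all three strategies are exposed and the
  choice is the caller's.
* The palindrome (`hits = 2`) convention is declared by this package;
  aligners are not documented on this corner case.
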
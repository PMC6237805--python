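# uniqmap

Single- and multi-read mappability of genomes — including in-silico
bisulfite-converted genomes — for short-read sequencing analysis.

## The problem

Short sequencing reads cannot always be placed at a unique genomic
location: repeats make many positions invisible to unique alignment, and
the shorter the read, the worse it gets. Bisulfite sequencing compounds
the problem: treatment converts unmethylated cytosine to uracil (read as
T), which merges formerly distinct sequences and destroys uniqueness in
exactly the CpG-dense regions methylation studies care about. Reads that
pile up at the wrong place create false signal in ChIP-seq peaks,
methylation calls and differential analyses, so any careful analysis
needs to know, per base and per region, how mappable the genome is at the
experiment's read length.

`uniqmap` computes this from first principles, by exact-match occurrence
counting (equivalent by construction to unique exact-match alignment):

* **Uniqueness mask** `X` per chromosome and read length `k`:
  `X_i = 1` iff the k-mer starting at `i` occurs at exactly one genomic
  location, counting both strands. One mask serves both strands, since
  the reverse complement of a unique k-mer is unique at the same locus.
* **Bisulfite mode**: complete conversion is simulated as C→T on the +
  strand and G→A on the − strand. The converted reference set holds C→T
  of each chromosome and C→T of each *reverse-complemented* chromosome
  (conversion happens after reverse complementation — the protocol
  involves no post-conversion replication), reads are matched
  forward-only, and the two strand masks can be combined (AND for the
  both-strand convention, or kept per strand).
* **Merged vector**: for a read-length range `K`, the per-position value
  is the smallest `k ∈ K` whose k-mer at that start is unique
  (0 if none) — one compact integer track for all read lengths, valid
  because uniqueness is monotone in `k`.
* **Scores**: single-read mappability of a base is 1 iff any unique
  k-mer overlaps it; of a region, the fraction of such bases. Multi-read
  mappability of a base is the number of unique overlapping k-mers
  divided by `k`; of a region of length `l`, the number of unique
  overlapping k-mers divided by `l − 1 + k`.
* **Tracks**: BED6 intervals of single-read-mappable bases, fixedStep
  wiggle of per-base multi-read values, merged-k BED, plus annotation of
  any user BED with both scores.

A seeded synthetic-genome simulator (planted dispersed/tandem/inverted
repeats, N-runs, cytosine-dense blocks) and a brute-force dictionary
oracle provide an engine-independent correctness reference.

## Worked example

```python
from uniqmap import Genome, merge_k_range, unique_start_mask

genome = Genome.from_dict({"chr1": "AACGAACGTTTGCAT"})
for k in (4, 8):
    print(k, unique_start_mask(genome, k).chroms["chr1"].tolist())
merged = merge_k_range([unique_start_mask(genome, k) for k in (4, 8)])
print(merged.chroms["chr1"].tolist())
```

prints

```
4 [0, 1, 1, 1, 0, 0, 0, 1, 1, 1, 0, 1, 0, 0, 0]
8 [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
[8, 4, 4, 4, 8, 8, 8, 4, 4, 4, 0, 4, 0, 0, 0]
```

`AACG` occurs twice (starts 0 and 4), so the 4-mer at start 0 is not
unique, but the 8-mer there is: the merged value 8 at position 0 says
"reads of length ≥ 8 starting here map uniquely", while 4 at position 1
says length ≥ 4 suffices. Position 10 gets 0: its 4-mer `TGCA` is its
own reverse complement (a forward and a reverse alignment at one locus,
hence two hits), and an 8-mer starting there would run past the
chromosome end — no length in the range works.

More narrative walkthroughs live in `examples/` (unique k-mers, the
bisulfite reference set, region scores including the 1099-k-mer /
10-tile contrast, track emission and BED annotation); each prints what
it computes and what the numbers mean.

## Command line

```sh
uniqmap simulate   --out-dir sim --seed 1 --length 50000 -k 24
uniqmap uniqueness --fasta sim/synthetic.seed1.fa -k 24 -k 36 --mode bismap --out-dir masks
uniqmap merge      masks/*.bisulfite_both.*.mask --out-dir merged
uniqmap tracks     masks/synthetic.seed1.bisulfite_both.k24.mask --out-dir tracks
uniqmap score-bed  --bed regions.bed --mask masks/synthetic.seed1.bisulfite_both.k24.mask --out scored.bed
```

Every command writes a JSON manifest of inputs, parameters and counts;
outputs are deterministic for a given configuration and independent of
`--threads`.

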
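"""Mappability of the bisulfite-converted genome.

Complete bisulfite conversion is simulated as C→T on the + strand and
G→A on the − strand; the converted reference set holds C→T of each
chromosome and C→T of each reverse-complemented chromosome (conversion
happens AFTER reverse complementation), and reads are matched
forward-only. Conversion merges k-mers, so uniqueness can only be lost.
"""

from uniqmap import (
    Feature,
    GenomeSpec,
    bisulfite_unique_masks,
    build_reference_set,
    combine_strands,
    convert,
    generate_genome,
    unique_start_mask,
)

print("C->T conversion:", "AATTCCGG", "->", convert("AATTCCGG"))
print("revcomp first, then C->T:", "CCGGAATT", "->", convert("CCGGAATT"))

# a 5-kb genome with a cytosine-dense 800-bp block: unique as-is, but
# C->T conversion collapses much of the block
spec = GenomeSpec(
    chrom_lengths=(5000,),
    gc=0.55,
    features=(Feature("cpg_block", ((0, 2000),), 800),),
    seed=42,
)
genome, _ = generate_genome(spec)
refs = build_reference_set(genome)
print(f"\nreference set: {len(refs.sequences())} sequences "
      f"(2 per chromosome)")

k = 20
unmodified = unique_start_mask(genome, k)
strands = bisulfite_unique_masks(genome, k)
both = combine_strands(strands, "both_strands")

n = len(genome["chr1"]) - k + 1
print(f"\nk={k}, {n} possible starts on a 5-kb genome:")
print(f"  unmodified unique starts:        {unmodified.total_unique()}")
print(f"  bisulfite + strand unique:       {strands.plus.total_unique()}")
print(f"  bisulfite - strand unique:       {strands.minus.total_unique()}")
print(f"  unique on BOTH strands:          {both.total_unique()}")
print("\nBisulfite counts never exceed the unmodified count: conversion")
print("is many-to-one, so distinct k-mers can only collapse together.")
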
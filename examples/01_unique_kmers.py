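"""Unique k-mer masks and the smallest-unique-k merged vector.

Builds a tiny genome with an exact repeat, computes which k-mer start
positions map uniquely (counting both strands), and merges two read
lengths into the compact integer vector.
"""

from uniqmap import Genome, merge_k_range, unique_start_mask

# "AACG" occurs at starts 0 and 4, so no 4-mer using both copies' interior
# can be unique; the junction-spanning 4-mers are.
genome = Genome.from_dict({"chr1": "AACGAACGTTTGCAT"})

for k in (4, 8):
    mask = unique_start_mask(genome, k)
    print(f"k={k}: unique-start mask {mask.chroms['chr1'].tolist()}")

merged = merge_k_range([unique_start_mask(genome, k) for k in (4, 8)])
print(f"merged (smallest unique k in {merged.k_range}):")
print(f"  {merged.chroms['chr1'].tolist()}")
print("A value v>0 at position i means the read of length v starting at i")
print("maps to exactly one place; any longer read there is unique too;")
print("0 means no read length in the range is unique at that start.")
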
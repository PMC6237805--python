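"""Single-read vs multi-read mappability of a region.

A region is single-read mappable wherever at least one unique k-mer
overlaps it; multi-read mappability is the probability that a randomly
chosen overlapping k-mer is unique. A 1-kb region with k=100 is overlapped
by 1000 - 1 + 100 = 1099 k-mers, yet needs only 10 disjoint unique
100-mers for full single-read coverage — the two scores answer different
questions.
"""

import numpy as np

from uniqmap import (
    Region,
    UniquenessMask,
    region_kmer_count,
    region_multi_read,
    region_single_read,
)

L, k = 1000, 100
region = Region("c", 0, L)
print(f"overlapping {k}-mers for a {L}-bp region:",
      region_kmer_count(L, k))

# minimal tiling: 10 disjoint unique 100-mers
vec = np.zeros(L, dtype=np.uint8)
vec[np.arange(0, L, k)] = 1
tiling = UniquenessMask(k=k, mode="unmodified", chroms={"c": vec})
print("10 disjoint unique 100-mers:")
print("  single-read :", region_single_read(tiling, region))
print("  multi-read  :", round(region_multi_read(tiling, region), 4))

# maximal overlap: every start unique
full = np.zeros(L, dtype=np.uint8)
full[: L - k + 1] = 1
dense = UniquenessMask(k=k, mode="unmodified", chroms={"c": full})
print("every overlapping 100-mer unique:")
print("  single-read :", region_single_read(dense, region))
print("  multi-read  :", round(region_multi_read(dense, region), 4))

# 2 of 10 overlapping k-mers unique -> multi-read 0.2
i, k2 = 50, 4
vec2 = np.zeros(200, dtype=np.uint8)
vec2[i] = vec2[i + 3] = 1
mask2 = UniquenessMask(k=k2, mode="unmodified", chroms={"c": vec2})
small = Region("c", i, i + 7)
print(f"2 of {region_kmer_count(small.length, k2)} overlapping "
      f"{k2}-mers unique -> multi-read",
      region_multi_read(mask2, small))
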
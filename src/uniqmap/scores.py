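"""Single-read and multi-read mappability scores.

Single-read mappability of a base is 1 if at least one uniquely mappable
k-mer overlaps it — any overlap suffices, wherever the base sits within the
k-mer — and 0 otherwise; for a region it is the fraction of bases with
value 1. Multi-read mappability is the probability that a randomly chosen
k-mer overlapping a base or region maps uniquely:

* per base: number of unique k-mers overlapping the base, divided by k
  (the denominator is always k, including at chromosome edges);
* per region of length ``l``: unique overlapping k-mers divided by
  ``l - 1 + k``. With inclusive endpoints i..j this is the classic
  ``j - i + k`` count — a 1000-bp region and k = 100 give 1099 maximally
  overlapping k-mers, while single-read mappability 1.0 needs as few as
  10 disjoint unique 100-mers.

Regions here are 0-based half-open ``[start, end)``. K-mer starts that
fall outside ``[0, L - k]`` still count in the region denominator but can
never be unique, keeping the printed formula exact at chromosome edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer_engine import MaskError, UniquenessMask

__all__ = [
    "Region",
    "PerBaseTrack",
    "RegionScore",
    "single_read_per_base",
    "multi_read_per_base",
    "region_single_read",
    "region_multi_read",
    "score_region",
    "region_kmer_count",
]


@dataclass(frozen=True)
class Region:
    """0-based half-open genomic interval, optionally named/stranded."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MaskError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PerBaseTrack:
    """Per-base mappability vectors: binary (single_read) or [0,1] floats."""

    kind: str  # "single_read" | "multi_read"
    k: int
    mode: str
    chroms: dict[str, np.ndarray]


@dataclass(frozen=True)
class RegionScore:
    """Region-level scores plus the underlying k-mer counts."""

    region: Region
    k: int
    mode: str
    single_read: float
    multi_read: float
    kmers_total: int
    kmers_unique: int


def region_kmer_count(region_length: int, k: int) -> int:
    """Number of distinct k-mers overlapping a region of that length."""
    if region_length < 1 or k < 1:
        raise MaskError("region length and k must be >= 1")
    return region_length - 1 + k


def _overlap_counts(mask_vec: np.ndarray, k: int) -> np.ndarray:
    """Per base, the number of unique k-mer starts overlapping it.

    Base p is overlapped by starts in [p-k+1, p] (clipped to valid
    starts); a length-k sliding sum of the start mask gives the count.
    """
    L = len(mask_vec)
    cs = np.concatenate(([0], np.cumsum(mask_vec, dtype=np.int64)))
    p = np.arange(L)
    lo = np.maximum(p - k + 1, 0)
    hi = np.minimum(p + 1, L)
    return cs[hi] - cs[lo]


def multi_read_per_base(mask: UniquenessMask) -> PerBaseTrack:
    """Per-base multi-read mappability: unique overlapping k-mers / k."""
    chroms = {
        name: _overlap_counts(vec, mask.k) / float(mask.k)
        for name, vec in mask.chroms.items()
    }
    return PerBaseTrack(kind="multi_read", k=mask.k, mode=mask.mode,
                        chroms=chroms)


def single_read_per_base(mask: UniquenessMask) -> PerBaseTrack:
    """Per-base single-read mappability: 1 iff any unique k-mer overlaps."""
    chroms = {
        name: (_overlap_counts(vec, mask.k) > 0).astype(np.uint8)
        for name, vec in mask.chroms.items()
    }
    return PerBaseTrack(kind="single_read", k=mask.k, mode=mask.mode,
                        chroms=chroms)


def _check_region(mask: UniquenessMask, region: Region) -> np.ndarray:
    if region.chrom not in mask.chroms:
        raise MaskError(f"chromosome {region.chrom!r} not in mask")
    vec = mask.chroms[region.chrom]
    if region.end > len(vec):
        raise MaskError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {len(vec)}"
        )
    return vec


def region_single_read(mask: UniquenessMask, region: Region) -> float:
    """Fraction of the region's bases overlapped by a unique k-mer."""
    vec = _check_region(mask, region)
    counts = _overlap_counts(vec, mask.k)[region.start : region.end]
    return float(np.mean(counts > 0))


def region_multi_read(mask: UniquenessMask, region: Region,
                      per_base_average: bool = False) -> float:
    """Fraction of the region's overlapping k-mers that map uniquely.

    Numerator: unique k-mer starts in ``[start - k + 1, end - 1]``
    (out-of-bounds starts count as non-unique). Denominator:
    ``length - 1 + k``. With ``per_base_average=True`` the mean of the
    per-base multi-read track over the region is returned instead.
    """
    vec = _check_region(mask, region)
    k = mask.k
    if per_base_average:
        counts = _overlap_counts(vec, k)[region.start : region.end]
        return float(np.mean(counts / k))
    lo = max(region.start - k + 1, 0)
    hi = min(region.end, len(vec) - k + 1)  # starts are < L - k + 1
    unique = int(vec[lo:hi].sum()) if hi > lo else 0
    return unique / region_kmer_count(region.length, k)


def score_region(mask: UniquenessMask, region: Region) -> RegionScore:
    """Bundle single-read and multi-read scores with k-mer counts."""
    vec = _check_region(mask, region)
    k = mask.k
    lo = max(region.start - k + 1, 0)
    hi = min(region.end, len(vec) - k + 1)
    unique = int(vec[lo:hi].sum()) if hi > lo else 0
    total = region_kmer_count(region.length, k)
    return RegionScore(
        region=region,
        k=k,
        mode=mask.mode,
        single_read=region_single_read(mask, region),
        multi_read=unique / total,
        kmers_total=total,
        kmers_unique=unique,
    )
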
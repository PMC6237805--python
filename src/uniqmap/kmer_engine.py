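"""Exact-match k-mer uniqueness engine.

Mappability here follows the exact-match definition: a k-mer is uniquely
mappable when its sequence occurs at exactly one genomic location, counting
both strands. Alignment is replaced by occurrence counting, which is
equivalent by construction to unique exact-match alignment: for each valid
start ``i`` the k-mer ``S`` is unique iff

    hits(S) = (#forward occurrences of S) + (#forward occurrences of rc(S))

equals 1, summed over all chromosomes. One mask serves both strands, since
the reverse complement of a unique k-mer is unique at the same locus.

Two consequences of this definition are deliberate and tested:

* a palindromic k-mer (``S == rc(S)``) occurring at a single locus has
  ``hits = 2`` and is never unique — it mirrors an aligner reporting a
  forward and a reverse alignment at the same position;
* any k-mer containing ``N`` is never unique.

Implementation: sequences are encoded 2 bits/base and every k-mer window is
packed into ``ceil(k/32)`` uint64 chunks, so counting is a single
``np.unique`` over the packed rows — exact for any k, with no hashing.
Counting may be done per chromosome and merged; the result is bit-identical
to one global dictionary count.
"""

from __future__ import annotations

import json
import os
import struct
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Mode",
    "UniquenessMask",
    "MergedMappability",
    "MaskError",
    "reverse_complement",
    "unique_start_mask",
    "merge_k_range",
    "write_mask",
    "read_mask",
    "write_merged",
    "read_merged",
]

MODES = ("unmodified", "bisulfite_plus", "bisulfite_minus", "bisulfite_both")
Mode = str

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")

# base codes: A=0 C=1 G=2 T=3, N=4 (N flagged separately; packed as 0)
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE_LUT[_b] = _i
del _i, _b


class MaskError(ValueError):
    """Mask construction or combination failure."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement a sequence over ``{A,C,G,T,N}`` (N maps to N)."""
    bad = set(seq) - _ALPHABET
    if bad:
        raise MaskError(f"characters outside {{A,C,G,T,N}}: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class UniquenessMask:
    """Binary per-chromosome vectors of uniquely mappable k-mer starts.

    ``chroms[name][i] == 1`` means the k-mer starting at 0-based position
    ``i`` maps uniquely under *mode*. Vectors have chromosome length;
    positions ``>= L - k + 1`` are structurally zero.
    """

    k: int
    mode: Mode
    chroms: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise MaskError(f"k must be >= 1, got {self.k}")
        if self.mode not in MODES:
            raise MaskError(f"unknown mode: {self.mode!r}")

    def lengths(self) -> dict[str, int]:
        return {name: len(v) for name, v in self.chroms.items()}

    def same_frame(self, other: "UniquenessMask") -> bool:
        return self.k == other.k and self.lengths() == other.lengths()

    def total_unique(self) -> int:
        return int(sum(int(v.sum()) for v in self.chroms.values()))


@dataclass(frozen=True)
class MergedMappability:
    """Per-chromosome integer vectors of the smallest unique read length.

    Value ``v > 0`` at position ``i`` means: of the read lengths in
    *k_range*, ``v`` is the smallest for which the k-mer starting at ``i``
    is unique — so the region ``[i, i + v)`` is uniquely mappable, and any
    longer read starting at ``i`` is also uniquely mappable. ``0`` means no
    read length in the range is unique at ``i``.
    """

    k_range: tuple[int, ...]
    mode: Mode
    chroms: dict[str, np.ndarray]


def _encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (A=0 C=1 G=2 T=3 N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if codes.max(initial=0) == 255:
        raise MaskError("sequence contains characters outside {A,C,G,T,N}")
    return codes


def _pack_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-k window into uint64 chunks; flag N-free windows.

    Returns ``(packed, valid)`` where ``packed`` has shape
    ``(L - k + 1, ceil(k / 32))`` and ``valid[i]`` is True iff the window
    at ``i`` contains no N. N bases are packed as 0 but such windows are
    excluded from counting and querying, so the collision is harmless.
    """
    L = len(codes)
    n = L - k + 1
    nchunks = (k + 31) // 32
    if n <= 0:
        return (np.empty((0, nchunks), dtype=np.uint64),
                np.empty(0, dtype=bool))
    is_n = codes == 4
    cs = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cs[k:] - cs[:-k]) == 0
    base = np.where(is_n, 0, codes).astype(np.uint64)
    packed = np.zeros((n, nchunks), dtype=np.uint64)
    for c in range(nchunks):
        lo, hi = c * 32, min(k, (c + 1) * 32)
        acc = np.zeros(n, dtype=np.uint64)
        for j in range(lo, hi):
            acc = (acc << np.uint64(2)) | base[j : j + n]
        packed[:, c] = acc
    return packed, valid


def _as_void(packed: np.ndarray) -> np.ndarray:
    """Row view of a packed (n, chunks) array for unique/searchsorted."""
    a = np.ascontiguousarray(packed)
    dt = np.dtype((np.void, a.dtype.itemsize * a.shape[1]))
    return a.view(dt).ravel()


class KmerCounter:
    """Occurrence counts of packed k-mers over a multiset of sequences."""

    def __init__(self, packed_arrays: list[np.ndarray]):
        if packed_arrays:
            allrows = np.concatenate([_as_void(a) for a in packed_arrays])
        else:
            allrows = np.empty(0, dtype=np.void)
        if allrows.size:
            self._uniq, self._counts = np.unique(allrows, return_counts=True)
        else:
            self._uniq = allrows
            self._counts = np.empty(0, dtype=np.int64)

    def counts_of(self, packed: np.ndarray) -> np.ndarray:
        """Occurrence count for each row of *packed* (0 if absent)."""
        q = _as_void(packed)
        if q.size == 0 or self._uniq.size == 0:
            return np.zeros(q.size, dtype=np.int64)
        idx = np.searchsorted(self._uniq, q)
        idx_c = np.clip(idx, 0, self._uniq.size - 1)
        hit = self._uniq[idx_c] == q
        out = np.where(hit, self._counts[idx_c], 0)
        return out.astype(np.int64)


def _prepare_unmodified(genome, k: int):
    """Per-chromosome packed windows of the forward and revcomp sequence."""
    per_chrom = {}
    for name, seq in genome.items():
        fwd_codes = _encode(seq)
        rev_codes = _encode(reverse_complement(seq))
        fwd, valid = _pack_windows(fwd_codes, k)
        rev, _ = _pack_windows(rev_codes, k)
        per_chrom[name] = (fwd, rev, valid, len(seq))
    return per_chrom


def unique_start_mask(genome, k: int) -> UniquenessMask:
    """Mark k-mer start positions that map uniquely in the unmodified genome.

    For each N-free window the hit count is the number of forward-strand
    occurrences of the k-mer plus those of its reverse complement, over all
    chromosomes; the start is marked iff the count is 1. If *k* exceeds
    every chromosome length the mask is all zeros (with a warning).
    """
    if k < 1:
        raise MaskError(f"k must be >= 1, got {k}")
    if len(genome) == 0:
        raise MaskError("genome has no chromosomes")
    lengths = genome.lengths
    if k > max(lengths.values()):
        warnings.warn(
            f"k={k} exceeds every chromosome length; mask is all zeros",
            stacklevel=2,
        )
        chroms = {n: np.zeros(L, dtype=np.uint8) for n, L in lengths.items()}
        return UniquenessMask(k=k, mode="unmodified", chroms=chroms)

    per_chrom = _prepare_unmodified(genome, k)
    counter = KmerCounter(
        [fwd[valid] for fwd, _, valid, _ in per_chrom.values()]
    )
    chroms = {}
    for name, (fwd, rev, valid, L) in per_chrom.items():
        X = np.zeros(L, dtype=np.uint8)
        if fwd.shape[0]:
            cf = counter.counts_of(fwd)
            # revcomp of window [i, i+k) starts at L-k-i in rc(chrom):
            # reversing the revcomp-window counts re-anchors them at i
            cr = counter.counts_of(rev)[::-1]
            hits = cf + cr
            X[: fwd.shape[0]] = (valid & (hits == 1)).astype(np.uint8)
        chroms[name] = X
    return UniquenessMask(k=k, mode="unmodified", chroms=chroms)


def merge_k_range(masks: list[UniquenessMask]) -> MergedMappability:
    """Merge masks over a read-length range into the smallest-unique-k vector.

    The value at each position is the smallest k in the range whose mask is
    set there, or 0. All masks must share mode and chromosome frame.
    """
    if not masks:
        raise MaskError("k-range merge needs at least one mask")
    mode = masks[0].mode
    frame = masks[0].lengths()
    ks = []
    for m in masks:
        if m.mode != mode:
            raise MaskError(f"mixed modes in merge: {mode!r} vs {m.mode!r}")
        if m.lengths() != frame:
            raise MaskError("masks cover different chromosomes/lengths")
        ks.append(m.k)
    if len(set(ks)) != len(ks):
        raise MaskError(f"duplicate read lengths in merge: {sorted(ks)}")
    order = sorted(range(len(ks)), key=lambda i: ks[i], reverse=True)
    chroms = {name: np.zeros(L, dtype=np.uint32) for name, L in frame.items()}
    for i in order:  # descending k: smaller k overwrites larger
        m = masks[i]
        for name, vec in m.chroms.items():
            chroms[name][vec == 1] = m.k
    return MergedMappability(
        k_range=tuple(sorted(ks)), mode=mode, chroms=chroms
    )


# ---------------------------------------------------------------------------
# Versioned binary containers for masks and merged vectors.
#
# Layout: 8-byte magic, uint32 little-endian JSON-header length, JSON header
# (k or k_range, mode, chromosome names + lengths, dtype), then the raw
# little-endian chromosome vectors concatenated in header order.
# ---------------------------------------------------------------------------

_MASK_MAGIC = b"UQMASK01"
_MERGED_MAGIC = b"UQMERG01"


def _write_container(path, magic: bytes, header: dict,
                     vectors: list[np.ndarray]) -> None:
    payload = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(magic)
        fh.write(struct.pack("<I", len(payload)))
        fh.write(payload)
        for vec in vectors:
            le = vec.dtype.newbyteorder("<")
            fh.write(np.ascontiguousarray(vec).astype(le, copy=False).tobytes())


def _read_container(path, magic: bytes) -> tuple[dict, list[np.ndarray]]:
    with open(path, "rb") as fh:
        got = fh.read(8)
        if got != magic:
            raise MaskError(
                f"bad container magic in {os.fspath(path)!r}: {got!r}"
            )
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen))
        dtype = np.dtype(header["dtype"])
        vectors = []
        for entry in header["chromosomes"]:
            nbytes = entry["length"] * dtype.itemsize
            buf = fh.read(nbytes)
            if len(buf) != nbytes:
                raise MaskError(f"truncated container: {os.fspath(path)!r}")
            vectors.append(np.frombuffer(buf, dtype=dtype).copy())
    return header, vectors


def write_mask(mask: UniquenessMask, path) -> None:
    header = {
        "k": mask.k,
        "mode": mask.mode,
        "dtype": "<u1",
        "chromosomes": [
            {"name": n, "length": len(v)} for n, v in mask.chroms.items()
        ],
    }
    _write_container(path, _MASK_MAGIC, header, list(mask.chroms.values()))


def read_mask(path) -> UniquenessMask:
    header, vectors = _read_container(path, _MASK_MAGIC)
    chroms = {
        e["name"]: v for e, v in zip(header["chromosomes"], vectors)
    }
    return UniquenessMask(k=header["k"], mode=header["mode"], chroms=chroms)


def write_merged(merged: MergedMappability, path) -> None:
    header = {
        "k_range": list(merged.k_range),
        "mode": merged.mode,
        "dtype": "<u4",
        "chromosomes": [
            {"name": n, "length": len(v)} for n, v in merged.chroms.items()
        ],
    }
    _write_container(path, _MERGED_MAGIC, header, list(merged.chroms.values()))


def read_merged(path) -> MergedMappability:
    header, vectors = _read_container(path, _MERGED_MAGIC)
    chroms = {
        e["name"]: v for e, v in zip(header["chromosomes"], vectors)
    }
    return MergedMappability(
        k_range=tuple(header["k_range"]), mode=header["mode"], chroms=chroms
    )
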
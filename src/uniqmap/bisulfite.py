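"""Mappability of the bisulfite-converted genome.

Bisulfite treatment converts unmethylated cytosine to uracil, sequenced as
thymine. Complete conversion is modeled in silico as C→T on the + strand
and, equivalently, G→A on the − strand; the two never occur on the same
read. The converted reference set therefore holds, for each chromosome,
the C→T conversion of the forward sequence (plus reference) and the C→T
conversion of the reverse-complemented sequence (minus reference).

Order matters: the minus reference is ``C→T(revcomp(c))``, not
``revcomp(C→T(c))``. Both strands undergo bisulfite treatment
simultaneously and no replication creates new complements afterwards, so
reverse complementation is not simulated after conversion. For the same
reason the occurrence search is forward-only: complement search is
disabled, and the minus strand is represented explicitly in the reference
set instead.

Conversion is many-to-one, so converted hit counts can only grow: every
position unique after conversion is unique before it (bisulfite masks are
a subset of unmodified masks, per strand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer_engine import (
    KmerCounter,
    MaskError,
    UniquenessMask,
    _encode,
    _pack_windows,
    reverse_complement,
)

__all__ = [
    "ConvertedReferenceSet",
    "StrandMasks",
    "convert",
    "build_reference_set",
    "bisulfite_unique_masks",
    "combine_strands",
]

_C2T = str.maketrans("C", "T")
_G2A = str.maketrans("G", "A")
_RULES = {"C->T": _C2T, "G->A": _G2A}

STRATEGIES = ("both_strands", "plus_only", "minus_only")


def convert(seq: str, rule: str = "C->T") -> str:
    """Fully bisulfite-convert a sequence (``"C->T"`` or ``"G->A"``).

    Every source base is replaced; everything else, including N, is
    unchanged. Length-preserving.
    """
    try:
        table = _RULES[rule]
    except KeyError:
        raise MaskError(f"unknown conversion rule {rule!r}; "
                        f"expected one of {sorted(_RULES)}") from None
    return seq.translate(table)


@dataclass(frozen=True)
class ConvertedReferenceSet:
    """Per-chromosome converted references: (plus_ref, minus_ref) pairs.

    ``plus_ref = C→T(chrom)``; ``minus_ref = C→T(revcomp(chrom))``.
    Both have the chromosome's length. Occurrence counting over this set
    is a multiset count: equal strings from different genomic origins
    count as distinct alignments.
    """

    refs: dict[str, tuple[str, str]]

    def sequences(self) -> list[str]:
        out = []
        for plus_ref, minus_ref in self.refs.values():
            out.append(plus_ref)
            out.append(minus_ref)
        return out


@dataclass(frozen=True)
class StrandMasks:
    """Strand-specific bisulfite uniqueness masks, both forward-anchored.

    The minus mask at forward position ``i`` refers to the read covering
    the forward interval ``[i, i + k)`` on the − strand, so plus and minus
    vectors are positionally comparable and can be ANDed.
    """

    plus: UniquenessMask
    minus: UniquenessMask

    def __post_init__(self) -> None:
        if self.plus.k != self.minus.k:
            raise MaskError("strand masks disagree on k")
        if self.plus.lengths() != self.minus.lengths():
            raise MaskError("strand masks cover different chromosomes")


def build_reference_set(genome) -> ConvertedReferenceSet:
    """Build the 2×(number of chromosomes) converted reference sequences."""
    if len(genome) == 0:
        raise MaskError("genome has no chromosomes")
    refs = {}
    for name, seq in genome.items():
        refs[name] = (convert(seq, "C->T"),
                      convert(reverse_complement(seq), "C->T"))
    return ConvertedReferenceSet(refs=refs)


def bisulfite_unique_masks(genome, k: int) -> StrandMasks:
    """Strand-specific uniqueness masks of the bisulfite-converted genome.

    For the forward interval ``[i, i + k)`` with N-free unconverted
    sequence ``s``, the plus-strand read is ``C→T(s)`` and the minus-strand
    read is ``C→T(revcomp(s))``. Each read is counted forward-only across
    all sequences of the converted reference set; the mask is set iff the
    count is 1. Conversion commutes with windowing, so the reads are
    windows of the converted references themselves: the plus read starts
    at ``i`` in the plus reference, the minus read at ``L - k - i`` in the
    minus reference.
    """
    if k < 1:
        raise MaskError(f"k must be >= 1, got {k}")
    if len(genome) == 0:
        raise MaskError("genome has no chromosomes")
    refset = build_reference_set(genome)

    per_chrom = {}
    for name, seq in genome.items():
        plus_ref, minus_ref = refset.refs[name]
        plus_pack, valid = _pack_windows(_encode(plus_ref), k)
        minus_pack, _ = _pack_windows(_encode(minus_ref), k)
        # N positions survive conversion unchanged, so window validity of
        # the converted references equals that of the unconverted windows
        per_chrom[name] = (plus_pack, minus_pack, valid, len(seq))

    counting = []
    for plus_pack, minus_pack, valid, _ in per_chrom.values():
        counting.append(plus_pack[valid])
        counting.append(minus_pack[valid[::-1]])
    counter = KmerCounter(counting)

    plus_chroms = {}
    minus_chroms = {}
    for name, (plus_pack, minus_pack, valid, L) in per_chrom.items():
        Xp = np.zeros(L, dtype=np.uint8)
        Xm = np.zeros(L, dtype=np.uint8)
        n = plus_pack.shape[0]
        if n:
            cp = counter.counts_of(plus_pack)
            cm = counter.counts_of(minus_pack)[::-1]  # re-anchor at forward i
            Xp[:n] = (valid & (cp == 1)).astype(np.uint8)
            Xm[:n] = (valid & (cm == 1)).astype(np.uint8)
        plus_chroms[name] = Xp
        minus_chroms[name] = Xm
    return StrandMasks(
        plus=UniquenessMask(k=k, mode="bisulfite_plus", chroms=plus_chroms),
        minus=UniquenessMask(k=k, mode="bisulfite_minus", chroms=minus_chroms),
    )


def combine_strands(sm: StrandMasks,
                    strategy: str = "both_strands") -> UniquenessMask:
    """Combine strand masks for track/score computation.

    ``both_strands`` (the multi-read convention): positionwise AND —
    a position counts only if the read maps uniquely on both strands.
    ``plus_only`` / ``minus_only`` pass the respective mask through, for
    strand-specific single-read tracks.
    """
    if strategy not in STRATEGIES:
        raise MaskError(f"unknown strand strategy {strategy!r}; "
                        f"expected one of {STRATEGIES}")
    if strategy == "plus_only":
        return sm.plus
    if strategy == "minus_only":
        return sm.minus
    chroms = {
        name: (sm.plus.chroms[name] & sm.minus.chroms[name]).astype(np.uint8)
        for name in sm.plus.chroms
    }
    return UniquenessMask(k=sm.plus.k, mode="bisulfite_both", chroms=chroms)
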
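"""Synthetic genomes with planted mappability structure, plus the
brute-force uniqueness oracle.

The generator draws an i.i.d. background at a chosen GC fraction and then
plants features that create known mappability structure:

* ``dispersed_repeat`` — copies a source segment to other loci, making
  every k-mer fully inside a copy non-unique (for k up to the copy
  length; junction-spanning k-mers may still be unique);
* ``tandem_duplication`` — copies a segment to the position immediately
  following it;
* ``inverted_repeat`` — plants the reverse complement of a segment,
  non-unique because both strands are searched;
* ``n_run`` — a run of N, unmappable by the N-policy;
* ``cpg_block`` — a CpG-dense segment emulating CpG-island-like sequence,
  where C→T conversion collapses many distinct k-mers onto one and the
  bisulfite masks fall well below the unmodified mask.

The same seed always yields the same genome, byte for byte.

:func:`oracle_unique_start_mask` is the slow, obvious dictionary count of
every k-mer of the appropriate reference set, written with plain strings
and :class:`collections.Counter`. It shares no code with the production
engine and is the correctness reference for it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genome_io import Genome
from .kmer_engine import UniquenessMask

__all__ = [
    "Feature",
    "GenomeSpec",
    "SpecError",
    "generate_genome",
    "random_genome",
    "oracle_unique_start_mask",
    "write_feature_manifest",
]

FEATURE_KINDS = ("dispersed_repeat", "tandem_duplication",
                 "inverted_repeat", "n_run", "cpg_block")

ORACLE_MAX_LENGTH = 1_000_000


class SpecError(ValueError):
    """Infeasible genome specification."""


@dataclass(frozen=True)
class Feature:
    """One planted feature.

    ``positions`` are (chromosome-index, start) pairs: the first is the
    feature's origin (source segment for repeats), the rest are copy
    targets where applicable.
    """

    kind: str
    positions: tuple[tuple[int, int], ...]
    length: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise SpecError(f"unknown feature kind {self.kind!r}")
        if self.length < 1:
            raise SpecError("feature length must be >= 1")
        if not self.positions:
            raise SpecError("feature needs at least one position")


@dataclass(frozen=True)
class GenomeSpec:
    """Deterministic recipe for a synthetic genome."""

    chrom_lengths: tuple[int, ...]
    gc: float = 0.41  # human-like background GC content
    features: tuple[Feature, ...] = ()
    seed: int = 0
    name_prefix: str = "chr"

    def __post_init__(self) -> None:
        if not self.chrom_lengths or min(self.chrom_lengths) < 1:
            raise SpecError("chromosome lengths must be positive")
        if not (0.0 <= self.gc <= 1.0):
            raise SpecError("gc must be in [0, 1]")


def _check_fits(spec: GenomeSpec, ci: int, start: int, length: int) -> None:
    if not (0 <= ci < len(spec.chrom_lengths)):
        raise SpecError(f"feature references chromosome index {ci}")
    if start < 0 or start + length > spec.chrom_lengths[ci]:
        raise SpecError(
            f"feature [{start}, {start + length}) does not fit in "
            f"chromosome {ci} (length {spec.chrom_lengths[ci]})"
        )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_IDX = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


def generate_genome(spec: GenomeSpec) -> tuple[Genome, list[dict]]:
    """Realize a :class:`GenomeSpec`; returns the genome and its manifest.

    The manifest lists every realized feature segment with chromosome,
    0-based half-open coordinates, kind and role (source/copy), so tests
    can assert expected non-uniqueness at the planted loci.
    """
    rng = np.random.default_rng(spec.seed)
    at = (1.0 - spec.gc) / 2.0
    gccomp = spec.gc / 2.0
    probs = np.array([at, gccomp, gccomp, at])  # A C G T
    chrom_idx = [
        rng.choice(4, size=L, p=probs).astype(np.uint8)
        for L in spec.chrom_lengths
    ]
    n_mask = [np.zeros(L, dtype=bool) for L in spec.chrom_lengths]
    manifest: list[dict] = []

    def record(kind: str, ci: int, start: int, length: int, role: str):
        manifest.append({
            "kind": kind,
            "chrom": f"{spec.name_prefix}{ci + 1}",
            "start": start,
            "end": start + length,
            "role": role,
        })

    for feat in spec.features:
        (src_ci, src_start), *targets = feat.positions
        _check_fits(spec, src_ci, src_start, feat.length)
        if feat.kind == "n_run":
            n_mask[src_ci][src_start : src_start + feat.length] = True
            record("n_run", src_ci, src_start, feat.length, "source")
            continue
        if feat.kind == "cpg_block":
            # cytosine-dense composition (A .04, C .55, G .08, T .33):
            # unique as-is, but C->T conversion leaves a low-entropy
            # T-rich sequence that collapses — the island-like regime
            block = rng.choice(
                4, size=feat.length, p=[0.04, 0.55, 0.08, 0.33]
            ).astype(np.uint8)
            chrom_idx[src_ci][src_start : src_start + feat.length] = block
            record("cpg_block", src_ci, src_start, feat.length, "source")
            continue
        source = chrom_idx[src_ci][src_start : src_start + feat.length].copy()
        record(feat.kind, src_ci, src_start, feat.length, "source")
        if feat.kind == "tandem_duplication":
            targets = [(src_ci, src_start + feat.length)] + list(targets)
        if not targets:
            raise SpecError(f"{feat.kind} needs at least one target locus")
        for tci, tstart in targets:
            _check_fits(spec, tci, tstart, feat.length)
            seg = source
            if feat.kind == "inverted_repeat":
                seg = _COMP_IDX[source][::-1]
            chrom_idx[tci][tstart : tstart + feat.length] = seg
            record(feat.kind, tci, tstart, feat.length, "copy")

    chroms = []
    for ci, idx in enumerate(chrom_idx):
        raw = _BASES[idx]
        raw = np.where(n_mask[ci], np.uint8(ord("N")), raw)
        chroms.append((f"{spec.name_prefix}{ci + 1}",
                       raw.tobytes().decode("ascii")))
    return Genome(tuple(chroms)), manifest


def random_genome(length: int, seed: int, gc: float = 0.41,
                  n_chrom: int = 1) -> Genome:
    """Featureless random genome (convenience wrapper)."""
    per = length // n_chrom
    spec = GenomeSpec(chrom_lengths=(per,) * n_chrom, gc=gc, seed=seed)
    return generate_genome(spec)[0]


def write_feature_manifest(manifest: list[dict], path) -> None:
    """Write the feature manifest as BED-like text (chrom start end kind role)."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tkind\trole\n")
        for entry in manifest:
            fh.write(f"{entry['chrom']}\t{entry['start']}\t{entry['end']}\t"
                     f"{entry['kind']}\t{entry['role']}\n")


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def oracle_unique_start_mask(genome: Genome, k: int,
                             mode: str = "unmodified") -> UniquenessMask:
    """Exhaustive dictionary-count uniqueness mask (the slow, obvious way).

    unmodified: every k-mer of every chromosome and of every
    reverse-complemented chromosome goes into one Counter; the start is
    unique iff its (N-free) k-mer occurs exactly once. Bisulfite modes:
    the Counter holds every k-mer of the converted reference set (C→T of
    each chromosome and C→T of each reverse-complemented chromosome,
    forward-only); the query read is C→T of the window (plus strand) or
    C→T of the reverse-complemented window (minus strand).

    Guard rail: refuses genomes longer than 1 Mb — this is O(L·k).
    """
    total = genome.total_length
    if total > ORACLE_MAX_LENGTH:
        raise SpecError(
            f"oracle guard rail: genome length {total} > {ORACLE_MAX_LENGTH}"
        )
    if mode == "unmodified":
        ref_seqs = [seq for _, seq in genome.items()]
        ref_seqs += [_rc(seq) for _, seq in genome.items()]
    elif mode in ("bisulfite_plus", "bisulfite_minus"):
        ref_seqs = [seq.replace("C", "T") for _, seq in genome.items()]
        ref_seqs += [_rc(seq).replace("C", "T") for _, seq in genome.items()]
    else:
        raise SpecError(f"oracle does not handle mode {mode!r}")

    counts: Counter = Counter()
    for seq in ref_seqs:
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1

    chroms = {}
    for name, seq in genome.items():
        L = len(seq)
        X = np.zeros(L, dtype=np.uint8)
        for i in range(L - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                continue
            if mode == "unmodified":
                query = window
            elif mode == "bisulfite_plus":
                query = window.replace("C", "T")
            else:
                query = _rc(window).replace("C", "T")
            if counts[query] == 1:
                X[i] = 1
        chroms[name] = X
    return UniquenessMask(k=k, mode=mode, chroms=chroms)
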
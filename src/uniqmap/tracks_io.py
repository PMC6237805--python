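"""Browser-track emission and BED-region annotation.

Plain BED6 and fixedStep wiggle are the output contract; conversion to
bigBed/bigWig is an optional post-step through an external converter and
is not part of the method. All BED coordinates are 0-based half-open;
wiggle fixedStep is 1-based, as the format requires.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass

import numpy as np

from .kmer_engine import MaskError, MergedMappability, UniquenessMask
from .scores import (
    PerBaseTrack,
    Region,
    region_multi_read,
    region_single_read,
    single_read_per_base,
)

__all__ = [
    "BedError",
    "write_single_read_bed",
    "write_merged_bed",
    "write_multi_read_wig",
    "read_wiggle",
    "read_bed",
    "score_bed_file",
    "BedScoreSummary",
]


class BedError(ValueError):
    """Malformed BED input (carries the offending line number)."""


def _open_text(path, mode: str):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _runs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as half-open (start, end) pairs."""
    if binary.size == 0:
        return []
    padded = np.concatenate(([0], binary.view(np.uint8), [0]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def write_single_read_bed(mask: UniquenessMask, out,
                          strand: str = ".") -> int:
    """Write maximal single-read-mappable intervals as BED6.

    Columns: chrom, start, end, ``k<k>``, score 0, strand (``.`` for the
    unmodified genome, ``+``/``-`` for strand-specific bisulfite tracks).
    Returns the number of intervals written.
    """
    track = single_read_per_base(mask)
    count = 0
    with _open_text(out, "w") as fh:
        fh.write(f"# single-read mappability k={mask.k} mode={mask.mode}\n")
        for name, vec in track.chroms.items():
            for start, end in _runs(vec):
                fh.write(f"{name}\t{start}\t{end}\tk{mask.k}\t0\t{strand}\n")
                count += 1
    return count


def write_merged_bed(merged: MergedMappability, out) -> int:
    """Write the smallest-unique-k vector as BED6 runs of constant value.

    The name column carries the smallest unique read length of the run.
    Zero runs (never unique in the range) are omitted.
    """
    count = 0
    krange = ",".join(str(k) for k in merged.k_range)
    with _open_text(out, "w") as fh:
        fh.write(f"# smallest unique k in range {{{krange}}} "
                 f"mode={merged.mode}\n")
        for name, vec in merged.chroms.items():
            if vec.size == 0:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for s, e in zip(starts.tolist(), ends.tolist()):
                v = int(vec[s])
                if v:
                    fh.write(f"{name}\t{s}\t{e}\tk{v}\t0\t.\n")
                    count += 1
    return count


def write_multi_read_wig(track: PerBaseTrack, out,
                         skip_zero_edges: bool = False) -> int:
    """Write a per-base multi-read track as fixedStep wiggle.

    One ``fixedStep chrom=<name> start=<s> step=1 span=1`` block per
    chromosome, values with 6 significant digits. By default every base is
    written; ``skip_zero_edges=True`` omits all-zero leading/trailing runs
    (the block start shifts accordingly). Returns the number of bases
    written.
    """
    if track.kind != "multi_read":
        raise MaskError(f"expected a multi_read track, got {track.kind!r}")
    written = 0
    with _open_text(out, "w") as fh:
        for name, vec in track.chroms.items():
            lo, hi = 0, vec.size
            if skip_zero_edges:
                nz = np.flatnonzero(vec)
                if nz.size == 0:
                    continue
                lo, hi = int(nz[0]), int(nz[-1]) + 1
            if hi <= lo:
                continue
            fh.write(f"fixedStep chrom={name} start={lo + 1} step=1 span=1\n")
            fh.write("\n".join(format(v, ".6g") for v in vec[lo:hi]))
            fh.write("\n")
            written += hi - lo
    return written


def read_wiggle(path) -> dict[str, np.ndarray]:
    """Parse fixedStep wiggle into per-chromosome vectors.

    Vectors extend to the last written base; bases never written are 0.
    """
    chroms: dict[str, list[tuple[int, list[float]]]] = {}
    cur = None
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:]
                )
                name = fields["chrom"]
                start = int(fields.get("start", 1)) - 1
                if int(fields.get("step", 1)) != 1:
                    raise BedError(f"line {lineno}: only step=1 supported")
                cur = (start, [])
                chroms.setdefault(name, []).append(cur)
            else:
                if cur is None:
                    raise BedError(f"line {lineno}: value before fixedStep")
                cur[1].append(float(line))
    out = {}
    for name, blocks in chroms.items():
        end = max(s + len(vals) for s, vals in blocks)
        vec = np.zeros(end, dtype=float)
        for s, vals in blocks:
            vec[s : s + len(vals)] = vals
        out[name] = vec
    return out


def read_bed(path) -> list[Region]:
    """Read BED3+ records as :class:`Region` (name/strand kept if present).

    Raises :class:`BedError` with the 1-based line number on malformed
    lines.
    """
    regions = []
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedError(f"line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedError(
                    f"line {lineno}: non-integer BED coordinates"
                ) from None
            if not (0 <= start < end):
                raise BedError(
                    f"line {lineno}: invalid interval [{start}, {end})"
                )
            regions.append(Region(
                chrom=fields[0],
                start=start,
                end=end,
                name=fields[3] if len(fields) > 3 else ".",
                strand=fields[5] if len(fields) > 5 else ".",
            ))
    return regions


@dataclass(frozen=True)
class BedScoreSummary:
    """Outcome of annotating a BED file."""

    scored: int
    skipped_unknown_chrom: int
    unknown_chroms: tuple[str, ...]


def score_bed_file(bed_in, mask: UniquenessMask, out=None,
                   per_base_average: bool = False,
                   ) -> tuple[list[tuple[Region, float, float]],
                              BedScoreSummary]:
    """Annotate each BED record with single- and multi-read mappability.

    Records on chromosomes absent from the mask are skipped and counted in
    the summary. If *out* is given the annotated records are written as
    the input columns plus two score columns (6 decimal places).
    """
    regions = read_bed(bed_in)
    results = []
    unknown: dict[str, None] = {}
    skipped = 0
    for region in regions:
        if region.chrom not in mask.chroms:
            unknown[region.chrom] = None
            skipped += 1
            continue
        sr = region_single_read(mask, region)
        mr = region_multi_read(mask, region,
                               per_base_average=per_base_average)
        results.append((region, sr, mr))
    summary = BedScoreSummary(
        scored=len(results),
        skipped_unknown_chrom=skipped,
        unknown_chroms=tuple(unknown),
    )
    if out is not None:
        with _open_text(out, "w") as fh:
            fh.write("# columns: chrom start end name score strand "
                     "single_read multi_read\n")
            for region, sr, mr in results:
                fh.write(
                    f"{region.chrom}\t{region.start}\t{region.end}\t"
                    f"{region.name}\t0\t{region.strand}\t"
                    f"{sr:.6f}\t{mr:.6f}\n"
                )
    return results, summary
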
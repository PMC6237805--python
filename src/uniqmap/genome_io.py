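"""Reading, sanitizing and writing genomes.

A :class:`Genome` is an ordered collection of named chromosome sequences
over the alphabet ``{A, C, G, T, N}``. All coordinates in this package are
0-based, half-open; conversion to 1-based happens only when browser tracks
are written.

Soft-masked (lowercase) bases are uppercased and treated as ordinary
bases: masking status is irrelevant to uniqueness of an exact match.
Every IUPAC ambiguity code collapses to ``N``; any k-mer containing ``N``
is never considered mappable, because an exact-match aligner cannot place
an ambiguous read.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "GenomeError",
    "DuplicateChromosomeError",
    "EmptyFastaError",
    "NotFastaError",
    "read_fasta",
    "write_fasta",
    "sanitize_sequence",
]

_CANONICAL = frozenset("ACGTN")

# str.translate table: A/C/G/T (either case) kept (uppercased), every
# other character, including IUPAC ambiguity codes, -> N


class _SanitizeTable(dict):
    def __missing__(self, key: int) -> str:
        return "N"


_SANITIZE_TABLE = _SanitizeTable(
    (ord(c), c.upper()) for c in "acgtACGT"
)


class GenomeError(ValueError):
    """Base class for genome I/O failures."""


class DuplicateChromosomeError(GenomeError):
    """Two FASTA records share the same name."""


class EmptyFastaError(GenomeError):
    """The FASTA file contains no records."""


class NotFastaError(GenomeError):
    """The file content is not FASTA."""


def sanitize_sequence(raw: str) -> str:
    """Map an arbitrary sequence string onto ``{A,C,G,T,N}``.

    Uppercases, then replaces every character that is not A/C/G/T with N.
    Total on strings; length-preserving; idempotent.
    """
    return raw.translate(_SANITIZE_TABLE)


@dataclass(frozen=True)
class Genome:
    """Ordered, sanitized chromosome sequences.

    Parameters
    ----------
    chromosomes:
        ``(name, sequence)`` pairs in file order. Sequences must already be
        over ``{A,C,G,T,N}`` (use :func:`sanitize_sequence`); names must be
        unique and non-empty.
    """

    chromosomes: tuple[tuple[str, str], ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, seq in self.chromosomes:
            if not name:
                raise GenomeError("chromosome name is empty")
            if name in seen:
                raise DuplicateChromosomeError(
                    f"duplicate chromosome name: {name!r}"
                )
            bad = set(seq) - _CANONICAL
            if bad:
                raise GenomeError(
                    f"chromosome {name!r} contains non-canonical "
                    f"characters {sorted(bad)!r}; run sanitize_sequence first"
                )
            seen[name] = seq
        object.__setattr__(self, "_index", seen)

    @classmethod
    def from_dict(cls, chroms: dict[str, str], sanitize: bool = True) -> "Genome":
        items = tuple(
            (name, sanitize_sequence(seq) if sanitize else seq)
            for name, seq in chroms.items()
        )
        return cls(items)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> str:
        return self._index[name]

    def items(self):
        return iter(self.chromosomes)


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a (possibly line-wrapped, possibly soft-masked) FASTA file.

    The chromosome name is the first whitespace-delimited token of the
    header. Sequences are sanitized onto ``{A,C,G,T,N}``.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    EmptyFastaError
        If the file has no records.
    NotFastaError
        If the content does not start with a FASTA header.
    DuplicateChromosomeError
        If two records share a name.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as handle:
        head = handle.read(1)
        if head == "":
            raise EmptyFastaError(f"empty FASTA file: {path}")
        if head != ">":
            raise NotFastaError(f"not FASTA content (no '>' header): {path}")
        handle.seek(0)
        records = [
            (rec.id, sanitize_sequence(str(rec.seq)))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return Genome(tuple(records))


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 60) -> None:
    """Write *genome* as FASTA, line-wrapped at *width* columns."""
    records = (
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.items()
    )
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def genome_from_string(text: str) -> Genome:
    """Parse FASTA from an in-memory string (convenience for tests/examples)."""
    records = [
        (rec.id, sanitize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise EmptyFastaError("no FASTA records in string")
    return Genome(tuple(records))
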
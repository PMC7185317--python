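"""Sequence collection and read input.

Parses FASTA collections and FASTQ read sets (plain or gzipped), builds the
concatenated text that the index is constructed over, and maps global text
offsets back to (sequence name, 1-based position) pairs for SAM emission.

The concatenated text joins all sequences in file order with a single
separator symbol between consecutive sequences and a single terminator
symbol at the very end.  The terminator sorts strictly below the separator,
which sorts strictly below every base symbol; this pins down the suffix
order and prevents matches from spanning sequence boundaries.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterator, Union

from Bio import SeqIO

#: Unique smallest symbol, final position of the concatenated text.
TERMINATOR = "$"
#: Symbol placed between consecutive sequences; sorts above the terminator
#: and below every base ('$' < '%' < 'A'..'Z' in ASCII).
SEPARATOR = "%"

_GZIP_MAGIC = b"\x1f\x8b"

Source = Union[str, Path, BinaryIO]


class CorpusError(ValueError):
    """Base class for malformed sequence input."""


class EmptyInputError(CorpusError):
    """FASTA input contained no records."""


class EmptySequenceError(CorpusError):
    """A FASTA record had an empty sequence body."""


class DuplicateNameError(CorpusError):
    """Two FASTA records share the same name."""


class InvalidBaseError(CorpusError):
    """A sequence contained a non-alphabetic symbol."""


class TruncatedRecordError(CorpusError):
    """A FASTQ record was incomplete (fewer than 4 lines)."""


class QualityLengthError(CorpusError):
    """FASTQ quality string length differs from the base string length."""


class NonSequencePositionError(ValueError):
    """A global text offset falls on a separator or the terminator."""


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    length: int
    global_start: int


@dataclass
class SequenceCatalog:
    """Ordered names, lengths and global start offsets of indexed sequences.

    Entry ``i+1`` starts at ``entry[i].global_start + entry[i].length + 1``
    (one separator between sequences).  This is the content of the
    ``<prefix>.1.ri`` companion file.
    """

    entries: list[CatalogEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    @classmethod
    def from_names_and_lengths(
        cls, names: list[str], lengths: list[int]
    ) -> "SequenceCatalog":
        entries = []
        start = 0
        for name, length in zip(names, lengths):
            entries.append(CatalogEntry(name, length, start))
            start += length + 1  # separator slot
        return cls(entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def lengths(self) -> list[int]:
        return [e.length for e in self.entries]

    def resolve_offset(self, global_pos: int) -> tuple[str, int]:
        """Map a 0-based text offset to (sequence name, 1-based position).

        Raises :class:`NonSequencePositionError` if the offset falls on a
        separator or the terminator, and ``IndexError`` if out of range.
        """
        n = self.text_length
        if not 0 <= global_pos < n:
            raise IndexError(f"offset {global_pos} outside text of length {n}")
        # binary search over entry starts
        lo, hi = 0, len(self.entries) - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self.entries[mid].global_start <= global_pos:
                lo = mid
            else:
                hi = mid - 1
        entry = self.entries[lo]
        local = global_pos - entry.global_start
        if local >= entry.length:
            raise NonSequencePositionError(
                f"offset {global_pos} is a separator/terminator slot"
            )
        return entry.name, local + 1

    @property
    def text_length(self) -> int:
        """Length of the concatenated text including separators + terminator."""
        if not self.entries:
            return 0
        last = self.entries[-1]
        return last.global_start + last.length + 1


@dataclass
class ConcatenatedText:
    """The indexed text: sequences joined by separators, terminator-final."""

    text: str

    @property
    def n(self) -> int:
        return len(self.text)

    def __len__(self) -> int:
        return len(self.text)


@dataclass
class Read:
    name: str
    bases: str
    qualities: str | None = None


def _open_maybe_gzip(source: Source, gzipped: bool | None = None) -> io.TextIOWrapper:
    """Open ``source`` as text, transparently decompressing gzip.

    Detection is by the two gzip magic bytes unless ``gzipped`` overrides it.
    """
    if isinstance(source, (str, Path)):
        raw: BinaryIO = open(source, "rb")
    else:
        raw = source
    if gzipped is None:
        head = raw.peek(2)[:2] if hasattr(raw, "peek") else None
        if head is None:
            pos = raw.tell()
            head = raw.read(2)
            raw.seek(pos)
        gzipped = head == _GZIP_MAGIC
    if gzipped:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


def read_fasta_collection(
    source: Source, gzipped: bool | None = None
) -> tuple[SequenceCatalog, ConcatenatedText]:
    """Parse a (possibly gzipped) multi-FASTA file into catalog + text.

    Record order is preserved, bodies are uppercased, and line wrapping is
    transparent.  Names are the record ids (first whitespace-delimited token
    of the description line) and must be unique.
    """
    names: list[str] = []
    seqs: list[str] = []
    with _open_maybe_gzip(source, gzipped) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if not name:
                raise CorpusError("FASTA record with empty name")
            if name in names:
                raise DuplicateNameError(f"duplicate sequence name {name!r}")
            seq = str(record.seq).upper()
            if not seq:
                raise EmptySequenceError(f"record {name!r} has an empty sequence")
            if not seq.isalpha():
                raise InvalidBaseError(
                    f"record {name!r} contains non-alphabetic symbols"
                )
            names.append(name)
            seqs.append(seq)
    if not names:
        raise EmptyInputError("FASTA input contains no records")
    catalog = SequenceCatalog.from_names_and_lengths(names, [len(s) for s in seqs])
    text = SEPARATOR.join(seqs) + TERMINATOR
    return catalog, ConcatenatedText(text)


def read_fastq(source: Source, gzipped: bool | None = None) -> list[Read]:
    """Parse a (possibly gzipped) 4-line-record FASTQ file into reads.

    Read names are the text after ``@`` up to the first whitespace;
    qualities are preserved verbatim.  An empty file yields an empty list;
    a truncated record or a base/quality length mismatch raises.
    """
    reads: list[Read] = []
    with _open_maybe_gzip(source, gzipped) as handle:
        while True:
            header = handle.readline()
            if not header:
                break
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise TruncatedRecordError(
                    f"expected '@' header line, got {header[:40]!r}"
                )
            bases = handle.readline().rstrip("\n")
            plus = handle.readline()
            quals = handle.readline()
            if not plus or not quals:
                raise TruncatedRecordError(
                    f"record {header[1:].split()[0] if len(header) > 1 else ''!r}"
                    " is truncated"
                )
            quals = quals.rstrip("\n")
            name = header[1:].split()[0] if len(header) > 1 else ""
            if len(quals) != len(bases):
                raise QualityLengthError(
                    f"read {name!r}: {len(bases)} bases but {len(quals)} qualities"
                )
            reads.append(Read(name=name, bases=bases.upper(), qualities=quals))
    return reads


def resolve_offset(catalog: SequenceCatalog, global_pos: int) -> tuple[str, int]:
    """Module-level convenience wrapper for
    :meth:`SequenceCatalog.resolve_offset`."""
    return catalog.resolve_offset(global_pos)
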
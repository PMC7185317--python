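"""Two-file index persistence: ``<prefix>.ri`` and ``<prefix>.1.ri``.

``<prefix>.ri`` holds the main structures (run-length BWT and run-boundary
suffix-array samples); ``<prefix>.1.ri`` holds the sequence catalog that
maps text offsets back to sequence names.  Once saved, the pair is
self-contained: queries never need the source FASTA again.

Binary layout (version 1, all integers little-endian):

``<prefix>.ri``::

    8 bytes   magic b"RINDEXv1"
    u32       format version (1)
    u64       n   total text length
    u64       r   number of BWT runs
    r bytes   run head symbols (ASCII)
    r * u64   run lengths
    r * u64   SA sample at each run's first row
    r * u64   SA sample at each run's last row

``<prefix>.1.ri``::

    8 bytes   magic b"RICATv1\\0"
    u32       format version (1)
    u32       number of sequences
    per sequence: u32 name byte-length, name (UTF-8), u64 sequence length

This layout is this implementation's own; no compatibility with any other
``.ri`` producer is claimed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .construction import RIndex, RunLengthBWT, SASamples
from .corpus_io import SequenceCatalog

MAGIC_MAIN = b"RINDEXv1"
MAGIC_CATALOG = b"RICATv1\x00"
FORMAT_VERSION = 1


class IndexFileError(ValueError):
    """Base class for unreadable index files."""


class MissingIndexFileError(IndexFileError, FileNotFoundError):
    """One of the two index files does not exist."""


class IndexFormatError(IndexFileError):
    """Bad magic bytes or unsupported format version."""


class TruncatedIndexError(IndexFileError):
    """File ended before its declared payload."""


@dataclass(frozen=True)
class IndexFilePair:
    main_path: Path
    catalog_path: Path
    format_version: int = FORMAT_VERSION


def _paths(prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    return prefix.with_name(prefix.name + ".ri"), prefix.with_name(
        prefix.name + ".1.ri"
    )


def save_index(index: RIndex, prefix: str | Path) -> IndexFilePair:
    """Write the index as ``<prefix>.ri`` + ``<prefix>.1.ri``."""
    main_path, catalog_path = _paths(prefix)
    r = index.rlbwt.r
    with open(main_path, "wb") as fh:
        fh.write(MAGIC_MAIN)
        fh.write(struct.pack("<I", FORMAT_VERSION))
        fh.write(struct.pack("<QQ", index.n, r))
        fh.write(index.rlbwt.heads.encode("ascii"))
        fh.write(index.rlbwt.lengths.astype("<u8").tobytes())
        fh.write(index.samples.at_run_start.astype("<u8").tobytes())
        fh.write(index.samples.at_run_end.astype("<u8").tobytes())
    with open(catalog_path, "wb") as fh:
        fh.write(MAGIC_CATALOG)
        fh.write(struct.pack("<I", FORMAT_VERSION))
        fh.write(struct.pack("<I", len(index.catalog)))
        for entry in index.catalog:
            name = entry.name.encode("utf-8")
            fh.write(struct.pack("<I", len(name)))
            fh.write(name)
            fh.write(struct.pack("<Q", entry.length))
    return IndexFilePair(main_path=main_path, catalog_path=catalog_path)


def _read_exact(fh, size: int, what: str) -> bytes:
    data = fh.read(size)
    if len(data) != size:
        raise TruncatedIndexError(f"{fh.name}: truncated while reading {what}")
    return data


def _check_header(fh, magic: bytes) -> None:
    got = _read_exact(fh, len(magic), "magic bytes")
    if got != magic:
        raise IndexFormatError(f"{fh.name}: bad magic {got!r}")
    (version,) = struct.unpack("<I", _read_exact(fh, 4, "format version"))
    if version != FORMAT_VERSION:
        raise IndexFormatError(f"{fh.name}: unsupported format version {version}")


def load_index(prefix: str | Path) -> RIndex:
    """Reconstruct an index from ``<prefix>.ri`` + ``<prefix>.1.ri``."""
    main_path, catalog_path = _paths(prefix)
    if not main_path.exists():
        raise MissingIndexFileError(f"missing index file {main_path}")
    if not catalog_path.exists():
        raise MissingIndexFileError(f"missing catalog file {catalog_path}")

    with open(main_path, "rb") as fh:
        _check_header(fh, MAGIC_MAIN)
        n, r = struct.unpack("<QQ", _read_exact(fh, 16, "n and r"))
        heads = _read_exact(fh, r, "run heads").decode("ascii")
        lengths = np.frombuffer(
            _read_exact(fh, 8 * r, "run lengths"), dtype="<u8"
        ).astype(np.int64)
        at_start = np.frombuffer(
            _read_exact(fh, 8 * r, "run-start samples"), dtype="<u8"
        ).astype(np.int64)
        at_end = np.frombuffer(
            _read_exact(fh, 8 * r, "run-end samples"), dtype="<u8"
        ).astype(np.int64)

    with open(catalog_path, "rb") as fh:
        _check_header(fh, MAGIC_CATALOG)
        (count,) = struct.unpack("<I", _read_exact(fh, 4, "sequence count"))
        names: list[str] = []
        seq_lengths: list[int] = []
        for _ in range(count):
            (name_len,) = struct.unpack("<I", _read_exact(fh, 4, "name length"))
            names.append(_read_exact(fh, name_len, "name").decode("utf-8"))
            (length,) = struct.unpack("<Q", _read_exact(fh, 8, "sequence length"))
            seq_lengths.append(length)

    rlbwt = RunLengthBWT(heads, lengths)
    if rlbwt.n != n:
        raise IndexFormatError(
            f"{main_path}: run lengths sum to {rlbwt.n}, header says {n}"
        )
    catalog = SequenceCatalog.from_names_and_lengths(names, seq_lengths)
    if catalog.text_length != n:
        raise IndexFormatError(
            f"{catalog_path}: catalog implies text length {catalog.text_length}, "
            f"index says {n}"
        )
    samples = SASamples(at_run_start=at_start, at_run_end=at_end)
    return RIndex(rlbwt=rlbwt, samples=samples, catalog=catalog, n=n)
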
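"""Desk-scale fixture generation: near-identical genome collections and reads.

The generator emulates the statistical shape of a viral pan-genome: one
random ancestral sequence plus many independently mutated copies, so the
concatenated text is highly repetitive and its BWT has far fewer runs than
symbols.  Reads are fixed-length windows sampled uniformly from one genome,
either verbatim (``simulated.<i>``) or with an exact number of substitution
edits (``simulated.<i>.<e>edits``), mirroring the naming of simulated read
sets used with this kind of index.

All randomness comes from NumPy's default PCG64 generator seeded from the
spec, so identical specs produce byte-identical FASTA/FASTQ output.
"""

from __future__ import annotations

import gzip
import textwrap
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_BASES = np.array(list("ACGT"))


@dataclass
class CollectionSpec:
    """Parameters for a collection of near-identical genomes.

    Defaults give 50 copies of a 5 kb genome with 1% substitutions and
    0.1% indels per base — a scaled-down stand-in for collections of a few
    thousand ~10 kb viral genomes.
    """

    num_sequences: int = 50
    base_length: int = 5000
    substitution_rate: float = 0.01
    indel_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.num_sequences < 1:
            raise ValueError("num_sequences must be >= 1")
        if self.base_length < 50:
            raise ValueError("base_length must be >= 50")
        for rate, label in (
            (self.substitution_rate, "substitution_rate"),
            (self.indel_rate, "indel_rate"),
        ):
            if not 0 <= rate <= 0.2:
                raise ValueError(f"{label} must lie in [0, 0.2], got {rate}")


@dataclass
class ReadSimSpec:
    """Parameters for simulated fixed-length reads from one genome."""

    num_reads: int = 100
    read_length: int = 100
    edits_per_read: int = 0
    source_index: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.num_reads < 1:
            raise ValueError("num_reads must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.edits_per_read < 0:
            raise ValueError("edits_per_read must be >= 0")
        if self.edits_per_read > self.read_length:
            raise ValueError("edits_per_read cannot exceed read_length")


def _mutate(genome: np.ndarray, sub_rate: float, indel_rate: float,
            rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitutions and indels applied to a genome."""
    out: list[str] = []
    n = len(genome)
    subs = rng.random(n) < sub_rate
    indels = rng.random(n) < indel_rate
    for i in range(n):
        base = genome[i]
        if subs[i]:
            choices = _BASES[_BASES != base]
            base = rng.choice(choices)
        if indels[i]:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(base)
            out.append(str(rng.choice(_BASES)))  # insertion after this base
            continue
        out.append(base)
    return np.array(out)


def generate_collection(spec: CollectionSpec) -> str:
    """FASTA text for one random genome plus independent mutant copies.

    Sequence 0 (``genome.0``) is uniform over {A,C,G,T}; sequences
    1..s-1 are independent mutants of it at the spec's rates.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.choice(_BASES, size=spec.base_length)
    records = [("genome.0", "".join(ancestor))]
    for i in range(1, spec.num_sequences):
        mutant = _mutate(ancestor, spec.substitution_rate, spec.indel_rate, rng)
        records.append((f"genome.{i}", "".join(mutant)))
    lines = []
    for name, seq in records:
        lines.append(f">{name}")
        lines.extend(textwrap.wrap(seq, 70))
    return "\n".join(lines) + "\n"


def simulate_reads(genome: str, spec: ReadSimSpec) -> str:
    """FASTQ text of fixed-length reads sampled uniformly from ``genome``.

    With ``edits_per_read`` = 0, every read is an exact substring and is
    named ``simulated.<i>``; with e > 0, exactly e distinct positions are
    substituted and reads are named ``simulated.<i>.<e>edits``.  Qualities
    are all ``~``.
    """
    spec.validate()
    if spec.read_length > len(genome):
        raise ValueError(
            f"read_length {spec.read_length} exceeds genome length {len(genome)}"
        )
    rng = np.random.default_rng(spec.seed)
    e = spec.edits_per_read
    qual = "~" * spec.read_length
    chunks = []
    for i in range(spec.num_reads):
        start = int(rng.integers(0, len(genome) - spec.read_length + 1))
        read = list(genome[start : start + spec.read_length])
        if e > 0:
            positions = rng.choice(spec.read_length, size=e, replace=False)
            for pos in positions:
                choices = _BASES[_BASES != read[pos]]
                read[pos] = str(rng.choice(choices))
            name = f"simulated.{i}.{e}edits"
        else:
            name = f"simulated.{i}"
        chunks.append(f"@{name}\n{''.join(read)}\n+\n{qual}\n")
    return "".join(chunks)


def write_text(content: str, path: str | Path, gzipped: bool | None = None) -> Path:
    """Write generated FASTA/FASTQ text, gzipping when the path ends in .gz."""
    path = Path(path)
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    if gzipped:
        with gzip.open(path, "wt") as fh:
            fh.write(content)
    else:
        path.write_text(content)
    return path
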
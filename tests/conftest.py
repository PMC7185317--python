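import random

import pytest

from rindex import (
    ConcatenatedText,
    SequenceCatalog,
    build_index,
)


def index_of_text(text: str):
    """Build an RIndex over a raw terminator-final text string.

    Wraps the text in a single-sequence catalog so the query layer can be
    exercised without going through FASTA parsing.
    """
    catalog = SequenceCatalog.from_names_and_lengths(["seq"], [len(text) - 1])
    return build_index(catalog, ConcatenatedText(text))


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def toy_index():
    """Index over the worked example text ACGACG$."""
    return index_of_text("ACGACG$")


@pytest.fixture
def two_seq_fasta(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(">s1 first\nACGT\n>s2 second\nGG\n")
    return path
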
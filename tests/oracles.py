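"""Brute-force reference implementations used only by the test suite.

Direct O(n^2)-ish transcriptions of the definitions: naive suffix sorting,
naive substring occurrence search, and naive longest-matching-suffix
computation.  They are deliberately kept out of the installed package.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class OracleResult:
    positions: list[int]  # sorted, 0-based
    count: int


def naive_occurrences(text: str, pattern: str) -> OracleResult:
    """All start offsets of ``pattern`` in ``text`` by direct scan."""
    assert pattern, "pattern must be non-empty"
    positions = []
    p = text.find(pattern)
    while p != -1:
        positions.append(p)
        p = text.find(pattern, p + 1)  # overlapping occurrences count
    return OracleResult(positions=positions, count=len(positions))


def naive_suffix_array(text: str) -> list[int]:
    """Suffix start offsets sorted by full lexicographic comparison."""
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_longest_suffix(text: str, pattern: str) -> tuple[int, int]:
    """Largest m with pattern[-m:] occurring in text, and that count."""
    assert pattern, "pattern must be non-empty"
    for m in range(len(pattern), 0, -1):
        result = naive_occurrences(text, pattern[-m:])
        if result.count:
            return m, result.count
    return 0, 0
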
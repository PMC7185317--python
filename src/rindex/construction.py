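"""Index construction: suffix array, BWT, run-length encoding, SA samples.

The suffix array is built with SA-IS (suffix array by induced sorting),
which runs in linear time in the text length.  From it we derive the BWT,
run-length encode it, and keep the suffix-array values only at the first
and last row of every BWT run.  Those O(r) samples are all that locate
queries need: the value at a run's last row seeds the "toehold" carried
through backward search, and the pairs (SA[b], SA[b-1]) at run-start rows b
define the phi predecessor structure that enumerates the remaining
occurrences.  The full suffix array and the plain BWT are discarded once
sampling is done, so the retained index state is O(r) plus the catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import ConcatenatedText, SequenceCatalog

#: Suffix counts at or below this size are sorted by direct comparison
#: instead of recursing.
_SAIS_BASE_CASE = 64


class MissingTerminatorError(ValueError):
    """Text does not end with its unique smallest symbol."""


class UnsupportedBackendError(ValueError):
    """A construction backend other than 'sais' was requested."""


# ---------------------------------------------------------------------------
# Suffix array (SA-IS)
# ---------------------------------------------------------------------------


def _sais(s: list[int], sigma: int) -> list[int]:
    """SA-IS on an integer string whose last symbol is 0, unique and smallest."""
    n = len(s)
    if n == 1:
        return [0]
    if n <= _SAIS_BASE_CASE:
        return sorted(range(n), key=lambda i: s[i:])

    # classify suffixes: True = S-type (suffix smaller than its successor)
    stype = [False] * n
    stype[n - 1] = True
    for i in range(n - 2, -1, -1):
        stype[i] = s[i] < s[i + 1] or (s[i] == s[i + 1] and stype[i + 1])
    is_lms = [i > 0 and stype[i] and not stype[i - 1] for i in range(n)]

    counts = [0] * sigma
    for c in s:
        counts[c] += 1

    def bucket_tails() -> list[int]:
        tails, total = [0] * sigma, 0
        for c in range(sigma):
            total += counts[c]
            tails[c] = total - 1
        return tails

    def bucket_heads() -> list[int]:
        heads, total = [0] * sigma, 0
        for c in range(sigma):
            heads[c] = total
            total += counts[c]
        return heads

    def induce(lms_order: list[int]) -> list[int]:
        sa = [-1] * n
        tails = bucket_tails()
        for i in reversed(lms_order):  # place LMS suffixes at bucket tails
            c = s[i]
            sa[tails[c]] = i
            tails[c] -= 1
        heads = bucket_heads()
        for i in range(n):  # induce L-types left to right
            j = sa[i] - 1
            if j >= 0 and not stype[j]:
                c = s[j]
                sa[heads[c]] = j
                heads[c] += 1
        tails = bucket_tails()
        for i in range(n - 1, -1, -1):  # induce S-types right to left
            j = sa[i] - 1
            if j >= 0 and stype[j]:
                c = s[j]
                sa[tails[c]] = j
                tails[c] -= 1
        return sa

    lms_positions = [i for i in range(n) if is_lms[i]]
    sa = induce(lms_positions)

    # name LMS substrings in the order they appear in sa
    def lms_equal(a: int, b: int) -> bool:
        # the sentinel's LMS substring is the single sentinel symbol
        if a == n - 1 or b == n - 1:
            return a == b
        k = 0
        while True:
            a_end = k > 0 and is_lms[a + k]
            b_end = k > 0 and is_lms[b + k]
            if a_end and b_end:
                return True
            if a_end != b_end or s[a + k] != s[b + k]:
                return False
            k += 1

    name_of = [-1] * n
    current = -1
    prev = -1
    for pos in sa:
        if not is_lms[pos]:
            continue
        if prev == -1 or not lms_equal(prev, pos):
            current += 1
        name_of[pos] = current
        prev = pos
    num_names = current + 1

    reduced = [name_of[i] for i in lms_positions]
    if num_names == len(reduced):
        # all names distinct: order is given directly
        order = [0] * len(reduced)
        for idx, name in enumerate(reduced):
            order[name] = idx
        lms_sorted = [lms_positions[order[k]] for k in range(len(reduced))]
    else:
        sub_sa = _sais(reduced, num_names)
        lms_sorted = [lms_positions[k] for k in sub_sa]

    return induce(lms_sorted)


@dataclass
class SuffixArray:
    sa: list[int]

    def __len__(self) -> int:
        return len(self.sa)

    def __getitem__(self, i: int) -> int:
        return self.sa[i]


def _check_terminator(text: str) -> None:
    if not text:
        raise MissingTerminatorError("empty text")
    last = text[-1]
    if text.count(last) != 1:
        raise MissingTerminatorError("terminator symbol is not unique")
    if min(text) != last:
        raise MissingTerminatorError("terminator is not the smallest symbol")


def build_suffix_array(text: ConcatenatedText | str) -> SuffixArray:
    """Suffix array of ``text`` by induced sorting.

    The text must end with a unique symbol that sorts strictly below every
    other symbol present (the terminator).
    """
    t = text.text if isinstance(text, ConcatenatedText) else text
    _check_terminator(t)
    alphabet = sorted(set(t))
    code = {ch: k for k, ch in enumerate(alphabet)}
    s = [code[ch] for ch in t]
    return SuffixArray(_sais(s, len(alphabet)))


# ---------------------------------------------------------------------------
# BWT and run-length encoding
# ---------------------------------------------------------------------------


def bwt_from_sa(text: ConcatenatedText | str, sa: SuffixArray) -> str:
    """Plain BWT: ``bwt[i] = text[sa[i] - 1]`` (row 0 wraps to the terminator)."""
    t = text.text if isinstance(text, ConcatenatedText) else text
    if len(t) != len(sa):
        raise ValueError(f"text length {len(t)} != suffix array length {len(sa)}")
    return "".join(t[p - 1] for p in sa.sa)


@dataclass
class RunLengthBWT:
    """BWT stored as r maximal runs with O(log r) rank support.

    ``heads[j]``/``lengths[j]`` give run j's symbol and length.  Per-symbol
    tables (run start rows, cumulative symbol lengths, global run ids) back
    rank queries by binary search, without ever decoding the BWT.
    """

    heads: str
    lengths: np.ndarray  # int64, one per run
    run_starts: np.ndarray = field(init=False)  # first BWT row of each run
    symbol_counts: dict[str, int] = field(init=False)
    _sym_starts: dict[str, np.ndarray] = field(init=False, repr=False)
    _sym_cumlen: dict[str, np.ndarray] = field(init=False, repr=False)
    _sym_runs: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if len(self.heads) != len(self.lengths):
            raise ValueError("heads and lengths disagree on run count")
        if len(self.heads) == 0:
            raise ValueError("empty BWT")
        if np.any(self.lengths <= 0):
            raise ValueError("run lengths must be positive")
        for a, b in zip(self.heads, self.heads[1:]):
            if a == b:
                raise ValueError("adjacent runs share a head symbol")
        ends = np.cumsum(self.lengths)
        self.run_starts = ends - self.lengths
        self.symbol_counts = {}
        self._sym_starts, self._sym_cumlen, self._sym_runs = {}, {}, {}
        by_symbol: dict[str, list[int]] = {}
        for j, c in enumerate(self.heads):
            by_symbol.setdefault(c, []).append(j)
        for c, runs in by_symbol.items():
            runs_arr = np.asarray(runs, dtype=np.int64)
            lens = self.lengths[runs_arr]
            self.symbol_counts[c] = int(lens.sum())
            self._sym_starts[c] = self.run_starts[runs_arr]
            self._sym_cumlen[c] = np.concatenate(([0], np.cumsum(lens)[:-1]))
            self._sym_runs[c] = runs_arr
        self._c_array: dict[str, int] = {}
        total = 0
        for sym in sorted(self.symbol_counts):
            self._c_array[sym] = total
            total += self.symbol_counts[sym]

    @property
    def r(self) -> int:
        return len(self.heads)

    @property
    def n(self) -> int:
        return int(self.lengths.sum())

    def rank(self, symbol: str, i: int) -> int:
        """Occurrences of ``symbol`` among the first ``i`` BWT symbols."""
        if not 0 <= i <= self.n:
            raise ValueError(f"rank prefix length {i} outside [0, {self.n}]")
        starts = self._sym_starts.get(symbol)
        if starts is None or i == 0:
            return 0
        k = int(np.searchsorted(starts, i - 1, side="right")) - 1
        if k < 0:
            return 0
        run = self._sym_runs[symbol][k]
        within = min(int(self.lengths[run]), i - int(starts[k]))
        return int(self._sym_cumlen[symbol][k]) + within

    def run_of_row(self, row: int) -> int:
        """Index of the run containing BWT row ``row``."""
        if not 0 <= row < self.n:
            raise ValueError(f"row {row} outside [0, {self.n})")
        return int(np.searchsorted(self.run_starts, row, side="right")) - 1

    def symbol_at(self, row: int) -> str:
        return self.heads[self.run_of_row(row)]

    def last_symbol_run_in(self, symbol: str, hi: int) -> int | None:
        """Global index of the last run of ``symbol`` starting at row <= hi."""
        starts = self._sym_starts.get(symbol)
        if starts is None:
            return None
        k = int(np.searchsorted(starts, hi, side="right")) - 1
        if k < 0:
            return None
        return int(self._sym_runs[symbol][k])

    def decode(self) -> str:
        """Reconstruct the plain BWT (testing/debugging only: O(n))."""
        return "".join(c * int(l) for c, l in zip(self.heads, self.lengths))

    def c_array(self) -> dict[str, int]:
        """For each symbol, the count of strictly smaller symbols in the text."""
        return self._c_array


def run_length_encode(bwt: str) -> RunLengthBWT:
    """Encode a plain BWT string into maximal runs."""
    if not bwt:
        raise ValueError("cannot run-length encode an empty BWT")
    heads: list[str] = []
    lengths: list[int] = []
    prev = None
    for c in bwt:
        if c == prev:
            lengths[-1] += 1
        else:
            heads.append(c)
            lengths.append(1)
            prev = c
    return RunLengthBWT("".join(heads), np.asarray(lengths, dtype=np.int64))


# ---------------------------------------------------------------------------
# Run-boundary SA samples and the assembled index
# ---------------------------------------------------------------------------


@dataclass
class SASamples:
    """Suffix-array values at the first and last row of every BWT run.

    ``phi_keys``/``phi_companions`` hold the sorted pairs (SA[b], SA[b-1])
    over run-start rows b > 0; since row b-1 is the previous run's last row,
    the companions are just ``at_run_end`` of the preceding run.
    """

    at_run_start: np.ndarray  # SA value at each run's first row
    at_run_end: np.ndarray  # SA value at each run's last row
    phi_keys: np.ndarray = field(init=False)
    phi_companions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.at_run_start = np.asarray(self.at_run_start, dtype=np.int64)
        self.at_run_end = np.asarray(self.at_run_end, dtype=np.int64)
        if len(self.at_run_start) != len(self.at_run_end):
            raise ValueError("sample arrays disagree on run count")
        keys = self.at_run_start[1:]
        companions = self.at_run_end[:-1]
        order = np.argsort(keys, kind="stable")
        self.phi_keys = keys[order]
        self.phi_companions = companions[order]

    @property
    def phi_pairs(self) -> dict[int, int]:
        return dict(zip(self.phi_keys.tolist(), self.phi_companions.tolist()))


def sample_run_boundaries(sa: SuffixArray, rlbwt: RunLengthBWT) -> SASamples:
    """Keep SA values at run boundaries; all other SA entries are dropped."""
    if len(sa) != rlbwt.n:
        raise ValueError("suffix array and BWT disagree on text length")
    starts = rlbwt.run_starts
    ends = starts + rlbwt.lengths.astype(np.int64) - 1
    sa_arr = np.asarray(sa.sa, dtype=np.int64)
    return SASamples(at_run_start=sa_arr[starts], at_run_end=sa_arr[ends])


@dataclass
class RIndex:
    """The complete r-index: run-length BWT, boundary samples, catalog."""

    rlbwt: RunLengthBWT
    samples: SASamples
    catalog: SequenceCatalog
    n: int

    def __post_init__(self) -> None:
        if self.n != self.rlbwt.n:
            raise ValueError("text length disagrees with BWT run lengths")
        if len(self.samples.at_run_start) != self.rlbwt.r:
            raise ValueError("sample count disagrees with run count")

    @property
    def r(self) -> int:
        return self.rlbwt.r


def build_index(
    catalog: SequenceCatalog, text: ConcatenatedText, backend: str = "sais"
) -> RIndex:
    """Build the full r-index for a parsed collection.

    Only the ``sais`` construction backend is available; the prefix-free
    parsing backend used by other implementations for very large inputs is
    intentionally not provided, and requesting it raises
    :class:`UnsupportedBackendError`.
    """
    if backend != "sais":
        raise UnsupportedBackendError(
            f"unsupported construction backend {backend!r}; only 'sais' is available"
        )
    if len(catalog) == 0:
        raise ValueError("empty sequence catalog")
    if catalog.text_length != text.n:
        raise ValueError("catalog and text disagree on total length")
    sa = build_suffix_array(text)
    rlbwt = run_length_encode(bwt_from_sa(text, sa))
    samples = sample_run_boundaries(sa, rlbwt)
    # sa and the plain BWT go out of scope here: retained state is O(r)
    return RIndex(rlbwt=rlbwt, samples=samples, catalog=catalog, n=text.n)
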
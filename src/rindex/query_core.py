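"""Backward search, counting and locating over the run-length BWT.

Count queries process a read right to left, maintaining the interval of
sorted suffixes prefixed by the matched suffix; the interval size is the
occurrence count and the number of successful steps is the length of the
longest read suffix present in the text.  Alongside the interval we carry a
single suffix-array value at the interval end (the toehold), updated at
each step from the run-boundary samples.  Locate queries start at the
toehold and recover every other occurrence with the phi function
phi(SA[i]) = SA[i-1], evaluated by predecessor search over the sampled
run-start pairs: for the largest sampled key s <= x, phi(x) =
companion(s) + (x - s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .construction import RIndex
from .corpus_io import Read


class EmptyPatternError(ValueError):
    """Count/locate semantics are undefined for a zero-length pattern."""


class PhiDomainError(ValueError):
    """phi was asked for the predecessor of the first suffix-array row."""


@dataclass
class MatchState:
    """Interval [lo, hi] of BWT rows plus the toehold SA value at row hi.

    ``matched`` counts pattern symbols consumed so far.  An empty interval
    (lo > hi) means the extended suffix does not occur; ``toehold`` is then
    meaningless and set to -1.
    """

    lo: int
    hi: int
    toehold: int
    matched: int

    @property
    def is_empty(self) -> bool:
        return self.lo > self.hi

    @property
    def width(self) -> int:
        return 0 if self.is_empty else self.hi - self.lo + 1


@dataclass
class CountResult:
    read_name: str
    matched: int
    read_len: int
    occurrences: int


def initial_state(index: RIndex) -> MatchState:
    """The full interval over all BWT rows, before any symbol is matched.

    The toehold is SA[n-1], which is the last run's end sample.
    """
    return MatchState(
        lo=0,
        hi=index.n - 1,
        toehold=int(index.samples.at_run_end[-1]),
        matched=0,
    )


_EMPTY = -1


def backward_extend(index: RIndex, state: MatchState, symbol: str) -> MatchState:
    """One backward-search step: prepend ``symbol`` to the matched suffix.

    Standard FM step on the interval (C-array plus rank at lo and hi+1),
    plus the toehold update: if row hi itself holds ``symbol``, the new
    toehold is the old one minus 1; otherwise the last occurrence of
    ``symbol`` in the interval is the final row of some run, whose end
    sample minus 1 becomes the new toehold.  Symbols absent from the index
    alphabet simply empty the interval.
    """
    if state.is_empty:
        return state
    rlbwt = index.rlbwt
    c_arr = rlbwt.c_array()
    if symbol not in c_arr:
        return MatchState(lo=1, hi=0, toehold=_EMPTY, matched=state.matched)
    base = c_arr[symbol]
    lo = base + rlbwt.rank(symbol, state.lo)
    hi = base + rlbwt.rank(symbol, state.hi + 1) - 1
    if lo > hi:
        return MatchState(lo=1, hi=0, toehold=_EMPTY, matched=state.matched)
    if rlbwt.symbol_at(state.hi) == symbol:
        toehold = state.toehold - 1
    else:
        run = rlbwt.last_symbol_run_in(symbol, state.hi)
        # the interval is non-empty, so a run of `symbol` intersects it and,
        # since row hi holds another symbol, ends strictly inside [lo, hi]
        toehold = int(index.samples.at_run_end[run]) - 1
    return MatchState(lo=lo, hi=hi, toehold=toehold, matched=state.matched + 1)


def longest_suffix_match(index: RIndex, pattern: str) -> MatchState:
    """Longest suffix of ``pattern`` occurring in the indexed text.

    Runs backward search right to left and stops at the first empty
    interval, returning the last non-empty state; ``matched`` is the suffix
    length and the interval width its occurrence count.  If even the final
    symbol is absent the returned state is empty with ``matched`` 0.
    """
    if not pattern:
        raise EmptyPatternError("cannot match an empty pattern")
    state = initial_state(index)
    for symbol in reversed(pattern):
        nxt = backward_extend(index, state, symbol)
        if nxt.is_empty:
            return nxt if state.matched == 0 else state
        state = nxt
    return state


def count_read(index: RIndex, read: Read) -> CountResult:
    """Longest-matching-suffix length and its occurrence count for a read."""
    state = longest_suffix_match(index, read.bases)
    return CountResult(
        read_name=read.name,
        matched=state.matched,
        read_len=len(read.bases),
        occurrences=state.width,
    )


def phi(index: RIndex, x: int) -> int:
    """SA[i-1] given x = SA[i] (i > 0), from the sampled run-start pairs."""
    if x == index.n - 1:
        # SA[0] is always n-1 (the terminator suffix); it has no predecessor
        raise PhiDomainError("phi is undefined for the first suffix-array row")
    keys = index.samples.phi_keys
    k = int(np.searchsorted(keys, x, side="right")) - 1
    if k < 0:
        raise PhiDomainError(f"no sampled key at or below {x}")
    s = int(keys[k])
    return int(index.samples.phi_companions[k]) + (x - s)


def locate_read(
    index: RIndex, read: Read, max_hits: int | None = None
) -> tuple[list[int], int, int]:
    """Occurrence positions of a perfectly matching read.

    Returns ``(positions, total, matched)``.  Positions are 0-based global
    text offsets, enumerated from the interval-end toehold by repeated phi
    application (a deterministic order under a --max-hits cap); ``total``
    is always the full interval size.  Reads whose longest matching suffix
    is shorter than the read yield no positions, but total and matched are
    still reported for the caller's bookkeeping.
    """
    if max_hits is not None and max_hits <= 0:
        raise ValueError(f"max_hits must be positive, got {max_hits}")
    state = longest_suffix_match(index, read.bases)
    total = state.width
    matched = state.matched
    if matched < len(read.bases) or total == 0:
        return [], total, matched
    limit = total if max_hits is None else min(total, max_hits)
    positions = [state.toehold]
    for _ in range(limit - 1):
        positions.append(phi(index, positions[-1]))
    return positions, total, matched
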
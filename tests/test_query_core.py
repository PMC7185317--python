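import random

import pytest

from rindex import (
    Read,
    TERMINATOR,
    backward_extend,
    build_suffix_array,
    count_read,
    initial_state,
    locate_read,
    longest_suffix_match,
    phi,
)
from rindex.query_core import EmptyPatternError, PhiDomainError

from conftest import index_of_text, random_dna
from oracles import naive_longest_suffix, naive_occurrences


class TestRank:
    @pytest.mark.parametrize(
        "symbol,i,expected",
        [
            ("A", 4, 1),
            ("A", 0, 0),
            ("G", 7, 2),
            ("C", 7, 2),
            ("$", 3, 1),
            ("T", 7, 0),  # symbol absent from the index alphabet
        ],
    )
    def test_against_decoded_prefix(self, toy_index, symbol, i, expected):
        # BWT of ACGACG$ is GG$AACC
        assert toy_index.rlbwt.rank(symbol, i) == expected
        assert toy_index.rlbwt.decode()[:i].count(symbol) == expected


class TestBackwardExtend:
    def test_single_symbol_interval_and_toehold(self, toy_index):
        state = backward_extend(toy_index, initial_state(toy_index), "G")
        # suffixes starting with G occupy rows 5..6 of SA [6,3,0,4,1,5,2]
        assert (state.lo, state.hi) == (5, 6)
        assert state.toehold == 2
        assert state.matched == 1

    def test_second_step_updates_toehold_from_run_sample(self, toy_index):
        state = backward_extend(toy_index, initial_state(toy_index), "G")
        state = backward_extend(toy_index, state, "C")
        assert (state.lo, state.hi) == (3, 4)
        assert state.toehold == 1
        assert state.matched == 2

    def test_absent_symbol_empties_interval(self, toy_index):
        state = backward_extend(toy_index, initial_state(toy_index), "G")
        state = backward_extend(toy_index, state, "C")
        state = backward_extend(toy_index, state, "T")
        assert state.is_empty
        assert state.matched == 2

    def test_toehold_equals_sa_at_hi_on_random_texts(self):
        """After every non-empty step, toehold = SA[hi] from the full SA."""
        rng = random.Random(11)
        for _ in range(40):
            text = random_dna(rng, rng.randint(2, 300)) + TERMINATOR
            index = index_of_text(text)
            sa = build_suffix_array(text).sa
            pattern = random_dna(rng, rng.randint(1, 20))
            state = initial_state(index)
            assert state.toehold == sa[state.hi]
            for symbol in reversed(pattern):
                state = backward_extend(index, state, symbol)
                if state.is_empty:
                    break
                assert state.toehold == sa[state.hi]


class TestLongestSuffixMatch:
    @pytest.mark.parametrize(
        "pattern,matched,occurrences",
        [
            ("TACG", 3, 2),
            ("GACG", 4, 1),
            ("TTT", 0, 0),
        ],
    )
    def test_worked_examples(self, toy_index, pattern, matched, occurrences):
        state = longest_suffix_match(toy_index, pattern)
        assert state.matched == matched
        assert state.width == occurrences

    def test_empty_pattern_rejected(self, toy_index):
        with pytest.raises(EmptyPatternError):
            longest_suffix_match(toy_index, "")

    def test_suffix_monotonicity(self):
        """Truncating the pattern from the left never shrinks matched nor
        the occurrence count of the matched suffix."""
        rng = random.Random(5)
        text = random_dna(rng, 500) + TERMINATOR
        index = index_of_text(text)
        for _ in range(20):
            pattern = random_dna(rng, 30)
            prev_m, prev_occ = None, None
            for start in range(len(pattern)):
                sub = pattern[start:]
                state = longest_suffix_match(index, sub)
                if prev_m is not None:
                    assert state.matched >= prev_m - 1
                    if state.matched == prev_m:
                        assert state.width >= prev_occ
                prev_m, prev_occ = state.matched, state.width


class TestPhi:
    def test_worked_examples(self, toy_index):
        # SA of ACGACG$ is [6,3,0,4,1,5,2]
        assert phi(toy_index, 3) == 6
        assert phi(toy_index, 0) == 3

    def test_first_row_has_no_predecessor(self, toy_index):
        with pytest.raises(PhiDomainError):
            phi(toy_index, 6)

    def test_phi_identity_on_random_texts(self):
        """phi(SA[i]) = SA[i-1] for every i > 0."""
        rng = random.Random(17)
        for _ in range(30):
            text = random_dna(rng, rng.randint(2, 400)) + TERMINATOR
            index = index_of_text(text)
            sa = build_suffix_array(text).sa
            for i in range(1, len(sa)):
                assert phi(index, sa[i]) == sa[i - 1]


class TestCountAndLocate:
    def test_count_full_match(self, toy_index):
        result = count_read(toy_index, Read("r", "ACG"))
        assert (result.matched, result.read_len, result.occurrences) == (3, 3, 2)

    def test_count_no_match(self, toy_index):
        result = count_read(toy_index, Read("r", "TTT"))
        assert (result.matched, result.occurrences) == (0, 0)

    def test_locate_all_occurrences(self, toy_index):
        positions, total, matched = locate_read(toy_index, Read("r", "ACG"))
        assert sorted(positions) == [0, 3]
        assert total == 2
        assert matched == 3

    def test_max_hits_caps_positions_not_total(self, toy_index):
        positions, total, _ = locate_read(toy_index, Read("r", "ACG"), max_hits=1)
        assert len(positions) == 1
        assert total == 2

    def test_partial_match_reports_no_positions(self, toy_index):
        positions, total, matched = locate_read(toy_index, Read("r", "TACG"))
        assert positions == []
        assert matched == 3
        assert total == 2

    def test_nonpositive_max_hits_rejected(self, toy_index):
        with pytest.raises(ValueError):
            locate_read(toy_index, Read("r", "ACG"), max_hits=0)

    def test_read_with_symbol_outside_alphabet_is_nonmatching(self, toy_index):
        result = count_read(toy_index, Read("r", "NACG"))
        assert result.matched == 3  # N simply stops the extension


class TestOracleEquivalence:
    def test_count_and_locate_match_naive_oracles(self):
        """Central correctness property: on hundreds of random (text,
        pattern) pairs, matched length, occurrence count and the full
        position set equal the brute-force answers exactly."""
        rng = random.Random(20240001)
        cases = 0
        while cases < 500:
            length = rng.randint(2, 2000)
            text = random_dna(rng, length) + TERMINATOR
            index = index_of_text(text)
            sa_cache = None
            for _ in range(5):
                style = rng.random()
                plen = rng.randint(1, min(60, length))
                if style < 0.4:  # exact substring of the text
                    i = rng.randint(0, length - plen)
                    pattern = text[i : i + plen]
                elif style < 0.8:  # mutated substring
                    i = rng.randint(0, length - plen)
                    chars = list(text[i : i + plen])
                    for _ in range(rng.randint(1, 4)):
                        chars[rng.randrange(plen)] = rng.choice("ACGT")
                    pattern = "".join(chars)
                else:  # fully random
                    pattern = random_dna(rng, plen)
                read = Read("q", pattern)
                m, occ = naive_longest_suffix(text, pattern)
                result = count_read(index, read)
                assert (result.matched, result.occurrences) == (m, occ)
                positions, total, matched = locate_read(index, read)
                oracle = naive_occurrences(text, pattern)
                if matched == plen:
                    assert sorted(positions) == oracle.positions
                    assert total == oracle.count
                    for p in positions:
                        assert text[p : p + plen] == pattern
                    assert len(set(positions)) == len(positions)
                else:
                    assert positions == [] and oracle.count == 0
                cases += 1
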
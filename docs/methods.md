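# Methods

## Text model

A collection of sequences is indexed as one concatenated text: the
sequences in file order, a single separator symbol between consecutive
sequences, and a single terminator symbol at the end. Internally the
terminator is `$` (0x24) and the separator `%` (0x25), chosen so plain
ASCII string comparison realizes the required order terminator <
separator < bases; sequences themselves are restricted to uppercase
letters (input is uppercased on read; `N` and other IUPAC letters are kept
as literal symbols and match only themselves). The separator guarantees no
pattern occurrence spans two sequences, because reads never contain it.
Offsets are 0-based half-open internally and converted to 1-based SAM
coordinates only at output.

## Construction

The suffix array is built with SA-IS (induced sorting): classify suffixes
as S- or L-type, sort the leftmost-S positions via induced sorting of
their LMS substrings, recurse on the renamed reduced string when names
collide, then induce the full array. Suffix sets of at most 64 elements
are sorted by direct comparison instead of recursing — a simplicity
choice; correctness of the whole construction is cross-checked in the
tests against naive suffix sorting on randomized corpora. The plain BWT
(`bwt[i] = text[sa[i]−1]`, row 0 wrapping to the terminator) is
run-length encoded into `r` maximal runs, and the suffix-array values at
every run's first and last row are retained. Everything else — the full
suffix array and the decoded BWT — is dropped, so the resident index is
O(r) integers plus the name catalog. The full array is deliberately
materialized during construction: the space guarantee of this structure
concerns the final index, not the builder, and desk-scale inputs (up to a
few hundred kilobases here) fit comfortably. Only the SA-IS backend
exists; requesting any other construction backend raises an explicit
unsupported-backend error.

## Queries

Backward search keeps the inclusive row interval `[lo, hi]` plus the
toehold `SA[hi]`. A step on symbol c maps `lo ← C[c] + rank_c(lo)` and
`hi ← C[c] + rank_c(hi+1) − 1`; rank is answered by binary search over the
per-symbol run tables, never by decoding. The toehold updates in O(log r):
if row `hi` holds c it decrements, otherwise it becomes the run-end sample
of the last c-run inside the interval, minus one. Counting stops at the
first empty interval and reports the previous state, which makes the
matched length exactly the longest read suffix occurring in the text.
Locate starts from the toehold and applies
`phi(x) = companion(pred(x)) + (x − pred(x))` repeatedly, where the
predecessor structure holds the pairs (SA[b], SA[b−1]) for run-start rows
b > 0 — equivalently, key `at_run_start[j]` with companion
`at_run_end[j−1]`. phi is undefined at SA[0] = n−1 (the terminator
suffix) and raises there; locate never requests more values than the
interval holds, so the error is unreachable in normal operation.

Degenerate inputs: an empty pattern is rejected (the reported fraction
would be undefined); symbols outside the index alphabet simply empty the
interval rather than erroring, so a read containing, say, `N` against an
N-free index just truncates its matching suffix there. Occurrence
enumeration order is the phi order starting at the interval end — the
field's canonical order for this structure — which makes `--max-hits`
truncation deterministic. The total count reported in `NH` is always the
full interval size regardless of the cap.

Only the forward strand is searched. Reverse-complement search,
approximate matching and mapping-quality estimation are out of scope; a
read that does not match in full length produces no locate record (or a
flag-4 record under the opt-in `--report-unmapped`).

## Serialization

`<prefix>.ri` stores magic, version, n, r, run head symbols, run lengths
and both sample arrays; `<prefix>.1.ri` stores the sequence catalog as
length-prefixed UTF-8 names with sequence lengths. All integers are
little-endian 64-bit (32-bit for record counts/name lengths); the exact
layout is documented in `rindex/serialization.py`. The phi predecessor
arrays and the C-array are rebuilt on load from the stored arrays. The
format is this package's own — no compatibility with any other `.ri`
producer is claimed — and load errors are strict and typed: missing file,
bad magic/version, truncated payload and internally inconsistent headers
are each distinct failures, never a silently wrong index.

## Synthetic data

The generator emulates the structure of a viral pan-genome: one uniform
random ancestor over {A,C,G,T} and independent mutant copies with per-base
substitution and indel rates. Defaults — 50 sequences × 5,000 bases, 1%
substitutions, 0.1% indels — are a scaled-down stand-in for collections of
a few thousand ~10.7 kb viral genomes; the 0.1% indel default keeps
sequence lengths slightly heterogeneous, as in real collections, without
dominating divergence. Reads are uniform-start windows of one genome
(default 100 bp, the common short-read length), either verbatim or with an
exact number of substitution edits; edits are substitutions only so that
the ground-truth longest matching suffix stays computable by direct suffix
comparison. All randomness flows through NumPy's seeded PCG64 generator,
so fixtures are byte-reproducible across platforms.

What the generator does *not* model: phylogenetic structure among the
variants (all mutants are independent draws from the ancestor),
quality-dependent or indel sequencing errors, and coverage biases.
Passing tests therefore demonstrate correctness of the index and query
machinery on repetitive collections, not robustness to realistic error
profiles.

## Test design and problem sizes

Every non-trivial operation is checked against an independent brute-force
oracle kept in the test tree (naive suffix sort, naive overlapping
substring scan, naive longest-suffix search): 500+ randomized
(text, pattern) pairs with texts up to 2,000 bases for the query path,
100+ random texts for construction, plus invariant checks (toehold =
SA[hi] after every step, phi ∘ SA identity, BWT inversion by LF walk).
The end-to-end check runs the full CLI on the default 50 × 5 kb
collection with 100 error-free and 100 three-edit reads, verifies every
count line and every SAM record against the FASTA, and validates the SAM
with pysam. These sizes keep the whole suite in the tens of seconds while
exercising every code path at text lengths well past the SA-IS recursion
base case.

The run-growth check freezes the empirically validated bound
r(s) − r(1) ≤ 4·s for s identical 1-kb copies; measured growth is about
one run in total (the bound is deliberately loose, pre-validated by brute
force before adoption).

## Known limitations

- Pure-Python construction: linear-time asymptotics but interpreter
  constants; practical up to megabase-scale texts, not human-genome scale.
- No prefix-free-parsing construction backend, no multithreading, no
  external-memory mode.
- Forward strand only; exact matching only; single-end reads only.
- The on-disk format stores run lengths and samples uncompressed (8 bytes
  each); the O(r) claim is about machine words, and no further bit-packing
  is attempted.
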
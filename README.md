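# rindex

Exact read matching against large collections of similar genomes, in
compressed space.

Pan-genome databases — thousands of assemblies of one species or strain —
are so repetitive that classical FM-indexes waste most of their space on
redundancy. The **r-index** stores the Burrows–Wheeler Transform (BWT) of
the whole collection as its *r* maximal runs and keeps suffix-array samples
only at run boundaries, so the entire index occupies *O(r)* machine words
while still answering both **count** queries (how long is the longest
suffix of a read that occurs anywhere in the database, and how often does
it occur?) and **locate** queries (at which positions?) exactly.

This package is a from-scratch Python implementation of that toolchain:

- **build** — parse a (possibly gzipped) multi-FASTA collection, construct
  the suffix array with SA-IS (induced sorting, linear time), derive and
  run-length-encode the BWT, sample SA values at run boundaries, and save
  the index as two files `<prefix>.ri` (main structures) and
  `<prefix>.1.ri` (offset → sequence-name catalog).
- **align count** — backward search over the run-length BWT, maintaining a
  single suffix-array value (the *toehold*) through every step; reports,
  per read, `name ⟨TAB⟩ m/len ⟨TAB⟩ occurrences`, where *m* is the length
  of the longest read suffix present in the database.
- **align locate** — for reads that match in full length, enumerates
  occurrence positions from the toehold with the phi function
  φ(SA[i]) = SA[i−1] (a predecessor structure over the run-boundary
  samples) and emits SAM v1.6 records with an `NH` tag carrying the total
  occurrence count.
- **simulate** — seeded generators for desk-scale fixtures: collections of
  near-identical genomes and fixed-length reads with a controlled number
  of substitution edits.

## The algorithmic core

For a pattern processed right to left, backward search maintains the
interval `[lo, hi]` of lexicographically sorted suffixes prefixed by the
matched suffix, via the C-array and rank queries answered directly on the
run-length encoding in *O(log r)*. The interval size is the occurrence
count. Alongside, the index keeps `SA[hi]`: when the extension symbol sits
at row `hi` the value just decrements; otherwise the last in-interval
occurrence of the symbol ends some BWT run, whose stored end sample takes
over. One suffix-array value is therefore always in hand when the search
finishes, and every further occurrence follows by iterating
φ(x) = companion(pred(x)) + (x − pred(x)) over the sorted pairs
(SA[b], SA[b−1]) collected at run-start rows b.

## Worked example

```
$ rindex simulate collection dengue_like.fa -s 20 -l 2000 --substitution-rate 0.01 --seed 4
$ rindex simulate reads dengue_like.fa reads.fq -n 4 -l 100 --seed 5
$ rindex simulate reads dengue_like.fa reads_w_errors.fq -n 4 -l 100 -e 3 --seed 5
$ rindex build -o dengue_like dengue_like.fa
indexed 20 sequences: n=40029 r=3938 (98478 + 426 bytes)
```

The 20 genomes total 40,029 symbols but their BWT has only 3,938 runs —
the repetitiveness the index exploits. Error-free reads match in full:

```
$ rindex align count dengue_like reads.fq
simulated.0	100/100	9
simulated.1	100/100	7
simulated.2	100/100	9
simulated.3	100/100	7
```

Each line: read name, longest-matching-suffix length over read length, and
how often that suffix occurs in the collection (simulated.0 occurs at 9
places because 8 mutant genomes retained its window unchanged). With three
random edits per read the matched suffix shortens to the stretch right of
the last edit:

```
$ rindex align count dengue_like reads_w_errors.fq
simulated.0.3edits	19/100	17
simulated.1.3edits	42/100	12
simulated.2.3edits	6/100	1
simulated.3.3edits	11/100	18
```

so e.g. the last 42 characters of `simulated.1.3edits` occur 12 times in
the database but the last 43 occur nowhere. Locating reports SAM, only for
perfect full-length matches; `--max-hits 1` caps the records per read
while `NH` still carries the full count:

```
$ rindex align locate --max-hits 1 dengue_like reads.fq
@HD	VN:1.6	SO:unknown
@SQ	SN:genome.0	LN:2000
@SQ	SN:genome.1	LN:2001
...
simulated.0	0	genome.10	1277	255	100M	*	0	0	AAGC...	~~~~...	NH:i:9
simulated.1	0	genome.17	1531	255	100M	*	0	0	GCTT...	~~~~...	NH:i:7
```

MAPQ 255, `RNEXT *`, `PNEXT 0` and `TLEN 0` are the SAM "unknown" values:
the tool performs exact matching only, no mapping-quality or pair
inference. `--max-range k` restricts output to reads occurring at most k
times.

The same functionality is available as a library
(`rindex.build_index`, `rindex.count_read`, `rindex.locate_read`,
`rindex.save_index` / `load_index`, ...).

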
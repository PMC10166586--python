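# trtile

Decompose, encode, align and visualize tandem-repeat (TR) alleles by motif
composition.

TRs — and especially variable number tandem repeats (VNTRs) with long
motifs — vary not only in copy number but in the internal composition of
their repeat units: substitutions and small indels create imperfect
repeats built from several related motifs. Length-based genotypers miss
this structure. trtile is for researchers who have resolved TR allele
sequences (e.g. from long-read assemblies) and a candidate motif set, and
want a motif-centric view: which motifs occur, in what order and number,
and how composition differs between alleles, populations, species or
case/control groups.

## The method

Given an allele `x` over {A,C,G,T} and motifs `M`, trtile computes the
*optimum parse* — a partition of `x` into consecutive substrings
`x(1), x(2), ...` maximizing

    D(x, M) = Σᵢ max_{m∈M} d(x(i), m)

where `d` is a global alignment score (match +5, mismatch −4, indel −4 by
default), solved exactly by dynamic programming over states `D[i, m, j]`
with free chaining between completed motifs. Substrings that match no
input motif become *novel* motifs. Each distinct motif is then encoded as
one printable symbol (≤ 90 symbols; rare motifs collapse into a grey
"private" class), the encoded alleles are multiple-aligned with a
substitution matrix derived from pairwise motif edit distances, rows are
reordered by hierarchical clustering so similar alleles sit together, and
the result is drawn as one color band per allele with an optional group
annotation and a motif/frequency legend. See `docs/methods.md` for the
full model, parameter meanings and limitations.

## Worked example

```python
>>> import trtile
>>> dec = trtile.decompose("ACCTTGACCTTGACCTTTG", ["ACCTTG"])
>>> [s.substring for s in dec.segments]
['ACCTTG', 'ACCTTG', 'ACCTTTG']
>>> [s.origin for s in dec.segments]
['input', 'input', 'novel']
>>> dec.total_score
86
>>> mapping = trtile.build_mapping([dec], 1)
>>> trtile.encode_allele(dec, mapping)
'112'
```

The 19-bp allele parses into two exact copies of the input motif (score
30 each: 6 matches × 5) and one 7-bp segment `ACCTTTG` that differs from
the motif by a single inserted base (score 26 = 30 − 4), emitted as a
novel motif. Total score 86 is the DP optimum over all partitions. The
two motifs are encoded as symbols `1` (count 2) and `2` (count 1), so the
allele reads `112`.

The same analysis from the shell, over a small FASTA:

```sh
$ trtile run demo.fasta -m ACCTTG --outdir out
$ cat out/decomposition.tsv
allele_id  segment_index  substring  aligned_motif  origin  segment_score
allele1    0              ACCTTG     ACCTTG         input   30
allele1    1              ACCTTG     ACCTTG         input   30
allele1    2              ACCTTTG    ACCTTG         novel   26
...
$ cat out/motif_table.tsv
symbol  motif    count  color
1       ACCTTG   5      #e65050
2       ACCTTTG  3      #50e6e6
```

`out/` also holds the motif→symbol mapping, the aligned symbol FASTA, the
display order, and `figure.svg` — one color band per allele, one cell per
motif, gaps blank, private motifs grey. Each stage (`decompose`,
`encode`, `align`, `rearrange`, `plot`) is also its own subcommand, and
`trtile.SimParams` / `trtile.simulate_alleles` generate seeded synthetic
panels for experimentation and testing.

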
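# Methods

## Problem and model

A tandem repeat (TR) allele is a DNA sequence built from consecutive,
possibly mutated copies of one or more repeat units (motifs). Given an
allele `x` over {A,C,G,T} and a user-supplied motif set `M`, trtile finds
the *optimum parse*: a partition of `x` into consecutive substrings
`x(1), x(2), ...` maximizing

    D(x, M) = sum_i  max_{m in M}  d(x(i), m)

where `d` is a Needleman–Wunsch global alignment score with match +5,
mismatch −4, indel −4 (all configurable; match > 0 > indel is enforced).
Each substring is "aligned" to its best motif; a substring that differs
from every input motif is emitted as a *novel* motif carrying the literal
substring. Novel motifs are not fed back into `M`: parsing is single-pass,
so the parse of one allele never depends on another allele's variants.

### Dynamic program

The optimum is computed over states `D[i, m, j]` — the best score of
parsing the prefix `x[1..i]` with the current segment aligned through
character `j` of motif `m`. Within a motif the standard three-way
recurrence applies (diagonal match/mismatch, vertical/horizontal indel).
Let `B[i] = max_m D[i, m, |m|]` be the best complete parse of the prefix;
`B[i]` feeds position `j = 0` of every motif, so motifs chain freely.
Segments must start at `j = 0` and end at `j = |m|` (no mid-motif entry or
exit) and must consume at least one query character; pure-deletion
(empty) segments are structurally excluded because the open state of row
`i` is only populated after `B[i]` is fixed. Alignments may begin with
insertions (query consumed at `j = 0`) or deletions (motif characters
skipped before the first query character), both at the indel penalty —
there are no free end gaps within a segment. Complexity is
`O(|x| * sum_m |m|)` time and memory; rows are filled with vectorized
running-max updates, so alleles of a few kilobases parse in well under a
second.

Backtracking is deterministic. Ties are resolved in this order:

1. an exact segment (substring equals a motif) over an inexact one;
2. the motif earliest in the user-supplied order;
3. the longer segment (moves that consume query characters are preferred
   over deletions, and extending a segment is preferred over closing it).

Input handling: sequences are upper-cased; `N` is accepted and mismatches
every character including `N`; any other non-ACGT character is an error.
The entire input is parsed — callers supply the TR region only, with
boundaries and candidate motifs produced by whatever upstream tool they
prefer (e.g. Tandem Repeats Finder).

## Encoding

Every observed motif (input or novel, counted once per segment) maps to
one character of a fixed, ordered 90-character alphabet: digits
`1234567890`, then `A–Z`, `a–z`, then punctuation, excluding the gap
character `-`, the private symbol `?`, and whitespace. Symbols are
assigned in descending count order, count ties broken lexicographically,
so symbol rank mirrors motif frequency. Motifs with count below the
private threshold collapse to the shared symbol `?`. With
`threshold="auto"` the smallest `t >= 1` is chosen such that at most 90
motifs reach count `t` — the threshold that maximizes the number of
distinct symbols; `auto` therefore never fails, while an explicit
threshold that would need more than 90 symbols raises an error. The
mapping round-trips through a TSV (`symbol`, `motif`, `count`, plus a
comment line holding the resolved threshold).

## Alignment

Encoded alleles are aligned over symbols, not nucleotides. The
substitution score of symbols `a`, `b` encoding motifs `m_a`, `m_b` is

    score(a, b) = round(s_max − (s_max − s_min) · ed(m_a, m_b) / max(|m_a|, |m_b|))

with `ed` the unit-cost edit distance (computed with edlib), `s_min = 0`,
`s_max = 10` by default and half-up rounding. Identical symbols score
`s_max`; the private symbol scores `s_min` against everything but itself.
Gap runs cost `gap_open + (g − 1) · gap_extend` with defaults −12 / −2;
`gap_open < s_min − 1` is enforced so that opening a gap is always worse
than the worst mismatch between retained symbols — gaps are pushed away
from pairs of similar motifs.

The MSA is progressive: all pairwise global alignments (affine-gap Gotoh)
give distances `1 − identical columns / alignment length`; average-linkage
clustering (scipy) on those distances fixes the merge order; profiles are
merged by Gotoh alignment of column pairs scored as the mean over all
row pairs (a gap inside a profile column scores `gap_extend` against a
symbol and 0 against another gap). Gaps, once inserted, are never removed
("once a gap, always a gap"). Output rows keep input order; all-gap
columns are stripped. The whole procedure is deterministic for a fixed
input order. An external aligner backend (e.g. MAFFT's text mode) could be
slotted in behind the same `EncodedAlignment` contract but is not needed:
the internal aligner keeps the package free of binary dependencies and is
what the tests and the pairwise-optimality oracle exercise.

For two sequences the progressive procedure reduces to a single pairwise
Gotoh alignment, which the test suite checks against an independent plain
DP on random pairs.

## Rearrangement

The display order of rows is, by default, the leaf order of average-linkage
hierarchical clustering on the fraction of alignment columns at which two
rows differ (gap versus symbol counts as a difference). Leaf order is made
deterministic without an optimal-leaf-ordering pass: at every merge the
smaller subtree is placed first, size ties going to the subtree containing
the lexicographically smallest allele id. Alternatives: `motif_count`
(ascending non-gap symbols, ties by id), `length` (identical to
`motif_count` at the symbol level, since the alignment no longer carries
nucleotide lengths), `lexicographic` (by id), and `manual` (caller-supplied
permutation, validated to be a permutation of the alignment ids).

## Rendering

Alleles are horizontal bands, motif position increasing left to right; one
colored cell per non-gap column, gaps left blank; sample names label each
band, with an optional group color chip (e.g. population codes) between
name and band. Symbol colors are evenly spaced HSV hues (saturation 0.65,
value 0.90) assigned by symbol rank, so the most frequent motifs are
maximally separated in hue; the private symbol is always grey (#808080);
on the rare rounding collision the value channel is nudged until all hex
colors are unique. The default output is SVG, written directly as
structured XML whose element classes (`allele-band`, `motif-cell`,
`group-label`, `legend-swatch`) make the figure machine-checkable; PNG and
PDF are drawn with matplotlib. A legend (symbol, motif, count) is embedded
in the figure and also written as a TSV with color hex codes.

## Pipeline and formats

`run_pipeline` chains decompose → encode → align → rearrange → render and
writes six text artifacts (decomposition TSV, mapping TSV, aligned FASTA
over symbols, row-order list, figure, motif table TSV). Each stage is a
standalone function and a CLI subcommand exchanging those same files. All
coordinates in outputs are 0-based with half-open intervals. Errors are
surfaced with the failing stage's name. Every stage is deterministic, so a
fixed configuration yields byte-identical outputs across runs.

## Synthetic data

The simulator emulates a resolved VNTR allele panel at desk scale: each
allele concatenates `k` motif copies (`k` uniform over a configurable
range, generating motif uniform over the motif set), and each copy is
mutated independently with i.i.d. per-base substitutions (to a uniformly
chosen different base) and single-base indels (insertion or deletion with
equal probability). Defaults — a 6-bp motif, 5–20 copies, 1% substitution,
0.2% indel, 100 alleles — model a polymorphic locus with mostly intact
copies and occasional variant motifs. The model deliberately omits
features of real data: duplication slippage and phylogenetic structure
among copies, length-dependent mutation, sequencing/assembly error, and
flanking sequence. Passing tests therefore demonstrate the correctness of
the parsing, encoding, alignment and rendering contracts, not recovery
performance on real assemblies.

A brute-force oracle (`brute_force_decompose`) scores every one of the
`2^(|x|−1)` partitions of a short sequence with a plain quadratic
alignment DP that shares no code with the production parser; it is the
independent ground truth for the DP in the tests and is limited to 15 bp.

## Numerical and degenerate-input choices

- Scores are integers throughout the decomposition DP; a −10⁹ sentinel
  stands in for −∞ (int64, overflow-safe at the supported sizes).
- Profile alignment scores are float means; traceback comparisons use a
  1e-6 absolute tolerance.
- Half-up rounding (`floor(x + 0.5)`) in the scoring matrix, so matrix
  entries do not depend on banker's-rounding parity.
- A single-sequence "MSA" is the sequence itself; a single-row clustering
  order is that row.
- Empty alleles, empty motif sets, duplicate allele ids, duplicate motifs
  and non-DNA characters are rejected with explicit errors.

## Problem sizes used in the checks

The bundled verification runs use instance sizes chosen to keep the
exhaustive oracles exact and the full suite quick on one CPU: oracle
comparisons at |x| ≤ 15 with ≤ 3 motifs of ≤ 5 bp (200 instances),
perfect repeats up to 20 bp × 30 copies, pairwise-MSA oracle checks on 50
random pairs, and an end-to-end panel of 100 alleles at the simulator
defaults.

## Known limitations

- The optimum parse is exact, but with very high mutation rates segment
  boundaries become ambiguous and copy-number recovery degrades — as it
  must, since multiple parses then score equally.
- Progressive MSA is a heuristic for ≥ 3 sequences; only the 2-sequence
  case carries an optimality guarantee.
- Symbols are dataset-relative: the same motif may receive different
  symbols in different runs over different inputs.
- A single scoring matrix is used for all motif pairs; no affine motif
  weighting or per-locus calibration is attempted.
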
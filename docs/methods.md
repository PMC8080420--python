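# Methods

## Model

All comparisons run on *folded* text: Unicode NFC normalization followed by
full case folding. Folding is applied once, on input; lengths are counted
in code points (combining marks in Arabic names compare as code points, no
grapheme clustering). Case-insensitive comparison is the convention that
makes the bundled reference pairs with case slips (`similar/Similer`,
`really/Realy`) score consistently; one bundled pair (`dilemma/Dilemma`)
is incompatible with any single case convention and is flagged anomalous
rather than regressed against.

A word of length *w* is decomposed into exactly *w* overlapping bigrams by
repeating its first letter, so the initial character participates in a
comparison like every other: `(c1,c1), (c1,c2), …, (c_{w−1},c_w)`. A
neutral pad symbol (`#`) was considered and rejected: it mis-scores edits
at the first position against the reference pairs, because a real repeated
letter lets a case-1/case-4 match absorb word-initial context while `#`
never matches anything.

The soft bigram distance is the standard insert/delete/substitute dynamic
program over the two bigram sequences with boundary cost `max(i, j)`.
The substitution cost of aligned bigrams `(S_{i−1},S_i)` vs `(T_{j−1},T_j)`
is a seven-case scale on the four pairwise letter equalities; the indel
cost is a two-case scale (the context-compatible deletion and insertion
patterns) with default 1. Each case carries a weight `wt1 … wt9 ∈ [0, 1]`.

### Numerical and tie-break choices

* **Case precedence.** The seven substitution conditions overlap (four
  identical letters satisfy both the identity and the crossed condition);
  cases are tested in numerical order and the first match wins. This makes
  the classification total and reproduces the reference table.
* **Indel totality.** Only two indel cases are discounted; any other indel
  costs the unit the DP boundary implies. A length-changing edit is
  therefore never cheaper than `min(wt8, wt9)`.
* **Which bigrams feed the indel scale.** Both the deletion and the
  insertion branch of cell `(i, j)` compare source bigram *i* with target
  bigram *j*. This is the only reading that prices a doubled letter at
  `wt8`/`wt9` exactly once (`embarrass/embarass` → 0.5 via case 8,
  `almost/allmost` → 0.5 via case 9).
* **Boundary indels** always cost one full unit even when `wt8, wt9 < 1`:
  leading insertions/deletions have no aligned context to discount.
* **Weights are validated, not clamped**; out-of-range values raise.
* **Rounding for reports** is half-up to 2 decimal places; full precision
  is kept internally and in machine-readable output.
* **Similarity** is `1 − D / max(|s|, |t|)` (bigram count equals word
  length, so one normalizer serves every comparator); the distance is
  clamped into `[0, max]` first, and two empty strings have similarity 1.
  This normalization reproduces the printed reference similarities
  exactly, e.g. `1 − 2/7 = 0.714 → 0.71`.

### Relation to the classical comparators

With `LD-equiv` the scale prices a bigram substitution at 0 exactly when
the current letters match and at 1 otherwise, with unit indels — provably
Levenshtein, and verified exhaustively (all pairs of lengths ≤ 5 over a
3-letter alphabet) plus on seeded random pairs. With `BIDIST-equiv`
(0.5 for one mismatched position, 1 for two) it is exactly the bigram
n-gram distance, verified the same way. `DLD-equiv` is only an
approximation of Damerau–Levenshtein: on alternating strings such as
`abab/baba` the crossed (case-3) zero weight is rewarded twice while the
true distance counts two transpositions; the test suite keeps this
counterexample as a documented demonstration, and asserts agreement only
on the typo fixtures.

The distance is symmetric whenever `wt6 = wt7` and `wt8 = wt9` (true for
every shipped preset), bounded by `max(|s|, |t|)` for any valid scale, and
monotone in each weight (the DP minimum of per-step costs that are
monotone in the weights).

MDLD, the block-transposition comparator, is implemented as the
Damerau-style DP extended with a swap of adjacent blocks of up to
`max_block` characters (default 2) at cost 1; with `max_block = 1` it
coincides with Damerau–Levenshtein, and it is cubic-time in the worst
case. Like the classical Damerau recurrence it is a *restricted* edit
model (transposed material is not edited again), so tests bracket it
between an unrestricted script search and the Damerau distance instead of
asserting equality with the search.

## Evaluation protocol

A labeled pair is predicted a match when its similarity is **at or above**
the threshold (the inclusive rule keeps the endpoints of the conventional
0.65–0.90 grid usable). Precision is `TP/(TP+FP)`, recall `TP/(TP+FN)`,
F their harmonic mean, with the standard record-linkage zero-denominator
conventions (P = 0 when nothing is predicted positive, R = 0 when there
are no true matches, F = 0 when P + R = 0). Column means are recomputed
from per-pair values at full precision and rounded last; the bundled
reference table's own printed column means are inconsistent with its cells
in two columns, so per-cell values are treated as ground truth.

## Synthetic data

The generator emulates the error classes observed in curated misspelling
and name-matching benchmarks: character insertion, deletion, substitution,
adjacent transposition, letter doubling/un-doubling and case flips, with
configurable operation probabilities, an edit-count distribution
(default 1–2 edits per corrupted name, the density typical of curated
typo lists), and a seed that makes datasets byte-for-byte reproducible.
Non-match distractors are sampled from distinct names and rejected when
their Levenshtein similarity exceeds a cap (default 0.9) so negative
labels stay meaningful. Bundled word lists (English, Arabic, Portuguese)
are synthetic, authored for this package to exercise the relevant
character inventories.

What the generator does *not* model: phonetic confusions (sound-alike
errors with different spellings), OCR-specific confusion matrices,
keyboard-adjacency bias, token reordering in multi-word names, or the
empirical error-rate mixtures of any published benchmark. Passing the
synthetic evaluation round trip therefore shows the scoring and
thresholding machinery is correct and that single-typo corruption of
well-separated names is recoverable — not that any particular F-measure
will transfer to real name data.

## Problem sizes

The exhaustive emulation checks run over all 364 strings of length ≤ 5 on
a 3-letter alphabet (132,496 ordered pairs, twice); randomized property
checks use a few hundred seeded pairs per invariant; the synthetic
benchmarks use 60–200 labeled pairs from a 56-name word list, and the
single-error calibration check uses 1,000 match pairs. The whole suite
runs in well under a minute on one CPU.

## Known limitations

* The nine weights are configuration, not fitted parameters; no weight
  optimization is provided.
* Bigrams only (n = 2); no general n-gram scale.
* The restricted (optimal-string-alignment) Damerau variant is
  implemented, matching the recurrence the comparators are defined by; it
  is not a metric (triangle inequality can fail), as is standard for this
  family.
* Similarity normalizes by the longer word, which penalizes length
  differences linearly; very short names (≤ 3 letters) leave little room
  between one-edit matches and distractors at the conventional
  thresholds.
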
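"""Bigram decomposition, the soft comparison scale, and the bigram distances.

The core idea: instead of comparing single characters, compare overlapping
character *bigrams*, so every edit is judged in the context of its
neighbouring letter.  A word of length ``w`` is decomposed into exactly ``w``
bigrams by first repeating its initial letter::

    "amend" -> (a,a) (a,m) (m,e) (e,n) (n,d)

Two distances are computed over these sequences by the usual
insert/delete/substitute dynamic program with boundary cost ``max(i, j)``:

* :func:`ndist` — the bigram n-gram distance (n = 2): a substitution of one
  bigram for another costs the fraction of mismatched positions (0, 1/2 or
  1) and every indel costs 1.
* :func:`soft_bidist` — the soft bigram distance: the substitution cost is
  chosen from a seven-case scale over the four pairwise letter comparisons
  of the two bigrams, and the indel cost from a two-case scale, each case
  carrying a tunable weight ``wt1`` … ``wt9`` (see
  :mod:`softbidist.presets`).

The seven substitution cases, checked in order (first match wins):

1. both positions equal                                    -> ``wt1``
2. all four straight and crossed comparisons unequal       -> ``wt2``
3. crossed positions equal (a transposition pattern)       -> ``wt3``
4. previous letters differ, current letters equal          -> ``wt4``
5. previous letters equal, current letters differ          -> ``wt5``
6. source-previous equals target-current only              -> ``wt6``
7. source-current equals target-previous only              -> ``wt7``

and the two discounted indel cases (default cost 1 when neither applies):

8. source-previous equals target-current, currents differ  -> ``wt8``
9. source-current equals target-previous, previouses differ-> ``wt9``

Cases 8/9 recognise an indel that is compatible with the surrounding bigram
context — the signature of a doubled or un-doubled letter — and let it cost
less than a full unit.
"""

from __future__ import annotations

from typing import NamedTuple

from .names import NameString, as_folded
from .presets import WeightScale

__all__ = [
    "BigramPair",
    "pad_and_bigrams",
    "classify_case",
    "dn_cost",
    "id_cost",
    "ndist",
    "soft_bidist",
]


class BigramPair(NamedTuple):
    """An aligned pair of character bigrams (source vs. target)."""

    s_prev: str
    s_cur: str
    t_prev: str
    t_cur: str


def pad_and_bigrams(name: "str | NameString") -> list[tuple[str, str]]:
    """Decompose a folded word into bigrams after doubling its first letter.

    A length-``w`` word yields exactly ``w`` bigrams
    ``(c1,c1), (c1,c2), ..., (c_{w-1},c_w)``; the empty word yields none.
    """
    word = as_folded(name)
    if not word:
        return []
    grams = [(word[0], word[0])]
    grams.extend((word[k - 1], word[k]) for k in range(1, len(word)))
    return grams


def classify_case(b: BigramPair) -> int:
    """Return the substitution case (1-7) for an aligned bigram pair.

    Conditions are tested in numerical order and the first match wins, which
    makes the classification total: the four equality comparisons always
    satisfy at least one case.
    """
    if b.s_prev == b.t_prev and b.s_cur == b.t_cur:
        return 1
    if (
        b.s_prev != b.t_prev
        and b.s_cur != b.t_cur
        and b.s_prev != b.t_cur
        and b.s_cur != b.t_prev
    ):
        return 2
    if b.s_prev == b.t_cur and b.s_cur == b.t_prev:
        return 3
    if b.s_prev != b.t_prev and b.s_cur == b.t_cur:
        return 4
    if b.s_prev == b.t_prev and b.s_cur != b.t_cur:
        return 5
    if b.s_prev == b.t_cur and b.s_cur != b.t_prev:
        return 6
    # remaining possibility: s_prev != t_cur and s_cur == t_prev
    return 7


def dn_cost(b: BigramPair, w: WeightScale) -> float:
    """Substitution cost of an aligned bigram pair under scale ``w``."""
    return w.as_tuple()[classify_case(b) - 1]


def id_cost(b: BigramPair, w: WeightScale) -> float:
    """Insertion/deletion cost of an aligned bigram pair under scale ``w``.

    ``wt8`` when the source-previous letter matches the target-current one
    (case 8, a deletion compatible with its context), ``wt9`` for the mirror
    insertion pattern (case 9), and 1 otherwise.
    """
    if b.s_prev == b.t_cur and b.s_cur != b.t_prev:
        return w.wt8
    if b.s_prev != b.t_cur and b.s_cur == b.t_prev:
        return w.wt9
    return 1.0


def _bigram_mismatch_half(b: BigramPair) -> float:
    # fraction of mismatched positions within the aligned bigrams
    return ((b.s_prev != b.t_prev) + (b.s_cur != b.t_cur)) / 2.0


def _dp(
    gs: list[tuple[str, str]],
    gt: list[tuple[str, str]],
    sub_cost,
    indel_cost,
) -> float:
    """Shared DP skeleton: boundary ``max(i, j)``, three-way minimum."""
    n, m = len(gs), len(gt)
    prev = [float(j) for j in range(m + 1)]
    for i in range(1, n + 1):
        sp, sc = gs[i - 1]
        cur = [float(i)] + [0.0] * m
        for j in range(1, m + 1):
            tp, tc = gt[j - 1]
            pair = BigramPair(sp, sc, tp, tc)
            ic = indel_cost(pair)
            cur[j] = min(
                prev[j] + ic,          # delete source bigram i
                cur[j - 1] + ic,       # insert target bigram j
                prev[j - 1] + sub_cost(pair),
            )
        prev = cur
    return prev[m]


def ndist(s: "str | NameString", t: "str | NameString") -> float:
    """Bigram n-gram distance (n = 2) with first-letter repetition.

    Substituting one bigram for another costs half the number of
    position-wise mismatches; indels cost 1.  Symmetric.
    """
    return _dp(
        pad_and_bigrams(s),
        pad_and_bigrams(t),
        _bigram_mismatch_half,
        lambda pair: 1.0,
    )


def soft_bidist(
    s: "str | NameString", t: "str | NameString", w: WeightScale
) -> float:
    """Soft bigram distance between ``s`` and ``t`` under weight scale ``w``.

    Runs the bigram DP with the seven-case substitution scale and the
    two-case indel scale.  Both the deletion and insertion branches of a cell
    compare source bigram ``i`` against target bigram ``j`` of that cell, so
    a contextually compatible indel is discounted to ``wt8``/``wt9``.
    Boundary indels always cost one full unit.

    The distance is in bigram units, at most ``max(|s|, |t|)`` for any scale
    with all weights <= 1, and is symmetric whenever ``wt6 == wt7`` and
    ``wt8 == wt9`` (true for every shipped preset).
    """
    return _dp(
        pad_and_bigrams(s),
        pad_and_bigrams(t),
        lambda pair: dn_cost(pair, w),
        lambda pair: id_cost(pair, w),
    )
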
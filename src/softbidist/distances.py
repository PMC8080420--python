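"""Classical character-level edit distances and the shared similarity scale.

Three comparators live here:

* :func:`lev_distance` — Levenshtein distance: minimum number of
  single-character insertions, deletions and substitutions.
* :func:`dld_distance` — Damerau–Levenshtein distance in its restricted
  (optimal string alignment) form: one extra operation, the transposition of
  two adjacent characters, at unit cost.
* :func:`mdld_distance` — a modified Damerau–Levenshtein distance in the
  Taxamatch tradition, where a transposed pair of adjacent *blocks* of up to
  ``max_block`` characters counts as a single operation.  The block search
  makes it cubic-time in the worst case.

All distances operate on folded text (see :mod:`softbidist.names`) and are
converted to the reporting scale by :func:`normalized_similarity`:
``sim = 1 - d / max(|s|, |t|)``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from .names import NameString, as_folded

__all__ = [
    "lev_distance",
    "dld_distance",
    "mdld_distance",
    "normalized_similarity",
    "round_half_up",
]


def lev_distance(s: "str | NameString", t: "str | NameString") -> int:
    """Levenshtein distance between the folded forms of ``s`` and ``t``."""
    a, b = as_folded(s), as_folded(t)
    n, m = len(a), len(b)
    if n == 0:
        return m
    if m == 0:
        return n
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,              # deletion
                cur[j - 1] + 1,           # insertion
                prev[j - 1] + (ai != b[j - 1]),  # substitution
            )
        prev = cur
    return prev[m]


def dld_distance(s: "str | NameString", t: "str | NameString") -> int:
    """Damerau–Levenshtein distance (adjacent transposition at cost 1).

    Restricted variant: no substring is edited after being transposed.
    Always ``<= lev_distance``.
    """
    a, b = as_folded(s), as_folded(t)
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                cost = min(cost, d[i - 2][j - 2] + 1)
            d[i][j] = cost
    return d[n][m]


def mdld_distance(
    s: "str | NameString", t: "str | NameString", max_block: int = 2
) -> int:
    """Block-transposition edit distance.

    Extends :func:`dld_distance` by treating the swap of two adjacent,
    non-overlapping blocks of up to ``max_block`` characters each as one
    operation.  With ``max_block=1`` it coincides with the Damerau
    transposition; larger blocks only add options, so
    ``mdld <= dld <= lev`` always.

    Parameters
    ----------
    max_block:
        Largest block length eligible for transposition (``>= 1``).
    """
    if max_block < 1:
        raise ValueError("max_block must be >= 1")
    a, b = as_folded(s), as_folded(t)
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
            # block swap: s ends ...A B, t ends ...B A  (|A|=k, |B|=l)
            for k in range(1, max_block + 1):
                if best == 0:
                    break
                for l in range(1, max_block + 1):
                    if i < k + l or j < k + l:
                        continue
                    if (
                        a[i - k - l : i - l] == b[j - k : j]
                        and a[i - l : i] == b[j - k - l : j - k]
                    ):
                        best = min(best, d[i - k - l][j - k - l] + 1)
            d[i][j] = best
    return d[n][m]


def normalized_similarity(
    distance: float, s: "str | NameString", t: "str | NameString"
) -> float:
    """Map a raw distance to a similarity in [0, 1].

    ``sim = 1 - distance / max(|s|, |t|)`` on folded lengths, with the
    distance clamped into ``[0, max(|s|, |t|)]``.  Two empty strings are
    identical, so their similarity is defined as 1.
    """
    la, lb = len(as_folded(s)), len(as_folded(t))
    longest = max(la, lb)
    if longest == 0:
        return 1.0
    clamped = min(max(float(distance), 0.0), float(longest))
    return 1.0 - clamped / longest


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as similarity tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
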
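"""Classical edit distances against independent recursive and search oracles."""

import itertools
from functools import lru_cache
from heapq import heappop, heappush

import pytest

from softbidist import (
    NameString,
    dld_distance,
    lev_distance,
    mdld_distance,
    normalized_similarity,
    round_half_up,
)

try:
    import edlib
except ImportError:  # pragma: no cover
    edlib = None


# --- independent oracles -------------------------------------------------


def lev_recursive(a: str, b: str) -> int:
    """Direct memoized transcription of the Levenshtein recurrence."""

    @lru_cache(maxsize=None)
    def f(i, j):
        if min(i, j) == 0:
            return max(i, j)
        return min(
            f(i, j - 1) + 1,
            f(i - 1, j) + 1,
            f(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return f(len(a), len(b))


def dld_recursive(a: str, b: str) -> int:
    """Direct memoized transcription of the Damerau–Levenshtein recurrence."""

    @lru_cache(maxsize=None)
    def f(i, j):
        options = []
        if i == 0 and j == 0:
            return 0
        if i > 0:
            options.append(f(i - 1, j) + 1)
        if j > 0:
            options.append(f(i, j - 1) + 1)
        if i > 0 and j > 0:
            options.append(f(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            options.append(f(i - 2, j - 2) + 1)
        return min(options)

    return f(len(a), len(b))


def block_script_search(a: str, b: str, max_block: int = 2, bound: int = 6) -> int:
    """Uniform-cost search over edit scripts including adjacent block swaps.

    Independent of any DP: explores strings reachable from ``a`` by
    substitutions, indels and one-shot swaps of adjacent blocks (each of
    length <= max_block), stopping at cost ``bound``.
    """
    alphabet = sorted(set(a + b)) or ["a"]
    max_len = max(len(a), len(b)) + 1
    frontier = [(0, a)]
    seen = {a: 0}
    while frontier:
        cost, word = heappop(frontier)
        if word == b:
            return cost
        if cost >= bound or cost > seen.get(word, bound):
            continue
        succ = []
        n = len(word)
        for i in range(n):
            succ.append(word[:i] + word[i + 1 :])  # delete
            for c in alphabet:
                if c != word[i]:
                    succ.append(word[:i] + c + word[i + 1 :])  # substitute
        if n < max_len:
            for i in range(n + 1):
                for c in alphabet:
                    succ.append(word[:i] + c + word[i:])  # insert
        for k in range(1, max_block + 1):
            for l in range(1, max_block + 1):
                for i in range(0, n - k - l + 1):
                    blockA, blockB = word[i : i + k], word[i + k : i + k + l]
                    succ.append(word[:i] + blockB + blockA + word[i + k + l :])
        for nxt in succ:
            nc = cost + 1
            if nc < seen.get(nxt, bound + 1):
                seen[nxt] = nc
                heappush(frontier, (nc, nxt))
    return bound


# --- example values ------------------------------------------------------


@pytest.mark.parametrize(
    "s,t,expected",
    [
        ("", "abc", 3),
        ("abc", "", 3),
        ("abc", "abc", 0),
        ("precede", "preceed", 2),
        ("amend", "ammend", 1),
        ("Zantac", "Xanax", 3),
    ],
)
def test_lev_examples(s, t, expected):
    assert lev_distance(s, t) == expected
    assert lev_distance(s, t) == lev_recursive(s.casefold(), t.casefold())


@pytest.mark.parametrize(
    "s,t,expected",
    [
        ("ab", "ba", 1),
        ("precede", "preceed", 1),
        ("abc", "abc", 0),
        ("achieve", "acheive", 1),
    ],
)
def test_dld_examples(s, t, expected):
    assert dld_distance(s, t) == expected


def test_mdld_examples():
    assert mdld_distance("abcd", "abcd") == 0
    assert mdld_distance("ab", "ba") == 1
    # frozen from block_script_search("abcd", "cdab") == 1: one swap of the
    # adjacent 2-blocks "ab" and "cd"
    assert block_script_search("abcd", "cdab") == 1
    assert mdld_distance("abcd", "cdab") == 1


def test_mdld_max_block_one_is_damerau(rng):
    from tests.conftest import random_word

    for _ in range(200):
        a, b = random_word(rng), random_word(rng)
        assert mdld_distance(a, b, max_block=1) == dld_distance(a, b)


def test_mdld_rejects_bad_block():
    with pytest.raises(ValueError):
        mdld_distance("a", "b", max_block=0)


def test_mdld_bracketed_by_script_search_and_dld(rng):
    from tests.conftest import random_word

    for _ in range(60):
        a = random_word(rng, alphabet="abc", max_len=5)
        b = random_word(rng, alphabet="abc", max_len=5)
        d = mdld_distance(a, b)
        assert block_script_search(a, b) <= d <= dld_distance(a, b)


def test_lev_dld_exhaustive_against_recursive_oracle():
    strings = [""]
    for length in range(1, 4):
        strings += ["".join(p) for p in itertools.product("abc", repeat=length)]
    for a in strings:
        for b in strings:
            assert lev_distance(a, b) == lev_recursive(a, b)
            assert dld_distance(a, b) == dld_recursive(a, b)


@pytest.mark.skipif(edlib is None, reason="edlib not installed")
def test_lev_against_edlib(rng):
    from tests.conftest import random_word

    for _ in range(300):
        a = random_word(rng, alphabet="abcde", max_len=10)
        b = random_word(rng, alphabet="abcde", max_len=10)
        expected = (
            max(len(a), len(b))
            if not a or not b
            else edlib.align(a, b, task="distance")["editDistance"]
        )
        assert lev_distance(a, b) == expected


# --- similarity ----------------------------------------------------------


@pytest.mark.parametrize(
    "distance,s,t,expected",
    [
        (2, "precede", "preceed", 0.71),
        (1, "amend", "ammend", 0.83),
        (0, "same", "same", 1.00),
    ],
)
def test_normalized_similarity_examples(distance, s, t, expected):
    assert round_half_up(normalized_similarity(distance, s, t)) == expected


def test_similarity_empty_vs_empty_is_one():
    assert normalized_similarity(0, "", "") == 1.0


def test_similarity_clamps_distance():
    assert normalized_similarity(99, "ab", "cd") == 0.0
    assert normalized_similarity(-1, "ab", "cd") == 1.0


def test_round_half_up_ties_go_up():
    assert round_half_up(0.845) == 0.85
    assert round_half_up(0.8443) == 0.84
    assert round_half_up(0.125, 2) == 0.13


def test_namestring_folding_and_length():
    n = NameString.from_text("Similer")
    assert n.folded == "similer"
    assert n.length == 7
    assert NameString.from_text(n.folded).folded == n.folded  # idempotent
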
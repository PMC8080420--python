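"""Seeded generator of labeled typo pairs, plus the bundled reference pairs.

Real name-matching benchmarks pair a clean name with a corrupted variant
(misspellings, keyboard typos, transposed letters, doubled or un-doubled
letters, case slips) and mix in non-matching distractor pairs.  This module
emulates exactly that: :class:`TypoModel` describes an error channel,
:func:`perturb` applies it to one name, and :func:`generate_pairs` builds a
labeled, reproducible dataset from a word list.

Fourteen hand-checked misspelling pairs (``precede/preceed`` …
``really/Realy``) ship as a packaged fixture with their expected similarity
values under each comparator; see :func:`table4_fixture`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .distances import lev_distance, normalized_similarity
from .names import NameString

__all__ = [
    "TypoModel",
    "TypoOp",
    "perturb",
    "generate_pairs",
    "LabeledPair",
    "Table4Row",
    "table4_fixture",
    "builtin_wordlist",
]

#: Operations understood by the typo channel.
TYPO_OPS: tuple[str, ...] = (
    "insert",
    "delete",
    "substitute",
    "transpose_adjacent",
    "double_letter",
    "undouble_letter",
    "case_flip",
)

_DEFAULT_WEIGHTS = {
    "insert": 0.15,
    "delete": 0.15,
    "substitute": 0.25,
    "transpose_adjacent": 0.15,
    "double_letter": 0.15,
    "undouble_letter": 0.05,
    "case_flip": 0.10,
}


@dataclass(frozen=True)
class TypoOp:
    """One applied edit, recorded for provenance."""

    op: str
    position: int
    before: str
    after: str


@dataclass(frozen=True)
class TypoModel:
    """Error channel: which typo operations occur, how often, over what alphabet.

    ``n_edits`` is either a fixed count or an inclusive ``(low, high)`` range
    sampled uniformly per pair.  The default of one to two edits per corrupted
    name mirrors the density of errors in hand-curated misspelling lists.
    """

    op_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    n_edits: "int | tuple[int, int]" = (1, 2)
    alphabet: str = "abcdefghijklmnopqrstuvwxyz"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.op_weights) - set(TYPO_OPS)
        if unknown:
            raise ValueError(f"unknown typo operations: {sorted(unknown)}")
        total = sum(self.op_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"op_weights sum to {total}, expected 1")
        lo, hi = self._edit_range()
        if lo < 0 or hi < lo:
            raise ValueError(f"bad n_edits {self.n_edits!r}")

    def _edit_range(self) -> tuple[int, int]:
        if isinstance(self.n_edits, int):
            return self.n_edits, self.n_edits
        lo, hi = self.n_edits
        return int(lo), int(hi)

    def sample_n_edits(self, rng: random.Random) -> int:
        lo, hi = self._edit_range()
        return rng.randint(lo, hi)

    def rng(self) -> random.Random:
        return random.Random(self.seed)


def _apply_op(
    word: str, op: str, rng: random.Random, alphabet: str
) -> "tuple[str, TypoOp] | None":
    """Apply one operation; return None when it cannot apply to this word."""
    n = len(word)
    if op == "insert":
        pos = rng.randrange(n + 1)
        ch = rng.choice(alphabet)
        return word[:pos] + ch + word[pos:], TypoOp(op, pos, "", ch)
    if op == "delete":
        if n <= 1:
            return None
        pos = rng.randrange(n)
        return word[:pos] + word[pos + 1 :], TypoOp(op, pos, word[pos], "")
    if op == "substitute":
        pos = rng.randrange(n)
        choices = [c for c in alphabet if c != word[pos]]
        if not choices:
            return None
        ch = rng.choice(choices)
        return word[:pos] + ch + word[pos + 1 :], TypoOp(op, pos, word[pos], ch)
    if op == "transpose_adjacent":
        positions = [i for i in range(n - 1) if word[i] != word[i + 1]]
        if not positions:
            return None
        pos = rng.choice(positions)
        swapped = word[:pos] + word[pos + 1] + word[pos] + word[pos + 2 :]
        return swapped, TypoOp(op, pos, word[pos : pos + 2], swapped[pos : pos + 2])
    if op == "double_letter":
        pos = rng.randrange(n)
        return (
            word[:pos] + word[pos] + word[pos:],
            TypoOp(op, pos, word[pos], word[pos] * 2),
        )
    if op == "undouble_letter":
        positions = [i for i in range(n - 1) if word[i] == word[i + 1]]
        if not positions or n <= 1:
            return None
        pos = rng.choice(positions)
        return word[:pos] + word[pos + 1 :], TypoOp(op, pos, word[pos] * 2, word[pos])
    if op == "case_flip":
        positions = [
            i for i, c in enumerate(word) if c.swapcase() != c
        ]
        if not positions:
            return None
        pos = rng.choice(positions)
        ch = word[pos].swapcase()
        return word[:pos] + ch + word[pos + 1 :], TypoOp(op, pos, word[pos], ch)
    raise ValueError(f"unknown operation {op!r}")


def perturb(
    name: "str | NameString",
    model: TypoModel,
    rng: random.Random | None = None,
    return_script: bool = False,
):
    """Corrupt ``name`` with ``model.n_edits`` sampled typo operations.

    Operations that cannot apply (deleting from a single-letter name,
    un-doubling a word with no doubled letter, case-flipping a caseless
    script) are resampled.  The result is never empty.  With
    ``return_script=True`` the list of applied :class:`TypoOp` is returned
    alongside the corrupted string.
    """
    word = name.original if isinstance(name, NameString) else name
    if not word:
        raise ValueError("cannot perturb an empty name")
    rng = rng if rng is not None else model.rng()
    ops = list(model.op_weights)
    weights = [model.op_weights[o] for o in ops]
    script: list[TypoOp] = []
    for _ in range(model.sample_n_edits(rng)):
        for _attempt in range(100):
            op = rng.choices(ops, weights=weights, k=1)[0]
            applied = _apply_op(word, op, rng, model.alphabet)
            if applied is not None:
                word, record = applied
                script.append(record)
                break
        else:  # pragma: no cover - requires a degenerate model
            raise RuntimeError("no typo operation applicable to this name")
    return (word, script) if return_script else word


@dataclass(frozen=True)
class LabeledPair:
    source: str
    target: str
    label: bool
    script: tuple[TypoOp, ...] = ()


def generate_pairs(
    names: Sequence["str | NameString"],
    model: TypoModel,
    n_match: int,
    n_nonmatch: int,
    max_nonmatch_similarity: float = 0.9,
) -> list[LabeledPair]:
    """Build a labeled dataset of match and non-match name pairs.

    Match pairs are ``(name, perturb(name))`` labeled true; non-match pairs
    are two distinct sampled names labeled false, rejecting candidates whose
    normalized Levenshtein similarity exceeds ``max_nonmatch_similarity`` so
    the negative labels stay meaningful.  Deterministic under
    ``model.seed``; no pair is emitted twice.
    """
    words = [n.original if isinstance(n, NameString) else n for n in names]
    words = [w for w in words if w]
    if n_match < 0 or n_nonmatch < 0:
        raise ValueError("pair counts must be >= 0")
    if n_nonmatch > 0 and len(set(words)) < 2:
        raise ValueError("need at least 2 distinct names for non-match pairs")
    rng = model.rng()
    out: list[LabeledPair] = []
    seen: set[tuple[str, str, bool]] = set()

    attempts = 0
    while sum(1 for p in out if p.label) < n_match:
        attempts += 1
        if attempts > 1000 * max(n_match, 1):
            raise RuntimeError("could not generate enough distinct match pairs")
        src = rng.choice(words)
        tgt, script = perturb(src, model, rng, return_script=True)
        key = (src, tgt, True)
        if key in seen:
            continue
        seen.add(key)
        out.append(LabeledPair(src, tgt, True, tuple(script)))

    attempts = 0
    while sum(1 for p in out if not p.label) < n_nonmatch:
        attempts += 1
        if attempts > 1000 * max(n_nonmatch, 1):
            raise RuntimeError("could not generate enough distinct non-match pairs")
        src, tgt = rng.sample(words, 2)
        if src == tgt:
            continue
        sim = normalized_similarity(lev_distance(src, tgt), src, tgt)
        if sim > max_nonmatch_similarity:
            continue
        key = (src, tgt, False)
        if key in seen:
            continue
        seen.add(key)
        out.append(LabeledPair(src, tgt, False))
    return out


@dataclass(frozen=True)
class Table4Row:
    """One bundled reference pair with its expected printed similarities."""

    no: int
    source: str
    target: str
    sim_dld: float
    sim_ld: float
    sim_ndist: float
    sim_soft_half: float      # scale (0,1,0,0.5,0.5,1,1,1,1); not regression-grade
    sim_soft_applied: float   # scale (0,1,0,0.2,0.2,1,1,0.5,0.5)
    anomalous: bool           # row 8: printed values conflict with case folding


def _read_data_text(filename: str) -> str:
    return (
        resources.files("softbidist").joinpath("data", filename).read_text("utf-8")
    )


def table4_fixture() -> list[Table4Row]:
    """The 14 bundled misspelling pairs, all true matches.

    Row 8 (``dilemma/Dilemma``) is flagged anomalous: its printed values are
    incompatible with case-insensitive comparison and it is excluded from
    regression checks.
    """
    rows: list[Table4Row] = []
    lines = _read_data_text("table4.tsv").strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        rows.append(
            Table4Row(
                no=int(rec["no"]),
                source=rec["source"],
                target=rec["target"],
                sim_dld=float(rec["sim_dld"]),
                sim_ld=float(rec["sim_ld"]),
                sim_ndist=float(rec["sim_ndist"]),
                sim_soft_half=float(rec["sim_soft_half"]),
                sim_soft_applied=float(rec["sim_soft_applied"]),
                anomalous=rec["anomalous"] == "1",
            )
        )
    return rows


def builtin_wordlist(language: str = "en") -> list[str]:
    """A small bundled word list (``en``, ``ar`` or ``pt``) for the generator.

    The lists are synthetic, authored for this package; they emulate the
    character inventory of English, Arabic and Portuguese name data.
    """
    filename = {"en": "names_en.txt", "ar": "names_ar.txt", "pt": "names_pt.txt"}
    if language not in filename:
        raise KeyError(f"no bundled word list for {language!r}; use en, ar or pt")
    lines = _read_data_text(filename[language]).splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
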
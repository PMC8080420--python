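"""Weight scales for the soft bigram distance, with named presets.

A :class:`WeightScale` is the 9-tuple ``(wt1..wt9)`` parameterizing the soft
bigram comparison: ``wt1..wt7`` price the seven substitution cases of a pair
of aligned bigrams and ``wt8``/``wt9`` price the two discounted
insertion/deletion cases.  Specific tuples make the soft distance collapse
onto a classical comparator:

* ``LD-equiv`` — behaves exactly like Levenshtein distance;
* ``DLD-equiv`` — behaves like Damerau–Levenshtein on typical typo pairs
  (the emulation is close but not exact; see the methods note);
* ``BIDIST-equiv`` — exactly the bigram n-gram distance (n = 2).

``applied`` is the configuration this package treats as the default
production scale: substitutions that share a bigram context cost 0.2,
cross-equal (transposed) bigrams cost 0, and context-compatible indels are
discounted to 0.5.  ``applied-indel1`` is the same scale with undiscounted
indels.  ``minimum``, ``average``, ``maximum-89``, ``average-89`` and
``rand-5`` … ``rand-15`` are the remaining explored configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = ["WeightScale", "PRESETS", "preset", "parse_weights"]

_FIELDS = ("wt1", "wt2", "wt3", "wt4", "wt5", "wt6", "wt7", "wt8", "wt9")


@dataclass(frozen=True)
class WeightScale:
    """The nine comparison weights; each must lie in [0, 1]."""

    wt1: float
    wt2: float
    wt3: float
    wt4: float
    wt5: float
    wt6: float
    wt7: float
    wt8: float
    wt9: float
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for f in _FIELDS:
            v = getattr(self, f)
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(
                    f"{f}={v!r} out of range: weights must lie in [0, 1]"
                )

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in _FIELDS)

    def replace(self, **kwargs: float) -> "WeightScale":
        values = {f: getattr(self, f) for f in _FIELDS}
        values.update(kwargs)
        return WeightScale(**values, name=None)

    def to_json(self) -> str:
        return json.dumps({f: getattr(self, f) for f in _FIELDS})

    @classmethod
    def from_json(cls, text: str) -> "WeightScale":
        obj = json.loads(text)
        missing = [f for f in _FIELDS if f not in obj]
        if missing:
            raise ValueError(f"weight JSON missing keys: {', '.join(missing)}")
        return cls(**{f: float(obj[f]) for f in _FIELDS})

    @classmethod
    def from_sequence(
        cls, values: "list[float] | tuple[float, ...]", name: str | None = None
    ) -> "WeightScale":
        if len(values) != 9:
            raise ValueError(f"expected 9 weights, got {len(values)}")
        return cls(*[float(v) for v in values], name=name)

    def __iter__(self):
        return iter(self.as_tuple())


def _mk(name: str, *values: float) -> WeightScale:
    return WeightScale.from_sequence(list(values), name=name)


#: Named weight configurations.  The three ``*-equiv`` scales emulate the
#: classical comparators; the rest are the explored alternatives, with
#: ``applied`` the recommended default.
PRESETS: dict[str, WeightScale] = {
    "LD-equiv": _mk("LD-equiv", 0, 1, 1, 0, 1, 1, 1, 1, 1),
    "DLD-equiv": _mk("DLD-equiv", 0, 1, 0, 0, 1, 1, 1, 1, 1),
    "BIDIST-equiv": _mk("BIDIST-equiv", 0, 1, 1, 0.5, 0.5, 1, 1, 1, 1),
    "minimum": _mk("minimum", 0, 1, 0, 0, 0.5, 1, 1, 1, 1),
    "average": _mk("average", 0, 1, 0.7, 0.2, 0.8, 1, 1, 1, 1),
    "maximum-89": _mk("maximum-89", 0, 1, 0, 0, 0.5, 1, 1, 0.5, 0.5),
    "average-89": _mk("average-89", 0, 1, 0.7, 0.2, 0.8, 1, 1, 0.5, 0.5),
    "rand-5": _mk("rand-5", 0, 1, 1, 0, 0.5, 1, 1, 1, 1),
    "rand-6": _mk("rand-6", 0, 1, 0, 0, 0.5, 1, 1, 1, 1),
    "rand-7": _mk("rand-7", 0, 1, 0, 0.2, 0.2, 1, 1, 1, 1),
    "rand-8": _mk("rand-8", 0, 1, 0, 0.1, 0.1, 1, 1, 1, 1),
    "rand-9": _mk("rand-9", 0, 1, 0, 0, 0.2, 1, 1, 1, 1),
    "rand-10": _mk("rand-10", 0, 1, 1, 0, 0.5, 1, 1, 0.5, 0.5),
    "rand-11": _mk("rand-11", 0, 1, 0.5, 0, 0.5, 1, 1, 0.5, 0.5),
    "rand-12": _mk("rand-12", 0, 1, 0, 0.1, 0.1, 1, 1, 0.5, 0.5),
    "rand-13": _mk("rand-13", 0, 1, 0.5, 0, 0.1, 1, 1, 0.5, 0.5),
    "rand-14": _mk("rand-14", 0, 1, 0, 0, 0.2, 1, 1, 0.5, 0.5),
    "rand-15": _mk("rand-15", 0, 1, 0, 0, 0.1, 1, 1, 0.5, 0.5),
    "applied": _mk("applied", 0, 1, 0, 0.2, 0.2, 1, 1, 0.5, 0.5),
    "applied-indel1": _mk("applied-indel1", 0, 1, 0, 0.2, 0.2, 1, 1, 1, 1),
}


def preset(name: str) -> WeightScale:
    """Look up a named weight scale.

    Raises ``KeyError`` listing the valid names when ``name`` is unknown.
    """
    try:
        return PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; valid presets: {valid}") from None


def parse_weights(text: str) -> WeightScale:
    """Parse a weight specification from user input.

    Accepts ``preset:NAME``, a bare preset name, a comma-separated 9-tuple
    such as ``0,1,0,0.2,0.2,1,1,0.5,0.5``, or a JSON object with keys
    ``wt1`` … ``wt9``.
    """
    text = text.strip()
    if text.startswith("preset:"):
        return preset(text[len("preset:") :])
    if text.startswith("{"):
        return WeightScale.from_json(text)
    if text in PRESETS:
        return PRESETS[text]
    parts = [p for p in text.split(",") if p.strip() != ""]
    if len(parts) == 9:
        try:
            return WeightScale.from_sequence([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"bad weight tuple {text!r}: {exc}") from exc
    raise ValueError(
        f"cannot interpret weights {text!r}: use preset:NAME, a 9-tuple, or JSON"
    )
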
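"""Name strings and the text normalization applied before any comparison.

Every distance in this package operates on a *folded* form of the input:
Unicode NFC normalization followed by full case folding.  NFC makes visually
identical sequences (precomposed vs. combining accents, common in Arabic and
Portuguese name lists) compare equal; case folding makes matching
case-insensitive, which is the convention for person/taxon name linkage.
Lengths are counted in code points; no grapheme clustering is attempted.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field


def fold_text(text: str) -> str:
    """NFC-normalize and case-fold ``text``.  Idempotent."""
    return unicodedata.normalize("NFC", text).casefold()


@dataclass(frozen=True)
class NameString:
    """A name plus the folded form used for all comparisons.

    Attributes
    ----------
    original:
        The text as supplied by the caller (preserved for reports).
    folded:
        ``fold_text(original)``; the sequence actually compared.
    """

    original: str
    folded: str = field(default="")

    def __post_init__(self) -> None:
        if not self.folded:
            object.__setattr__(self, "folded", fold_text(self.original))

    @classmethod
    def from_text(cls, text: str) -> "NameString":
        return cls(original=text)

    @property
    def length(self) -> int:
        """Number of code points in the folded form."""
        return len(self.folded)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.original


def as_folded(name: "str | NameString") -> str:
    """Accept either a plain string or a :class:`NameString`; return folded text."""
    if isinstance(name, NameString):
        return name.folded
    return fold_text(name)
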
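"""Edit distance and the normalized string / phonetic similarity scores.

Both similarity scores are built on plain Levenshtein distance (unit-cost
insertions, deletions, substitutions; no transposition operation — an
adjacent swap costs 2) and normalized into [0, 1] as

    sim(w1, w2) = 1 - ED(w1, w2) / max(|w1|, |w2|)

which is 1 exactly on identical inputs and 0 when the strings share nothing.
``phonetic_sim`` applies the same formula at the phoneme-symbol level: both
words are encoded with the Brazilian-Portuguese rule table and the symbol
sequences are compared, so homophonous spellings ("cassa"/"caça") score 1.0.

The distance computation is delegated to edlib; phoneme symbols (some of
which are digraphs like "SH") are mapped onto a private single-character
alphabet first so that each symbol counts as one editable unit.
"""

from __future__ import annotations

from typing import Sequence

import edlib

from .phonetics import PhoneticEncoder, default_encoder, normalize_word

__all__ = ["edit_distance", "string_sim", "phonetic_sim", "UndefinedSimilarityError"]


class UndefinedSimilarityError(ValueError):
    """Similarity of two empty objects is undefined."""


def edit_distance(w1: str, w2: str) -> int:
    """Levenshtein distance between two words (unit costs, no transposition)."""
    if w1 == w2:
        return 0
    if not w1 or not w2:
        return max(len(w1), len(w2))
    return edlib.align(w1, w2, task="distance")["editDistance"]


def string_sim(w1: str, w2: str) -> float:
    """Normalized string similarity ``1 - ED/max(len)`` in [0, 1].

    Raises
    ------
    UndefinedSimilarityError
        If both words are empty.
    """
    longest = max(len(w1), len(w2))
    if longest == 0:
        raise UndefinedSimilarityError("similarity of two empty strings")
    return 1.0 - edit_distance(w1, w2) / longest


# Phoneme symbols are remapped to single characters per encoder instance so
# edlib sees one editable unit per symbol.
_symbol_charmaps: dict[int, dict[str, str]] = {}


def _to_chars(symbols: Sequence[str], charmap: dict[str, str]) -> str:
    out = []
    for s in symbols:
        if s not in charmap:
            charmap[s] = chr(0xE000 + len(charmap))  # private use area
        out.append(charmap[s])
    return "".join(out)


def symbol_edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Levenshtein distance between two phoneme-symbol sequences."""
    if tuple(a) == tuple(b):
        return 0
    if not a or not b:
        return max(len(a), len(b))
    charmap = _symbol_charmaps.setdefault(0, {})
    return edlib.align(_to_chars(a, charmap), _to_chars(b, charmap), task="distance")[
        "editDistance"
    ]


def phonetic_sim(
    w1: str,
    w2: str,
    *,
    encoder: PhoneticEncoder | None = None,
    pre_normalized: bool = True,
) -> float:
    """Phoneme-level similarity of two words, in [0, 1].

    Words are expected already normalized (``normalize_word``); pass
    ``pre_normalized=False`` to normalize here.

    Raises
    ------
    UndefinedSimilarityError
        If either word encodes to an empty phoneme sequence.
    """
    enc = encoder or default_encoder()
    if not pre_normalized:
        w1, w2 = normalize_word(w1), normalize_word(w2)
    a = enc.encode(w1).symbols
    b = enc.encode(w2).symbols
    if not a or not b:
        raise UndefinedSimilarityError(
            f"word encodes to an empty phoneme sequence: {w1 if not a else w2!r}"
        )
    return 1.0 - symbol_edit_distance(a, b) / max(len(a), len(b))
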
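"""Grapheme-to-phoneme encoding for Brazilian Portuguese.

Misspellings in Portuguese clinical text are often *phonetic*: the writer
substitutes a spelling that sounds the same (``ss``/``ç``, intervocalic
``s``/``z``, ``qu``/``k``, a silent ``h``).  Collapsing homophonous spellings
onto a shared canonical phoneme sequence lets a matcher score such variants
as identical even when their edit distance is large.

The encoder is rule-based and deterministic: an ordered table of rewrite
rules (pattern, optional left/right letter context, emitted symbols) is
scanned left to right over the normalized word; the first applicable rule
wins and consumes its pattern.  The default table ships as a JSON resource
(``data/phonetic_rules_pt.json``) and can be replaced by the caller; it is
an explicit, versioned approximation of Brazilian Portuguese orthography,
not a full IPA transcription — stress and vowel quality are out of scope.

Consonantal phonemes double as a cheap blocking key: two words that share at
least a few consonant sounds in order are plausible spelling variants of one
another, whatever their vowels do.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DegenerateTokenError",
    "PhonemeSequence",
    "PhoneticEncoder",
    "normalize_word",
    "encode",
    "consonantal_phonemes",
    "matching_consonant_count",
    "default_encoder",
]

_ASCII_LOWER = frozenset("abcdefghijklmnopqrstuvwxyz")
_VOWEL_LETTERS = frozenset("aeiou")
_CEDILLA = "̧"  # combining cedilla, produced by NFD("ç")


class DegenerateTokenError(ValueError):
    """Raised when a token contains no usable Portuguese letters."""


def normalize_word(word: str) -> str:
    """Lowercase, strip accents (keeping ``ç``) and drop non-letters.

    ``ç`` survives normalization because it carries phonemic information the
    rule table needs (``ç`` → S); every other diacritic is stripped, since
    misspellings routinely omit them.

    Raises
    ------
    DegenerateTokenError
        If nothing remains after removing non-letters.
    """
    out: list[str] = []
    for ch in unicodedata.normalize("NFD", word.lower()):
        if ch == _CEDILLA and out and out[-1] == "c":
            out[-1] = "ç"
        elif unicodedata.combining(ch):
            continue
        elif ch in _ASCII_LOWER or ch == "ç":
            out.append(ch)
    if not out:
        raise DegenerateTokenError(f"no Portuguese letters in {word!r}")
    return "".join(out)


@dataclass(frozen=True)
class PhonemeSequence:
    """Ordered phoneme symbols for a word, with a per-symbol consonant flag."""

    symbols: tuple[str, ...]
    consonantal_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.consonantal_mask):
            raise ValueError("symbols and consonantal_mask lengths differ")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    @property
    def consonantal(self) -> tuple[str, ...]:
        """The consonantal subsequence, in order."""
        return tuple(
            s for s, c in zip(self.symbols, self.consonantal_mask) if c
        )

    def __str__(self) -> str:  # e.g. "F L U O K S E T I N A"
        return " ".join(self.symbols)


@dataclass(frozen=True)
class _Rule:
    pattern: str
    emit: tuple[str, ...]
    prev: frozenset[str] | None  # classes/letters; None = unconstrained
    next: frozenset[str] | None


def _parse_context(spec: str | None) -> frozenset[str] | None:
    return None if spec is None else frozenset(spec.split("|"))


def _context_matches(allowed: frozenset[str] | None, letter: str | None) -> bool:
    # letter is None at a word boundary
    if allowed is None:
        return True
    if letter is None:
        return "start" in allowed or "end" in allowed
    if letter in allowed:
        return True
    if letter in _VOWEL_LETTERS:
        return "vowel" in allowed
    return "consonant" in allowed


class PhoneticEncoder:
    """Deterministic rule-table encoder; stateless after construction.

    Parameters
    ----------
    rules_path : str or Path, optional
        JSON rule table to load instead of the packaged Brazilian-Portuguese
        default.  The format is documented in the default resource file.
    """

    def __init__(self, rules_path: str | Path | None = None):
        if rules_path is None:
            raw = (
                resources.files("farmatch.data")
                .joinpath("phonetic_rules_pt.json")
                .read_text(encoding="utf-8")
            )
            table = json.loads(raw)
        else:
            table = json.loads(Path(rules_path).read_text(encoding="utf-8"))
        self.version = table.get("version")
        self.vowel_symbols = frozenset(table["vowel_symbols"])
        self._rules = tuple(
            _Rule(
                pattern=r["pattern"],
                emit=tuple(r["emit"]),
                prev=_parse_context(r.get("prev")),
                next=_parse_context(r.get("next")),
            )
            for r in table["rules"]
        )
        self.alphabet = frozenset(
            s for r in self._rules for s in r.emit
        )
        self._cached_encode = lru_cache(maxsize=65536)(self._encode_uncached)

    # -- public API ---------------------------------------------------------

    def encode(self, word: str) -> PhonemeSequence:
        """Encode an already-normalized word into its phoneme sequence."""
        return self._cached_encode(word)

    def consonantal_phonemes(self, word: str) -> tuple[str, ...]:
        """Ordered consonantal phoneme symbols of a normalized word."""
        return self.encode(word).consonantal

    def matching_consonant_count(
        self, w1: str, w2: str, *, ordered: bool = True
    ) -> int:
        """Number of shared consonantal phonemes between two words.

        With ``ordered=True`` (default) this is the length of the longest
        common *subsequence* of the two consonant lists, so anagrams do not
        inflate the count; ``ordered=False`` falls back to multiset
        intersection size.
        """
        a, b = self.consonantal_phonemes(w1), self.consonantal_phonemes(w2)
        if not ordered:
            from collections import Counter

            common = Counter(a) & Counter(b)
            return sum(common.values())
        return _lcs_length(a, b)

    # -- internals ----------------------------------------------------------

    def _encode_uncached(self, word: str) -> PhonemeSequence:
        symbols: list[str] = []
        i, n = 0, len(word)
        while i < n:
            for rule in self._rules:
                j = i + len(rule.pattern)
                if word[i:j] != rule.pattern:
                    continue
                prev = word[i - 1] if i > 0 else None
                nxt = word[j] if j < n else None
                if _context_matches(rule.prev, prev) and _context_matches(
                    rule.next, nxt
                ):
                    symbols.extend(rule.emit)
                    # collapse doubled letters: 'tt', 'll', 'sss', ...
                    if len(set(rule.pattern)) == 1:
                        while j < n and word[j] == rule.pattern[-1]:
                            j += 1
                    i = j
                    break
            else:  # no rule matched — skip the unknown character
                i += 1
        # degemination: adjacent identical symbols merge, so doubled vowels
        # (also across a silent h) sound once, like doubled consonants
        collapsed = [s for k, s in enumerate(symbols) if k == 0 or s != symbols[k - 1]]
        mask = tuple(s not in self.vowel_symbols for s in collapsed)
        return PhonemeSequence(tuple(collapsed), mask)


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


_DEFAULT: PhoneticEncoder | None = None


def default_encoder() -> PhoneticEncoder:
    """The packaged Brazilian-Portuguese encoder (singleton)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = PhoneticEncoder()
    return _DEFAULT


def encode(word: str) -> PhonemeSequence:
    """Encode a normalized word with the default rule table."""
    return default_encoder().encode(word)


def consonantal_phonemes(word: str) -> tuple[str, ...]:
    """Consonantal phonemes of a normalized word (default rule table)."""
    return default_encoder().consonantal_phonemes(word)


def matching_consonant_count(w1: str, w2: str, *, ordered: bool = True) -> int:
    """Shared consonantal phonemes of two normalized words (default table)."""
    return default_encoder().matching_consonant_count(w1, w2, ordered=ordered)
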
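"""Trie-indexed approximate dictionary lookup bounded by edit distance.

Annotating a large corpus against a variant dictionary cannot afford a
linear edit-distance scan per token.  Indexing the dictionary in a prefix
tree lets one Levenshtein dynamic-programming row be propagated down each
trie edge, sharing work across every entry with a common prefix and pruning
a whole subtree as soon as the row minimum exceeds the distance bound.  With
the small bounds that matter here (ED <= 1 in routine use) a lookup touches
a tiny fraction of the tree.

Cost grows steeply with the bound — beyond ED 2 the pruning loses most of
its bite — so lookups above that log a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

__all__ = ["FuzzyIndex", "FuzzyMatch", "build_index", "fuzzy_lookup"]

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1
MAX_SUPPORTED_ED = 3


@dataclass(frozen=True)
class FuzzyMatch:
    """A dictionary entry within the requested distance of a query."""

    entry: str
    canonical: str
    distance: int


class _Node:
    __slots__ = ("children", "entry")

    def __init__(self) -> None:
        self.children: dict[str, _Node] = {}
        self.entry: str | None = None  # terminal: the stored word


class FuzzyIndex:
    """Prefix-tree index over a variant dictionary (word -> canonical)."""

    def __init__(self, dictionary: Mapping[str, str] | None = None):
        self._root = _Node()
        self._payload: dict[str, str] = {}
        if dictionary:
            for word, canonical in dictionary.items():
                self.add(word, canonical)

    def add(self, word: str, canonical: str) -> None:
        if word in self._payload:
            if self._payload[word] != canonical:
                raise ValueError(
                    f"conflicting canonicals for {word!r}: "
                    f"{self._payload[word]!r} vs {canonical!r}"
                )
            return
        node = self._root
        for ch in word:
            node = node.children.setdefault(ch, _Node())
        node.entry = word
        self._payload[word] = canonical

    def __len__(self) -> int:
        return len(self._payload)

    def __contains__(self, word: str) -> bool:
        return word in self._payload

    def entries(self) -> Iterator[tuple[str, str]]:
        """All (word, canonical) pairs, in insertion order."""
        return iter(self._payload.items())

    def lookup(self, query: str, max_ed: int = 1) -> list[FuzzyMatch]:
        """All dictionary entries within ``max_ed`` edits of ``query``.

        Results carry their true edit distance and are sorted by
        (distance, entry).  ``max_ed`` must lie in [0, 3]; values above 1
        log a performance warning.
        """
        if not 0 <= max_ed <= MAX_SUPPORTED_ED:
            raise ValueError(f"max_ed must be in [0, {MAX_SUPPORTED_ED}]")
        if max_ed > 1:
            logger.warning(
                "fuzzy lookup with max_ed=%d: cost grows steeply beyond 1", max_ed
            )
        if max_ed == 0:  # degenerates to exact hash lookup
            canonical = self._payload.get(query)
            return (
                [FuzzyMatch(query, canonical, 0)] if canonical is not None else []
            )
        matches: list[FuzzyMatch] = []
        first_row = list(range(len(query) + 1))
        self._walk(self._root, query, first_row, max_ed, matches)
        matches.sort(key=lambda m: (m.distance, m.entry))
        return matches

    def _walk(
        self,
        node: _Node,
        query: str,
        row: list[int],
        max_ed: int,
        out: list[FuzzyMatch],
    ) -> None:
        if node.entry is not None and row[-1] <= max_ed:
            out.append(FuzzyMatch(node.entry, self._payload[node.entry], row[-1]))
        for ch, child in node.children.items():
            new_row = [row[0] + 1]
            for j in range(1, len(query) + 1):
                cost = 0 if query[j - 1] == ch else 1
                new_row.append(
                    min(new_row[j - 1] + 1, row[j] + 1, row[j - 1] + cost)
                )
            if min(new_row) <= max_ed:  # otherwise the whole subtree is out
                self._walk(child, query, new_row, max_ed, out)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {"format_version": _FORMAT_VERSION, "entries": self._payload}
        Path(path).write_text(
            json.dumps(payload, ensure_ascii=False, indent=0) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "FuzzyIndex":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        version = payload.get("format_version")
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported index format version: {version!r}")
        return cls(payload["entries"])


def build_index(dictionary: Mapping[str, str]) -> FuzzyIndex:
    """Build a fuzzy index from a (word -> canonical drug) mapping."""
    return FuzzyIndex(dictionary)


def fuzzy_lookup(index: FuzzyIndex, query: str, max_ed: int = 1) -> list[FuzzyMatch]:
    """Bounded-edit-distance lookup; see :meth:`FuzzyIndex.lookup`."""
    return index.lookup(query, max_ed)
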
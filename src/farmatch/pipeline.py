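"""End-to-end annotation: lexicon I/O, tokenization, fuzzy drug tagging.

Documents are plain UTF-8 text; tokens are maximal runs of letters
(accented letters and ``ç`` included), everything else is a separator.
Each sufficiently long token is normalized and looked up in a fuzzy index
built over the canonical lexicon plus the variant dictionary; the closest
entry within the edit-distance bound yields an annotation with 0-based
half-open character offsets.

Mention-level evaluation follows the usual information-extraction
convention: a prediction counts as a true positive only when document,
span and canonical drug all agree with a gold mention exactly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .phonetics import DegenerateTokenError, normalize_word
from .trie import FuzzyIndex, build_index
from .tuning import ConfusionCounts, VariantDictionary, f1 as _f1, precision, recall

__all__ = [
    "Annotation",
    "Document",
    "DrugLexicon",
    "tokenize",
    "annotate",
    "evaluate_annotations",
    "read_documents_jsonl",
    "write_documents_jsonl",
    "read_annotations_jsonl",
    "write_annotations_jsonl",
]

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)

#: Tokens shorter than this are never matched (too ambiguous at small ED).
MIN_TOKEN_LEN = 4


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str


@dataclass(frozen=True)
class Annotation:
    """A matched drug mention; offsets are 0-based half-open."""

    doc_id: str
    start: int
    end: int
    surface: str
    canonical: str
    variant: str | None = None  # dictionary entry the token matched
    distance: int | None = None  # edit distance token -> variant

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad span [{self.start}, {self.end})")

    def span_key(self) -> tuple[str, int, int, str]:
        return (self.doc_id, self.start, self.end, self.canonical)


@dataclass(frozen=True)
class DrugLexicon:
    """Unique normalized canonical drug names."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate names in lexicon")
        if any(not n for n in self.names):
            raise ValueError("empty name in lexicon")

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in set(self.names)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "DrugLexicon":
        seen: dict[str, None] = {}
        for raw in names:
            raw = raw.strip()
            if not raw:
                continue
            seen.setdefault(normalize_word(raw), None)
        return cls(tuple(seen))

    @classmethod
    def from_file(cls, path: str | Path) -> "DrugLexicon":
        return cls.from_names(
            Path(path).read_text(encoding="utf-8").splitlines()
        )


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Letter-run tokens with 0-based half-open offsets."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def annotate(
    docs: Sequence[Document],
    lexicon: DrugLexicon,
    variants: VariantDictionary | None = None,
    max_ed: int = 1,
    *,
    min_token_len: int = MIN_TOKEN_LEN,
    index: FuzzyIndex | None = None,
) -> list[Annotation]:
    """Tag drug mentions in documents via fuzzy dictionary lookup.

    The index covers the canonical lexicon plus the variant dictionary; a
    token matching several entries keeps the minimum-distance match, ties
    broken lexicographically by canonical name (and logged — disambiguation
    proper is out of scope).
    """
    if index is None:
        entries = {name: name for name in lexicon}
        if variants is not None:
            for variant, canonical in variants.as_lookup().items():
                entries[variant] = canonical
        index = build_index(entries)
    out: list[Annotation] = []
    n_tokens = n_ties = 0
    for doc in docs:
        for surface, start, end in tokenize(doc.text):
            n_tokens += 1
            if len(surface) < min_token_len:
                continue
            try:
                query = normalize_word(surface)
            except DegenerateTokenError:
                continue
            matches = index.lookup(query, max_ed)
            if not matches:
                continue
            best_d = matches[0].distance
            tied = sorted(
                (m for m in matches if m.distance == best_d),
                key=lambda m: m.canonical,
            )
            if len({m.canonical for m in tied}) > 1:
                n_ties += 1
                logger.info(
                    "tie at %s[%d:%d] %r: %s",
                    doc.doc_id, start, end, surface,
                    sorted({m.canonical for m in tied}),
                )
            chosen = tied[0]
            out.append(
                Annotation(
                    doc_id=doc.doc_id,
                    start=start,
                    end=end,
                    surface=surface,
                    canonical=chosen.canonical,
                    variant=chosen.entry,
                    distance=chosen.distance,
                )
            )
    logger.info(
        "annotated %d documents: %d tokens, %d matches, %d ties",
        len(docs), n_tokens, len(out), n_ties,
    )
    return out


def evaluate_annotations(
    pred: Sequence[Annotation], gold: Sequence[Annotation]
) -> tuple[float, float, float]:
    """Mention-level (precision, recall, F1) against gold annotations.

    A prediction is a true positive iff (doc_id, start, end, canonical)
    matches a gold mention exactly.  When a side is empty the affected
    metrics are reported as 0.0 rather than undefined.
    """
    spans: dict[tuple[str, int, int], str] = {}
    for a in pred:
        key = (a.doc_id, a.start, a.end)
        if key in spans:
            raise ValueError(f"duplicate prediction for span {key}")
        spans[key] = a.canonical
    gold_keys = {g.span_key() for g in gold}
    tp = sum(1 for a in pred if a.span_key() in gold_keys)
    c = ConfusionCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)
    p = precision(c) if c.tp + c.fp > 0 else 0.0
    r = recall(c) if c.tp + c.fn > 0 else 0.0
    score = _f1(p, r) if p + r > 0 else 0.0
    return p, r, score


# -- JSONL I/O -------------------------------------------------------------


def write_documents_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps(asdict(d), ensure_ascii=False) + "\n")


def read_documents_jsonl(path: str | Path) -> list[Document]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                out.append(Document(doc_id=rec["doc_id"], text=rec["text"]))
    return out


def write_annotations_jsonl(
    annotations: Iterable[Annotation], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write(json.dumps(asdict(a), ensure_ascii=False) + "\n")


def read_annotations_jsonl(path: str | Path) -> list[Annotation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                out.append(Annotation(**rec))
    return out
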
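"""Seeded generation of synthetic misspelt drug-name variants and decoys.

Clinical free text cannot be redistributed, so tuning and annotation are
exercised against a generator that emulates the error processes the matcher
targets:

* **typo variants** — random single-character insertions, deletions,
  substitutions and adjacent swaps within a declared edit budget (a swap
  consumes two units of the budget, so plain Levenshtein distance never
  exceeds the declared ``n_edits``);
* **phonetic variants** — homophone-class respellings (``ss``/``ç``,
  intervocalic ``s``/``z``, ``ch``/``x`` in fricative contexts, ``qu``/``k``,
  silent-``h`` insertion or removal) that leave the phoneme encoding exactly
  unchanged, plus near-homophone vowel swaps (``e``/``i``, ``o``/``u``)
  flagged separately because they alter the encoding slightly;
* **concatenation variants** — the drug name glued to a following short word
  ("fluoxetinapara"), a frequent artefact of missing whitespace;
* **decoys** — negatives drawn from a packaged list of common Portuguese
  clinical-note words, drug names outside the benchmark's own list, and
  morphological derivatives of the drug itself ("insulinizar"-style), which
  make deliberately hard negatives.

Everything is deterministic under a seed.  Default mixture: 50% typo,
30% phonetic, 20% concatenation positives.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .candidates import CandidatePair, make_pair
from .phonetics import PhoneticEncoder, default_encoder, normalize_word
from .pipeline import Annotation, Document

__all__ = [
    "SimulatedVariant",
    "InapplicableBaseError",
    "typo_variant",
    "phonetic_variant",
    "concat_variant",
    "make_benchmark",
    "packaged_drug_names",
    "packaged_decoy_words",
]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_VOWELS = "aeiou"

#: Words glued onto a drug name in concatenation variants.
_CONCAT_SUFFIXES = ("para", "por", "ate", "com", "dia")
#: Derivational suffixes used to build "insulinizar"-style decoys.
_DERIV_SUFFIXES = ("izar", "izada", "izado", "ismo")

#: Drug names used only as decoys (never as benchmark bases by default).
_DECOY_DRUGS = (
    "propanolol", "glibenclamida", "anlodipino", "medroxiprogesterona",
    "metoclopramida", "loratadina", "dexametasona", "furosemida",
    "prednisona", "hidroclorotiazida", "diclofenaco", "ciprofloxacino",
    "espironolactona", "salbutamol", "clonazepam", "beclometasona",
    "dexclorfeniramina", "metronidazol", "prednisolona", "isossorbida",
)

DEFAULT_MIXTURE = (0.5, 0.3, 0.2)  # typo, phonetic, concatenation


class InapplicableBaseError(ValueError):
    """The base word offers no context for the requested substitution."""


@dataclass(frozen=True)
class SimulatedVariant:
    base: str
    surface: str
    label: str  # positive-typo | positive-phonetic | positive-concatenation | negative-decoy
    n_edits: int  # declared edit budget actually consumed (0 for non-typo)
    seed: int
    near_homophone: bool = False


def packaged_drug_names() -> list[str]:
    """The packaged list of 20 frequently prescribed drug names."""
    text = resources.files("farmatch.data").joinpath("drugs_pt.txt").read_text("utf-8")
    return [w for w in text.split() if w]


def packaged_decoy_words() -> list[str]:
    """The packaged Portuguese clinical-note decoy lexicon."""
    text = (
        resources.files("farmatch.data").joinpath("decoy_words_pt.txt").read_text("utf-8")
    )
    return [w for w in text.split() if w]


# -- typo variants ---------------------------------------------------------


def _apply_typo_ops(base: str, budget: int, rng: random.Random) -> tuple[str, int]:
    """Apply random edits until the budget is spent; returns (word, spent)."""
    word = list(base)
    spent = 0
    while spent < budget:
        ops = ["insert", "delete", "substitute"]
        if budget - spent >= 2 and len(word) >= 2:
            ops.append("swap")  # an adjacent swap costs 2 Levenshtein edits
        if len(word) <= 2:
            ops = [o for o in ops if o != "delete"]
        op = rng.choice(ops)
        if op == "insert":
            i = rng.randrange(len(word) + 1)
            word.insert(i, rng.choice(_ALPHABET))
            spent += 1
        elif op == "delete":
            del word[rng.randrange(len(word))]
            spent += 1
        elif op == "substitute":
            i = rng.randrange(len(word))
            choices = _ALPHABET.replace(word[i], "")
            word[i] = rng.choice(choices)
            spent += 1
        else:  # swap
            i = rng.randrange(len(word) - 1)
            if word[i] != word[i + 1]:
                word[i], word[i + 1] = word[i + 1], word[i]
                spent += 2
            else:  # swapping equal letters is a no-op; substitute instead
                continue
    return "".join(word), spent


def typo_variant(base: str, n_edits: int, seed: int) -> SimulatedVariant:
    """A random typographic misspelling within a declared edit budget.

    Deterministic under ``seed``; guarantees ``surface != base`` and
    ``edit_distance(base, surface) <= n_edits``.
    """
    if n_edits < 1:
        raise ValueError("n_edits must be >= 1")
    if len(base) < 4:
        raise ValueError("base must have at least 4 letters")
    rng = random.Random(seed)
    for _ in range(100):
        surface, spent = _apply_typo_ops(base, n_edits, rng)
        if surface != base and surface:
            return SimulatedVariant(
                base=base, surface=surface, label="positive-typo",
                n_edits=spent, seed=seed,
            )
    raise RuntimeError("could not generate a distinct typo variant")


# -- phonetic variants -----------------------------------------------------


def _is_vowel(ch: str) -> bool:
    return ch in _VOWELS


def _exact_homophone_subs(w: str) -> list[tuple[int, int, str]]:
    """(start, end, replacement) edits that leave the encoding unchanged."""
    subs: list[tuple[int, int, str]] = []
    n = len(w)
    for i, ch in enumerate(w):
        nxt = w[i + 1] if i + 1 < n else None
        prv = w[i - 1] if i > 0 else None
        two = w[i : i + 2]
        if two == "ss":
            after = w[i + 2] if i + 2 < n else None
            if after in ("a", "o", "u", None):
                subs.append((i, i + 2, "ç"))
            elif after in ("e", "i"):
                subs.append((i, i + 2, "c"))
        if ch == "ç":
            subs.append((i, i + 1, "ss"))
        if ch == "c" and nxt in ("e", "i"):
            subs.append((i, i + 1, "ss"))
        if ch == "z" and prv and nxt and _is_vowel(prv) and _is_vowel(nxt):
            subs.append((i, i + 1, "s"))
        if (
            ch == "s"
            and prv and nxt
            and _is_vowel(prv) and _is_vowel(nxt)
            and two != "ss" and (i == 0 or w[i - 1 : i + 1] != "ss")
        ):
            subs.append((i, i + 1, "z"))
        # ch <-> x only where x is a fricative: word-initial or post-consonant
        if two == "ch" and (i == 0 or (prv and not _is_vowel(prv))):
            subs.append((i, i + 2, "x"))
        if ch == "x" and (i == 0 or (prv and not _is_vowel(prv) and prv != "x")):
            subs.append((i, i + 1, "ch"))
        if two == "qu" and w[i + 2 : i + 3] in ("e", "i"):
            subs.append((i, i + 2, "k"))
        if ch == "k" and nxt in ("e", "i"):
            subs.append((i, i + 1, "qu"))
        # silent h: removable word-initially, or between vowels when that
        # does not disturb a context-sensitive neighbour (qu/gu digraphs)
        digraph_u = prv == "u" and i >= 2 and w[i - 2] in ("q", "g")
        if ch == "h" and (
            i == 0
            or (prv and nxt and _is_vowel(prv) and _is_vowel(nxt) and not digraph_u)
        ):
            subs.append((i, i + 1, ""))
        # silent h: insertable word-initially before a vowel or between vowels
        if _is_vowel(ch) and (
            i == 0 or (prv and _is_vowel(prv) and not digraph_u)
        ):
            subs.append((i, i, "h"))
    return subs


def _near_homophone_subs(w: str) -> list[tuple[int, int, str]]:
    """Unstressed-vowel e/i and o/u swaps (encoding changes slightly)."""
    swap = {"e": "i", "i": "e", "o": "u", "u": "o"}
    return [(i, i + 1, swap[ch]) for i, ch in enumerate(w) if ch in swap]


def phonetic_variant(
    base: str, seed: int, *, allow_near: bool = True
) -> SimulatedVariant:
    """A homophone-class respelling of ``base``, deterministic under seed.

    Prefers exact homophone substitutions (phonetic similarity stays 1.0);
    with ``allow_near=True`` falls back to a flagged near-homophone vowel
    swap when the base offers no exact context.

    Raises
    ------
    InapplicableBaseError
        If no substitution context exists at all.
    """
    rng = random.Random(seed)
    subs = _exact_homophone_subs(base)
    near = False
    if not subs and allow_near:
        subs = _near_homophone_subs(base)
        near = True
    if not subs:
        raise InapplicableBaseError(f"no homophone context in {base!r}")
    start, end, repl = rng.choice(sorted(subs))
    surface = base[:start] + repl + base[end:]
    return SimulatedVariant(
        base=base, surface=surface, label="positive-phonetic",
        n_edits=0, seed=seed, near_homophone=near,
    )


def concat_variant(base: str, seed: int) -> SimulatedVariant:
    """The drug name glued to a following short word (missing whitespace)."""
    rng = random.Random(seed)
    suffix = rng.choice(_CONCAT_SUFFIXES)
    return SimulatedVariant(
        base=base, surface=base + suffix, label="positive-concatenation",
        n_edits=0, seed=seed,
    )


# -- benchmark assembly ----------------------------------------------------


def _derivatives(drug: str) -> list[str]:
    stem = drug[:-1] if drug[-1] in _VOWELS else drug
    return [stem + suf for suf in _DERIV_SUFFIXES]


def _positive_counts(n_pos: int, mixture: tuple[float, float, float]) -> tuple[int, int, int]:
    n_typo = int(round(n_pos * mixture[0]))
    n_phon = int(round(n_pos * mixture[1]))
    n_typo = min(n_typo, n_pos)
    n_phon = min(n_phon, n_pos - n_typo)
    return n_typo, n_phon, n_pos - n_typo - n_phon


def make_benchmark(
    drugs: Sequence[str],
    n_pos_per_drug: int,
    n_neg_per_drug: int,
    seed: int,
    *,
    mixture: tuple[float, float, float] = DEFAULT_MIXTURE,
    max_typo_edits: int = 2,
    encoder: PhoneticEncoder | None = None,
    docs_per_drug: int = 1,
) -> tuple[list[CandidatePair], list[SimulatedVariant], list[Document], list[Annotation]]:
    """Labelled candidate pairs plus synthetic documents with gold mentions.

    Returns ``(pairs, variants, documents, gold_mentions)``.  Each drug
    receives ``n_pos_per_drug`` positives (typo / phonetic / concatenation
    per ``mixture``) and ``n_neg_per_drug`` decoy negatives; decoys are never
    equal to any benchmark drug.  Every positive variant is also embedded in
    a small synthetic document at a recorded character offset.
    """
    if n_pos_per_drug < 1 or n_neg_per_drug < 1:
        raise ValueError("positive and negative counts must be >= 1")
    enc = encoder or default_encoder()
    rng = random.Random(seed)
    drug_set = {normalize_word(d) for d in drugs}
    filler = [w for w in packaged_decoy_words() if w not in drug_set]
    decoy_drugs = [d for d in _DECOY_DRUGS if d not in drug_set]

    pairs: list[CandidatePair] = []
    variants: list[SimulatedVariant] = []
    documents: list[Document] = []
    gold: list[Annotation] = []

    for drug in drugs:
        base = normalize_word(drug)
        n_typo, n_phon, n_cat = _positive_counts(n_pos_per_drug, mixture)
        positives: list[SimulatedVariant] = []
        seen: set[str] = {base}

        def _add_unique(maker, count):
            attempts = 0
            while count > 0 and attempts < 50 * max(count, 1):
                attempts += 1
                v = maker(rng.randrange(2**31))
                if v.surface not in seen:
                    seen.add(v.surface)
                    positives.append(v)
                    count -= 1

        _add_unique(
            lambda s: typo_variant(base, rng.randint(1, max_typo_edits), s), n_typo
        )

        def _make_phonetic(s: int) -> SimulatedVariant:
            v = phonetic_variant(base, s, allow_near=True)
            if v.surface in seen:  # stack a second substitution for variety
                v2 = phonetic_variant(v.surface, s + 1, allow_near=True)
                return SimulatedVariant(
                    base=base, surface=v2.surface, label="positive-phonetic",
                    n_edits=0, seed=s,
                    near_homophone=v.near_homophone or v2.near_homophone,
                )
            return v

        try:
            _add_unique(_make_phonetic, n_phon)
        except InapplicableBaseError:
            _add_unique(
                lambda s: typo_variant(base, rng.randint(1, max_typo_edits), s), n_phon
            )
        _add_unique(lambda s: concat_variant(base, s), n_cat)
        # top up with typos if any stratum fell short of its quota
        _add_unique(
            lambda s: typo_variant(base, rng.randint(1, max_typo_edits), s),
            n_pos_per_drug - len(positives),
        )

        decoy_pool = sorted(
            (set(decoy_drugs) | set(filler) | set(_derivatives(base))) - drug_set
        )
        decoys = rng.sample(decoy_pool, min(n_neg_per_drug, len(decoy_pool)))

        for v in positives:
            variants.append(v)
            pairs.append(make_pair(base, v.surface, label="pos", encoder=enc))
        for w in decoys:
            variants.append(
                SimulatedVariant(
                    base=base, surface=w, label="negative-decoy",
                    n_edits=0, seed=seed,
                )
            )
            pairs.append(make_pair(base, w, label="neg", encoder=enc))

        # synthetic documents embedding this drug's positive variants
        per_doc = max(1, len(positives) // max(docs_per_drug, 1))
        for d in range(docs_per_drug):
            chunk = positives[d * per_doc : (d + 1) * per_doc] or positives[:1]
            doc_id = f"{base}-doc{d}"
            words: list[str] = []
            mention_idx: list[int] = []
            for v in chunk:
                words.extend(rng.sample(filler, 3))
                mention_idx.append(len(words))
                words.append(v.surface)
            words.extend(rng.sample(filler, 2))
            text = " ".join(words)
            offset = 0
            spans: list[tuple[int, int, str]] = []
            for k, w in enumerate(words):
                if k in mention_idx:
                    spans.append((offset, offset + len(w), w))
                offset += len(w) + 1
            documents.append(Document(doc_id=doc_id, text=text))
            for s, e, w in spans:
                gold.append(
                    Annotation(
                        doc_id=doc_id, start=s, end=e, surface=w,
                        canonical=base, variant=w, distance=None,
                    )
                )
    return pairs, variants, documents, gold
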
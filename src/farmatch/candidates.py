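"""Candidate generation: blocking and filtering of (drug, word) pairs.

For each canonical drug name, plausible misspelt variants are pulled out of a
corpus vocabulary by a cheap, high-recall *blocking* rule — keep a word when
it shares at least 3 consonantal phonemes (in order) with the drug, or sits
within edit distance 3 of it — and then narrowed by similarity filters.  The
final match decision is the hybrid joint-threshold rule: a pair is accepted
only if its phonetic similarity and its string similarity both clear their
respective cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .metrics import edit_distance, phonetic_sim, string_sim
from .phonetics import PhoneticEncoder, _lcs_length, default_encoder

__all__ = [
    "CandidatePair",
    "ThresholdPair",
    "block",
    "filter_by_string_sim",
    "classify",
    "make_pair",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "MIN_BLOCK_WORD_LEN",
    "CONSONANT_BLOCK_MIN",
    "ED_BLOCK_MAX",
]

#: Blocking constants: >= 3 shared consonantal phonemes OR edit distance <= 3.
CONSONANT_BLOCK_MIN = 3
ED_BLOCK_MAX = 3
#: Tokens shorter than this are never blocked (they match everything at ED 3).
MIN_BLOCK_WORD_LEN = 4

LABELS = ("pos", "neg", "unk")


@dataclass(frozen=True)
class ThresholdPair:
    """Joint (phonetic, string) similarity cutoffs, each in [0, 1]."""

    phonetic: float
    string: float

    def __post_init__(self) -> None:
        for name, v in (("phonetic", self.phonetic), ("string", self.string)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} threshold {v} outside [0, 1]")


@dataclass(frozen=True)
class CandidatePair:
    """A (drug, word) pair with its two similarity scores and optional label."""

    drug: str
    word: str
    s_sim: float
    p_sim: float
    label: str = "unk"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def make_pair(
    drug: str,
    word: str,
    label: str = "unk",
    *,
    encoder: PhoneticEncoder | None = None,
) -> CandidatePair:
    """Build a CandidatePair, computing both similarities from the strings."""
    return CandidatePair(
        drug=drug,
        word=word,
        s_sim=string_sim(drug, word),
        p_sim=phonetic_sim(drug, word, encoder=encoder),
        label=label,
    )


def block(
    drug: str,
    vocab: Sequence[str],
    *,
    encoder: PhoneticEncoder | None = None,
    min_word_len: int = MIN_BLOCK_WORD_LEN,
) -> list[CandidatePair]:
    """High-recall candidate selection for one drug against a vocabulary.

    A vocabulary word is kept iff it shares at least ``CONSONANT_BLOCK_MIN``
    consonantal phonemes (ordered) with the drug OR lies within edit distance
    ``ED_BLOCK_MAX`` of it.  The drug itself is excluded from its own list;
    so are words shorter than ``min_word_len``.  ``vocab`` is expected
    deduplicated and normalized.
    """
    enc = encoder or default_encoder()
    drug_cons = enc.consonantal_phonemes(drug)
    out: list[CandidatePair] = []
    for word in vocab:
        if word == drug or len(word) < min_word_len:
            continue
        if edit_distance(drug, word) > ED_BLOCK_MAX:
            shared = _lcs_length(drug_cons, enc.consonantal_phonemes(word))
            if shared < CONSONANT_BLOCK_MIN:
                continue
        out.append(make_pair(drug, word, encoder=enc))
    return out


def filter_by_string_sim(
    pairs: Iterable[CandidatePair], cutoff: float = 0.6
) -> list[CandidatePair]:
    """Keep pairs whose string similarity is at least ``cutoff`` (default 0.6).

    The default matches the deliberately permissive pre-filter used when
    assembling annotation candidates: low enough to admit roughly as many
    false as true candidates, so the threshold tuner sees both classes.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    return [p for p in pairs if p.s_sim >= cutoff]


def classify(pair: CandidatePair, thr: ThresholdPair) -> bool:
    """Hybrid match rule: both similarities must clear their thresholds."""
    return pair.p_sim >= thr.phonetic and pair.s_sim >= thr.string


# -- TSV I/O ---------------------------------------------------------------

_COLUMNS = ["drug", "word", "string_sim", "phonetic_sim", "label"]


def write_pairs_tsv(pairs: Iterable[CandidatePair], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.drug, p.word, p.s_sim, p.p_sim, p.label) for p in pairs],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> list[CandidatePair]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"drug": str, "word": str, "label": str},
        float_precision="round_trip",
    )
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"candidate TSV {path} missing columns {sorted(missing)}")
    return [
        CandidatePair(
            drug=row.drug,
            word=row.word,
            s_sim=float(row.string_sim),
            p_sim=float(row.phonetic_sim),
            label=row.label,
        )
        for row in df.itertuples(index=False)
    ]
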
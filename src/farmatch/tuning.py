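"""Joint-threshold tuning for the hybrid similarity match rule.

The match rule has two free parameters — a phonetic-similarity cutoff and a
string-similarity cutoff — and a (drug, word) pair is accepted only when both
are cleared.  Given two manually labelled candidate sets (training and
validation, split by drug), an exhaustive search walks a list of candidate
threshold pairs in order and keeps a pair whenever it *strictly* improves the
F1-score on both sets simultaneously; the last accepted pair wins.  Requiring
simultaneous improvement guards against overfitting the training drugs: a
cutoff pair that helps only one side never displaces the incumbent.

The tuned rule is exposed both functionally (``grid_search``) and as the
scikit-learn estimator :class:`HybridThresholdClassifier`, whose feature
matrix is simply ``[phonetic_sim, string_sim]`` per pair.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .candidates import (
    CandidatePair,
    ThresholdPair,
    block,
    classify,
    filter_by_string_sim,
)
from .phonetics import PhoneticEncoder

__all__ = [
    "ConfusionCounts",
    "TuningResult",
    "TuningFailureError",
    "UndefinedMetricError",
    "precision",
    "recall",
    "f1",
    "evaluate",
    "default_grid",
    "read_grid_tsv",
    "write_grid_tsv",
    "grid_search",
    "split_pairs_by_drug",
    "random_drug_split",
    "HybridThresholdClassifier",
    "VariantEntry",
    "VariantDictionary",
    "build_variant_dictionary",
]


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero."""


class TuningFailureError(RuntimeError):
    """Raised when no grid point yields defined F1 on both sets."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); undefined when nothing was retrieved."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: tp + fp == 0")
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); undefined when there is nothing to retrieve."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: tp + fn == 0")
    return c.tp / (c.tp + c.fn)


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall."""
    if p + r == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall == 0")
    return 2.0 * p * r / (p + r)


def evaluate(pairs: Sequence[CandidatePair], thr: ThresholdPair) -> ConfusionCounts:
    """Confusion counts of the joint-threshold rule on labelled pairs."""
    tp = fp = fn = 0
    for pair in pairs:
        if pair.label == "unk":
            raise ValueError(f"unlabelled pair ({pair.drug!r}, {pair.word!r})")
        matched = classify(pair, thr)
        if pair.label == "pos":
            tp += matched
            fn += not matched
        else:
            fp += matched
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


@dataclass(frozen=True)
class TuningResult:
    thresholds: ThresholdPair
    train_counts: ConfusionCounts
    valid_counts: ConfusionCounts
    train_metrics: tuple[float, float, float]  # (precision, recall, f1)
    valid_metrics: tuple[float, float, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "thresholds": asdict(self.thresholds),
            "train": {**asdict(self.train_counts),
                      **dict(zip(("precision", "recall", "f1"), self.train_metrics))},
            "valid": {**asdict(self.valid_counts),
                      **dict(zip(("precision", "recall", "f1"), self.valid_metrics))},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def default_grid() -> list[ThresholdPair]:
    """The default Cartesian threshold grid.

    Phonetic cutoffs run 0.50..1.00 in steps of 0.005; string cutoffs cover
    the same range plus 0, the phonetic-only configuration in which the
    string filter is vacuous.
    """
    fine = [round(0.5 + 0.005 * i, 3) for i in range(101)]
    svals = [0.0] + fine
    return [ThresholdPair(p, s) for p in fine for s in svals]


def write_grid_tsv(grid: Iterable[ThresholdPair], path: str | Path) -> None:
    pd.DataFrame(
        [(t.phonetic, t.string) for t in grid], columns=["phonetic", "string"]
    ).to_csv(path, sep="\t", index=False)


def read_grid_tsv(path: str | Path) -> list[ThresholdPair]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [ThresholdPair(float(r.phonetic), float(r.string)) for r in df.itertuples()]


def _as_arrays(pairs: Sequence[CandidatePair]):
    p = np.array([x.p_sim for x in pairs])
    s = np.array([x.s_sim for x in pairs])
    for x in pairs:
        if x.label == "unk":
            raise ValueError(f"unlabelled pair ({x.drug!r}, {x.word!r})")
    y = np.array([x.label == "pos" for x in pairs])
    return p, s, y


def _counts_per_grid_point(p, s, y, gp, gs):
    """tp/fp/fn arrays, one entry per grid point (vectorized)."""
    match = (p[None, :] >= gp[:, None]) & (s[None, :] >= gs[:, None])
    tp = (match & y[None, :]).sum(axis=1)
    fp = (match & ~y[None, :]).sum(axis=1)
    fn = ((~match) & y[None, :]).sum(axis=1)
    return tp, fp, fn


def _f1_or_nan(tp, fp, fn):
    # F1 == 2TP/(2TP+FP+FN); precision, recall and their sum are all
    # defined exactly when tp > 0, so points without a true positive are NaN.
    denom = np.maximum(2 * tp + fp + fn, 1)
    return np.where(tp > 0, 2 * tp / denom, np.nan)


def grid_search(
    train: Sequence[CandidatePair],
    valid: Sequence[CandidatePair],
    grid: Sequence[ThresholdPair] | None = None,
) -> TuningResult:
    """Exhaustive joint-threshold search with simultaneous-improvement rule.

    Walks ``grid`` in the given order; the incumbent is replaced only when a
    candidate pair strictly improves the F1-score on *both* the training and
    the validation set.  Grid points where either F1 is undefined are
    skipped.  Returns the last accepted pair with its metrics.

    Raises
    ------
    TuningFailureError
        If no grid point yields a defined F1 on both sets.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise TuningFailureError("empty threshold grid")
    pt, st_, yt = _as_arrays(train)
    pv, sv, yv = _as_arrays(valid)
    gp = np.array([g.phonetic for g in grid])
    gs = np.array([g.string for g in grid])

    t_tp, t_fp, t_fn = _counts_per_grid_point(pt, st_, yt, gp, gs)
    v_tp, v_fp, v_fn = _counts_per_grid_point(pv, sv, yv, gp, gs)
    f1_t = _f1_or_nan(t_tp, t_fp, t_fn)
    f1_v = _f1_or_nan(v_tp, v_fp, v_fn)

    best = -1
    best_t, best_v = -np.inf, -np.inf
    for i in range(len(grid)):
        if np.isnan(f1_t[i]) or np.isnan(f1_v[i]):
            continue
        if f1_t[i] > best_t and f1_v[i] > best_v:
            best, best_t, best_v = i, f1_t[i], f1_v[i]
    if best < 0:
        raise TuningFailureError("no grid point yields defined F1 on both sets")

    tc = ConfusionCounts(int(t_tp[best]), int(t_fp[best]), int(t_fn[best]))
    vc = ConfusionCounts(int(v_tp[best]), int(v_fp[best]), int(v_fn[best]))
    return TuningResult(
        thresholds=grid[best],
        train_counts=tc,
        valid_counts=vc,
        train_metrics=(precision(tc), recall(tc), f1(precision(tc), recall(tc))),
        valid_metrics=(precision(vc), recall(vc), f1(precision(vc), recall(vc))),
    )


def split_pairs_by_drug(
    pairs: Sequence[CandidatePair],
    train_drugs: Iterable[str],
    valid_drugs: Iterable[str],
) -> tuple[list[CandidatePair], list[CandidatePair]]:
    """Partition labelled pairs into train/validation by drug membership."""
    tset, vset = set(train_drugs), set(valid_drugs)
    overlap = tset & vset
    if overlap:
        raise ValueError(f"drugs in both splits: {sorted(overlap)}")
    train = [p for p in pairs if p.drug in tset]
    valid = [p for p in pairs if p.drug in vset]
    return train, valid


def random_drug_split(
    drugs: Sequence[str], seed: int, train_fraction: float = 0.5
) -> tuple[list[str], list[str]]:
    """Seeded random split of a drug list into train/validation groups."""
    rng = np.random.default_rng(seed)
    order = list(drugs)
    rng.shuffle(order)
    k = int(round(len(order) * train_fraction))
    return sorted(order[:k]), sorted(order[k:])


class HybridThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Joint phonetic/string threshold rule as a scikit-learn classifier.

    The feature matrix is ``(n_samples, 2)`` with columns
    ``[phonetic_sim, string_sim]``; the target is 1 for a true drug-name
    variant, 0 for a decoy.  ``fit`` runs the simultaneous-improvement grid
    search; pass a held-out set via ``X_valid``/``y_valid`` to reproduce the
    two-set tuning protocol (without one, the training set doubles as the
    validation set and the rule degenerates to plain F1 maximisation along
    the grid order).

    Attributes
    ----------
    phonetic_threshold_ : float
        Tuned phonetic-similarity cutoff.
    string_threshold_ : float
        Tuned string-similarity cutoff.
    result_ : TuningResult
        Full tuning record (counts and metrics on both sets).
    """

    def __init__(self, grid: Sequence[ThresholdPair] | None = None):
        self.grid = grid

    @staticmethod
    def _to_pairs(X, y) -> list[CandidatePair]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): [phonetic_sim, string_sim]")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        return [
            CandidatePair(
                drug="", word="", p_sim=float(p), s_sim=float(s),
                label="pos" if t else "neg",
            )
            for (p, s), t in zip(X, y)
        ]

    def fit(self, X, y, X_valid=None, y_valid=None):
        train = self._to_pairs(X, y)
        if X_valid is None:
            valid = train
        else:
            valid = self._to_pairs(X_valid, y_valid)
        res = grid_search(train, valid, self.grid)
        self.result_ = res
        self.phonetic_threshold_ = res.thresholds.phonetic
        self.string_threshold_ = res.thresholds.string
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "phonetic_threshold_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): [phonetic_sim, string_sim]")
        return (
            (X[:, 0] >= self.phonetic_threshold_)
            & (X[:, 1] >= self.string_threshold_)
        ).astype(int)

    @property
    def thresholds_(self) -> ThresholdPair:
        check_is_fitted(self, "phonetic_threshold_")
        return ThresholdPair(self.phonetic_threshold_, self.string_threshold_)


# -- variant dictionary ----------------------------------------------------


@dataclass(frozen=True)
class VariantEntry:
    canonical: str
    s_sim: float
    p_sim: float


@dataclass
class VariantDictionary:
    """Accepted misspelt variant -> canonical drug, with provenance scores."""

    entries: dict[str, VariantEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, variant: str) -> bool:
        return variant in self.entries

    def canonical_of(self, variant: str) -> str:
        return self.entries[variant].canonical

    def as_lookup(self) -> dict[str, str]:
        """Plain variant -> canonical map (for index building)."""
        return {v: e.canonical for v, e in self.entries.items()}

    def canonicals(self) -> set[str]:
        return {e.canonical for e in self.entries.values()}

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(v, e.canonical, e.s_sim, e.p_sim) for v, e in sorted(self.entries.items())],
            columns=["variant", "canonical", "string_sim", "phonetic_sim"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantDictionary":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"variant": str, "canonical": str},
            float_precision="round_trip",
        )
        return cls(
            {
                r.variant: VariantEntry(r.canonical, float(r.string_sim), float(r.phonetic_sim))
                for r in df.itertuples(index=False)
            }
        )


def build_variant_dictionary(
    drugs: Sequence[str],
    vocab: Sequence[str],
    thr: ThresholdPair,
    *,
    encoder: PhoneticEncoder | None = None,
    string_prefilter: float | None = None,
) -> VariantDictionary:
    """Block, filter and classify a vocabulary into a variant dictionary.

    Every accepted (variant -> drug) entry satisfies the joint-threshold
    rule.  A variant claimed by several drugs keeps the one with the highest
    (phonetic, string) similarity, ties broken by lexicographic canonical
    name; a variant identical to a canonical name always maps to itself.
    """
    if not drugs:
        raise ValueError("empty drug list")
    drug_set = set(drugs)
    entries: dict[str, VariantEntry] = {}
    for drug in drugs:
        pairs = block(drug, vocab, encoder=encoder)
        if string_prefilter is not None:
            pairs = filter_by_string_sim(pairs, string_prefilter)
        for pair in pairs:
            if not classify(pair, thr):
                continue
            if pair.word in drug_set:  # canonical names map to themselves
                continue
            cur = entries.get(pair.word)
            new = VariantEntry(drug, pair.s_sim, pair.p_sim)
            if (
                cur is None
                or (new.p_sim, new.s_sim) > (cur.p_sim, cur.s_sim)
                or ((new.p_sim, new.s_sim) == (cur.p_sim, cur.s_sim)
                    and new.canonical < cur.canonical)
            ):
                entries[pair.word] = new
    for drug in drugs:  # canonical names always map to themselves
        entries[drug] = VariantEntry(drug, 1.0, 1.0)
    return VariantDictionary(entries)
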
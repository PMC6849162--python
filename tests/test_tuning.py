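import json

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import f1_score, precision_score, recall_score

from farmatch.candidates import CandidatePair, ThresholdPair, make_pair
from farmatch.tuning import (
    ConfusionCounts,
    HybridThresholdClassifier,
    TuningFailureError,
    UndefinedMetricError,
    VariantDictionary,
    build_variant_dictionary,
    classify,
    default_grid,
    evaluate,
    f1,
    grid_search,
    precision,
    random_drug_split,
    read_grid_tsv,
    recall,
    split_pairs_by_drug,
    write_grid_tsv,
)


def _pair(p, s, label):
    return CandidatePair("d", "w", s_sim=s, p_sim=p, label=label)


class TestMetrics:
    def test_training_set_reconstruction(self):
        c = ConfusionCounts(tp=417, fp=31, fn=25)
        assert round(precision(c), 3) == 0.931
        assert round(recall(c), 3) == 0.943
        assert round(f1(precision(c), recall(c)), 3) == 0.937

    def test_validation_set_reconstruction(self):
        c = ConfusionCounts(tp=477, fp=39, fn=19)
        assert round(precision(c), 3) == 0.924
        assert round(f1(0.924, 0.961), 3) == 0.942

    def test_trivial_values(self):
        assert precision(ConfusionCounts(0, 5, 0)) == 0.0
        assert recall(ConfusionCounts(7, 0, 0)) == 1.0
        assert recall(ConfusionCounts(1, 0, 1)) == 0.5
        assert f1(0.5, 0.5) == 0.5  # harmonic-mean fixed point

    def test_undefined_metrics_raise(self):
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(0, 0, 3))
        with pytest.raises(UndefinedMetricError):
            recall(ConfusionCounts(0, 3, 0))
        with pytest.raises(UndefinedMetricError):
            f1(0.0, 0.0)

    def test_agrees_with_sklearn_on_random_data(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        c = ConfusionCounts(tp, fp, fn)
        assert precision(c) == pytest.approx(precision_score(y_true, y_pred))
        assert recall(c) == pytest.approx(recall_score(y_true, y_pred))
        assert f1(precision(c), recall(c)) == pytest.approx(
            f1_score(y_true, y_pred)
        )


class TestEvaluate:
    def test_vacuous_thresholds(self):
        pairs = [_pair(0.9, 0.9, "pos"), _pair(0.1, 0.1, "neg"), _pair(0.2, 0.9, "neg")]
        c = evaluate(pairs, ThresholdPair(0.0, 0.0))
        assert (c.tp, c.fp, c.fn) == (1, 2, 0)

    def test_unit_thresholds_match_nothing(self):
        pairs = [_pair(0.9, 0.9, "pos"), _pair(0.5, 0.5, "neg")]
        c = evaluate(pairs, ThresholdPair(1.0, 1.0))
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_direct_enumeration(self):
        pairs = [
            _pair(0.9, 0.9, "pos"),
            _pair(0.9, 0.9, "pos"),
            _pair(0.5, 0.5, "neg"),
        ]
        c = evaluate(pairs, ThresholdPair(0.8, 0.8))
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_unlabelled_pair_rejected(self):
        with pytest.raises(ValueError, match="unlabelled"):
            evaluate([_pair(0.5, 0.5, "unk")], ThresholdPair(0.5, 0.5))


def _separable_pairs(n=20):
    pos = [_pair(0.95, 0.92, "pos") for _ in range(n)]
    neg = [_pair(0.4, 0.3, "neg") for _ in range(n)]
    return pos + neg


class TestGridSearch:
    def test_single_element_grid(self):
        pairs = _separable_pairs()
        grid = [ThresholdPair(0.7, 0.7)]
        res = grid_search(pairs, pairs, grid)
        assert res.thresholds == grid[0]

    def test_separable_data_reaches_perfect_f1(self):
        train, valid = _separable_pairs(), _separable_pairs(30)
        res = grid_search(train, valid, default_grid())
        assert res.train_metrics[2] == 1.0
        assert res.valid_metrics[2] == 1.0

    def test_result_is_grid_member(self):
        grid = default_grid()
        res = grid_search(_separable_pairs(), _separable_pairs(), grid)
        assert res.thresholds in grid

    def test_failure_when_nothing_matches(self):
        pairs = [_pair(0.1, 0.1, "pos")]
        with pytest.raises(TuningFailureError):
            grid_search(pairs, pairs, [ThresholdPair(0.9, 0.9)])

    def test_strict_improvement_keeps_first_of_ties(self):
        pairs = _separable_pairs()
        grid = [ThresholdPair(0.6, 0.6), ThresholdPair(0.7, 0.7)]
        res = grid_search(pairs, pairs, grid)  # both perfect: first wins
        assert res.thresholds == grid[0]

    def test_matches_exhaustive_oracle_on_noisy_data(self):
        rng = np.random.default_rng(3)
        pairs = []
        for _ in range(120):
            if rng.random() < 0.5:
                pairs.append(_pair(rng.uniform(0.75, 1), rng.uniform(0.7, 1), "pos"))
            else:
                pairs.append(_pair(rng.uniform(0.3, 0.8), rng.uniform(0.2, 0.75), "neg"))
        train, valid = pairs[:60], pairs[60:]
        grid = default_grid()
        res = grid_search(train, valid, grid)

        # oracle: evaluate every grid point independently
        def f1_of(pairs_, thr):
            c = evaluate(pairs_, thr)
            if c.tp == 0:
                return np.nan
            return f1(precision(c), recall(c))

        best = max(
            (t for t in grid if not np.isnan(f1_of(train, t))),
            key=lambda t: f1_of(train, t),
        )
        # the simultaneous-improvement rule must come within one grid step
        # of the exhaustive training optimum
        assert f1_of(train, res.thresholds) >= f1_of(train, best) - 0.02

    def test_monotonicity_raising_thresholds_shrinks_matches(self):
        pairs = _separable_pairs()
        lo = evaluate(pairs, ThresholdPair(0.3, 0.3))
        hi = evaluate(pairs, ThresholdPair(0.96, 0.96))
        assert hi.tp <= lo.tp
        assert hi.fp <= lo.fp


class TestSplits:
    def test_split_by_drug_partition(self):
        pairs = [make_pair("fluoxetina", "fluoxetna", "pos"),
                 make_pair("insulina", "insulinas", "pos")]
        train, valid = split_pairs_by_drug(pairs, ["fluoxetina"], ["insulina"])
        assert [p.drug for p in train] == ["fluoxetina"]
        assert [p.drug for p in valid] == ["insulina"]

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError):
            split_pairs_by_drug([], ["a"], ["a", "b"])

    def test_random_split_is_seeded_and_balanced(self):
        drugs = [f"drug{i}" for i in range(20)]
        a = random_drug_split(drugs, seed=5)
        b = random_drug_split(drugs, seed=5)
        assert a == b
        assert len(a[0]) == len(a[1]) == 10
        assert sorted(a[0] + a[1]) == sorted(drugs)


class TestHybridThresholdClassifier:
    def _xy(self, pairs):
        X = np.array([[p.p_sim, p.s_sim] for p in pairs])
        y = np.array([p.label == "pos" for p in pairs], dtype=int)
        return X, y

    def test_fit_predict_round_trip(self):
        X, y = self._xy(_separable_pairs())
        clf = HybridThresholdClassifier().fit(X, y)
        assert clf.phonetic_threshold_ <= 0.95
        assert (clf.predict(X) == y).all()

    def test_predict_agrees_with_classify(self):
        X, y = self._xy(_separable_pairs())
        clf = HybridThresholdClassifier().fit(X, y)
        thr = clf.thresholds_
        for (p, s), pred in zip(X, clf.predict(X)):
            pair = CandidatePair("d", "w", s_sim=s, p_sim=p)
            assert bool(pred) == classify(pair, thr)

    def test_sklearn_clone_and_params(self):
        grid = [ThresholdPair(0.7, 0.7)]
        clf = HybridThresholdClassifier(grid=grid)
        cloned = clone(clf)
        assert cloned.get_params()["grid"] == grid

    def test_validation_set_constrains_fit(self):
        X, y = self._xy(_separable_pairs())
        Xv, yv = self._xy(_separable_pairs(10))
        clf = HybridThresholdClassifier().fit(X, y, X_valid=Xv, y_valid=yv)
        assert clf.result_.valid_metrics[2] == 1.0

    def test_predict_before_fit_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            HybridThresholdClassifier().predict([[0.5, 0.5]])


class TestGridIO:
    def test_round_trip(self, tmp_path):
        grid = [ThresholdPair(0.5, 0.0), ThresholdPair(0.844, 0.831)]
        path = tmp_path / "grid.tsv"
        write_grid_tsv(grid, path)
        assert read_grid_tsv(path) == grid

    def test_default_grid_shape(self):
        grid = default_grid()
        assert len(grid) == 101 * 102
        assert ThresholdPair(0.5, 0.0) in grid
        assert ThresholdPair(1.0, 1.0) in grid

    def test_result_json(self, tmp_path):
        res = grid_search(_separable_pairs(), _separable_pairs(), default_grid())
        path = tmp_path / "result.json"
        res.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["thresholds"]["phonetic"] == res.thresholds.phonetic
        assert payload["train"]["f1"] == res.train_metrics[2]


class TestVariantDictionary:
    def test_identity_when_vocab_equals_drugs(self):
        drugs = ["fluoxetina", "insulina"]
        vd = build_variant_dictionary(drugs, drugs, ThresholdPair(0.8, 0.8))
        assert vd.as_lookup() == {d: d for d in drugs}

    def test_close_variant_accepted(self):
        vd = build_variant_dictionary(
            ["fluoxetina"], ["fluoxetna"], ThresholdPair(0.8, 0.8)
        )
        assert vd.canonical_of("fluoxetna") == "fluoxetina"

    def test_failing_word_absent(self):
        vd = build_variant_dictionary(
            ["fluoxetina"], ["paracetamol"], ThresholdPair(0.8, 0.8)
        )
        assert "paracetamol" not in vd

    def test_every_entry_satisfies_thresholds(self):
        thr = ThresholdPair(0.7, 0.7)
        vd = build_variant_dictionary(
            ["fluoxetina", "paracetamol"],
            ["fluoxetna", "fluoxetona", "paracetamo", "parasetamol"],
            thr,
        )
        for variant, entry in vd.entries.items():
            pair = make_pair(entry.canonical, variant) if variant != entry.canonical \
                else CandidatePair(variant, variant, 1.0, 1.0)
            assert classify(pair, thr)

    def test_empty_drug_list_rejected(self):
        with pytest.raises(ValueError):
            build_variant_dictionary([], ["x"], ThresholdPair(0.5, 0.5))

    def test_tsv_round_trip(self, tmp_path):
        vd = build_variant_dictionary(
            ["fluoxetina"], ["fluoxetna"], ThresholdPair(0.8, 0.8)
        )
        path = tmp_path / "variants.tsv"
        vd.to_tsv(path)
        assert VariantDictionary.from_tsv(path).as_lookup() == vd.as_lookup()
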
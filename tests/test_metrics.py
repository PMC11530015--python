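"""Chou-style multi-label metrics and the cross-validation harness."""

import numpy as np
import pytest

import premls
from premls import network, synthetic
from premls.metrics import (
    MetricsReport,
    cross_validate,
    multilabel_metrics,
    per_category_absolute_true,
    ratio_sweep,
    stratified_folds,
)


def _brute_force_metrics(true_rows, pred_rows):
    """Independent oracle built on Python set arithmetic."""
    n, M = len(true_rows), 4
    aim = cov = acc = at = af = 0.0
    for t, p in zip(true_rows, pred_rows):
        Y = {i for i, f in enumerate(t) if f}
        Ystar = {i for i, f in enumerate(p) if f}
        inter, union = Y & Ystar, Y | Ystar
        aim += len(inter) / len(Ystar) if Ystar else 0.0
        cov += len(inter) / len(Y)
        acc += len(inter) / len(union) if Ystar else 0.0
        at += 1.0 if Y == Ystar else 0.0
        af += (len(union) - len(inter)) / M
    return tuple(v / n for v in (aim, cov, acc, at, af))


class TestMultilabelMetrics:
    def test_perfect_predictions(self, rng):
        y = rng.integers(0, 2, size=(20, 4))
        y[y.sum(axis=1) == 0, 0] = 1
        rep = multilabel_metrics(y, y)
        assert (rep.aiming, rep.coverage, rep.accuracy, rep.absolute_true,
                rep.absolute_false) == (1.0, 1.0, 1.0, 1.0, 0.0)

    def test_partial_overlap_single_sample(self):
        # truth {A, C}, prediction {A}
        rep = multilabel_metrics([[1, 1, 0, 0]], [[1, 0, 0, 0]])
        assert rep.aiming == 1.0
        assert rep.coverage == 0.5
        assert rep.accuracy == 0.5
        assert rep.absolute_true == 0.0
        assert rep.absolute_false == 0.25

    def test_disjoint_single_sample(self):
        rep = multilabel_metrics([[1, 0, 0, 0]], [[0, 1, 0, 0]])
        assert (rep.aiming, rep.coverage, rep.accuracy, rep.absolute_true,
                rep.absolute_false) == (0.0, 0.0, 0.0, 0.0, 0.5)

    def test_empty_prediction_penalized_and_counted(self):
        rep = multilabel_metrics([[1, 0, 0, 0]], [[0, 0, 0, 0]])
        assert rep.aiming == 0.0
        assert rep.accuracy == 0.0
        assert rep.absolute_false == 0.25
        assert rep.n_empty_predictions == 1

    def test_matches_set_arithmetic_oracle_on_random_cases(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 8))
            y = rng.integers(0, 2, size=(n, 4))
            y[y.sum(axis=1) == 0, int(rng.integers(0, 4))] = 1
            p = rng.integers(0, 2, size=(n, 4))
            rep = multilabel_metrics(y, p)
            oracle = _brute_force_metrics(y.tolist(), p.tolist())
            got = (rep.aiming, rep.coverage, rep.accuracy, rep.absolute_true,
                   rep.absolute_false)
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_sample_permutation_invariance(self, rng):
        y = rng.integers(0, 2, size=(30, 4))
        y[y.sum(axis=1) == 0, 0] = 1
        p = rng.integers(0, 2, size=(30, 4))
        order = rng.permutation(30)
        a, b = multilabel_metrics(y, p), multilabel_metrics(y[order], p[order])
        for field in ("aiming", "coverage", "accuracy", "absolute_true",
                      "absolute_false"):
            # invariant up to floating-point summation order
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-12)
        assert a.n_empty_predictions == b.n_empty_predictions

    def test_all_true_labels_required_nonempty(self):
        with pytest.raises(ValueError):
            multilabel_metrics([[0, 0, 0, 0]], [[1, 0, 0, 0]])

    def test_absolute_true_never_exceeds_accuracy(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, size=(10, 4))
            y[y.sum(axis=1) == 0, 0] = 1
            p = rng.integers(0, 2, size=(10, 4))
            rep = multilabel_metrics(y, p)
            assert rep.absolute_true <= rep.accuracy + 1e-12


class TestPerCategoryAbsoluteTrue:
    def test_absent_category_is_none_not_zero(self):
        out = per_category_absolute_true([1, 1], [[1, 0, 0, 0]] * 2, [[1, 0, 0, 0]] * 2)
        assert out[1] == 1.0
        assert out[2] is None

    def test_half_exact_category(self):
        out = per_category_absolute_true(
            [3, 3], [[0, 0, 1, 0]] * 2, [[0, 0, 1, 0], [1, 0, 1, 0]]
        )
        assert out[3] == 0.5

    def test_weighted_mean_equals_global_absolute_true(self, rng):
        n = 200
        cats = rng.integers(1, 12, size=n)
        y = np.array([list(premls.onehot_label(c)) for c in cats])
        p = rng.integers(0, 2, size=(n, 4))
        rep = multilabel_metrics(y, p, cats)
        weighted = sum(
            v * np.sum(cats == c)
            for c, v in rep.per_category_absolute_true.items()
            if v is not None
        )
        assert weighted / n == pytest.approx(rep.absolute_true, abs=1e-12)


class TestStratifiedFolds:
    def test_partition_each_sample_once(self, rng):
        cats = rng.integers(1, 12, size=97).tolist()
        folds = stratified_folds(cats, 5, seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx.tolist()) == list(range(97))

    def test_category_balance_across_folds(self):
        cats = [1] * 50 + [2] * 10
        folds = stratified_folds(cats, 5, seed=1)
        for f in folds:
            assert np.sum(np.array(cats)[f] == 1) == 10
            assert np.sum(np.array(cats)[f] == 2) == 2

    def test_seed_determinism(self, rng):
        cats = rng.integers(1, 12, size=50).tolist()
        a = stratified_folds(cats, 5, seed=3)
        b = stratified_folds(cats, 5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds([1, 2], 1, seed=0)


@pytest.fixture(scope="module")
def small_signal_windows():
    spec = synthetic.default_imbalanced_spec(seed=11, scale=0.02)
    return synthetic.generate(spec)


FAST_CFG = network.ClassifierConfig(epochs=6, batch_size=16, seed=0)


class TestCrossValidate:
    def test_partition_and_determinism(self, small_signal_windows):
        pooled_a, folds_a = cross_validate(
            small_signal_windows, folds=2, ratio=0.5,
            classifier_config=FAST_CFG, seed=5,
        )
        pooled_b, _ = cross_validate(
            small_signal_windows, folds=2, ratio=0.5,
            classifier_config=FAST_CFG, seed=5,
        )
        assert sum(r.n for r in folds_a) == len(small_signal_windows)
        assert pooled_a.as_dict() == pooled_b.as_dict()

    def test_pooled_n_equals_dataset_size(self, small_signal_windows):
        pooled, _ = cross_validate(
            small_signal_windows, folds=2, ratio=1.0,
            classifier_config=FAST_CFG, seed=0,
        )
        assert pooled.n == len(small_signal_windows)


class TestRatioSweep:
    def test_table_layout(self, small_signal_windows):
        table = ratio_sweep(
            small_signal_windows, [1.0, 0.5], folds=2,
            classifier_config=FAST_CFG, seed=0,
        )
        assert list(table.index) == [1.0, 0.5]
        assert list(table.columns) == [
            "A", "C", "M", "S", "AC", "AM", "AS", "CM", "ACM", "ACS", "ACMS"
        ]

    def test_single_ratio_equals_cross_validate(self, small_signal_windows):
        table = ratio_sweep(
            small_signal_windows, [0.5], folds=2,
            classifier_config=FAST_CFG, seed=5,
        )
        pooled, _ = cross_validate(
            small_signal_windows, folds=2, ratio=0.5,
            classifier_config=FAST_CFG, seed=5,
        )
        expect = {
            k: round(100 * v, 2)
            for k, v in pooled.as_dict()["per_category_absolute_true"].items()
            if v is not None
        }
        got = table.iloc[0].dropna().to_dict()
        assert got == expect

    def test_invalid_ratio_rejected(self, small_signal_windows):
        with pytest.raises(ValueError):
            ratio_sweep(small_signal_windows, [0.0], folds=2)


class TestMetricsReportInvariant:
    def test_inconsistent_report_rejected(self):
        with pytest.raises(ValueError):
            MetricsReport(
                aiming=1, coverage=1, accuracy=0.5, absolute_true=0.9,
                absolute_false=0, n=10,
            )
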
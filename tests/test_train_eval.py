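"""Split protocols, metric definitions, training loop behavior."""

import numpy as np
import pytest

from semgst import (MatrixSignal, STConfig, SignalTransformer, TrainConfig,
                    cross_subject_report, evaluate, split_by_repetition,
                    split_odd_even, train)
from semgst.train_eval import (NINAPRO_TEST_REPS, NINAPRO_TRAIN_REPS,
                               report_from_predictions)


def _items(reps, labels=None, size=6):
    rng = np.random.default_rng(0)
    labels = labels if labels is not None else [1] * len(reps)
    return [MatrixSignal(pixels=rng.random((size, size, 1)), label=l,
                         subject_id="S", source_grid=(2, 5), repetition=r)
            for r, l in zip(reps, labels)]


class TestSplits:
    def test_seven_three_repetition_split(self):
        data = _items(list(range(1, 11)) * 3)
        tr, te = split_by_repetition(data, NINAPRO_TRAIN_REPS, NINAPRO_TEST_REPS)
        assert {d.repetition for d in tr} == {1, 3, 4, 6, 8, 9, 10}
        assert {d.repetition for d in te} == {2, 5, 7}
        assert len(tr) + len(te) == len(data)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            split_by_repetition(_items([1, 2]), {1, 2}, {2, 3})

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            split_by_repetition(_items([1, 2]), {1, 2}, set())

    def test_rest_windows_belong_to_neither_split(self):
        data = _items([0, 1, 2, 0, 5])
        tr, te = split_by_repetition(data, {1}, {2, 5})
        assert len(tr) == 1 and len(te) == 2

    def test_odd_even_split(self):
        data = _items(list(range(1, 11)))
        tr, te = split_odd_even(data)
        assert {d.repetition for d in tr} == {1, 3, 5, 7, 9}
        assert {d.repetition for d in te} == {2, 4, 6, 8, 10}
        assert not ({d.repetition for d in tr} & {d.repetition for d in te})


class TestMetrics:
    def test_perfect_predictions(self):
        r = report_from_predictions([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert (r.accuracy, r.f1_macro, r.f1_micro) == (100.0, 100.0, 100.0)

    def test_one_flip_in_balanced_binary(self):
        y = [0] * 5 + [1] * 5
        pred = list(y)
        pred[0] = 1
        r = report_from_predictions(y, pred, 2)
        assert r.accuracy == pytest.approx(90.0)
        assert r.confusion.sum() == r.n_test == 10

    def test_micro_f1_equals_accuracy(self, rng):
        """Single-label complete predictions: micro F1 is identically the
        accuracy, for any confusion structure."""
        for _ in range(200):
            k = rng.integers(2, 6)
            n = rng.integers(5, 50)
            y = rng.integers(0, k, size=n)
            pred = rng.integers(0, k, size=n)
            r = report_from_predictions(y, pred, int(k))
            assert r.f1_micro == pytest.approx(r.accuracy, abs=1e-9)

    def test_macro_f1_matches_sklearn_when_no_empty_classes(self, rng):
        from sklearn.metrics import f1_score
        y = rng.integers(0, 4, size=200)
        pred = rng.integers(0, 4, size=200)
        r = report_from_predictions(y, pred, 4)
        want = 100 * f1_score(y, pred, average="macro", labels=range(4))
        assert r.f1_macro == pytest.approx(want, abs=1e-9)

    def test_absent_class_contributes_zero_to_macro(self):
        # class 2 never occurs in truth or prediction -> its F1 counts as 0
        r = report_from_predictions([0, 1, 0, 1], [0, 1, 0, 1], 3)
        assert r.f1_macro == pytest.approx(100 * 2 / 3)

    def test_metrics_agree_with_direct_recomputation(self, rng):
        y = rng.integers(0, 3, size=120)
        pred = rng.integers(0, 3, size=120)
        r = report_from_predictions(y, pred, 3)
        assert r.accuracy == pytest.approx(100 * np.mean(y == pred))
        f1s = []
        for k in range(3):
            tp = np.sum((pred == k) & (y == k))
            fp = np.sum((pred == k) & (y != k))
            fn = np.sum((pred != k) & (y == k))
            f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
        assert r.f1_macro == pytest.approx(100 * np.mean(f1s))


class TestCrossSubject:
    def _report(self, acc, sid):
        return report_from_predictions([0] * 10, [0] * int(acc / 10) + [1] * (10 - int(acc / 10)),
                                       2, subject_id=sid)

    def test_mean_of_two_subjects(self):
        a, b = self._report(80, "A"), self._report(90, "B")
        s = cross_subject_report([a, b])
        assert s["accuracy"] == pytest.approx(85.0)

    def test_single_subject_summary_equals_report(self):
        a = self._report(70, "A")
        s = cross_subject_report([a])
        assert s["accuracy"] == a.accuracy
        assert s["f1_macro"] == a.f1_macro

    def test_permutation_invariance(self):
        reports = [self._report(a, s) for a, s in ((60, "A"), (80, "B"), (100, "C"))]
        s1 = cross_subject_report(reports)
        s2 = cross_subject_report(reports[::-1])
        assert s1["accuracy"] == s2["accuracy"]


def _separable_dataset(n_per_class=40, size=6, seed=0):
    """Two classes distinguished by which image half is bright."""
    rng = np.random.default_rng(seed)
    data = []
    for label in (0, 1):
        for _ in range(n_per_class):
            img = 0.1 * rng.random((size, size, 1))
            if label == 0:
                img[:, :size // 2] += 1.0
            else:
                img[:, size // 2:] += 1.0
            img = (img - img.mean()) / img.std()
            data.append(MatrixSignal(pixels=img, label=label, subject_id="S",
                                     source_grid=(2, 3), repetition=1))
    return data


TRAIN_TINY = dict(image_size=6, patch_size=3, embed_dim=8, n_layers=1,
                  n_heads=2, mlp_head_dims=(16,), n_classes=2, dropout=0.0)


class TestTrain:
    def test_loss_halves_on_separable_data(self):
        data = _separable_dataset()
        model = SignalTransformer(STConfig(**TRAIN_TINY, seed=1))
        cfg = TrainConfig(batch_size=8, epochs=8, seed=1, learning_rate=3e-3)
        _, log = train(model, data, cfg)
        first = np.mean(log["loss"][:5])
        last = np.mean(log["loss"][-5:])
        assert last <= 0.5 * first

    def test_same_seed_identical_weights(self):
        data = _separable_dataset()
        out = []
        for _ in range(2):
            model = SignalTransformer(STConfig(**TRAIN_TINY, seed=2))
            cfg = TrainConfig(batch_size=16, epochs=2, seed=7)
            model, _ = train(model, data, cfg)
            out.append({k: v.copy() for k, v in model.params.items()})
        for k in out[0]:
            np.testing.assert_array_equal(out[0][k], out[1][k])

    def test_tiny_learning_rate_leaves_weights_nearly_unchanged(self):
        data = _separable_dataset()
        model = SignalTransformer(STConfig(**TRAIN_TINY, seed=2))
        before = {k: v.copy() for k, v in model.params.items()}
        cfg = TrainConfig(batch_size=16, epochs=1, seed=7, learning_rate=1e-12,
                          weight_decay=0.0)
        model, _ = train(model, data, cfg)
        for k, v in model.params.items():
            np.testing.assert_allclose(v, before[k], atol=1e-9)

    def test_empty_training_data_rejected(self):
        model = SignalTransformer(STConfig(**TRAIN_TINY))
        with pytest.raises(ValueError):
            train(model, [], TrainConfig())

    def test_evaluate_on_separable_data_after_training(self):
        data = _separable_dataset()
        model = SignalTransformer(STConfig(**TRAIN_TINY, seed=3))
        cfg = TrainConfig(batch_size=8, epochs=8, seed=3, learning_rate=3e-3)
        model, _ = train(model, data, cfg)
        report = evaluate(model, data)
        assert report.accuracy >= 95.0
        assert report.confusion.sum() == len(data)
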
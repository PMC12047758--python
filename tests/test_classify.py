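"""CNN construction, splitting, training, evaluation, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from eggsight import _nn
from eggsight.classify import (TrainConfig, build_model, cross_validate,
                               evaluate, load_model, predict, split_dataset,
                               train)


def make_clutch_manifest(n_clutches_per_class, classes=("A", "B"),
                         eggs_per_clutch=5):
    rows = []
    for cls in classes:
        for c in range(n_clutches_per_class):
            for e in range(eggs_per_clutch):
                rows.append({"species": cls, "clutch_id": f"{cls}-c{c}",
                             "egg_id": f"{cls}-c{c}-e{e}"})
    return pd.DataFrame(rows)


def toy_class_images(n, size=64, n_classes=2, seed=0):
    """Trivially separable images: per-class constant colour + noise."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % n_classes
    x = rng.normal(0.5, 0.02, size=(n, 3, size, size)).astype(np.float32)
    for i, c in enumerate(y):
        x[i, 0] += 0.25 * (c + 1) / n_classes
        x[i, 1] -= 0.2 * c / n_classes
    return np.clip(x, 0, 1), y


class TestBuildModel:
    def test_block_spatial_sizes_halve_five_times(self):
        model = build_model(64, 4, width_scale=0.0625, seed=0)
        x = np.random.default_rng(0).random((1, 3, 64, 64)).astype(np.float32)
        sizes = []
        a = x
        for i, layer in enumerate(model.net.layers):
            a = layer.forward(a)
            if i in model.block_ends.values():
                sizes.append(a.shape[-1])
        assert sizes == [64, 32, 16, 8, 4]  # pre-pool activations

    def test_softmax_output_is_probability_simplex(self):
        model = build_model(64, 4, width_scale=0.0625, seed=1)
        x = np.random.default_rng(1).random((3, 3, 64, 64)).astype(np.float32)
        probs = predict(model, x)
        assert probs.shape == (3, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()
        assert (probs.max(axis=1) >= 1 / 4).all()  # argmax bound

    def test_width_scale_shrinks_parameter_count(self):
        full = build_model(64, 4, width_scale=1.0, seed=0).n_parameters()
        eighth = build_model(64, 4, width_scale=0.125, seed=0).n_parameters()
        assert eighth < full / 50

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            build_model(64, 4, width_scale=0.001)

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValueError):
            build_model(100, 4)

    def test_duplicated_input_gives_identical_probabilities(self):
        model = build_model(64, 3, width_scale=0.0625, seed=2)
        x = np.random.default_rng(2).random((1, 3, 64, 64)).astype(np.float32)
        probs = predict(model, np.concatenate([x, x]))
        assert np.allclose(probs[0], probs[1])

    def test_predict_rejects_wrong_size(self):
        model = build_model(64, 2, width_scale=0.0625)
        with pytest.raises(ValueError, match="64"):
            predict(model, np.zeros((1, 3, 32, 32), dtype=np.float32))

    def test_save_load_roundtrip(self, tmp_path):
        model = build_model(64, 3, width_scale=0.0625, seed=3)
        model.class_labels = ["x", "y", "z"]
        x = np.random.default_rng(3).random((2, 3, 64, 64)).astype(np.float32)
        p1 = predict(model, x)
        model.save(tmp_path / "w.npz")
        loaded = load_model(tmp_path / "w.npz")
        assert loaded.class_labels == ["x", "y", "z"]
        assert np.allclose(predict(loaded, x), p1)


class TestSplitDataset:
    def test_clutch_counts_follow_fractions(self):
        manifest = make_clutch_manifest(50, classes=("A",))
        tr, va, te = split_dataset(manifest, (0.5, 0.2, 0.3),
                                   np.random.default_rng(0))
        n = lambda df: df["clutch_id"].nunique()
        assert (n(tr), n(va), n(te)) == (25, 10, 15)

    def test_plain_split_without_grouping(self):
        manifest = make_clutch_manifest(2, classes=("A",), eggs_per_clutch=5)
        tr, va, te = split_dataset(manifest, (0.5, 0.2, 0.3),
                                   np.random.default_rng(1), group_key=None)
        assert (len(tr), len(va), len(te)) == (5, 2, 3)

    def test_no_clutch_spans_two_splits(self):
        manifest = make_clutch_manifest(10, classes=("A", "B", "C"))
        tr, va, te = split_dataset(manifest, (0.5, 0.2, 0.3),
                                   np.random.default_rng(2))
        sets = [set(part["clutch_id"]) for part in (tr, va, te)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
            and not (sets[1] & sets[2])
        assert len(tr) + len(va) + len(te) == len(manifest)

    def test_single_clutch_class_goes_to_train_with_warning(self):
        manifest = pd.concat([make_clutch_manifest(5, classes=("A",)),
                              make_clutch_manifest(1, classes=("B",))],
                             ignore_index=True)
        with pytest.warns(UserWarning, match="single clutch"):
            tr, va, te = split_dataset(manifest, (0.5, 0.2, 0.3),
                                       np.random.default_rng(3))
        assert set(tr[tr["species"] == "B"]["clutch_id"]) == {"B-c0"}
        assert "B" not in set(va["species"]) | set(te["species"])


class TestTrain:
    def test_overfits_tiny_separable_set(self):
        """Sanity: elevated learning rate drives training accuracy to 1."""
        x, y = toy_class_images(10, seed=5)
        model = build_model(64, 2, width_scale=0.0625, seed=5)
        cfg = TrainConfig(learning_rate=0.005, epochs=40, width_scale=0.0625,
                          input_size=64, early_stop_val_acc=None, seed=5)
        history = train(model, x, y, x, y, cfg)
        assert max(h["train_acc"] for h in history) == 1.0

    def test_zero_epochs_leaves_weights_untouched(self):
        x, y = toy_class_images(4, seed=6)
        model = build_model(64, 2, width_scale=0.0625, seed=6)
        before = [p.copy() for p in model.net.params()]
        history = train(model, x, y, x, y,
                        TrainConfig(epochs=0, width_scale=0.0625,
                                    input_size=64))
        assert history == []
        for p, q in zip(model.net.params(), before):
            assert np.array_equal(p, q)

    def test_fixed_seed_reproduces_history(self):
        x, y = toy_class_images(8, seed=7)
        cfg = TrainConfig(learning_rate=0.002, epochs=2, width_scale=0.0625,
                          input_size=64, seed=7)
        h1 = train(build_model(64, 2, 0.0625, seed=7), x, y, x, y, cfg)
        h2 = train(build_model(64, 2, 0.0625, seed=7), x, y, x, y, cfg)
        assert h1 == h2

    def test_history_schema(self):
        x, y = toy_class_images(8, seed=8)
        cfg = TrainConfig(learning_rate=1e-4, epochs=3, width_scale=0.0625,
                          input_size=64)
        history = train(build_model(64, 2, 0.0625, seed=8), x, y, x, y, cfg)
        assert len(history) == 3
        assert set(history[0]) == {"epoch", "train_loss", "train_acc",
                                   "val_loss", "val_acc"}


class TestEvaluate:
    def brute_force(self, y_true, y_pred, labels):
        """Independent per-pair recount of all four confusion cells."""
        stats = {}
        for i, lab in enumerate(labels):
            tp = sum(1 for t, p in zip(y_true, y_pred) if t == i and p == i)
            fp = sum(1 for t, p in zip(y_true, y_pred) if t != i and p == i)
            fn = sum(1 for t, p in zip(y_true, y_pred) if t == i and p != i)
            tn = len(y_true) - tp - fp - fn
            stats[lab] = (tp, fp, tn, fn)
        acc = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
        return stats, acc

    def test_simple_precision_value(self):
        # 3 true positives and 1 false positive for class 0
        y_true = [0, 0, 0, 1, 1]
        y_pred = [0, 0, 0, 0, 1]
        _, rep = evaluate(y_true, y_pred, ["a", "b"])
        assert rep.precision["a"] == 0.75
        assert rep.recall["a"] == 1.0

    def test_perfect_predictions(self):
        y = [0, 1, 2, 3] * 5
        cm, rep = evaluate(y, y, list("abcd"))
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.f1.values())
        off_diag = cm.counts.sum() - np.trace(cm.counts)
        assert off_diag == 0

    def test_matches_brute_force_recount_on_random_sets(self):
        rng = np.random.default_rng(0)
        labels = list("abcd")
        for _ in range(25):
            n = int(rng.integers(5, 60))
            y_true = rng.integers(0, 4, n)
            y_pred = rng.integers(0, 4, n)
            cm, rep = evaluate(y_true, y_pred, labels)
            stats, acc = self.brute_force(y_true, y_pred, labels)
            assert rep.accuracy == pytest.approx(acc)
            for i, lab in enumerate(labels):
                tp, fp, tn, fn = stats[lab]
                assert (rep.tp[lab], rep.fp[lab], rep.tn[lab],
                        rep.fn[lab]) == (tp, fp, tn, fn)
                expected_p = tp / (tp + fp) if tp + fp else 0.0
                expected_r = tp / (tp + fn) if tp + fn else 0.0
                assert rep.precision[lab] == pytest.approx(expected_p)
                assert rep.recall[lab] == pytest.approx(expected_r)
                if expected_p + expected_r:
                    hm = 2 * expected_p * expected_r / (expected_p + expected_r)
                    assert rep.f1[lab] == pytest.approx(hm)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 3, 40)
        y_pred = rng.integers(0, 3, 40)
        perm = rng.permutation(40)
        cm1, rep1 = evaluate(y_true, y_pred, list("abc"))
        cm2, rep2 = evaluate(y_true[perm], y_pred[perm], list("abc"))
        assert (cm1.counts == cm2.counts).all()
        assert rep1.accuracy == rep2.accuracy

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [], ["a"])


class TestCrossValidate:
    def test_fold_summary_matches_fold_values(self):
        x, y = toy_class_images(60, seed=9)
        clutches = [f"{c}-cl{i // 10}" for i, c in enumerate(y)]
        cfg = TrainConfig(learning_rate=0.003, epochs=2, width_scale=0.0625,
                          input_size=64, seed=9)
        res = cross_validate(x, y, clutches, k=3, config=cfg,
                             labels=["a", "b"])
        for metric, vals in res["fold_metrics"].items():
            assert len(vals) == 3
            assert res["summary"][metric]["mean"] == pytest.approx(np.mean(vals))
            assert res["summary"][metric]["sd"] == pytest.approx(
                np.std(vals, ddof=1))

    def test_too_few_clutches_rejected(self):
        x, y = toy_class_images(8, seed=10)
        clutches = ["c0"] * 4 + ["c1"] * 4
        cfg = TrainConfig(width_scale=0.0625, input_size=64, epochs=1)
        with pytest.raises(ValueError, match="clutches"):
            cross_validate(x, y, clutches, k=3, config=cfg)
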
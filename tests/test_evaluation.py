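import numpy as np
import pytest

import kicksense as ks
from kicksense.exceptions import ConfigurationError
from kicksense.model import Prediction

from conftest import make_feature_matrix

NAMES = ("pass", "shot")


def pred(p_shot, intensity=0.0):
    return Prediction(class_probs=np.array([1 - p_shot, p_shot]),
                      intensity_raw=intensity, class_names=NAMES)


def ap_oracle(y_true, scores):
    """Independent step-interpolated AP: sum over recall steps of precision."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(y_true)[order]
    tp = fp = 0
    n_pos = y.sum()
    ap = 0.0
    for yi in y:
        if yi:
            tp += 1
            ap += (tp / (tp + fp)) / n_pos
        else:
            fp += 1
    return ap


def tiny_dataset(rng, n_per_class=10, subjects=("S1", "S2")):
    samples = []
    for i in range(n_per_class):
        for c in NAMES:
            samples.append(
                make_feature_matrix(rng, n_rows=4, class_label=c,
                                    intensity=float(i % 3 + 1),
                                    subject=subjects[i % len(subjects)])
            )
    return ks.AugmentedDataset(samples=samples)


class TestSplit:
    def test_80_20_counts(self, rng):
        ds = tiny_dataset(rng, n_per_class=5)  # 10 samples
        train, test = ks.split_train_test(ds, 0.8, seed=0)
        assert (len(train), len(test)) == (8, 2)

    def test_same_seed_same_split(self, rng):
        ds = tiny_dataset(rng)
        a = ks.split_train_test(ds, 0.8, seed=5)
        b = ks.split_train_test(ds, 0.8, seed=5)
        assert [id(s) for s in a[0].samples] == [id(s) for s in b[0].samples]

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        ds = tiny_dataset(rng)
        train, test = ks.split_train_test(ds, 0.8, seed=1)
        ids = sorted(id(s) for s in list(train.samples) + list(test.samples))
        assert ids == sorted(id(s) for s in ds.samples)

    def test_split_is_stratified(self, rng):
        ds = tiny_dataset(rng, n_per_class=10)
        train, test = ks.split_train_test(ds, 0.8, seed=2)
        assert sorted(test.class_labels).count("pass") == 2
        assert sorted(test.class_labels).count("shot") == 2

    def test_tiny_class_warns_and_falls_back(self, rng):
        samples = [make_feature_matrix(rng, class_label="pass")] * 4
        samples.append(make_feature_matrix(rng, class_label="shot"))
        ds = ks.AugmentedDataset(samples=samples)
        with pytest.warns(UserWarning, match="unstratified"):
            ks.split_train_test(ds, 0.8, seed=0)


class TestComputeMetrics:
    def test_perfect_predictions_hit_all_extremes(self):
        preds = [pred(0.1, 1), pred(0.2, 2), pred(0.9, 3), pred(0.8, 4)]
        truths = ["pass", "pass", "shot", "shot"]
        rep = ks.compute_metrics(preds, truths, [1, 2, 3, 4])
        assert rep.accuracy == 1.0
        assert rep.f1 == 1.0
        assert rep.mAP == 1.0
        assert rep.mae == 0.0
        assert rep.mape == 0.0

    def test_single_error_matches_hand_confusion_matrix(self):
        # 2x2 confusion by hand: pass: TP 2 FN 0; shot: TP 1 FN 1 (as pass)
        preds = [pred(0.1), pred(0.2), pred(0.9), pred(0.4)]
        truths = ["pass", "pass", "shot", "shot"]
        rep = ks.compute_metrics(preds, truths)
        assert rep.accuracy == pytest.approx(0.75)
        # pass: precision 2/3, recall 1 -> f1 0.8; shot: 1, 0.5 -> 2/3
        assert rep.f1 == pytest.approx((0.8 + 2 / 3) / 2)
        probs = np.stack([p.class_probs for p in preds])
        y = np.array([0, 0, 1, 1])
        expected_map = (ap_oracle(y == 0, probs[:, 0])
                        + ap_oracle(y == 1, probs[:, 1])) / 2
        assert rep.mAP == pytest.approx(expected_map)

    def test_constant_intensity_mae_matches_loop_oracle(self, rng):
        t = rng.integers(1, 9, size=12).astype(float)
        preds = [pred(0.2, 3.0) for _ in t]
        rep = ks.compute_metrics(preds, ["pass"] * 12, t)
        assert rep.mae == pytest.approx(np.mean([abs(x - 3.0) for x in t]))

    def test_zero_truths_are_excluded_from_mape(self):
        preds = [pred(0.1, 2), pred(0.1, 2), pred(0.1, 2)]
        rep = ks.compute_metrics(preds, ["pass"] * 3, [0.0, 4.0, 2.0])
        assert rep.n_mape_excluded == 1
        assert rep.mape == pytest.approx((abs(4 - 2) / 4 + 0) / 2 * 100)

    def test_all_zero_truths_leave_mape_absent(self):
        preds = [pred(0.1, 1), pred(0.1, 0)]
        rep = ks.compute_metrics(preds, ["pass"] * 2, [0.0, 0.0])
        assert rep.mape is None
        assert rep.mae is not None

    def test_map_invariant_under_monotone_score_rescale(self, rng):
        probs = rng.random((20, 2))
        probs /= probs.sum(1, keepdims=True)
        y = rng.integers(0, 2, 20)
        preds_a = [Prediction(class_probs=p, intensity_raw=0,
                              class_names=NAMES) for p in probs]
        # cubing preserves the per-class ranking of scores
        preds_b = [Prediction(class_probs=p ** 3, intensity_raw=0,
                              class_names=NAMES) for p in probs]
        rep_a = ks.compute_metrics(preds_a, [NAMES[i] for i in y])
        rep_b = ks.compute_metrics(preds_b, [NAMES[i] for i in y])
        assert rep_a.mAP == pytest.approx(rep_b.mAP)


FAST = dict(hidden_units=4, extra_fc_units=0, batch_size=16)


class TestCrossValidate:
    def test_subject_wise_folds_are_pure(self, rng):
        ds = tiny_dataset(rng, n_per_class=6)
        cfg = ks.MultitaskModelConfig(**FAST)
        rep = ks.cross_validate(ds, cfg, subject_wise=True, iterations=2)
        assert len(rep.folds) == 2  # one fold per subject
        assert rep.n == len(ds)

    def test_aggregate_is_mean_of_folds(self, rng):
        ds = tiny_dataset(rng, n_per_class=6)
        cfg = ks.MultitaskModelConfig(**FAST)
        rep = ks.cross_validate(ds, cfg, folds=3, iterations=2, seed=0)
        assert rep.accuracy == pytest.approx(
            np.mean([f.accuracy for f in rep.folds])
        )

    def test_five_folds_cover_every_sample_once(self, rng):
        ds = tiny_dataset(rng, n_per_class=50)  # 100 samples
        rng2 = np.random.default_rng(0)
        by_class = {}
        for i, l in enumerate(ds.class_labels):
            by_class.setdefault(l, []).append(i)
        parts = [[] for _ in range(5)]
        for idxs in by_class.values():
            idxs = np.array(idxs)
            perm = rng2.permutation(len(idxs))
            for k, i in enumerate(idxs[perm]):
                parts[k % 5].append(int(i))
        covered = sorted(i for p in parts for i in p)
        assert covered == list(range(100))

    def test_single_subject_subject_wise_rejected(self, rng):
        ds = tiny_dataset(rng, subjects=("S1",))
        cfg = ks.MultitaskModelConfig(**FAST)
        with pytest.raises(ConfigurationError):
            ks.cross_validate(ds, cfg, subject_wise=True)


class TestCompareModels:
    def test_classification_only_row_has_no_mae(self, rng):
        ds = tiny_dataset(rng, n_per_class=8)
        configs = {
            "single-task classification": ks.MultitaskModelConfig(
                alpha_i=0.0, **FAST),
            "multitask": ks.MultitaskModelConfig(**FAST),
        }
        table = ks.compare_models(configs, ds, seed=0, iterations=3)
        assert list(table["model"]) == list(configs)
        clf_row = table.iloc[0]
        assert np.isnan(clf_row["mae"]) and np.isnan(clf_row["mape"])
        assert np.isfinite(table.iloc[1]["mae"])

    def test_identical_configs_give_identical_rows(self, rng):
        ds = tiny_dataset(rng, n_per_class=8)
        cfgs = {"a": ks.MultitaskModelConfig(seed=4, **FAST),
                "b": ks.MultitaskModelConfig(seed=4, **FAST)}
        table = ks.compare_models(cfgs, ds, seed=0, iterations=3)
        a, b = table.iloc[0], table.iloc[1]
        for col in ["accuracy", "f1", "mAP", "mae", "mape"]:
            assert a[col] == b[col]

    def test_layer_unit_grid_yields_six_rows(self, rng):
        ds = tiny_dataset(rng, n_per_class=4)
        grid = {
            f"L{l}:{u}": ks.MultitaskModelConfig(
                lstm_layers=l, hidden_units=u, extra_fc_units=0, batch_size=8)
            for l in (1, 2) for u in (16, 32, 64)
        }
        table = ks.compare_models(grid, ds, seed=0, iterations=1)
        assert len(table) == 6
        assert list(table["model"]) == ["L1:16", "L1:32", "L1:64",
                                        "L2:16", "L2:32", "L2:64"]
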
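"""Metrics, splits, cross-validation and model-comparison reports.

Classification quality is measured by accuracy, macro-averaged F1 and mean
average precision (mAP, mean over classes of the area under the one-vs-rest
precision-recall curve); intensity estimation by mean absolute error (MAE)
and mean absolute percentage error (MAPE, zero-valued truths excluded with
the exclusion count reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, average_precision_score, f1_score

from .augmentation import AugmentedDataset
from .exceptions import ConfigurationError, EmptyInputError
from .model import MultitaskLSTM, MultitaskModelConfig, Prediction


@dataclass
class EvalReport:
    """One evaluation: classification and intensity metrics side by side."""

    accuracy: float
    f1: float
    mAP: float
    mae: Optional[float] = None
    mape: Optional[float] = None
    mape_per_class: dict = field(default_factory=dict)
    n: int = 0
    n_mape_excluded: int = 0
    folds: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "mAP": self.mAP,
            "mae": self.mae,
            "mape": self.mape,
            "mape_per_class": self.mape_per_class,
            "n": self.n,
            "n_mape_excluded": self.n_mape_excluded,
        }


def split_train_test(
    ds: AugmentedDataset, fraction: float = 0.8, seed: int = 0
) -> tuple[AugmentedDataset, AugmentedDataset]:
    """Seeded stratified split into disjoint, exhaustive train/test pools.

    A class with fewer than 2 samples triggers a warning and an
    unstratified fallback.
    """
    if not 0 < fraction < 1:
        raise ConfigurationError(f"fraction must be in (0, 1), got {fraction}")
    if len(ds) == 0:
        raise EmptyInputError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    labels = ds.class_labels
    by_class: dict = {}
    for i, l in enumerate(labels):
        by_class.setdefault(l, []).append(i)
    stratify = all(len(v) >= 2 for v in by_class.values())
    if not stratify:
        warnings.warn(
            "a class has fewer than 2 samples; falling back to an "
            "unstratified split",
            stacklevel=2,
        )
        by_class = {None: list(range(len(ds)))}
    train_idx: list[int] = []
    test_idx: list[int] = []
    for idxs in by_class.values():
        idxs = np.array(idxs)
        perm = rng.permutation(len(idxs))
        n_train = int(round(fraction * len(idxs)))
        n_train = min(max(n_train, 1), len(idxs) - 1) if len(idxs) >= 2 else n_train
        train_idx.extend(idxs[perm[:n_train]])
        test_idx.extend(idxs[perm[n_train:]])
    train_idx.sort()
    test_idx.sort()
    return (
        AugmentedDataset(samples=[ds.samples[i] for i in train_idx], seed=seed),
        AugmentedDataset(samples=[ds.samples[i] for i in test_idx], seed=seed),
    )


def compute_metrics(
    preds: Sequence[Prediction],
    true_classes: Sequence,
    true_intensity: Optional[Sequence[float]] = None,
    class_names: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Score aligned predictions against ground truth.

    ``true_classes`` may be label strings (matched through the predictions'
    class names) or integer indices.  AP per class uses the ranked
    probability scores; classes absent from the truth are skipped in mAP.
    """
    if len(preds) == 0:
        raise EmptyInputError("no predictions to score")
    if len(preds) != len(true_classes):
        raise ConfigurationError("predictions and truths differ in length")
    names = class_names or preds[0].class_names
    if names is not None and not isinstance(true_classes[0], (int, np.integer)):
        index = {n: i for i, n in enumerate(names)}
        y_true = np.array([index[c] for c in true_classes])
    else:
        y_true = np.asarray(true_classes, dtype=int)
    probs = np.stack([p.class_probs for p in preds])
    y_pred = probs.argmax(axis=1)

    acc = float(accuracy_score(y_true, y_pred))
    f1 = float(f1_score(y_true, y_pred, average="macro", zero_division=0))
    aps = []
    for c in range(probs.shape[1]):
        mask = y_true == c
        if mask.any():
            aps.append(average_precision_score(mask.astype(int), probs[:, c]))
    mAP = float(np.mean(aps)) if aps else 0.0

    mae = mape = None
    mape_per_class: dict = {}
    n_excluded = 0
    if true_intensity is not None:
        t = np.asarray(true_intensity, dtype=float)
        yhat = np.array([p.intensity for p in preds])
        mae = float(np.mean(np.abs(t - yhat)))
        nonzero = t != 0
        n_excluded = int((~nonzero).sum())
        if nonzero.any():
            mape = float(np.mean(np.abs((t[nonzero] - yhat[nonzero]) / t[nonzero])) * 100)
            for c in np.unique(y_true):
                m = nonzero & (y_true == c)
                if m.any():
                    label = names[c] if names is not None else int(c)
                    mape_per_class[label] = float(
                        np.mean(np.abs((t[m] - yhat[m]) / t[m])) * 100
                    )
    return EvalReport(
        accuracy=acc, f1=f1, mAP=mAP, mae=mae, mape=mape,
        mape_per_class=mape_per_class, n=len(preds), n_mape_excluded=n_excluded,
    )


def evaluate_model(results, test: AugmentedDataset) -> EvalReport:
    """Predict on a test dataset and score against its labels."""
    preds = results.predict(test)
    truths = test.class_labels
    intens = [s.intensity_label for s in test.samples]
    has_int = all(v is not None for v in intens)
    return compute_metrics(
        preds, truths, intens if has_int else None,
        class_names=results.class_names,
    )


def _aggregate(reports: list[EvalReport]) -> EvalReport:
    maes = [r.mae for r in reports if r.mae is not None]
    mapes = [r.mape for r in reports if r.mape is not None]
    agg = EvalReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        mAP=float(np.mean([r.mAP for r in reports])),
        mae=float(np.mean(maes)) if maes else None,
        mape=float(np.mean(mapes)) if mapes else None,
        n=int(sum(r.n for r in reports)),
        n_mape_excluded=int(sum(r.n_mape_excluded for r in reports)),
        folds=reports,
    )
    return agg


def cross_validate(
    ds: AugmentedDataset,
    cfg: MultitaskModelConfig,
    folds: int = 5,
    subject_wise: bool = False,
    iterations: Optional[int] = None,
    seed: int = 0,
) -> EvalReport:
    """K-fold or leave-one-subject-out cross-validation.

    Subject-wise mode holds out all samples of one subject per fold and
    averages fold reports, mirroring per-subject result averaging.
    """
    if subject_wise:
        subjects = ds.subjects
        if len(subjects) < 2:
            raise ConfigurationError("subject-wise CV needs >= 2 subjects")
        partitions = [
            [i for i, s in enumerate(ds.samples) if s.subject_id == subj]
            for subj in subjects
        ]
        if any(len(p) == 0 for p in partitions):
            raise ConfigurationError("a subject has zero samples")
    else:
        if folds < 2:
            raise ConfigurationError("need >= 2 folds")
        rng = np.random.default_rng(seed)
        by_class: dict = {}
        for i, l in enumerate(ds.class_labels):
            by_class.setdefault(l, []).append(i)
        partitions = [[] for _ in range(folds)]
        for idxs in by_class.values():
            idxs = np.array(idxs)
            perm = rng.permutation(len(idxs))
            for k, i in enumerate(idxs[perm]):
                partitions[k % folds].append(int(i))
    reports = []
    for held_out in partitions:
        held = set(held_out)
        train = AugmentedDataset(
            samples=[s for i, s in enumerate(ds.samples) if i not in held]
        )
        test = AugmentedDataset(samples=[ds.samples[i] for i in sorted(held)])
        model = MultitaskLSTM.from_dataset(train, config=cfg)
        res = model.fit(iterations=iterations)
        reports.append(evaluate_model(res, test))
    return _aggregate(reports)


def compare_models(
    configs: dict[str, MultitaskModelConfig],
    ds: AugmentedDataset,
    fraction: float = 0.8,
    seed: int = 0,
    iterations: Optional[int] = None,
) -> pd.DataFrame:
    """Train each configuration on the same split and tabulate the metrics.

    One row per configuration with accuracy / F1 / mAP / MAE / MAPE columns;
    regression metrics are absent (NaN) for classification-only
    configurations (alpha_i = 0) and classification metrics for
    regression-only ones.
    """
    if len(configs) < 2:
        raise ConfigurationError("compare_models needs >= 2 configurations")
    train, test = split_train_test(ds, fraction=fraction, seed=seed)
    rows = []
    for name, cfg in configs.items():
        model = MultitaskLSTM.from_dataset(train, config=cfg)
        res = model.fit(iterations=iterations)
        rep = evaluate_model(res, test)
        row = {"model": name, "accuracy": rep.accuracy, "f1": rep.f1,
               "mAP": rep.mAP, "mae": rep.mae, "mape": rep.mape}
        if cfg.alpha_i == 0:
            row["mae"] = row["mape"] = np.nan
        if cfg.alpha_c == 0:
            row["accuracy"] = row["f1"] = row["mAP"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["model", "accuracy", "f1", "mAP", "mae", "mape"])
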
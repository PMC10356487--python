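"""Multitask motion model: statsmodels-style Model and Results objects.

:class:`MultitaskLSTM` is built from training data (arrays or an
:class:`~kicksense.augmentation.AugmentedDataset`); ``fit()`` runs seeded
Adam on the weighted composite loss and returns a
:class:`MultitaskLSTMResults` carrying the trained weights, the per-iteration
training log, the feature normalizer, prediction methods and a text
``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .augmentation import AugmentedDataset
from .exceptions import ConfigurationError, EmptyInputError
from .network import (
    AdamOptimizer,
    LSTMNetwork,
    MultitaskModelConfig,
    build_model,
    classification_loss,
    composite_loss,
    regression_loss,
)

__all__ = [
    "MultitaskModelConfig",
    "MultitaskLSTM",
    "MultitaskLSTMResults",
    "Prediction",
    "build_model",
    "classification_loss",
    "regression_loss",
    "composite_loss",
]


@dataclass
class Prediction:
    """Joint output of one forward pass: class probabilities + intensity."""

    class_probs: np.ndarray
    intensity_raw: float
    intensity_mode: str = "count"
    class_names: Optional[tuple] = None

    @property
    def intensity(self) -> float:
        """Nonnegative intensity; integer-rounded in count mode."""
        if self.intensity_mode == "count":
            return float(max(0, int(round(self.intensity_raw))))
        return float(max(0.0, self.intensity_raw))

    @property
    def class_index(self) -> int:
        return int(np.argmax(self.class_probs))

    @property
    def class_label(self):
        if self.class_names is None:
            return self.class_index
        return self.class_names[self.class_index]


def _pad_stack(arrays: Sequence[np.ndarray]) -> np.ndarray:
    """Stack variable-length sequences, NaN-padding shorter ones in front.

    Augmentation produces half- and quarter-length variants; padding rows
    are NaN markers that the normalizer maps to exactly zero, so the LSTM
    sees a silent prefix before the real rows.
    """
    T = max(a.shape[0] for a in arrays)
    m = arrays[0].shape[1]
    out = np.full((len(arrays), T, m), np.nan)
    for i, a in enumerate(arrays):
        out[i, T - a.shape[0]:] = a
    return out


def _stack_dataset(ds: AugmentedDataset, class_names=None):
    X = _pad_stack([s.values for s in ds.samples])
    labels = [s.class_label for s in ds.samples]
    if class_names is None:
        class_names = tuple(sorted({l for l in labels if l is not None}))
    index = {name: i for i, name in enumerate(class_names)}
    y_class = np.array([index.get(l, -1) for l in labels], dtype=int)
    y_int = np.array(
        [0.0 if s.intensity_label is None else float(s.intensity_label)
         for s in ds.samples]
    )
    return X, y_class, y_int, class_names


class MultitaskLSTM:
    """The multitask LSTM model bound to its training data.

    Parameters
    ----------
    X : ndarray, shape (n_samples, seq_len, n_channels)
        Feature-row sequences (e.g. stacked spectral feature matrices).
    y_class : ndarray of int, shape (n_samples,)
        Class indices in ``range(config.num_classes)``.
    y_intensity : ndarray of float, shape (n_samples,)
        Intensity targets (counts or completion rates).
    config : MultitaskModelConfig, optional
    class_names : sequence of str, optional
        Display names aligned with class indices.
    """

    def __init__(self, X, y_class, y_intensity=None,
                 config: Optional[MultitaskModelConfig] = None,
                 class_names: Optional[Sequence[str]] = None):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 3:
            raise ConfigurationError(
                f"X must be (n_samples, seq_len, n_channels), got shape {self.X.shape}"
            )
        if self.X.shape[0] == 0:
            raise EmptyInputError("empty training set")
        self.y_class = np.asarray(y_class, dtype=int)
        self.y_intensity = (
            np.zeros(self.X.shape[0])
            if y_intensity is None
            else np.asarray(y_intensity, dtype=float)
        )
        n_cls = int(self.y_class.max()) + 1 if len(self.y_class) else 2
        if config is None:
            config = MultitaskModelConfig(num_classes=max(2, n_cls))
        self.config = config
        self.class_names = tuple(class_names) if class_names is not None else None
        # per-channel z-score fit on the training data only; NaN rows are
        # sequence padding and are excluded from the statistics
        flat = self.X.reshape(-1, self.X.shape[2])
        self._mean = np.nanmean(flat, axis=0)
        sd = np.nanstd(flat, axis=0)
        self._std = np.where(sd > 0, sd, 1.0)

    @classmethod
    def from_dataset(cls, ds: AugmentedDataset,
                     config: Optional[MultitaskModelConfig] = None,
                     class_names: Optional[Sequence[str]] = None) -> "MultitaskLSTM":
        """Build the model from a labeled feature dataset."""
        if len(ds) == 0:
            raise EmptyInputError("empty dataset")
        X, y_class, y_int, names = _stack_dataset(ds, class_names)
        if (y_class < 0).any():
            raise ConfigurationError("dataset contains unlabeled samples")
        if config is None:
            config = MultitaskModelConfig(num_classes=len(names))
        return cls(X, y_class, y_int, config=config, class_names=names)

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return np.nan_to_num((X - self._mean) / self._std, nan=0.0)

    def fit(self, iterations: Optional[int] = None) -> "MultitaskLSTMResults":
        """Train with seeded Adam; returns a results object with the log.

        The log records Lc, Li and the total penalized loss at every
        iteration.  A non-finite loss aborts with a diagnostic.
        """
        cfg = self.config
        n_iter = cfg.iterations if iterations is None else int(iterations)
        rng = np.random.default_rng(cfg.seed)
        dropout_rng = np.random.default_rng((cfg.seed + 1) % (2 ** 31))
        net = LSTMNetwork(cfg, input_dim=self.X.shape[2], rng=rng)
        opt = AdamOptimizer(net, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        Xn = self._normalize(self.X)
        n = Xn.shape[0]
        bs = min(cfg.batch_size, n)
        log = {"iteration": [], "lc": [], "li": [], "loss": []}
        for it in range(n_iter):
            idx = rng.choice(n, size=bs, replace=False)
            cache = net.forward(Xn[idx], train=True, dropout_rng=dropout_rng)
            parts = net.loss(cache, self.y_class[idx], self.y_intensity[idx])
            if not np.isfinite(parts["loss"]):
                raise RuntimeError(
                    f"non-finite loss at iteration {it}: lc={parts['lc']}, "
                    f"li={parts['li']} — lower the learning rate or check inputs"
                )
            grads = net.backward(cache, self.y_class[idx], self.y_intensity[idx])
            opt.step(grads)
            log["iteration"].append(it)
            log["lc"].append(parts["lc"])
            log["li"].append(parts["li"])
            log["loss"].append(parts["loss"])
        return MultitaskLSTMResults(
            model=self, network=net, training_log=pd.DataFrame(log)
        )


class MultitaskLSTMResults:
    """Fitted multitask LSTM: weights, training log, prediction, summary."""

    def __init__(self, model: MultitaskLSTM, network: LSTMNetwork,
                 training_log: pd.DataFrame):
        self.model = model
        self.network = network
        self.training_log = training_log
        self.config = model.config
        self.class_names = model.class_names

    # ------------------------------------------------------------------ #

    def _as_array(self, data) -> np.ndarray:
        if isinstance(data, AugmentedDataset):
            return _pad_stack([s.values for s in data.samples])
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
        return arr

    def predict(self, data) -> list[Prediction]:
        """One shared forward pass per sample; both heads' outputs together."""
        X = self.model._normalize(self._as_array(data))
        probs, intensity = self.network.predict(X)
        return [
            Prediction(
                class_probs=probs[i],
                intensity_raw=float(intensity[i]),
                intensity_mode=self.config.intensity_mode,
                class_names=self.class_names,
            )
            for i in range(X.shape[0])
        ]

    def predict_arrays(self, data) -> tuple[np.ndarray, np.ndarray]:
        """(probs, intensity) arrays — convenience for metric computation."""
        X = self.model._normalize(self._as_array(data))
        return self.network.predict(X)

    @property
    def final_loss(self) -> float:
        return float(self.training_log["loss"].iloc[-1])

    @property
    def n_params(self) -> int:
        return self.network.n_params

    # ------------------------------------------------------------------ #

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Multitask LSTM results",
            "=" * 46,
            f"{'LSTM layers':<28}{cfg.lstm_layers}",
            f"{'Hidden units':<28}{cfg.hidden_units}",
            f"{'Extra FC units (regress.)':<28}{cfg.extra_fc_units}",
            f"{'Classes':<28}{cfg.num_classes}",
            f"{'Trainable parameters':<28}{self.n_params}",
            f"{'Iterations run':<28}{len(self.training_log)}",
            f"{'alpha_c / alpha_i':<28}{cfg.alpha_c} / {cfg.alpha_i}",
            f"{'Intensity mode':<28}{cfg.intensity_mode}",
            f"{'Final Lc':<28}{self.training_log['lc'].iloc[-1]:.6f}",
            f"{'Final Li':<28}{self.training_log['li'].iloc[-1]:.6f}",
            f"{'Final total loss':<28}{self.final_loss:.6f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Loss curves over iterations (Lc, Li, total)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.training_log["iteration"]
        ax.plot(t, self.training_log["lc"], label="classification loss")
        ax.plot(t, self.training_log["li"], label="intensity loss")
        ax.plot(t, self.training_log["loss"], label="total loss")
        ax.set_xlabel("iteration")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    # ------------------------------------------------------------------ #

    def save(self, directory) -> None:
        """Write weights, config snapshot, normalizer and training log."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.network.params)
        cfg = dict(self.config.__dict__)
        with open(d / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
        meta = {
            "mean": self.model._mean.tolist(),
            "std": self.model._std.tolist(),
            "class_names": list(self.class_names) if self.class_names else None,
            "input_dim": self.network.input_dim,
        }
        with open(d / "normalizer.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        self.training_log.to_csv(d / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "MultitaskLSTMResults":
        d = Path(directory)
        with open(d / "config.yaml") as fh:
            cfg = MultitaskModelConfig(**yaml.safe_load(fh))
        with open(d / "normalizer.json") as fh:
            meta = json.load(fh)
        net = LSTMNetwork(cfg, input_dim=int(meta["input_dim"]))
        with np.load(d / "weights.npz") as z:
            for name in net.params:
                net.params[name] = z[name]
        log = pd.read_csv(d / "training_log.csv")
        # rebuild a shell model carrying only the normalizer and names
        shell = MultitaskLSTM.__new__(MultitaskLSTM)
        shell.config = cfg
        shell.class_names = tuple(meta["class_names"]) if meta["class_names"] else None
        shell._mean = np.asarray(meta["mean"], dtype=float)
        shell._std = np.asarray(meta["std"], dtype=float)
        shell.X = np.zeros((1, 1, int(meta["input_dim"])))
        return cls(model=shell, network=net, training_log=log)
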
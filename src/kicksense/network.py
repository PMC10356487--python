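"""NumPy implementation of the shared-encoder multitask LSTM.

One or two stacked LSTM layers encode the feature-row sequence of a motion
window; the final hidden state feeds two non-overlapping heads: a fully
connected softmax layer producing class probabilities, and a regression
branch (optional ReLU fully connected layer with dropout, then a scalar
output) estimating motion intensity.  Training minimizes

    L = alpha_c * Lc + alpha_i * Li + reg_constant * sum_w (|w| + w^2)

with Lc the cross-entropy of Eq.-style softmax classification, Li the mean
squared error of the intensity estimate, and an elastic L1+L2 penalty on the
weight matrices.  Gradients are derived analytically (backpropagation
through time) and checked numerically in the test suite; optimization is
Adam with decoupled weight decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError

_EPS_LOG = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MultitaskModelConfig:
    """Architecture and optimization settings of the multitask LSTM.

    Defaults follow the tuned operating point: dropout 0.5 on the
    regression branch, learning rate 2e-4, weight decay 1e-5,
    regularization constant 2e-4, batch size 300, and task weights
    alpha_c = 1 with alpha_i = 0.001 in count mode (intensity losses start
    around three orders of magnitude above the classification loss) or
    alpha_i = 0.1 in completion-rate mode.
    """

    lstm_layers: int = 1
    hidden_units: int = 32
    extra_fc_units: int = 32
    dropout_rate: float = 0.5
    num_classes: int = 2
    learning_rate: float = 2e-4
    weight_decay: float = 1e-5
    reg_constant: float = 2e-4
    batch_size: int = 300
    iterations: int = 14_000
    alpha_c: float = 1.0
    alpha_i: Optional[float] = None
    intensity_mode: str = "count"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lstm_layers not in (1, 2):
            raise ConfigurationError(f"lstm_layers must be 1 or 2, got {self.lstm_layers}")
        if self.hidden_units < 1:
            raise ConfigurationError(f"hidden_units must be >= 1, got {self.hidden_units}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(
                f"dropout_rate must be in [0, 1), got {self.dropout_rate}"
            )
        if self.intensity_mode not in ("count", "completion_rate"):
            raise ConfigurationError(
                f"intensity_mode must be 'count' or 'completion_rate', "
                f"got {self.intensity_mode!r}"
            )
        if self.alpha_i is None:
            self.alpha_i = 0.001 if self.intensity_mode == "count" else 0.1
        if self.alpha_c < 0 or self.alpha_i < 0:
            raise ConfigurationError("alpha_c and alpha_i must be nonnegative")
        if self.num_classes < 2:
            raise ConfigurationError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.extra_fc_units < 0:
            raise ConfigurationError("extra_fc_units must be >= 0")


def classification_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy: -(1/N) sum_i sum_c 1[y_i = c] log p_ic.

    Probabilities are clamped at 1e-12 inside the log so a confident wrong
    prediction yields a finite loss.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape[0] != labels.shape[0]:
        raise ConfigurationError("batch sizes of probs and labels differ")
    p_true = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(p_true, _EPS_LOG, None))))


def regression_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error (1/N) sum_i (y_i - yhat_i)^2."""
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if pred.shape != target.shape:
        raise ConfigurationError("batch sizes of pred and target differ")
    return float(np.mean((target - pred) ** 2))


def composite_loss(lc: float, li: float, cfg: MultitaskModelConfig) -> float:
    """Weighted total loss L = alpha_c * Lc + alpha_i * Li."""
    return cfg.alpha_c * lc + cfg.alpha_i * li


class LSTMNetwork:
    """Weights + forward/backward passes of the multitask LSTM."""

    def __init__(self, cfg: MultitaskModelConfig, input_dim: int,
                 rng: Optional[np.random.Generator] = None):
        self.cfg = cfg
        self.input_dim = int(input_dim)
        if self.input_dim < 1:
            raise ConfigurationError(f"input_dim must be >= 1, got {input_dim}")
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        H, C, F = cfg.hidden_units, cfg.num_classes, cfg.extra_fc_units
        self.params: dict[str, np.ndarray] = {}

        def init(shape, fan_in):
            return rng.uniform(-1, 1, size=shape) / np.sqrt(fan_in)

        in_dim = self.input_dim
        for l in range(cfg.lstm_layers):
            self.params[f"W{l}"] = init((in_dim, 4 * H), in_dim)
            self.params[f"U{l}"] = init((H, 4 * H), H)
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias: remember by default
            self.params[f"b{l}"] = b
            in_dim = H
        self.params["Wc"] = init((H, C), H)
        self.params["bc"] = np.zeros(C)
        if F > 0:
            self.params["Wf"] = init((H, F), H)
            self.params["bf"] = np.zeros(F)
            self.params["Wr"] = init((F, 1), F)
        else:
            self.params["Wr"] = init((H, 1), H)
        self.params["br"] = np.zeros(1)
        # single-task degeneracy: a zero-weighted head is frozen entirely
        frozen = (["Wc", "bc"] if cfg.alpha_c == 0 else []) + (
            ["Wf", "bf", "Wr", "br"] if cfg.alpha_i == 0 else []
        )
        self.frozen: frozenset = frozenset(n for n in frozen if n in self.params)

    # ------------------------------------------------------------------ #

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _is_weight(self, name: str) -> bool:
        return name[0] in ("W", "U")

    def _penalized(self, name: str) -> bool:
        return self._is_weight(name) and name not in self.frozen

    def penalty(self) -> float:
        """Elastic L1 + L2 penalty on unfrozen weight matrices."""
        r = self.cfg.reg_constant
        if r == 0:
            return 0.0
        return float(
            r * sum(np.abs(w).sum() + (w ** 2).sum()
                    for n, w in self.params.items() if self._penalized(n))
        )

    # ------------------------------------------------------------------ #

    def forward(self, X: np.ndarray, train: bool = False,
                dropout_rng: Optional[np.random.Generator] = None) -> dict:
        """Run the shared encoder once and both heads on its output.

        Returns a cache dict with 'probs' (B, C), 'intensity' (B,), the
        encoder's final hidden state, and everything backward() needs.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        B, T, m = X.shape
        if m != self.input_dim:
            raise ConfigurationError(
                f"input has {m} channels, network expects {self.input_dim}"
            )
        cfg, H = self.cfg, self.cfg.hidden_units
        layer_caches = []
        inp = X
        for l in range(cfg.lstm_layers):
            W, U, b = self.params[f"W{l}"], self.params[f"U{l}"], self.params[f"b{l}"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            steps = []
            outs = np.empty((B, T, H))
            # input projection of all timesteps in one GEMM
            Zx = inp.reshape(B * T, -1) @ W + b
            Zx = Zx.reshape(B, T, 4 * H)
            for t in range(T):
                x_t = inp[:, t]
                z = Zx[:, t] + h @ U
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H :])
                c_prev, h_prev = c, h
                c = f * c_prev + i * g
                tc = np.tanh(c)
                h = o * tc
                outs[:, t] = h
                steps.append((x_t, h_prev, c_prev, i, f, g, o, tc))
            layer_caches.append({"steps": steps, "input": inp})
            inp = outs
        h_last = inp[:, -1]

        logits = h_last @ self.params["Wc"] + self.params["bc"]
        probs = softmax(logits)

        cache: dict = {
            "X": X, "layers": layer_caches, "h_last": h_last,
            "encoded": inp, "probs": probs, "B": B, "T": T,
        }
        if cfg.extra_fc_units > 0:
            pre = h_last @ self.params["Wf"] + self.params["bf"]
            a = np.maximum(pre, 0.0)
            if train and cfg.dropout_rate > 0:
                if dropout_rng is None:
                    dropout_rng = np.random.default_rng(cfg.seed)
                keep = 1.0 - cfg.dropout_rate
                mask = (dropout_rng.random(a.shape) < keep) / keep
            else:
                mask = np.ones_like(a)
            ad = a * mask
            yhat = (ad @ self.params["Wr"]).ravel() + self.params["br"][0]
            cache.update({"pre": pre, "a": a, "mask": mask, "ad": ad})
        else:
            yhat = (h_last @ self.params["Wr"]).ravel() + self.params["br"][0]
        cache["intensity"] = yhat
        return cache

    def loss(self, cache: dict, y_class: np.ndarray, y_int: np.ndarray) -> dict:
        lc = classification_loss(cache["probs"], y_class)
        li = regression_loss(cache["intensity"], y_int)
        total = composite_loss(lc, li, self.cfg) + self.penalty()
        return {"lc": lc, "li": li, "loss": total}

    def backward(self, cache: dict, y_class: np.ndarray,
                 y_int: np.ndarray) -> dict[str, np.ndarray]:
        """Analytic gradients of the penalized composite loss."""
        cfg = self.cfg
        H = cfg.hidden_units
        B = cache["B"]
        grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        h_last = cache["h_last"]
        dh_last = np.zeros_like(h_last)

        if cfg.alpha_c > 0:
            onehot = np.zeros_like(cache["probs"])
            onehot[np.arange(B), np.asarray(y_class, dtype=int)] = 1.0
            dlogits = cfg.alpha_c * (cache["probs"] - onehot) / B
            grads["Wc"] = h_last.T @ dlogits
            grads["bc"] = dlogits.sum(axis=0)
            dh_last += dlogits @ self.params["Wc"].T

        if cfg.alpha_i > 0:
            yhat = cache["intensity"]
            dy = cfg.alpha_i * 2.0 * (yhat - np.asarray(y_int, dtype=float)) / B
            if cfg.extra_fc_units > 0:
                ad = cache["ad"]
                grads["Wr"] = ad.T @ dy[:, None]
                grads["br"] = np.array([dy.sum()])
                dad = dy[:, None] @ self.params["Wr"].T
                da = dad * cache["mask"]
                dpre = da * (cache["pre"] > 0)
                grads["Wf"] = h_last.T @ dpre
                grads["bf"] = dpre.sum(axis=0)
                dh_last += dpre @ self.params["Wf"].T
            else:
                grads["Wr"] = h_last.T @ dy[:, None]
                grads["br"] = np.array([dy.sum()])
                dh_last += dy[:, None] @ self.params["Wr"].T

        # backprop through time, top layer down
        T = cache["T"]
        dH = np.zeros((B, T, H))
        dH[:, -1] = dh_last
        for l in range(cfg.lstm_layers - 1, -1, -1):
            lc_ = cache["layers"][l]
            W, U = self.params[f"W{l}"], self.params[f"U{l}"]
            dU = np.zeros_like(U)
            dZ = np.empty((B, T, 4 * H))
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                _, h_prev, c_prev, i, f, g, o, tc = lc_["steps"][t]
                dh = dH[:, t] + dh_next
                do = dh * tc
                dc = dc_next + dh * o * (1.0 - tc ** 2)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dz = np.hstack([
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g ** 2),
                    do * o * (1 - o),
                ])
                dZ[:, t] = dz
                dU += h_prev.T @ dz
                dh_next = dz @ U.T
            inp = lc_["input"]
            in_dim = inp.shape[2]
            dZ_flat = dZ.reshape(B * T, 4 * H)
            grads[f"W{l}"] = inp.reshape(B * T, in_dim).T @ dZ_flat
            grads[f"U{l}"] = dU
            grads[f"b{l}"] = dZ_flat.sum(axis=0)
            # upstream gradient of the layer below, in one GEMM
            dH = (dZ_flat @ W.T).reshape(B, T, in_dim)

        r = cfg.reg_constant
        if r > 0:
            for n, w in self.params.items():
                if self._penalized(n):
                    grads[n] += r * (np.sign(w) + 2.0 * w)
        for n in self.frozen:
            grads[n][...] = 0.0
        return grads

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inference forward pass (dropout disabled): (probs, intensity)."""
        cache = self.forward(X, train=False)
        return cache["probs"], cache["intensity"]


def build_model(cfg: MultitaskModelConfig, input_shape: tuple[int, int]) -> LSTMNetwork:
    """Construct an untrained network for (sequence_len, n_channels) inputs."""
    _, m = input_shape
    return LSTMNetwork(cfg, input_dim=m, rng=np.random.default_rng(cfg.seed))


class AdamOptimizer:
    """Adam with decoupled weight decay on the weight matrices."""

    def __init__(self, net: LSTMNetwork, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {n: np.zeros_like(p) for n, p in net.params.items()}
        self.v = {n: np.zeros_like(p) for n, p in net.params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for n, p in self.net.params.items():
            if n in self.net.frozen:
                continue
            g = grads[n]
            self.m[n] = b1 * self.m[n] + (1 - b1) * g
            self.v[n] = b2 * self.v[n] + (1 - b2) * g * g
            mhat = self.m[n] / (1 - b1 ** self.t)
            vhat = self.v[n] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd > 0 and self.net._is_weight(n):
                p -= self.lr * self.wd * p
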
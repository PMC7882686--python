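"""The 1-D convolutional classifier and the classical baselines.

The network mirrors the architecture used for transporter prediction: five
stride-2 1-D convolutional layers (32 filters each) with batch normalization
after every convolution, two max-pooling layers, and two fully connected
layers ending in a single sigmoid unit trained with Adam and binary
cross-entropy under a step-decayed learning rate (1e-3, divided by 10 every
100 epochs). A smaller four-convolution preset (16/16/32/32 filters, fully
connected 13 -> 2 softmax) is provided for small datasets.

Everything is plain numpy: forward, backward, and Adam are implemented here,
which keeps training single-threaded and bit-reproducible under a seed.
Baselines (SVM / naive Bayes / random forest / multilayer perceptron) come
from scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the 1-D convolutional classifier.

    ``fc_sizes`` includes the output layer; ``head`` selects between a
    1-unit sigmoid output and a 2-unit softmax output. ``pool_positions``
    are 1-based indices of conv layers followed by a max-pool.
    """

    input_dim: int
    filters: tuple[int, ...] = (32, 32, 32, 32, 32)
    kernel_size: int = 3
    conv_stride: int = 2
    pool_positions: tuple[int, ...] = (2, 4)
    pool_size: int = 2
    pool_stride: int = 2
    fc_sizes: tuple[int, ...] = (64, 1)
    head: str = "sigmoid1"
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.input_dim < self.kernel_size:
            raise ValueError("input_dim must be at least kernel_size")
        if self.head not in ("sigmoid1", "softmax2"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.head == "sigmoid1" and self.fc_sizes[-1] != 1:
            raise ValueError("sigmoid1 head requires a 1-unit output layer")
        if self.head == "softmax2" and self.fc_sizes[-1] != 2:
            raise ValueError("softmax2 head requires a 2-unit output layer")
        bad = [p for p in self.pool_positions if not 1 <= p <= len(self.filters)]
        if bad:
            raise ValueError(f"pool positions {bad} outside 1..{len(self.filters)}")

    @property
    def n_conv(self) -> int:
        return len(self.filters)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule: Adam + binary cross-entropy with step decay."""

    epochs: int = 1000
    lr0: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be in (0, 1]")

    def learning_rate_at(self, epoch: int) -> float:
        """Learning rate in force during ``epoch`` (0-based)."""
        return self.lr0 * self.lr_decay_factor ** (epoch // self.lr_decay_every)


def default_dcnn(input_dim: int) -> ModelConfig:
    """The main preset: 5 conv layers x 32 filters, 2 pools, FC 64 -> 1."""
    return ModelConfig(input_dim=input_dim)


def small_dcnn(input_dim: int) -> ModelConfig:
    """The compact preset for small datasets: 4 convs (16,16,32,32), FC 13 -> 2."""
    return ModelConfig(
        input_dim=input_dim,
        filters=(16, 16, 32, 32),
        fc_sizes=(13, 2),
        head="softmax2",
    )


def conv_output_length(L: int, F: int, S: int) -> int:
    """Output length of a valid 1-D convolution: floor((L-F)/S) + 1.

    The +1 counts the window anchored at position 0, which the bare ratio
    (L-F)/S misses and which may otherwise be fractional.
    """
    if F < 1 or S < 1:
        raise ValueError("filter length and stride must be >= 1")
    if L < F:
        raise ValueError(f"input length {L} shorter than filter {F}")
    return (L - F) // S + 1


# ---------------------------------------------------------------------------
# layers (numpy, NCL layout)


class _Conv1D:
    def __init__(self, c_in, c_out, k, stride, padding, rng):
        scale = np.sqrt(2.0 / (c_in * k))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.dw, self.db = np.zeros_like(self.w), np.zeros_like(self.b)
        self.k, self.stride, self.padding = k, stride, padding

    def out_len(self, L):
        if self.padding == "same":
            return -(-L // self.stride)  # ceil
        return conv_output_length(L, self.k, self.stride)

    def _pad(self, L):
        if self.padding != "same":
            return 0, 0
        total = max((self.out_len(L) - 1) * self.stride + self.k - L, 0)
        return total // 2, total - total // 2

    def forward(self, x, train):
        N, C, L = x.shape
        pl, pr = self._pad(L)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        lout = self.out_len(L)
        idx = (np.arange(lout) * self.stride)[:, None] + np.arange(self.k)[None, :]
        xw = xp[:, :, idx]  # (N, C, lout, k)
        self._cache = (xw, idx, xp.shape, pl, L)
        return np.einsum("nctf,ocf->not", xw, self.w) + self.b[None, :, None]

    def backward(self, dy):
        xw, idx, xpshape, pl, L = self._cache
        self.dw = np.einsum("not,nctf->ocf", dy, xw)
        self.db = dy.sum(axis=(0, 2))
        dxw = np.einsum("not,ocf->nctf", dy, self.w)
        dxp = np.zeros(xpshape)
        for f in range(self.k):
            dxp[:, :, idx[:, f]] += dxw[:, :, :, f]
        return dxp[:, :, pl : pl + L]

    @property
    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class _BatchNorm1D:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma, self.dbeta = np.zeros_like(self.gamma), np.zeros_like(self.beta)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std, x.shape)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy):
        xhat, std, shape = self._cache
        n = shape[0] * shape[2]
        self.dgamma = (dy * xhat).sum(axis=(0, 2))
        self.dbeta = dy.sum(axis=(0, 2))
        g = self.gamma[None, :, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / n
        ) / std[None, :, None]
        return dx

    @property
    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    params = []


class _MaxPool1D:
    def __init__(self, size, stride):
        self.size, self.stride = size, stride

    def forward(self, x, train):
        N, C, L = x.shape
        lout = conv_output_length(L, self.size, self.stride)
        idx = (np.arange(lout) * self.stride)[:, None] + np.arange(self.size)[None, :]
        xw = x[:, :, idx]  # (N, C, lout, size)
        self._arg = xw.argmax(axis=3)
        self._cache = (idx, x.shape)
        return xw.max(axis=3)

    def backward(self, dy):
        idx, shape = self._cache
        dx = np.zeros(shape)
        N, C, lout = dy.shape
        n_i, c_i, t_i = np.meshgrid(
            np.arange(N), np.arange(C), np.arange(lout), indexing="ij"
        )
        src = idx[t_i, self._arg]
        np.add.at(dx, (n_i, c_i, src), dy)
        return dx

    params = []


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    params = []


class _Dense:
    def __init__(self, d_in, d_out, rng):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.b = np.zeros(d_out)
        self.dw, self.db = np.zeros_like(self.w), np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.dw = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.w

    @property
    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class _ReLUFlat(_ReLU):
    pass


def _build_layers(mc: ModelConfig, rng: np.random.Generator) -> list:
    layers: list = []
    c, L = 1, mc.input_dim
    for i, f in enumerate(mc.filters, start=1):
        conv = _Conv1D(c, f, mc.kernel_size, mc.conv_stride, mc.padding, rng)
        layers += [conv, _BatchNorm1D(f), _ReLU()]
        L, c = conv.out_len(L), f
        if i in mc.pool_positions:
            if L < mc.pool_size:
                raise ValueError(
                    f"feature map length {L} too short for pool after conv {i}"
                )
            layers.append(_MaxPool1D(mc.pool_size, mc.pool_stride))
            L = conv_output_length(L, mc.pool_size, mc.pool_stride)
    layers.append(_Flatten())
    d = c * L
    for j, width in enumerate(mc.fc_sizes):
        layers.append(_Dense(d, width, rng))
        if j < len(mc.fc_sizes) - 1:
            layers.append(_ReLUFlat())
        d = width
    return layers


def _forward(layers, x, train):
    h = x[:, None, :]  # add channel axis
    for layer in layers:
        h = layer.forward(h, train)
    return h  # logits (N, 1) or (N, 2)


def _loss_and_grad(logits, y, head):
    """Mean cross-entropy and d(loss)/d(logits); numerically stable."""
    n = len(y)
    if head == "sigmoid1":
        z = logits[:, 0]
        p = np.where(z >= 0, 1 / (1 + np.exp(-np.abs(z))), np.exp(z) / (1 + np.exp(z)))
        # log(1+exp(-|z|)) form of BCE-with-logits
        loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
        dz = ((p - y) / n)[:, None]
        return loss, dz, p
    zmax = logits.max(axis=1, keepdims=True)
    ez = np.exp(logits - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)
    loss = -np.mean(np.log(probs[np.arange(n), y.astype(int)] + 1e-12))
    d = probs.copy()
    d[np.arange(n), y.astype(int)] -= 1
    return loss, d / n, probs[:, 1]


class _Adam:
    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, layers, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(layers):
            for name, p, g in layer.params:
                key = (li, name)
                m = self.m.get(key, np.zeros_like(p))
                v = self.v.get(key, np.zeros_like(p))
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self.m[key], self.v[key] = m, v
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainState:
    """A fitted network plus its full training history."""

    model_config: ModelConfig
    train_config: TrainConfig
    layers: list = field(repr=False)
    history: list[dict] = field(default_factory=list, repr=False)
    reducer: object | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.model_config.input_dim:
            raise ValueError(
                f"input width {X.shape[1]} != model input_dim "
                f"{self.model_config.input_dim}"
            )
        logits = _forward(self.layers, X, train=False)
        _, _, p = _loss_and_grad(
            logits, np.zeros(len(X)), self.model_config.head
        )
        return p

    def predict_label(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def predict_proba(state: TrainState, X: np.ndarray) -> np.ndarray:
    """Probability of the positive class for each row of X."""
    return state.predict_proba(X)


def predict_label(state: TrainState, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: probability >= threshold (argmax for the softmax head)."""
    return state.predict_label(X, threshold)


def train_dcnn(
    X: np.ndarray,
    y: np.ndarray,
    mc: ModelConfig | None = None,
    tc: TrainConfig | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainState:
    """Train the convolutional classifier with Adam + cross-entropy.

    The learning rate follows the step-decay schedule of ``tc``; one history
    record per epoch carries lr, training loss/accuracy and, when a
    validation split is given, validation loss/accuracy. Fully deterministic
    given ``tc.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    y = y.astype(float)
    mc = mc or default_dcnn(X.shape[1])
    tc = tc or TrainConfig()
    if X.shape[1] != mc.input_dim:
        raise ValueError(f"X width {X.shape[1]} != input_dim {mc.input_dim}")

    rng = np.random.default_rng(tc.seed)
    layers = _build_layers(mc, rng)
    opt = _Adam()
    state = TrainState(mc, tc, layers)
    n = len(X)
    for epoch in range(tc.epochs):
        lr = tc.learning_rate_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            batch = order[start : start + tc.batch_size]
            if len(batch) < 2:
                continue  # batchnorm needs more than one sample
            logits = _forward(layers, X[batch], train=True)
            loss, dlogits, _ = _loss_and_grad(logits, y[batch], mc.head)
            grad = dlogits
            for layer in reversed(layers):
                grad = layer.backward(grad)
            opt.step(layers, lr)
            losses.append(loss)
        record = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}
        p_train = state.predict_proba(X)
        record["train_acc"] = float(np.mean((p_train >= 0.5) == (y == 1)))
        if X_val is not None:
            logits_v = _forward(layers, np.asarray(X_val, dtype=float), train=False)
            vloss, _, pv = _loss_and_grad(
                logits_v, np.asarray(y_val, dtype=float), mc.head
            )
            record["val_loss"] = float(vloss)
            record["val_acc"] = float(np.mean((pv >= 0.5) == (np.asarray(y_val) == 1)))
        state.history.append(record)
    return state


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Persist config as JSON and weights as an .npz alongside it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = {
        "model_config": asdict(state.model_config),
        "train_config": asdict(state.train_config),
        "history": state.history,
    }
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=1))
    arrays = {}
    for li, layer in enumerate(state.layers):
        for name, p, *_ in getattr(layer, "params", []):
            arrays[f"{li}.{name}"] = p
        if isinstance(layer, _BatchNorm1D):
            arrays[f"{li}.run_mean"] = layer.run_mean
            arrays[f"{li}.run_var"] = layer.run_var
    if state.reducer is not None:
        arrays["reducer.mean"] = state.reducer.mean
        arrays["reducer.components"] = state.reducer.components
    np.savez(path.with_suffix(".npz"), **arrays)


def load_checkpoint(path: str | Path) -> TrainState:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    mcd = cfg["model_config"]
    for key in ("filters", "pool_positions", "fc_sizes"):
        mcd[key] = tuple(mcd[key])
    mc = ModelConfig(**mcd)
    tc = TrainConfig(**cfg["train_config"])
    layers = _build_layers(mc, np.random.default_rng(0))
    data = np.load(path.with_suffix(".npz"))
    for li, layer in enumerate(layers):
        for name, p, *_ in getattr(layer, "params", []):
            p[...] = data[f"{li}.{name}"]
        if isinstance(layer, _BatchNorm1D):
            layer.run_mean = data[f"{li}.run_mean"]
            layer.run_var = data[f"{li}.run_var"]
    state = TrainState(mc, tc, layers, history=cfg["history"])
    if "reducer.mean" in data:
        from .features import Reducer

        state.reducer = Reducer(
            mean=data["reducer.mean"],
            components=data["reducer.components"],
            d_out=data["reducer.components"].shape[0],
        )
    return state


# ---------------------------------------------------------------------------
# baselines


class BaselineModel:
    """Thin wrapper giving scikit-learn baselines a common score contract."""

    def __init__(self, kind: str, estimator):
        self.kind = kind
        self.estimator = estimator

    def predict_label(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def predict_proba(self, X) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        # map a decision score through the logistic for a (0,1) ranking score
        from .features import sigmoid_scale

        return np.asarray(sigmoid_scale(est.decision_function(X)))

    def decision_score(self, X) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X))
        return est.predict_proba(X)[:, 1]


def train_baseline(X, y, kind: str, params: dict | None = None, seed: int = 0) -> BaselineModel:
    """Fit one of the classical baselines: svm, nb, rf, or ann.

    The SVM default matches the reference configuration: RBF kernel with
    penalty C = 1e5 and gamma = 'auto' (1 / n_features).
    """
    params = dict(params or {})
    if kind == "svm":
        est = SVC(kernel="rbf", C=1e5, gamma="auto", random_state=seed, **params)
    elif kind == "nb":
        est = GaussianNB(**params)
    elif kind == "rf":
        est = RandomForestClassifier(random_state=seed, **params)
    elif kind == "ann":
        params.setdefault("hidden_layer_sizes", (64,))
        params.setdefault("max_iter", 500)
        est = MLPClassifier(random_state=seed, **params)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    est.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))
    return BaselineModel(kind, est)
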
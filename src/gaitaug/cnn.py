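"""Convolutional networks mapping 100 x 12 inertial cycles to 100-point trajectories.

One network per output variable.  The architecture is two 2D convolution +
max-pooling stages filtering over time x sensor channel, a flattening step,
and two dense layers:

    input 100x12 -> conv 5x3 (64 filters, zero padding, stride 1, ReLU)
    -> pool 2x2 -> conv 5x3 (128, ReLU) -> pool 2x2 -> flatten (9600)
    -> dense 100 (ReLU) -> dense 100 (linear)

Training uses the Adam optimizer on the mean squared error with L2 kernel
regularization on the dense layers, mini-batches reshuffled every epoch, and
min-max input normalization fitted on the training pool.  Everything is
implemented on numpy (im2col convolutions with analytic backprop), so training
is deterministic given the seed under a fixed thread configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

N_TIME = 100
N_CHANNELS = 12


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters (defaults = selected values)."""

    kernel1: tuple = (5, 3)
    filters1: int = 64
    pool1: tuple = (2, 2)
    kernel2: tuple = (5, 3)
    filters2: int = 128
    pool2: tuple = (2, 2)
    dense_units: int = 100
    output_units: int = 100
    l2: float = 0.001
    l2_all_dense: bool = True  # apply L2 to both dense kernels (else final only)
    batch_size: int = 64
    learning_rate: float = 0.001
    epochs: int = 1000

    def __post_init__(self):
        for name in ("filters1", "filters2", "dense_units", "output_units", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.l2 < 0:
            raise ValueError("learning_rate must be positive and l2 non-negative")

    @classmethod
    def desk(cls, epochs: int = 60, **kw) -> "CNNConfig":
        """Reduced profile for desk-scale experiments (same topology, fewer filters)."""
        return cls(filters1=8, filters2=16, epochs=epochs, batch_size=32, **kw)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class _Conv2D:
    """'Same'-padded 2D convolution over (time, channel), stride 1, via im2col."""

    def __init__(self, kernel, c_in, c_out, rng):
        kh, kw = kernel
        fan_in = kh * kw * c_in
        self.W = rng.normal(scale=np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.dW, self.db = np.zeros_like(self.W), np.zeros_like(self.b)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out

    def _cols(self, x):
        kh, kw = self.kernel
        n, H, W, C = x.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        # win: (n, H, W, C, kh, kw) -> (n*H*W, kh*kw*C)
        win = win.transpose(0, 1, 2, 4, 5, 3)
        return win.reshape(n * H * W, kh * kw * C)

    def forward(self, x):
        n, H, W, _ = x.shape
        self._x_shape = x.shape
        self._cols_cache = self._cols(x)
        y = self._cols_cache @ self.W + self.b
        return y.reshape(n, H, W, self.c_out)

    def backward(self, dy):
        n, H, W, _ = self._x_shape
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        dy2 = dy.reshape(n * H * W, self.c_out)
        self.dW = self._cols_cache.T @ dy2
        self.db = dy2.sum(axis=0)
        dcols = (dy2 @ self.W.T).reshape(n, H, W, kh, kw, self.c_in)
        dxp = np.zeros((n, H + 2 * ph, W + 2 * pw, self.c_in))
        for i in range(kh):
            for j in range(kw):
                dxp[:, i : i + H, j : j + W, :] += dcols[:, :, :, i, j, :]
        return dxp[:, ph : ph + H, pw : pw + W, :]

    def params_grads(self):
        return [(self.W, self.dW, 0.0), (self.b, self.db, 0.0)]


class _MaxPool:
    def __init__(self, pool):
        self.pool = pool

    def forward(self, x):
        ph, pw = self.pool
        n, H, W, C = x.shape
        if H % ph or W % pw:
            raise ValueError(
                f"pooling {self.pool} does not divide feature map {H}x{W}"
            )
        xr = x.reshape(n, H // ph, ph, W // pw, pw, C)
        y = xr.max(axis=(2, 4))
        self._mask = xr == y[:, :, None, :, None, :]
        self._shape = x.shape
        return y

    def backward(self, dy):
        n, H, W, C = self._shape
        ph, pw = self.pool
        dyr = dy[:, :, None, :, None, :] * self._mask
        return dyr.reshape(n, H, W, C)

    def params_grads(self):
        return []


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params_grads(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def params_grads(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng, l2=0.0):
        self.W = rng.normal(scale=np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW, self.db = np.zeros_like(self.W), np.zeros_like(self.b)
        self.l2 = l2

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy + 2.0 * self.l2 * self.W
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW, self.l2), (self.b, self.db, 0.0)]


class Network:
    """The two-conv / two-dense regression network."""

    def __init__(self, cfg: CNNConfig, seed: int = 0, input_shape=(N_TIME, N_CHANNELS)):
        self.cfg = cfg
        self.input_shape = input_shape
        rng = np.random.default_rng(seed)
        H, W = input_shape
        h1, w1 = H // cfg.pool1[0], W // cfg.pool1[1]
        if H % cfg.pool1[0] or W % cfg.pool1[1]:
            raise ValueError(f"pool1 {cfg.pool1} does not divide input {H}x{W}")
        if h1 % cfg.pool2[0] or w1 % cfg.pool2[1]:
            raise ValueError(f"pool2 {cfg.pool2} does not divide feature map {h1}x{w1}")
        h2, w2 = h1 // cfg.pool2[0], w1 // cfg.pool2[1]
        self.flat_features = h2 * w2 * cfg.filters2
        l2_first = cfg.l2 if cfg.l2_all_dense else 0.0
        self.layers = [
            _Conv2D(cfg.kernel1, 1, cfg.filters1, rng),
            _ReLU(),
            _MaxPool(cfg.pool1),
            _Conv2D(cfg.kernel2, cfg.filters1, cfg.filters2, rng),
            _ReLU(),
            _MaxPool(cfg.pool2),
            _Flatten(),
            _Dense(self.flat_features, cfg.dense_units, rng, l2=l2_first),
            _ReLU(),
            _Dense(cfg.dense_units, cfg.output_units, rng, l2=cfg.l2),
        ]

    def layer_output_shapes(self) -> list:
        """Per-stage output shapes for one input cycle (conv/pool/flatten/dense)."""
        H, W = self.input_shape
        cfg = self.cfg
        shapes = [("conv1", (H, W, cfg.filters1))]
        H1, W1 = H // cfg.pool1[0], W // cfg.pool1[1]
        shapes.append(("pool1", (H1, W1, cfg.filters1)))
        shapes.append(("conv2", (H1, W1, cfg.filters2)))
        H2, W2 = H1 // cfg.pool2[0], W1 // cfg.pool2[1]
        shapes.append(("pool2", (H2, W2, cfg.filters2)))
        shapes.append(("flatten", (self.flat_features,)))
        shapes.append(("dense1", (cfg.dense_units,)))
        shapes.append(("output", (cfg.output_units,)))
        return shapes

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x[..., None] if x.ndim == 3 else x
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def params_grads(self):
        for layer in self.layers:
            yield from layer.params_grads()


def build_network(cfg: CNNConfig | None = None, seed: int = 0) -> Network:
    """Untrained network with the configured architecture."""
    return Network(cfg or CNNConfig(), seed=seed)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationSpec:
    """Per-channel min/max fitted on the training inputs; applied everywhere."""

    mins: np.ndarray  # (12,)
    maxs: np.ndarray


def fit_normalization(X: np.ndarray) -> NormalizationSpec:
    """Channel-wise min/max over all training cycles and time points."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit normalization on an empty training set")
    mins = X.min(axis=(0, 1))
    maxs = X.max(axis=(0, 1))
    return NormalizationSpec(mins=mins, maxs=maxs)


def apply_normalization(spec: NormalizationSpec, X: np.ndarray) -> np.ndarray:
    """Map each channel to [0, 1] by the training min/max; no clipping.

    Constant training channels map to 0; test values outside the training
    range fall outside [0, 1] by design.
    """
    span = spec.maxs - spec.mins
    span = np.where(span > 0, span, 1.0)
    return (X - spec.mins) / span


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, net: Network, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in net.params_grads()]
        self.v = [np.zeros_like(p) for p, _, _ in net.params_grads()]

    def step(self, net: Network):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g, _) in enumerate(net.params_grads()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedEstimator:
    """A trained per-variable network with its input normalization."""

    variable: str
    network: Network
    norm: NormalizationSpec
    seed: int
    history: list = field(default_factory=list)  # per-epoch training MSE
    train_fingerprint: tuple = ()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Trajectories (n, 100) in the variable's physical units."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (N_TIME, self.network.input_shape[1]):
            raise ValueError(
                f"expected inputs (n, {N_TIME}, {self.network.input_shape[1]}), got {X.shape}"
            )
        return self.network.forward(apply_normalization(self.norm, X))


def train(
    network: Network,
    X: np.ndarray,
    y: np.ndarray,
    cfg: CNNConfig,
    seed: int = 0,
    variable: str = "",
    norm: NormalizationSpec | None = None,
) -> TrainedEstimator:
    """Train one network on (X (n,100,12), y (n,100)) targets in physical units.

    Mini-batches are reshuffled every epoch; the loss is the MSE plus the L2
    kernel penalty.  Deterministic given the seed (fixed thread configuration).
    Raises on NaN loss.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 3 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} disagree")
    if y.ndim != 2 or y.shape[1] != cfg.output_units:
        raise ValueError(f"targets must be (n, {cfg.output_units}), got {y.shape}")
    n = X.shape[0]
    batch = cfg.batch_size
    if n < batch:
        warnings.warn(f"training set ({n}) smaller than batch size ({batch}); shrinking batch")
        batch = n

    norm = norm or fit_normalization(X)
    Xn = apply_normalization(norm, X)
    rng = np.random.default_rng(seed)
    opt = _Adam(network, cfg.learning_rate)
    history = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, yb = Xn[idx], y[idx]
            pred = network.forward(xb)
            err = pred - yb
            loss = float((err**2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch} (variable {variable!r}); "
                    "check target scaling or lower the learning rate"
                )
            network.backward(2.0 * err / err.size)
            opt.step(network)
            ep_loss += loss
            nb += 1
        history.append(ep_loss / nb)

    return TrainedEstimator(
        variable=variable,
        network=network,
        norm=norm,
        seed=seed,
        history=history,
        train_fingerprint=(n, float(np.sum(X) % 1e6)),
    )


def predict(est: TrainedEstimator, X: np.ndarray) -> np.ndarray:
    return est.predict(X)


def save_estimator(path, est: TrainedEstimator) -> None:
    """Serialize weights, config, normalization, and seed to an .npz container."""
    import dataclasses

    arrays = {}
    for i, (p, _, _) in enumerate(est.network.params_grads()):
        arrays[f"param_{i}"] = p
    cfg = dataclasses.asdict(est.network.cfg)
    np.savez_compressed(
        path,
        variable=est.variable,
        seed=est.seed,
        norm_mins=est.norm.mins,
        norm_maxs=est.norm.maxs,
        config_repr=repr(cfg),
        history=np.asarray(est.history),
        **arrays,
    )


def load_estimator(path) -> TrainedEstimator:
    import ast

    d = np.load(path, allow_pickle=False)
    cfg = CNNConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in ast.literal_eval(str(d["config_repr"])).items()
    })
    net = Network(cfg, seed=int(d["seed"]))
    for i, (p, _, _) in enumerate(net.params_grads()):
        p[...] = d[f"param_{i}"]
    return TrainedEstimator(
        variable=str(d["variable"]),
        network=net,
        norm=NormalizationSpec(mins=d["norm_mins"], maxs=d["norm_maxs"]),
        seed=int(d["seed"]),
        history=list(d["history"]),
    )
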
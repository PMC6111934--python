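"""Per-joint time-series CNN attribute estimators.

Each of the 14 body joints gets its own small convolutional network that
maps a 1 s sliding window (60 samples at 60 Hz) of the joint's IMU
channels to its attribute value: a softmax distribution over categories
for classification joints, a sigmoid-squashed scalar in [0, 1] for
regression joints.

Windows are treated as 2-D images (time x channel) and convolved with 2-D
kernels so that different sensor modalities (acceleration, gyro,
quaternion) are mixed from the first layer on.  The architecture is four
valid-padded convolution layers with 25, 20, 15 and 10 feature channels
(kernel 3x3, or 3x10 for the sensor-dense hand joints), batch
normalisation and leaky-ReLU after each, one fully connected layer with
100 nodes (leaky ReLU + dropout), and a softmax or sigmoid head.
Training uses momentum SGD (momentum 0.9) with cross-entropy loss for
classification and mean-absolute error for regression.

The networks are implemented directly on numpy (im2col convolutions with
analytic backward passes); everything is seeded and runs in float32.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attribute_space import AttributeSchema, JointSpec

__all__ = [
    "Recording",
    "EstimatorSpec",
    "TrainConfig",
    "JointEstimator",
    "sliding_windows",
    "estimator_spec",
    "build_estimator",
    "train_estimator",
    "estimate_attributes",
    "save_estimator",
    "load_estimator",
    "save_recording",
    "load_recording",
]

WINDOW_LENGTH = 60  # samples: 1 s at 60 Hz
WINDOW_SHIFT = 30   # samples: 0.5 s
CHANNELS_PER_SENSOR = 10  # 3 acceleration + 3 gyro + 4 quaternion
LEAKY_SLOPE = 0.1
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class TrainConfig:
    """Training hyper-parameters (unspecified by the architecture; defaults
    live here and are recorded in saved-model manifests)."""

    epochs: int = 20
    batch_size: int = 64
    lr: float = 0.01
    momentum: float = 0.9
    dropout: float = 0.5
    seed: int = 0


# ---------------------------------------------------------------------------
# recordings and windowing
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A multichannel IMU time series with pose label and subject id.

    ``samples`` is (T, C) with C = 10 x len(sensors); each sensor
    contributes a contiguous block of 10 channels in ``sensors`` order.
    """

    samples: np.ndarray
    rate: float = 60.0
    label: str = ""
    subject: str = ""
    sensors: tuple[str, ...] = ()
    #: optional per-joint ground-truth states (joint name -> category label or
    #: float); synthetic recordings carry their realised states here so that
    #: estimator training targets reflect intra-class variation.
    states: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (T, C) matrix")
        if self.sensors and self.samples.shape[1] != CHANNELS_PER_SENSOR * len(self.sensors):
            raise ValueError(
                f"channel count {self.samples.shape[1]} inconsistent with "
                f"{len(self.sensors)} sensors x {CHANNELS_PER_SENSOR}"
            )

    def channel_indices(self, sensor_ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given sensors' channel blocks."""
        idx = []
        for s in sensor_ids:
            try:
                k = self.sensors.index(s)
            except ValueError:
                raise KeyError(f"sensor {s!r} not present in recording") from None
            idx.extend(range(k * CHANNELS_PER_SENSOR, (k + 1) * CHANNELS_PER_SENSOR))
        return np.asarray(idx)


def sliding_windows(
    rec: Recording | np.ndarray,
    length: int = WINDOW_LENGTH,
    shift: int = WINDOW_SHIFT,
) -> np.ndarray:
    """Cut a recording into overlapping windows.

    Windows are half-open ranges starting at 0, shift, 2*shift, ...; the
    count is floor((T - length)/shift) + 1.  Returns (n_windows, length, C).
    """
    x = rec.samples if isinstance(rec, Recording) else np.asarray(rec)
    T = x.shape[0]
    if T < length:
        raise ValueError(f"recording too short: T={T} < window length {length}")
    n = (T - length) // shift + 1
    starts = np.arange(n) * shift
    return np.stack([x[s : s + length] for s in starts])


def save_recording(path: str | Path, rec: Recording) -> None:
    """Write a recording as CSV (one row per time step) + JSON sidecar."""
    path = Path(path)
    cols = [f"{s}:{c}" for s in rec.sensors for c in range(CHANNELS_PER_SENSOR)]
    pd.DataFrame(rec.samples, columns=cols or None).to_csv(path, index=False)
    meta = {
        "rate": rec.rate,
        "label": rec.label,
        "subject": rec.subject,
        "sensors": list(rec.sensors),
        "states": rec.states,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    samples = pd.read_csv(path).to_numpy(dtype=np.float32)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return Recording(
        samples, meta["rate"], meta["label"], meta["subject"],
        tuple(meta["sensors"]), meta.get("states"),
    )


# ---------------------------------------------------------------------------
# network layers (numpy, float32, analytic backward)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) -> patch matrix (N*oh*ow, C*kh*kw) for valid convolution."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    n, c, oh, ow = v.shape[:4]
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


class _Conv2D:
    """Valid 2-D convolution (cross-correlation), stride 1."""

    def __init__(self, c_in: int, c_out: int, kh: int, kw: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kh * kw))
        self.W = (rng.standard_normal((c_out, c_in, kh, kw)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kh, self.kw = kh, kw

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._xshape = x.shape
        cols, oh, ow = _im2col(x, self.kh, self.kw)
        if train:
            self._cols = cols
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(x.shape[0], oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c_out, oh, ow = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.grads = {
            "W": (dmat.T @ self._cols).reshape(self.W.shape),
            "b": dmat.sum(axis=0),
        }
        # dx = full correlation of dout with the 180-degree-rotated kernel
        pad = ((0, 0), (0, 0), (self.kh - 1, self.kh - 1), (self.kw - 1, self.kw - 1))
        cols_d, H, W_ = _im2col(np.pad(dout, pad), self.kh, self.kw)
        w_rot = np.flip(self.W, axis=(2, 3)).transpose(1, 0, 2, 3)
        dx = cols_d @ w_rot.reshape(w_rot.shape[0], -1).T
        del self._cols
        return dx.reshape(n, H, W_, -1).transpose(0, 3, 1, 2)


class _BatchNorm2D:
    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)

    @property
    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = _BN_MOMENTUM * self.run_mean + (1 - _BN_MOMENTUM) * mu
            self.run_var = _BN_MOMENTUM * self.run_var + (1 - _BN_MOMENTUM) * var
        else:
            mu, var = self.run_mean, self.run_var
        ivar = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._xhat, self._ivar = xhat, ivar
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dbeta = dout.sum(axis=(0, 2, 3))
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads = {"gamma": dgamma, "beta": dbeta}
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) * ivar[None, :, None, None]
        del self._xhat, self._ivar
        return dx.astype(np.float32)


class _LeakyReLU:
    params: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, LEAKY_SLOPE * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {}
        return np.where(self._mask, dout, LEAKY_SLOPE * dout)


class _Flatten:
    params: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {}
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        dx = dout @ self.W.T
        del self._x
        return dx


class _Dropout:
    params: dict = {}

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self._rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.rate).astype(np.float32) / (
            1.0 - self.rate
        )
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {}
        return dout if self._mask is None else dout * self._mask


# ---------------------------------------------------------------------------
# estimator spec and model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EstimatorSpec:
    """Architecture description for one joint's estimator."""

    joint: JointSpec
    conv_channels: tuple[int, ...] = (25, 20, 15, 10)
    kernel: tuple[int, int] = (3, 3)
    fc_nodes: int = 100

    @property
    def head(self) -> str:
        return "softmax" if self.joint.kind == "classification" else "sigmoid"

    @property
    def loss(self) -> str:
        return "cross_entropy" if self.joint.kind == "classification" else "mae"

    @property
    def out_dim(self) -> int:
        return len(self.joint.categories) if self.joint.kind == "classification" else 1


def estimator_spec(joint: JointSpec) -> EstimatorSpec:
    """Default spec: 3x10 kernel for the sensor-dense hand joints, 3x3 else."""
    wide = joint.name.startswith("Ha")
    return EstimatorSpec(joint, kernel=(3, 10) if wide else (3, 3))


class JointEstimator:
    """One joint's CNN plus its input standardisation statistics."""

    def __init__(self, spec: EstimatorSpec, n_channels: int, seed: int = 0):
        kh, kw = spec.kernel
        t_extent = WINDOW_LENGTH - len(spec.conv_channels) * (kh - 1)
        c_extent = n_channels - len(spec.conv_channels) * (kw - 1)
        if c_extent < 1:
            raise ValueError(
                f"joint {spec.joint.name!r}: {n_channels} channels too few for "
                f"{len(spec.conv_channels)} conv layers with kernel width {kw}"
            )
        if t_extent < 1:
            raise ValueError("window too short for the convolution stack")
        self.spec = spec
        self.n_channels = n_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        layers: list = []
        c_in = 1
        for c_out in spec.conv_channels:
            layers += [_Conv2D(c_in, c_out, kh, kw, rng), _BatchNorm2D(c_out), _LeakyReLU()]
            c_in = c_out
        layers.append(_Flatten())
        flat = spec.conv_channels[-1] * t_extent * c_extent
        layers += [
            _Dense(flat, spec.fc_nodes, rng),
            _LeakyReLU(),
            _Dropout(0.5, self._dropout_rng),
            _Dense(spec.fc_nodes, spec.out_dim, rng),
        ]
        self.layers = layers
        self.mean = np.zeros(n_channels, dtype=np.float32)
        self.std = np.ones(n_channels, dtype=np.float32)
        self.loss_history: list[float] = []
        self._velocity: dict[int, dict[str, np.ndarray]] = {}

    # -- forward ----------------------------------------------------------
    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != WINDOW_LENGTH or X.shape[2] != self.n_channels:
            raise ValueError(
                f"expected windows of shape ({WINDOW_LENGTH}, {self.n_channels}), "
                f"got {X.shape[1:]}"
            )
        X = (X - self.mean) / self.std
        return X[:, None, :, :]  # (N, 1, T, M)

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Head outputs: (N, K) simplex rows or (N,) values in [0, 1]."""
        x = self._prep(X)
        outs = []
        for i in range(0, len(x), batch_size):
            z = self._forward(x[i : i + batch_size], train=False)
            if self.spec.head == "softmax":
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                outs.append(e / e.sum(axis=1, keepdims=True))
            else:
                outs.append(1.0 / (1.0 + np.exp(-z[:, 0])))
        return np.concatenate(outs).astype(np.float64)

    # -- training ---------------------------------------------------------
    def _loss_and_grad(self, z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        n = len(z)
        if self.spec.loss == "cross_entropy":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
            loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
            dz = p
            dz[np.arange(n), y] -= 1.0
            return loss, (dz / n).astype(np.float32)
        p = 1.0 / (1.0 + np.exp(-z[:, 0]))
        err = p - y
        loss = float(np.abs(err).mean())
        dz = (np.sign(err) * p * (1.0 - p) / n).astype(np.float32)[:, None]
        return loss, dz

    def _sgd_step(self, lr: float, momentum: float) -> None:
        for li, layer in enumerate(self.layers):
            if not layer.params:
                continue
            vel = self._velocity.setdefault(
                li, {k: np.zeros_like(v) for k, v in layer.params.items()}
            )
            for k, param in layer.params.items():
                vel[k] = momentum * vel[k] - lr * layer.grads[k]
                param += vel[k]

    def fit(self, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None) -> list[float]:
        """Train on labeled windows; returns per-epoch mean loss history.

        ``y`` holds integer category indices (classification) or floats in
        [0, 1] (regression).  Standardisation statistics are (re)computed
        from ``X`` per channel.
        """
        config = config or TrainConfig()
        X = np.asarray(X, dtype=np.float32)
        if len(X) == 0:
            raise ValueError("empty training set")
        if self.spec.loss == "cross_entropy":
            y = np.asarray(y, dtype=np.int64)
            if len(np.unique(y)) < 2:
                raise ValueError("degenerate training set: a single category present")
        else:
            y = np.asarray(y, dtype=np.float32)
        self.mean = X.mean(axis=(0, 1)).astype(np.float32)
        self.std = (X.std(axis=(0, 1)) + 1e-6).astype(np.float32)
        rng = np.random.default_rng(config.seed)
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                layer.rate = config.dropout
        xs = self._prep(X)
        for _ in range(config.epochs):
            order = rng.permutation(len(xs))
            losses = []
            for i in range(0, len(xs), config.batch_size):
                idx = order[i : i + config.batch_size]
                z = self._forward(xs[idx], train=True)
                loss, dz = self._loss_and_grad(z, y[idx])
                losses.append(loss)
                d = dz
                for layer in reversed(self.layers):
                    d = layer.backward(d)
                self._sgd_step(config.lr, config.momentum)
            self.loss_history.append(float(np.mean(losses)))
        return self.loss_history


def build_estimator(
    spec: EstimatorSpec, n_channels: int | None = None, seed: int = 0
) -> JointEstimator:
    """Instantiate an untrained estimator for a joint.

    ``n_channels`` defaults to 10 x number of sensors feeding the joint.
    """
    if n_channels is None:
        n_channels = CHANNELS_PER_SENSOR * len(spec.joint.sensor_ids)
    return JointEstimator(spec, n_channels, seed)


def train_estimator(
    model: JointEstimator,
    windows: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[JointEstimator, list[float]]:
    """Train an estimator in place; returns (model, loss history)."""
    history = model.fit(windows, targets, config)
    return model, history


def estimate_attributes(
    models: Mapping[str, JointEstimator],
    rec: Recording,
    schema: AttributeSchema,
    length: int = WINDOW_LENGTH,
    shift: int = WINDOW_SHIFT,
) -> np.ndarray:
    """Run all joint estimators over a recording's sliding windows.

    Returns an (n_windows, D) matrix of attribute vectors: per-joint head
    outputs concatenated in schema order.  Simplex/range invariants hold
    by construction of the heads.
    """
    missing = [j.name for j in schema if j.name not in models]
    if missing:
        raise KeyError(f"no estimator supplied for joints: {missing}")
    wins = sliding_windows(rec, length, shift)
    out = np.zeros((len(wins), schema.D))
    for j in schema:
        cols = rec.channel_indices(j.sensor_ids)
        pred = models[j.name].predict(wins[:, :, cols])
        sl = schema.slices[j.name]
        if j.kind == "classification":
            out[:, sl] = pred
        else:
            out[:, sl.start] = pred
    return out


def _stratified_subsample(y: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of <= cap samples spread as evenly as possible over labels."""
    groups = [np.flatnonzero(y == lab) for lab in np.unique(y)]
    groups.sort(key=len)
    keep: list[np.ndarray] = []
    left = cap
    for gi, g in enumerate(groups):
        quota = left // (len(groups) - gi)
        take = min(len(g), quota)
        keep.append(rng.choice(g, take, replace=False))
        left -= take
    return np.concatenate(keep)


def train_all_estimators(
    recs: Sequence[Recording],
    defs,
    schema: AttributeSchema,
    config: TrainConfig | None = None,
    max_windows_per_joint: int | Mapping[str, int] | None = None,
) -> dict[str, JointEstimator]:
    """Train one estimator per schema joint on a labeled recording corpus.

    Per-window targets are each recording's per-joint ground-truth states
    (``rec.states`` when present — synthetic recordings record their
    realised variation there — else the definition-table row of the
    recording's pose label).  ``max_windows_per_joint`` caps the training
    set by a seeded random subsample; a mapping gives per-joint caps
    (useful to keep the sensor-dense hand estimators cheap).

    ``defs`` is a :class:`~zspose.attribute_space.PoseDefinitionTable`.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    models: dict[str, JointEstimator] = {}
    for j in schema:
        cap = (
            max_windows_per_joint.get(j.name)
            if isinstance(max_windows_per_joint, Mapping)
            else max_windows_per_joint
        )
        xs, ys = [], []
        for rec in recs:
            state_row = rec.states if rec.states is not None else defs.row(rec.label)
            state = state_row[j.name]
            wins = sliding_windows(rec)[:, :, :]
            cols = rec.channel_indices(j.sensor_ids)
            xs.append(wins[:, :, cols])
            if j.kind == "classification":
                target = j.categories.index(str(state))
            else:
                target = float(state)
            ys.append(np.full(len(wins), target))
        X = np.concatenate(xs)
        y = np.concatenate(ys)
        if cap is not None and len(X) > cap:
            # rare joint states (few poses use them) must survive the cap:
            # subsample evenly per distinct state, spilling unused quota.
            # Continuous regression targets (many unique values) fall back
            # to a plain random subsample.
            if j.kind == "classification" or len(np.unique(y)) <= 32:
                keep = _stratified_subsample(y, cap, rng)
            else:
                keep = rng.choice(len(X), cap, replace=False)
            X, y = X[keep], y[keep]
        model = build_estimator(estimator_spec(j), X.shape[2], seed=config.seed)
        model.fit(X, y, config)
        models[j.name] = model
    return models


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_estimator(model: JointEstimator, path: str | Path) -> None:
    """Save weights as .npz plus a JSON manifest alongside."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {"mean": model.mean, "std": model.std}
    for li, layer in enumerate(model.layers):
        for k, v in layer.params.items():
            arrays[f"L{li}:{k}"] = v
        if isinstance(layer, _BatchNorm2D):
            arrays[f"L{li}:run_mean"] = layer.run_mean
            arrays[f"L{li}:run_var"] = layer.run_var
    np.savez(path, **arrays)
    j = model.spec.joint
    manifest = {
        "joint": {
            "name": j.name,
            "kind": j.kind,
            "categories": list(j.categories),
            "sensor_ids": list(j.sensor_ids),
        },
        "conv_channels": list(model.spec.conv_channels),
        "kernel": list(model.spec.kernel),
        "fc_nodes": model.spec.fc_nodes,
        "n_channels": model.n_channels,
        "seed": model.seed,
        "loss_history": model.loss_history,
    }
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1))


def load_estimator(path: str | Path) -> JointEstimator:
    path = Path(path)
    manifest = json.loads(Path(str(path) + ".manifest.json").read_text())
    jm = manifest["joint"]
    joint = JointSpec(
        jm["name"], jm["kind"], tuple(jm["categories"]), tuple(jm["sensor_ids"])
    )
    spec = EstimatorSpec(
        joint,
        tuple(manifest["conv_channels"]),
        tuple(manifest["kernel"]),
        manifest["fc_nodes"],
    )
    model = JointEstimator(spec, manifest["n_channels"], manifest["seed"])
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    model.mean, model.std = data["mean"], data["std"]
    for li, layer in enumerate(model.layers):
        for k in layer.params:
            layer.params[k][...] = data[f"L{li}:{k}"]
        if isinstance(layer, _BatchNorm2D):
            layer.run_mean = data[f"L{li}:run_mean"]
            layer.run_var = data[f"L{li}:run_var"]
    model.loss_history = list(manifest["loss_history"])
    return model
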
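"""Minimal convolutional-network regressor, implemented on numpy.

Architecture (defaults): two valid-mode conv blocks (3x3 kernels, ReLU,
2x2 max-pool) with 8 and 16 channels, a 32-unit ReLU dense head and a
linear scalar output, trained with Adam on mean-squared error.  Sized so a
few thousand 32x32 images train in minutes on one CPU core.  Training and
prediction are deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class CnnConfig:
    conv_channels: tuple = (8, 16)
    kernel: int = 3
    pool: int = 2
    dense: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.conv_channels) < 1 or self.kernel < 1 or self.dense < 1:
            raise ValueError("all layer sizes must be positive")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size and learning_rate must be positive")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error loss is supported")


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (N, C, H, W) -> (N, Ho, Wo, C*k*k)
    v = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, Ho, Wo, k, k)
    v = v.transpose(0, 2, 3, 1, 4, 5)
    n, ho, wo = v.shape[:3]
    return v.reshape(n, ho, wo, -1)


class _Conv:
    """Valid-mode 2-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in

    def forward(self, x):
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k)  # (N, Ho, Wo, C*k*k)
        out = self.cols @ self.w.T + self.b  # (N, Ho, Wo, c_out)
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout):
        d = dout.transpose(0, 2, 3, 1)  # (N, Ho, Wo, c_out)
        flat_d = d.reshape(-1, d.shape[-1])
        flat_c = self.cols.reshape(-1, self.cols.shape[-1])
        self.dw = (flat_d.T @ flat_c).astype(np.float32)
        self.db = flat_d.sum(axis=0).astype(np.float32)
        dcols = d @ self.w  # (N, Ho, Wo, C*k*k)
        n, ho, wo, _ = dcols.shape
        dcols = dcols.reshape(n, ho, wo, self.c_in, self.k, self.k)
        dx = np.zeros(self.x_shape, dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


class _MaxPool:
    def __init__(self, p: int):
        self.p = p

    def forward(self, x):
        p = self.p
        n, c, h, w = x.shape
        hp, wp = h // p, w // p
        self.crop = (n, c, hp * p, wp * p)
        xc = x[:, :, : hp * p, : wp * p]
        r = xc.reshape(n, c, hp, p, wp, p)
        out = r.max(axis=(3, 5))
        mask = r == out[:, :, :, None, :, None]
        # split gradient between duplicate maxima so backward stays exact
        self.mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self.in_shape = x.shape
        return out

    def backward(self, dout):
        n, c, hp, wp = dout.shape
        d = self.mask * dout[:, :, :, None, :, None]
        d = d.reshape(self.crop)
        dx = np.zeros(self.in_shape, dtype=np.float32)
        dx[:, :, : self.crop[2], : self.crop[3]] = d
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self.x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = (self.x.T @ dout).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        return dout @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class CnnRegressor:
    """Image -> scalar regressor; see module docstring for the layout."""

    def __init__(self, config: CnnConfig, input_side: int = 32):
        self.config = config
        self.input_side = input_side
        rng = np.random.default_rng(config.seed)
        k, p = config.kernel, config.pool
        c1, c2 = config.conv_channels[0], config.conv_channels[-1]
        side = input_side
        self.conv1 = _Conv(1, c1, k, rng)
        side = (side - k + 1) // p
        self.conv2 = _Conv(c1, c2, k, rng)
        side = (side - k + 1) // p
        if side < 1:
            raise ValueError("input image too small for this architecture")
        self.flat_dim = c2 * side * side
        self.fc1 = _Dense(self.flat_dim, config.dense, rng)
        self.fc2 = _Dense(config.dense, 1, rng)
        self.pool1, self.pool2 = _MaxPool(p), _MaxPool(p)
        self.relu1, self.relu2, self.relu3 = _ReLU(), _ReLU(), _ReLU()
        self._rng = rng

    # -- forward / backward -------------------------------------------------
    def _forward(self, x):
        h = self.pool1.forward(self.relu1.forward(self.conv1.forward(x)))
        h = self.pool2.forward(self.relu2.forward(self.conv2.forward(h)))
        self._conv_out_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.relu3.forward(self.fc1.forward(h))
        return self.fc2.forward(h)[:, 0]

    def _backward(self, dpred):
        d = self.fc2.backward(dpred[:, None])
        d = self.fc1.backward(self.relu3.backward(d))
        d = d.reshape(self._conv_out_shape)
        d = self.conv2.backward(self.relu2.backward(self.pool2.backward(d)))
        self.conv1.backward(self.relu1.backward(self.pool1.backward(d)))

    def _layers(self):
        return [self.conv1, self.conv2, self.fc1, self.fc2]

    # -- training -----------------------------------------------------------
    def fit(self, images: np.ndarray, labels: np.ndarray, verbose: bool = False) -> list:
        """Train with Adam on MSE; returns the per-epoch training-loss curve."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        y = np.asarray(labels, dtype=np.float32)
        n = x.shape[0]
        cfg = self.config
        # input scaling: count-fraction pixels are tiny; scale to O(1)
        self.input_scale = float(1.0 / max(x.std(), 1e-8))
        x = x * self.input_scale
        # standardize the regression target; predictions are mapped back
        self.y_mean = float(y.mean())
        self.y_scale = float(max(y.std(), 1e-8))
        y = (y - self.y_mean) / self.y_scale

        adam_m, adam_v = {}, {}
        for li, layer in enumerate(self._layers()):
            for name, w, _ in layer.params():
                adam_m[(li, name)] = np.zeros_like(w)
                adam_v[(li, name)] = np.zeros_like(w)
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        curve = []
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                pred = self._forward(xb)
                err = pred - yb
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}, step {step}"
                    )
                ep_loss += loss * idx.size
                self._backward((2.0 / idx.size) * err.astype(np.float32))
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
                for li, layer in enumerate(self._layers()):
                    for name, w, gname in layer.params():
                        g = getattr(layer, gname)
                        m = adam_m[(li, name)]
                        v = adam_v[(li, name)]
                        m += (1 - b1) * (g - m)
                        v += (1 - b2) * (g * g - v)
                        w -= lr_t * m / (np.sqrt(v) + eps)
            curve.append(ep_loss / n)
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.epochs}  mse={curve[-1]:.6f}")
        self.training_curve = curve
        return curve

    def predict(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None, :, :]
        x = x * self.input_scale
        out = np.empty(x.shape[0], dtype=float)
        for start in range(0, x.shape[0], batch_size):
            out[start : start + batch_size] = self._forward(x[start : start + batch_size])
        return out * self.y_scale + self.y_mean

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict:
        state = {
            "input_scale": np.float32(self.input_scale),
            "y_mean": np.float32(self.y_mean),
            "y_scale": np.float32(self.y_scale),
        }
        for li, layer in enumerate(self._layers()):
            for name, w, _ in layer.params():
                state[f"{li}.{name}"] = w
        return state

    def save(self, path) -> None:
        np.savez(
            path,
            config=json.dumps(asdict(self.config)),
            input_side=self.input_side,
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "CnnRegressor":
        data = np.load(path, allow_pickle=False)
        cfg_d = json.loads(str(data["config"]))
        cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
        model = cls(CnnConfig(**cfg_d), input_side=int(data["input_side"]))
        for li, layer in enumerate(model._layers()):
            for name, w, _ in layer.params():
                w[...] = data[f"{li}.{name}"]
        model.input_scale = float(data["input_scale"])
        model.y_mean = float(data["y_mean"])
        model.y_scale = float(data["y_scale"])
        return model
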
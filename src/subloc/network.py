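"""An 11-layer convolutional classifier for two-channel cell patches.

The architecture is a VGG-style stack: eight 3x3 stride-1 convolutions
(widths 64, 64, 128, 128, 256, 256, 256, 256), batch normalization before
every rectified-linear activation, three 2x2 stride-2 max-poolings (after
convolutions 2, 4 and 8, so a 64x64 input flattens at 256x8x8), then fully
connected layers of 512, 512 and ``n_classes`` units with dropout on the
first two. Training is plain SGD with momentum, weight decay, and a
halve-every-k-iterations learning-rate schedule; per-pixel training-set
mean is subtracted from every image.

The whole network — forward, backward, and the optimizer — is implemented
in numpy (im2col convolutions via stride tricks), so training and
activation extraction run anywhere numpy runs. Gradients are validated
against central finite differences in the test suite.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synth import Dataset

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkConfig:
    """Layer specification. Defaults are the full-scale architecture."""

    conv_widths: tuple[int, ...] = (64, 64, 128, 128, 256, 256, 256, 256)
    fc_widths: tuple[int, ...] = (512, 512, 12)
    pool_positions: tuple[int, ...] = (2, 4, 8)  # 1-based conv indices followed by pooling
    n_classes: int = 12
    input_shape: tuple[int, int, int] = (2, 64, 64)
    filter_size: int = 3
    batchnorm: bool = True
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.fc_widths[-1] != self.n_classes:
            raise ValueError("last fc width must equal n_classes")
        side = self.input_shape[1]
        if side % (2 ** len(self.pool_positions)) != 0:
            raise ValueError(
                f"input side {side} not divisible by 2^{len(self.pool_positions)} poolings"
            )
        if any(p < 1 or p > len(self.conv_widths) for p in self.pool_positions):
            raise ValueError("pool_positions must index conv layers")

    @classmethod
    def paper(cls, n_classes: int = 12) -> "NetworkConfig":
        """The published full-scale configuration (>10M parameters)."""
        return cls(n_classes=n_classes, fc_widths=(512, 512, n_classes))

    @classmethod
    def small(cls, n_classes: int = 12) -> "NetworkConfig":
        """Desk-scale preset: same depth and topology, widths cut 8-fold."""
        return cls(
            conv_widths=(8, 8, 16, 16, 32, 32, 32, 32),
            fc_widths=(64, 64, n_classes),
            n_classes=n_classes,
            dropout_rate=0.0,  # 64-wide FC layers under-fit with dropout
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings: SGD with momentum and stepwise LR halving."""

    initial_lr: float = 0.1
    momentum: float = 0.9
    batch_size: int = 100
    weight_decay: float = 0.0005
    lr_halving_interval: int = 16250
    epochs: int = 300
    seed: int = 0
    checkpoint_every_epochs: int = 1  # model-selection cadence
    warmup_iterations: int = 0  # linear LR ramp-in, guards tiny nets from early collapse

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.initial_lr <= 0 or self.lr_halving_interval < 1 or self.epochs < 1:
            raise ValueError("rates and intervals must be positive")


def iteration_schedule(n_train: int, batch_size: int, epochs: int) -> int:
    """Total SGD iterations: ``ceil(n_train / batch_size) * epochs``.

    The last incomplete mini-batch of each epoch is used (ceil convention).
    """
    if n_train < 1 or epochs < 1:
        raise ValueError("n_train and epochs must be >= 1")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    return math.ceil(n_train / batch_size) * epochs


def learning_rate_at(iteration: int, initial_lr: float = 0.1, interval: int = 16250) -> float:
    """LR schedule: halved after every ``interval`` iterations."""
    return initial_lr * 0.5 ** (iteration // interval)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]
    decay: list[bool]  # weight decay applies only where True

    def __init__(self):
        self.params, self.grads, self.decay = [], [], []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3x3(_Layer):
    """3x3 convolution, stride 1, zero padding 1 (size preserving).

    Activations flow channels-last (N, H, W, C) internally; the convolution
    is nine shifted GEMMs, which avoids materializing an im2col tensor.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        fan_in, fan_out = c_in * 9, c_out * 9
        std = math.sqrt(2.0 / (fan_in + fan_out))  # Glorot normal
        self.W = rng.normal(0.0, std, (3, 3, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.decay = [True, False]

    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp, self._hw = (xp, (h, w)) if train else (None, (h, w))
        if c <= 4:
            # narrow input: one im2col GEMM beats nine tiny-K GEMMs
            win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
            cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
                n * h * w, 9 * c
            )
            Wm = self.W.reshape(9 * c, -1)
            out = (cols @ Wm).reshape(n, h, w, -1)
        else:
            out = np.zeros((n, h, w, self.W.shape[3]), dtype=x.dtype)
            for ky in range(3):
                for kx in range(3):
                    out += xp[:, ky : ky + h, kx : kx + w, :] @ self.W[ky, kx]
        out += self.b
        return out

    def backward(self, dy):
        xp, (h, w) = self._xp, self._hw
        n, c = xp.shape[0], xp.shape[3]
        # weight gradient as one im2col GEMM (a single copy of the input
        # windows instead of nine strided reductions)
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, 9 * c
        )
        dy_flat = dy.reshape(n * h * w, -1)
        self.grads[0][...] = (cols.T @ dy_flat).reshape(3, 3, c, -1)
        self.grads[1][...] = dy_flat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for ky in range(3):
            for kx in range(3):
                dxp[:, ky : ky + h, kx : kx + w, :] += dy @ self.W[ky, kx].T
        self._xp = None
        return dxp[:, 1 : h + 1, 1 : w + 1, :]


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        std = math.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, std, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.decay = [True, False]

    def forward(self, x, train, rng):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T


class BatchNorm(_Layer):
    """Batch normalization before the activation.

    ``spatial=True`` normalizes over (batch, H, W) per channel; inference
    uses running averages accumulated with momentum 0.9.
    """

    def __init__(self, n: int, spatial: bool, dtype=np.float32, momentum: float = 0.9):
        super().__init__()
        self.gamma = np.ones(n, dtype=dtype)
        self.beta = np.zeros(n, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.decay = [False, False]
        self.spatial = spatial
        self.momentum = momentum
        self.eps = 1e-5
        self.run_mean = np.zeros(n, dtype=np.float64)
        self.run_var = np.zeros(n, dtype=np.float64)
        self._updates = 0  # for exact EMA debiasing (zero-init correction)

    def _shape(self, v):
        return v.reshape(1, 1, 1, -1) if self.spatial else v.reshape(1, -1)

    def forward(self, x, train, rng):
        axes = (0, 1, 2) if self.spatial else (0,)
        if train:
            xm = x.reshape(-1, x.shape[-1])
            s1 = xm.sum(axis=0, dtype=np.float64)
            s2 = np.einsum("nc,nc->c", xm, xm, dtype=np.float64)
            m = xm.shape[0]
            mean = (s1 / m).astype(x.dtype)
            var = np.maximum(s2 / m - (s1 / m) ** 2, 0.0).astype(x.dtype)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            self._updates += 1
        else:
            # debias the exponential averages (they start from zero)
            corr = 1.0 - self.momentum ** max(self._updates, 1)
            mean = (self.run_mean / corr).astype(x.dtype)
            var = np.maximum(self.run_var / corr, 0.0).astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mean)) * self._shape(inv_std)
        if train:
            self._xhat, self._inv_std, self._axes = xhat, inv_std, axes
        return self._shape(self.gamma) * xhat + self._shape(self.beta)

    def backward(self, dy):
        xhat, inv_std, axes = self._xhat, self._inv_std, self._axes
        m = dy.size / dy.shape[-1]
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        g = self._shape(self.gamma) * self._shape(inv_std)
        dx = g * (
            dy
            - self._shape(dy.sum(axis=axes)) / m
            - xhat * self._shape((dy * xhat).sum(axis=axes)) / m
        )
        self._xhat = self._inv_std = None
        return dx


class ReLU(_Layer):
    def forward(self, x, train, rng):
        out = np.maximum(x, 0)
        self._mask = out > 0 if train else None
        return out

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2(_Layer):
    def forward(self, x, train, rng):
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = np.ascontiguousarray(r).reshape(n, h // 2, w // 2, c, 4)
        idx = r.argmax(axis=-1)  # ties: first (lowest flat index) wins
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape_in = idx, x.shape
        return out

    def backward(self, dy):
        n, h, w, c = self._shape_in
        g = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(g, self._idx[..., None], dy[..., None], axis=-1)
        g = g.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._idx = None
        return np.ascontiguousarray(g).reshape(n, h, w, c)


class Flatten(_Layer):
    def forward(self, x, train, rng):
        self._shape_in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape_in)


class Dropout(_Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask.astype(dy.dtype)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class Network:
    """Sequential network built from a :class:`NetworkConfig`.

    ``activation_points`` maps weight-bearing layer index (1-based, 1..11
    for the full configuration) to the position in ``self.layers`` whose
    output is that layer's post-activation output (post-ReLU for layers
    1..10, raw logits for the final layer).
    """

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.layers: list[_Layer] = []
        self.activation_points: dict[int, int] = {}
        self.layer_kinds: dict[int, str] = {}

        c_prev = config.input_shape[0]
        weight_idx = 0
        for i, width in enumerate(config.conv_widths, start=1):
            self.layers.append(Conv3x3(c_prev, width, rng, dtype))
            if config.batchnorm:
                self.layers.append(BatchNorm(width, spatial=True, dtype=dtype))
            self.layers.append(ReLU())
            weight_idx += 1
            self.activation_points[weight_idx] = len(self.layers) - 1
            self.layer_kinds[weight_idx] = "conv"
            if i in config.pool_positions:
                self.layers.append(MaxPool2x2())
            c_prev = width
        side = config.input_shape[1] // (2 ** len(config.pool_positions))
        self.layers.append(Flatten())
        n_prev = c_prev * side * side
        n_fc = len(config.fc_widths)
        for j, width in enumerate(config.fc_widths):
            self.layers.append(Dense(n_prev, width, rng, dtype))
            weight_idx += 1
            last = j == n_fc - 1
            if not last:
                if config.batchnorm:
                    self.layers.append(BatchNorm(width, spatial=False, dtype=dtype))
                self.layers.append(ReLU())
                if j < 2 and config.dropout_rate > 0:
                    # dropout on the first two FC layers only; insert after
                    # recording the activation point (post-ReLU, pre-dropout)
                    self.activation_points[weight_idx] = len(self.layers) - 1
                    self.layer_kinds[weight_idx] = "fc"
                    self.layers.append(Dropout(config.dropout_rate))
                    n_prev = width
                    continue
            self.activation_points[weight_idx] = len(self.layers) - 1
            self.layer_kinds[weight_idx] = "logits" if last else "fc"
            n_prev = width
        self.n_weight_layers = weight_idx

    # -- plumbing ----------------------------------------------------------
    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads, layer.decay)

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        capture: Sequence[int] = (),
    ):
        """Run the network; optionally capture post-activation outputs of
        the given weight-bearing layer indices."""
        if x.shape[1:] != self.config.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match {self.config.input_shape}"
            )
        rng = rng or np.random.default_rng(0)
        want = {self.activation_points[i]: i for i in capture}
        captured: dict[int, np.ndarray] = {}
        out = np.ascontiguousarray(x.astype(self.dtype).transpose(0, 2, 3, 1))
        for pos, layer in enumerate(self.layers):
            out = layer.forward(out, train, rng)
            if pos in want:
                # expose feature maps channels-first (N, C, H, W)
                captured[want[pos]] = out.transpose(0, 3, 1, 2) if out.ndim == 4 else out
        return (out, captured) if capture else out

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(copy.deepcopy(layer.params))
            if isinstance(layer, BatchNorm):
                out.append(layer.run_mean.copy())
                out.append(layer.run_var.copy())
                out.append(np.array([layer._updates]))
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer in self.layers:
            for p in layer.params:
                p[...] = next(it)
            if isinstance(layer, BatchNorm):
                layer.run_mean = next(it).copy()
                layer.run_var = next(it).copy()
                layer._updates = int(next(it)[0])


def build_network(config: NetworkConfig, seed: int = 0, dtype=np.float32) -> Network:
    """Instantiate an untrained network with Glorot-normal weights."""
    return Network(config, seed=seed, dtype=dtype)


def count_parameters(network: Network) -> int:
    """Total learnable scalars: conv/FC weights and biases plus batch-norm
    scale and shift (running statistics are not learnable)."""
    return int(sum(p.size for p, _, _ in network.parameters()))


def count_parameters_closed_form(config: NetworkConfig) -> int:
    """Independent layer-by-layer arithmetic for the parameter count."""
    total = 0
    c_prev = config.input_shape[0]
    for w in config.conv_widths:
        total += 9 * c_prev * w + w
        if config.batchnorm:
            total += 2 * w
        c_prev = w
    side = config.input_shape[1] // (2 ** len(config.pool_positions))
    n_prev = c_prev * side * side
    for j, w in enumerate(config.fc_widths):
        total += n_prev * w + w
        if config.batchnorm and j < len(config.fc_widths) - 1:
            total += 2 * w
        n_prev = w
    return total


# ---------------------------------------------------------------------------
# Loss, preprocessing, training
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


def compute_pixel_mean(images: np.ndarray) -> np.ndarray:
    """Per-pixel mean image over the training fold only."""
    return images.mean(axis=0)


def preprocess(images: np.ndarray, pixel_mean: np.ndarray) -> np.ndarray:
    """Subtract the per-pixel training-set mean; no rescaling."""
    images = np.asarray(images)
    if images.shape[1:] != pixel_mean.shape:
        raise ValueError(
            f"image shape {images.shape[1:]} does not match pixel_mean {pixel_mean.shape}"
        )
    return images - pixel_mean


@dataclass
class TrainedNetwork:
    """A trained classifier: weights, class order, normalization, history."""

    network: Network
    pixel_mean: np.ndarray
    classes: tuple[str, ...]
    history: dict = field(default_factory=dict)
    intensity_scale: float = 65535.0  # images divided by this before mean subtraction

    @property
    def config(self) -> NetworkConfig:
        return self.network.config


def _as_arrays(dataset: Dataset, fold: str, classes: Sequence[str]):
    sub = dataset.manifest[dataset.manifest["fold"] == fold]
    if sub.empty:
        return np.zeros((0,) + (2, 64, 64)), np.zeros(0, dtype=int)
    x = np.stack([dataset.images[c] for c in sub["cell_id"]])
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[l] for l in sub["label"]])
    return x, y


def train(
    network: Network,
    dataset: Dataset,
    train_config: TrainConfig,
) -> TrainedNetwork:
    """Train on the dataset's ``train`` fold with SGD + momentum.

    Minimizes cross-entropy with the stepwise-halved learning rate, weight
    decay on convolution/FC weights, and dropout active only during
    training. After every ``checkpoint_every_epochs`` epochs the validation
    loss is evaluated and the best checkpoint's weights are restored at the
    end (model selection by validation loss). History records per-iteration
    training loss and per-checkpoint validation loss/accuracy.
    """
    classes = tuple(sorted(set(dataset.manifest["label"])))
    x_train, y_train = _as_arrays(dataset, "train", classes)
    if len(x_train) == 0:
        raise ValueError("empty training fold")
    x_val, y_val = _as_arrays(dataset, "val", classes)

    scale = 65535.0
    x_train = x_train / scale
    pixel_mean = compute_pixel_mean(x_train)
    x_train = preprocess(x_train, pixel_mean).astype(network.dtype)
    have_val = len(x_val) > 0
    if have_val:
        x_val = preprocess(x_val / scale, pixel_mean).astype(network.dtype)

    rng = np.random.default_rng(train_config.seed)
    n = len(x_train)
    bs = train_config.batch_size
    velocities = [np.zeros_like(p) for p, _, _ in network.parameters()]

    history = {"iteration": [], "loss": [], "lr": [], "val_loss": [], "val_acc": [],
               "checkpoint_epoch": []}
    best = (np.inf, None)
    iteration = 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            lr = learning_rate_at(
                iteration, train_config.initial_lr, train_config.lr_halving_interval
            )
            if iteration < train_config.warmup_iterations:
                lr *= (iteration + 1) / train_config.warmup_iterations
            logits = network.forward(x_train[idx], train=True, rng=rng)
            loss, dlogits = cross_entropy(logits, y_train[idx])
            network.backward(dlogits)
            for vel, (p, g, decay) in zip(velocities, network.parameters()):
                grad = g + train_config.weight_decay * p if decay else g
                vel *= train_config.momentum
                vel -= lr * grad
                p += vel
            history["iteration"].append(iteration)
            history["loss"].append(loss)
            history["lr"].append(lr)
            iteration += 1
        if (epoch + 1) % train_config.checkpoint_every_epochs == 0 or epoch == train_config.epochs - 1:
            if have_val:
                v_logits = _forward_batched(network, x_val)
                v_loss, _ = cross_entropy(v_logits, y_val)
                v_acc = float((v_logits.argmax(axis=1) == y_val).mean())
            else:  # fall back to training loss for selection
                t_logits = _forward_batched(network, x_train)
                v_loss, _ = cross_entropy(t_logits, y_train)
                v_acc = float((t_logits.argmax(axis=1) == y_train).mean())
            history["val_loss"].append(v_loss)
            history["val_acc"].append(v_acc)
            history["checkpoint_epoch"].append(epoch + 1)
            if v_loss < best[0]:
                best = (v_loss, network.state())
    if best[1] is not None:
        network.load_state(best[1])
    return TrainedNetwork(
        network=network,
        pixel_mean=pixel_mean,
        classes=classes,
        history=history,
        intensity_scale=scale,
    )


def _forward_batched(network: Network, x: np.ndarray, batch: int = 200) -> np.ndarray:
    outs = [network.forward(x[i : i + batch], train=False) for i in range(0, len(x), batch)]
    return np.concatenate(outs)


def predict_proba(trained: TrainedNetwork, images: np.ndarray) -> np.ndarray:
    """Class probabilities for raw images (simplex rows).

    Images are normalized with the network's own intensity scale and pixel
    mean; batch normalization runs in inference mode, so outputs are
    deterministic and independent of batch composition.
    """
    images = np.asarray(images)
    if images.shape[1:] != trained.config.input_shape:
        raise ValueError(
            f"images of shape {images.shape[1:]} do not match network input "
            f"{trained.config.input_shape}"
        )
    x = preprocess(images / trained.intensity_scale, trained.pixel_mean).astype(
        trained.network.dtype
    )
    logits = _forward_batched(trained.network, x)
    return softmax(logits.astype(np.float64))


def predict_labels(trained: TrainedNetwork, images: np.ndarray) -> list[str]:
    """Argmax labels; exact ties resolve to the lowest class index."""
    probs = predict_proba(trained, images)
    return [trained.classes[i] for i in probs.argmax(axis=1)]


def extract_activations(
    trained: TrainedNetwork,
    images: np.ndarray,
    layer_index: int,
    pool: str = "flat",
    batch: int = 200,
) -> np.ndarray:
    """Post-activation outputs of a weight-bearing layer, one row per image.

    ``layer_index`` is 1-based over the 11 weight-bearing layers. Outputs
    are post-ReLU for layers 1..10 and the raw pre-softmax logits for the
    final layer. Convolutional feature maps are flattened (``pool="flat"``)
    or global-average-pooled per channel (``pool="gap"``).
    """
    net = trained.network
    if not (1 <= layer_index <= net.n_weight_layers):
        raise ValueError(
            f"layer_index must be in [1, {net.n_weight_layers}], got {layer_index}"
        )
    images = np.asarray(images)
    x = preprocess(images / trained.intensity_scale, trained.pixel_mean).astype(net.dtype)
    rows = []
    for i in range(0, len(x), batch):
        _, caps = net.forward(x[i : i + batch], train=False, capture=[layer_index])
        act = caps[layer_index]
        if act.ndim == 4:
            act = act.mean(axis=(2, 3)) if pool == "gap" else act.reshape(act.shape[0], -1)
        rows.append(act.astype(np.float64))
    return np.concatenate(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(trained: TrainedNetwork, path) -> None:
    """Serialize a trained network to a single portable ``.npz`` archive.

    The archive stores the configuration, class order, pixel mean,
    intensity scale, and every weight / batch-norm statistic in order.
    """
    config = trained.config
    meta = dict(
        conv_widths=np.array(config.conv_widths),
        fc_widths=np.array(config.fc_widths),
        pool_positions=np.array(config.pool_positions),
        n_classes=np.array(config.n_classes),
        input_shape=np.array(config.input_shape),
        batchnorm=np.array(int(config.batchnorm)),
        dropout_rate=np.array(config.dropout_rate),
        classes=np.array(trained.classes),
        pixel_mean=trained.pixel_mean,
        intensity_scale=np.array(trained.intensity_scale),
    )
    state = trained.network.state()
    arrays = {f"state_{i:04d}": arr for i, arr in enumerate(state)}
    np.savez(path, **meta, **arrays)


def load_model(path) -> TrainedNetwork:
    """Load a network saved by :func:`save_model`."""
    data = np.load(path, allow_pickle=False)
    config = NetworkConfig(
        conv_widths=tuple(int(w) for w in data["conv_widths"]),
        fc_widths=tuple(int(w) for w in data["fc_widths"]),
        pool_positions=tuple(int(p) for p in data["pool_positions"]),
        n_classes=int(data["n_classes"]),
        input_shape=tuple(int(s) for s in data["input_shape"]),
        batchnorm=bool(int(data["batchnorm"])),
        dropout_rate=float(data["dropout_rate"]),
    )
    network = Network(config, seed=0)
    keys = sorted(k for k in data.files if k.startswith("state_"))
    network.load_state([data[k] for k in keys])
    return TrainedNetwork(
        network=network,
        pixel_mean=data["pixel_mean"],
        classes=tuple(str(c) for c in data["classes"]),
        intensity_scale=float(data["intensity_scale"]),
    )
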
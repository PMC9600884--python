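"""UNet slice segmentation: architecture, training regime, and volume inference.

The network is the classic encoder-decoder with skip concatenations: each
encoder level applies two 3x3 convolutions (batch-normalised, leaky-ReLU) and
halves the spatial extent with 2x2 max-pooling; the decoder mirrors it with
nearest-neighbor upsampling followed by a 3x3 convolution, concatenation of
the same-resolution encoder feature map, and two more convolutions.  Dropout
is applied only in the first upsampling stage.  A final 1x1 convolution emits
per-pixel class logits; training minimises sparse categorical cross-entropy
with Adam.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .augment import AugmentConfig, SliceAugmenter
from .volume_io import CTVolume, MaskVolume


@dataclasses.dataclass
class UNetConfig:
    input_shape: tuple[int, int] = (256, 256)
    depth: int = 4
    base_filters: int = 64
    negative_slope: float = 0.2          # encoder leaky-ReLU
    dropout_rate_first_upsample: float = 0.5
    n_classes: int = 2
    batch_norm: bool = True
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.dropout_rate_first_upsample < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        div = 2 ** self.depth
        h, w = self.input_shape
        if h % div or w % div:
            raise ValueError(
                f"input shape {self.input_shape} must be divisible by 2^depth = {div} "
                "so every max-pool halving is exact"
            )


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 20
    learning_rate: float = 1e-4
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


class _ConvBlock:
    """conv -> [batch norm] -> activation."""

    def __init__(self, c_in, c_out, kernel, slope, use_bn, rng):
        self.conv = _nn.Conv2D(c_in, c_out, kernel, rng)
        self.bn = _nn.BatchNorm2D(c_out) if use_bn else None
        self.act = _nn.LeakyReLU(slope)

    def forward(self, x, train):
        x = self.conv.forward(x, train)
        if self.bn is not None:
            x = self.bn.forward(x, train)
        return self.act.forward(x, train)

    def backward(self, d):
        d = self.act.backward(d)
        if self.bn is not None:
            d = self.bn.backward(d)
        return self.conv.backward(d)

    @property
    def layers(self):
        return [self.conv] + ([self.bn] if self.bn is not None else [])


class UNet:
    """The assembled network with explicit forward/backward passes."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        slope = cfg.negative_slope
        c = cfg.in_channels

        self.enc: list[tuple[_ConvBlock, _ConvBlock]] = []
        self.pools: list[_nn.MaxPool2D] = []
        for i in range(cfg.depth):
            f = cfg.base_filters * 2 ** i
            self.enc.append((
                _ConvBlock(c, f, 3, slope, cfg.batch_norm, rng),
                _ConvBlock(f, f, 3, slope, cfg.batch_norm, rng),
            ))
            self.pools.append(_nn.MaxPool2D())
            c = f

        fb = cfg.base_filters * 2 ** cfg.depth
        self.bottleneck = (
            _ConvBlock(c, fb, 3, slope, cfg.batch_norm, rng),
            _ConvBlock(fb, fb, 3, slope, cfg.batch_norm, rng),
        )
        c = fb

        # decoder: ReLU (slope 0) activations
        self.ups: list[_nn.NearestUpsample2D] = []
        self.dec: list[tuple[_ConvBlock, _ConvBlock, _ConvBlock]] = []
        for i in reversed(range(cfg.depth)):
            f = cfg.base_filters * 2 ** i
            self.ups.append(_nn.NearestUpsample2D())
            self.dec.append((
                _ConvBlock(c, f, 3, 0.0, cfg.batch_norm, rng),       # post-upsample conv
                _ConvBlock(2 * f, f, 3, 0.0, cfg.batch_norm, rng),   # after skip concat
                _ConvBlock(f, f, 3, 0.0, cfg.batch_norm, rng),
            ))
            c = f

        self.dropout = _nn.Dropout(cfg.dropout_rate_first_upsample)
        self.final = _nn.Conv2D(c, cfg.n_classes, 1, rng)

    # -- plumbing ----------------------------------------------------------

    @property
    def layers(self) -> list[_nn.Layer]:
        out: list[_nn.Layer] = []
        for s1, s2 in self.enc:
            out += s1.layers + s2.layers
        out += self.bottleneck[0].layers + self.bottleneck[1].layers
        for up, c1, c2 in self.dec:
            out += up.layers + c1.layers + c2.layers
        out.append(self.final)
        return out

    @property
    def n_parameters(self) -> int:
        return sum(ly.n_parameters for ly in self.layers)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        self.dropout.rng = rng

    # -- passes ------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cfg = self.config
        skips = []
        for i, (s1, s2) in enumerate(self.enc):
            x = s2.forward(s1.forward(x, train), train)
            skips.append(x)
            x = self.pools[i].forward(x, train)
        x = self.bottleneck[1].forward(self.bottleneck[0].forward(x, train), train)
        for j, (up, c1, c2) in enumerate(self.dec):
            x = self.ups[j].forward(x, train)
            x = up.forward(x, train)
            if j == 0:
                x = self.dropout.forward(x, train)
            skip = skips[cfg.depth - 1 - j]
            self._last_concat_split = skip.shape[1]
            x = np.concatenate([skip, x], axis=1)
            x = c2.forward(c1.forward(x, train), train)
        return self.final.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        cfg = self.config
        d = self.final.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * cfg.depth
        for j in reversed(range(cfg.depth)):
            up, c1, c2 = self.dec[j]
            d = c1.backward(c2.backward(d))
            f = cfg.base_filters * 2 ** (cfg.depth - 1 - j)
            dskips[cfg.depth - 1 - j] = d[:, :f]
            d = d[:, f:]
            if j == 0:
                d = self.dropout.backward(d)
            d = up.backward(d)
            d = self.ups[j].backward(d)
        d = self.bottleneck[0].backward(self.bottleneck[1].backward(d))
        for i in reversed(range(cfg.depth)):
            d = self.pools[i].backward(d) + dskips[i]
            s1, s2 = self.enc[i]
            d = s1.backward(s2.backward(d))
        return d

    # -- serialization -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, ly in enumerate(self.layers):
            for name, p in ly.params.items():
                out[f"p{i}_{name}"] = p
            for name, b in ly.buffers.items():
                out[f"b{i}_{name}"] = b
        return out

    def load_state_arrays(self, arrays) -> None:
        for i, ly in enumerate(self.layers):
            for name in ly.params:
                ly.params[name] = np.asarray(arrays[f"p{i}_{name}"])
            for name in ly.buffers:
                ly.buffers[name] = np.asarray(arrays[f"b{i}_{name}"])


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    """Construct a :class:`UNet` from a config; parameter count is reportable
    via ``model.n_parameters``."""
    return UNet(config or UNetConfig(), seed=seed)


def train_val_split(n_total: int, train_fraction: float, seed: int):
    """Deterministic shuffled index split; 465 slices at 0.8 -> 372 / 93."""
    if n_total < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_total)
    n_train = int(round(n_total * train_fraction))
    n_train = min(max(n_train, 1), n_total - 1)
    return idx[:n_train], idx[n_train:]


class UNetSegmenter(BaseEstimator):
    """Per-slice IVC-filter segmenter with a scikit-learn estimator surface.

    ``fit`` expects ``X`` of shape ``(n_slices, H, W)`` with intensities
    already normalised to [0, 1] and ``y`` integer label slices of the same
    shape.  ``predict`` returns argmax class maps; ``predict_proba`` the
    softmax class probabilities ``(n, K, H, W)``.

    Fitted attributes: ``model_`` (the network), ``loss_history_`` /
    ``val_loss_history_`` (one entry per epoch), ``n_parameters_``.
    """

    def __init__(self, input_shape=(256, 256), depth=4, base_filters=64,
                 negative_slope=0.2, dropout_rate_first_upsample=0.5,
                 n_classes=2, batch_norm=True,
                 epochs=500, batch_size=20, learning_rate=1e-4,
                 train_fraction=0.8, seed=0, augment=None):
        self.input_shape = input_shape
        self.depth = depth
        self.base_filters = base_filters
        self.negative_slope = negative_slope
        self.dropout_rate_first_upsample = dropout_rate_first_upsample
        self.n_classes = n_classes
        self.batch_norm = batch_norm
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.train_fraction = train_fraction
        self.seed = seed
        self.augment = augment  # AugmentConfig or None

    # -- config assembly ---------------------------------------------------

    def _unet_config(self) -> UNetConfig:
        return UNetConfig(
            input_shape=tuple(self.input_shape), depth=self.depth,
            base_filters=self.base_filters, negative_slope=self.negative_slope,
            dropout_rate_first_upsample=self.dropout_rate_first_upsample,
            n_classes=self.n_classes, batch_norm=self.batch_norm,
        )

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or y.shape != X.shape:
            raise ValueError("X and y must both be (n_slices, H, W) with equal shapes")
        if X.shape[0] == 0:
            raise ValueError("empty dataset")
        if X.shape[1:] != tuple(self.input_shape):
            raise ValueError(
                f"slice shape {X.shape[1:]} does not match input_shape {self.input_shape}")
        if not np.issubdtype(y.dtype, np.integer):
            yi = y.astype(np.int64)
            if not np.array_equal(yi, y):
                raise ValueError("mask labels must be integers")
            y = yi
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError(
                f"mask labels must lie in [0, {self.n_classes}), got "
                f"[{y.min()}, {y.max()}]")
        return X, y.astype(np.int64)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X, y = self._validate_xy(X, y)
        rng = np.random.default_rng(self.seed)
        model = UNet(self._unet_config(), seed=int(rng.integers(2 ** 31)))
        model.set_dropout_rng(np.random.default_rng(int(rng.integers(2 ** 31))))

        if X.shape[0] >= 2 and 0 < self.train_fraction < 1:
            tr_idx, va_idx = train_val_split(X.shape[0], self.train_fraction, self.seed)
        else:
            tr_idx, va_idx = np.arange(X.shape[0]), np.array([], dtype=int)
        self.split_sizes_ = (len(tr_idx), len(va_idx))

        augmenter = None
        if self.augment is not None:
            cfg = self.augment if isinstance(self.augment, AugmentConfig) else \
                AugmentConfig(**self.augment)
            augmenter = SliceAugmenter(cfg)
            augmenter.reseed(int(rng.integers(2 ** 31)))

        opt = _nn.Adam(model.layers, learning_rate=self.learning_rate)
        loss_hist, val_hist = [], []
        for _ in range(self.epochs):
            order = rng.permutation(len(tr_idx))
            epoch_losses = []
            for start in range(0, len(order), self.batch_size):
                batch = tr_idx[order[start:start + self.batch_size]]
                xb = X[batch]
                yb = y[batch]
                if augmenter is not None:
                    xb = xb.copy()
                    yb = yb.copy()
                    for k in range(xb.shape[0]):
                        xb[k], yb[k] = augmenter(xb[k], yb[k])
                logits = model.forward(xb[:, None], train=True)
                loss, dlogits = _nn.softmax_cross_entropy(logits, yb)
                model.backward(dlogits)
                opt.step()
                epoch_losses.append(loss)
            loss_hist.append(float(np.mean(epoch_losses)))
            if len(va_idx):
                logits = model.forward(X[va_idx][:, None], train=False)
                vloss, _ = _nn.softmax_cross_entropy(logits, y[va_idx])
                val_hist.append(vloss)

        self.model_ = model
        self.loss_history_ = loss_hist
        self.val_loss_history_ = val_hist
        self.n_parameters_ = model.n_parameters
        self.classes_ = np.arange(self.n_classes)
        return self

    def _check_input(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1:] != tuple(self.input_shape):
            raise ValueError(
                f"expected (n, {self.input_shape[0]}, {self.input_shape[1]}) input, "
                f"got {X.shape}")
        return X

    def predict_proba(self, X, batch_size: int = 16) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("segmenter is not fitted")
        X = self._check_input(X)
        out = []
        for start in range(0, X.shape[0], batch_size):
            logits = self.model_.forward(X[start:start + batch_size][:, None], train=False)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def predict(self, X, batch_size: int = 16) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("segmenter is not fitted")
        X = self._check_input(X)
        out = []
        for start in range(0, X.shape[0], batch_size):
            logits = self.model_.forward(X[start:start + batch_size][:, None], train=False)
            out.append(logits.argmax(axis=1).astype(np.uint8))
        return np.concatenate(out, axis=0)

    # -- volume-level inference --------------------------------------------

    def predict_volume(self, volume: CTVolume) -> MaskVolume:
        """Segment every slice of a preprocessed volume into a MaskVolume."""
        labels = self.predict(volume.voxels)
        return MaskVolume(labels=labels, spacing=volume.spacing, scan_id=volume.scan_id)

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        """Self-describing checkpoint: estimator params + weights + BN stats."""
        if not hasattr(self, "model_"):
            raise RuntimeError("segmenter is not fitted")
        meta = {k: v for k, v in self.get_params().items()}
        if isinstance(meta.get("augment"), AugmentConfig):
            meta["augment"] = dataclasses.asdict(meta["augment"])
        meta["input_shape"] = list(tuple(meta["input_shape"]))
        np.savez(path,
                 _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 _loss_history=np.asarray(self.loss_history_, dtype=np.float64),
                 _val_loss_history=np.asarray(self.val_loss_history_, dtype=np.float64),
                 **self.model_.state_arrays())

    @classmethod
    def load(cls, path) -> "UNetSegmenter":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            if meta.get("augment") is not None:
                meta["augment"] = AugmentConfig(**meta["augment"])
            meta["input_shape"] = tuple(meta["input_shape"])
            est = cls(**meta)
            model = UNet(est._unet_config(), seed=0)
            model.load_state_arrays(data)
            est.model_ = model
            est.loss_history_ = list(data["_loss_history"])
            est.val_loss_history_ = list(data["_val_loss_history"])
        est.n_parameters_ = est.model_.n_parameters
        est.classes_ = np.arange(est.n_classes)
        return est
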
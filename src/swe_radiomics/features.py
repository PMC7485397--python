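"""Deep radiomic feature extraction.

The extractor is a small CNN — two 3x3 convolution blocks (depths 32 and
64, each followed by ReLU and 2x2 max-pooling) and three fully connected
layers (512, 256, 2) with a 0.5-dropout after the 512 layer — trained on
lesion patches with the benign/malignant diagnosis as label.  After
training, the post-ReLU activations of the 512- and 256-node layers are
concatenated into the deep radiomic feature vector, 512 + 256 = 768 values
at the default widths.

Training follows the reference regimen: stratified 8:2 train/internal
validation split, on-the-fly horizontal/vertical flips and random rescaling
on the training stream only, SGD (learning rate 0.01) on categorical
cross-entropy for 80 epochs, keeping the checkpoint with the best
internal-validation accuracy.  At the full 302x430 input geometry the first
dense layer is enormous; desk-scale runs use a reduced input (96x128 by
default here) with the identical layer stack.

Exposed both as an sklearn-style transformer (:class:`CNNFeatureExtractor`)
and as the functional wrappers ``build_network`` / ``train_network`` /
``extract_features``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import rescale as _sk_rescale
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .exceptions import ArchitectureError, DegenerateLabelError
from .io_roi import PatchInput

EXTRACTOR_VERSION = "npcnn-1:postrelu-fc512+fc256"


@dataclass
class NetworkConfig:
    """Layer geometry; defaults are the full-scale reference architecture."""

    input_size: tuple[int, int, int] = (302, 430, 3)  # (height, width, channels)
    conv_depths: tuple[int, int] = (32, 64)
    conv_kernel: int = 3
    pool_kernel: int = 2
    fc_sizes: tuple[int, int, int] = (512, 256, 2)
    dropout_rate: float = 0.5

    def validate(self) -> None:
        if self.fc_sizes[-1] != 2:
            raise ArchitectureError("final layer width must equal the 2 classes")
        if not 0 <= self.dropout_rate < 1:
            raise ArchitectureError("dropout rate must be in [0, 1)")
        h, w, c = self.input_size
        if h // (self.pool_kernel ** 2) < 1 or w // (self.pool_kernel ** 2) < 1:
            raise ArchitectureError("input too small for two pooling stages")
        if c not in (1, 3):
            raise ArchitectureError("input channels must be 1 or 3")


@dataclass
class TrainingConfig:
    """Optimization regimen; defaults mirror the reference recipe."""

    epochs: int = 80
    learning_rate: float = 0.01
    momentum: float = 0.0
    batch_size: int = 8
    validation_fraction: float = 0.2  # the 8:2 internal split
    augment: bool = True
    rescale_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation fraction must be in (0, 1)")


def feature_dimension(cfg: NetworkConfig) -> int:
    """Length of the deep feature vector: sum of the two penultimate FC widths."""
    return cfg.fc_sizes[0] + cfg.fc_sizes[1]


def build_network(cfg: NetworkConfig) -> list[dict]:
    """Describe the layer stack: name, output shape, parameter count.

    Pure arithmetic — no weights are allocated, so the description works at
    the full input geometry too.
    """
    cfg.validate()
    h, w, c = cfg.input_size
    k = cfg.conv_kernel
    desc = []
    in_ch = c
    for depth in cfg.conv_depths:
        desc.append(
            {"layer": f"conv{k}x{k}-{depth}", "output_shape": (h, w, depth),
             "n_params": k * k * in_ch * depth + depth}
        )
        desc.append({"layer": "relu", "output_shape": (h, w, depth), "n_params": 0})
        h, w = h // cfg.pool_kernel, w // cfg.pool_kernel
        desc.append({"layer": f"maxpool{cfg.pool_kernel}x{cfg.pool_kernel}",
                     "output_shape": (h, w, depth), "n_params": 0})
        in_ch = depth
    flat = h * w * in_ch
    desc.append({"layer": "flatten", "output_shape": (flat,), "n_params": 0})
    widths = [flat, *cfg.fc_sizes]
    for i, (n_in, n_out) in enumerate(zip(widths[:-1], widths[1:])):
        desc.append({"layer": f"fc{n_out}", "output_shape": (n_out,),
                     "n_params": n_in * n_out + n_out})
        if i < len(cfg.fc_sizes) - 1:
            desc.append({"layer": "relu", "output_shape": (n_out,), "n_params": 0})
        if i == 0:
            desc.append({"layer": f"dropout{cfg.dropout_rate}",
                         "output_shape": (n_out,), "n_params": 0})
    return desc


def _instantiate(cfg: NetworkConfig, rng: np.random.Generator) -> _nn.Network:
    cfg.validate()
    h, w, c = cfg.input_size
    layers: list[_nn.Layer] = []
    in_ch = c
    for depth in cfg.conv_depths:
        layers += [_nn.Conv2D(in_ch, depth, cfg.conv_kernel, rng), _nn.ReLU(), _nn.MaxPool2()]
        h, w = h // cfg.pool_kernel, w // cfg.pool_kernel
        in_ch = depth
    layers.append(_nn.Flatten())
    widths = [h * w * in_ch, *cfg.fc_sizes]
    feature_layers = []
    for i, (n_in, n_out) in enumerate(zip(widths[:-1], widths[1:])):
        layers.append(_nn.Dense(n_in, n_out, rng))
        if i < len(cfg.fc_sizes) - 1:
            layers.append(_nn.ReLU())
            feature_layers.append(len(layers) - 1)  # capture post-ReLU activations
        if i == 0:
            layers.append(_nn.Dropout(cfg.dropout_rate, rng))
    return _nn.Network(layers, feature_layers=tuple(feature_layers))


@dataclass
class FeatureVector:
    values: np.ndarray
    modality: str
    case_id: str
    extractor_version: str = EXTRACTOR_VERSION


def _augment_batch(x: np.ndarray, rng: np.random.Generator,
                   rescale_range: tuple[float, float]) -> np.ndarray:
    """Random horizontal/vertical flips and zoom, per sample."""
    out = np.empty_like(x)
    h, w = x.shape[1:3]
    for i in range(x.shape[0]):
        img = x[i]
        if rng.uniform() < 0.5:
            img = img[:, ::-1]
        if rng.uniform() < 0.5:
            img = img[::-1, :]
        factor = rng.uniform(*rescale_range)
        if abs(factor - 1.0) > 1e-3:
            z = _sk_rescale(img, factor, order=1, channel_axis=2,
                            preserve_range=True, anti_aliasing=False)
            zh, zw = z.shape[:2]
            if factor >= 1.0:  # center crop back
                r0, c0 = (zh - h) // 2, (zw - w) // 2
                img = z[r0 : r0 + h, c0 : c0 + w]
            else:  # pad back with zeros
                img = np.zeros_like(x[i])
                r0, c0 = (h - zh) // 2, (w - zw) // 2
                img[r0 : r0 + zh, c0 : c0 + zw] = z
        out[i] = img
    return out.astype(np.float32)


class CNNFeatureExtractor(BaseEstimator, TransformerMixin):
    """CNN trained on lesion patches; ``transform`` emits deep radiomic features.

    Parameters
    ----------
    net_config, train_config :
        Geometry and regimen.  ``None`` selects the desk-scale defaults
        (96x128x3 input, 20 epochs); pass explicit configs for the
        full-scale geometry or the 80-epoch regimen.

    Fitted attributes
    -----------------
    network_ : the trained layer stack (best internal-validation checkpoint)
    history_ : per-epoch DataFrame (train loss/acc, validation acc)
    best_epoch_, best_val_accuracy_ : model-selection record
    n_features_out_ : feature vector length (512 + 256 = 768 by default)
    classes_ : sorted class labels (benign=0, malignant=1 ordering by sort)
    """

    def __init__(self, net_config: NetworkConfig | None = None,
                 train_config: TrainingConfig | None = None):
        self.net_config = net_config
        self.train_config = train_config

    def _configs(self) -> tuple[NetworkConfig, TrainingConfig]:
        net = self.net_config or NetworkConfig(input_size=(96, 128, 3))
        train = self.train_config or TrainingConfig(epochs=20)
        return net, train

    def _check_X(self, X, net: NetworkConfig) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1:] != tuple(net.input_size):
            raise ValueError(
                f"X must have shape (n, {net.input_size[0]}, {net.input_size[1]}, "
                f"{net.input_size[2]}), got {X.shape}"
            )
        return X

    def fit(self, X, y):
        net_cfg, train_cfg = self._configs()
        net_cfg.validate()
        train_cfg.validate()
        X = self._check_X(X, net_cfg)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise DegenerateLabelError(
                f"need both classes, got {list(self.classes_)}"
            )
        if np.bincount(y_idx).min() < 2:
            raise DegenerateLabelError("need at least 2 cases per class")

        rng = np.random.default_rng(train_cfg.seed)
        net = _instantiate(net_cfg, np.random.default_rng(train_cfg.seed + 1))
        opt = _nn.SGD(net, lr=train_cfg.learning_rate, momentum=train_cfg.momentum)

        idx_train, idx_val = train_test_split(
            np.arange(len(y_idx)),
            test_size=train_cfg.validation_fraction,
            stratify=y_idx,
            random_state=train_cfg.seed % (2**32 - 1),
        )
        Xtr, ytr = X[idx_train], y_idx[idx_train]
        Xval, yval = X[idx_val], y_idx[idx_val]

        history = []
        best = (-np.inf, None, -1)
        for epoch in range(train_cfg.epochs):
            order = rng.permutation(len(ytr))
            losses, correct = [], 0
            for start in range(0, len(order), train_cfg.batch_size):
                sel = order[start : start + train_cfg.batch_size]
                xb = Xtr[sel]
                if train_cfg.augment:
                    xb = _augment_batch(xb, rng, train_cfg.rescale_range)
                logits = net.forward(xb, train=True)
                loss, dlogits = _nn.cross_entropy(logits, ytr[sel])
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
                correct += int((logits.argmax(axis=1) == ytr[sel]).sum())
            val_logits = net.forward(Xval, train=False)
            val_acc = float((val_logits.argmax(axis=1) == yval).mean())
            history.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "train_accuracy": correct / len(ytr), "val_accuracy": val_acc}
            )
            if val_acc > best[0]:
                best = (val_acc, net.get_weights(), epoch)
        net.set_weights(best[1])
        self.network_ = net
        self.history_ = pd.DataFrame(history)
        self.best_val_accuracy_ = float(best[0])
        self.best_epoch_ = int(best[2])
        self.n_features_out_ = feature_dimension(net_cfg)
        self.net_config_ = net_cfg
        self.train_config_ = train_cfg
        return self

    def transform(self, X) -> np.ndarray:
        """Deep radiomic features: concatenated post-ReLU FC512 and FC256 activations."""
        check_is_fitted(self, "network_")
        X = self._check_X(X, self.net_config_)
        feats = []
        for start in range(0, len(X), 32):  # chunked to bound memory
            _, captured = self.network_.forward(X[start : start + 32],
                                                train=False, capture=True)
            feats.append(np.concatenate(captured, axis=1))
        return np.concatenate(feats, axis=0)

    def predict(self, X):
        check_is_fitted(self, "network_")
        X = self._check_X(X, self.net_config_)
        logits = self.network_.forward(X, train=False)
        return self.classes_[logits.argmax(axis=1)]

    def weights_hash(self) -> str:
        """Hex digest of all trained weights (determinism checks)."""
        import hashlib

        h = hashlib.sha256()
        for w in self.network_.get_weights():
            h.update(np.ascontiguousarray(w).tobytes())
        return h.hexdigest()


def train_network(
    patches: Sequence[PatchInput],
    labels: Sequence[str],
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainingConfig | None = None,
) -> CNNFeatureExtractor:
    """Fit a :class:`CNNFeatureExtractor` on a list of patches."""
    X = np.stack([p.pixels for p in patches])
    model = CNNFeatureExtractor(net_config=net_cfg, train_config=train_cfg)
    return model.fit(X, np.asarray(labels))


def extract_features(model: CNNFeatureExtractor, patch: PatchInput) -> FeatureVector:
    """Feature vector of one patch, evaluated in inference mode (dropout off)."""
    values = model.transform(patch.pixels[None])[0]
    return FeatureVector(values=values, modality=patch.source_modality,
                         case_id=patch.case_id)


def features_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """CSV-ready table: case_id, modality, f000..fNNN."""
    rows = []
    for v in vectors:
        row = {"case_id": v.case_id, "modality": v.modality}
        row.update({f"f{i:03d}": float(x) for i, x in enumerate(v.values)})
        rows.append(row)
    return pd.DataFrame(rows)
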
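"""The generalizable segment classifier.

A two-layer convolutional encoder reads raw preprocessed 16 x 1280
segments end to end (3x3 kernels, stride 1, batch normalization in every
layer, ReLU, dropout, one 2x2/stride-2 max pool) and feeds either a
two-hidden-layer fully connected softmax head or an SVM fitted on the
flattened encoder features. Both heads expose the same score contract:
higher means more preictal-like.

Block ordering inside each layer is conv -> batch norm -> ReLU -> dropout.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .windowing import SegmentSet

__all__ = [
    "EncoderSpec",
    "HeadSpec",
    "TrainConfig",
    "ModelBundle",
    "DivergenceError",
    "ENCODER_GROUPS",
    "build_encoder",
    "train_generalizable",
    "predict_scores",
]

#: Parameter-group names that make up the convolutional encoder.
ENCODER_GROUPS = ("conv1", "bn1", "conv2", "bn2")


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of the convolutional feature extractor.

    Exactly two 3x3/stride-1 convolution layers with batch normalization,
    followed by one 2x2/stride-2 max pool. ``channels`` sets the filter
    counts of the two layers.
    """

    channels: tuple[int, int] = (16, 32)
    kernel: int = 3
    stride: int = 1
    pool: int = 2
    conv_dropout: float = 0.25
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if len(self.channels) != 2 or any(c < 1 for c in self.channels):
            raise ValueError("encoder must have exactly 2 conv layers")
        if self.kernel != 3 or self.stride != 1 or self.pool != 2:
            raise ValueError("encoder uses 3x3 kernels, stride 1, 2x2 pool")
        if not self.batch_norm:
            raise ValueError("batch normalization is used in all layers")
        if not 0.0 <= self.conv_dropout < 1.0:
            raise ValueError("conv_dropout must be in [0, 1)")

    def feature_dim(self, n_channels: int = 16, n_samples: int = 1280) -> int:
        """Flattened feature length after the pooling stage."""
        if n_channels % 2 or n_samples % 2:
            raise ValueError("input height/width must be divisible by the pool")
        return self.channels[1] * (n_channels // 2) * (n_samples // 2)


@dataclass(frozen=True)
class HeadSpec:
    """Classifier head: FC-softmax (two hidden layers) or SVM on features."""

    kind: str = "fc"
    fc_hidden: tuple[int, int] = (256, 64)
    fc_dropout: float = 0.5
    svm_kernel: str = "linear"
    svm_C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("fc", "svm"):
            raise ValueError(f"head kind must be 'fc' or 'svm', got {self.kind!r}")
        if len(self.fc_hidden) != 2:
            raise ValueError("FC head has exactly two hidden layers")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")


@dataclass(frozen=True)
class TrainConfig:
    seed: int = 0
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 5
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if not 0.0 <= self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in [0, 0.5)")


class ConvNet:
    """Parameter container + forward/backward for encoder and FC head."""

    def __init__(self, encoder: EncoderSpec, head: HeadSpec,
                 n_channels: int = 16, n_samples: int = 1280, seed: int = 0):
        self.encoder_spec = encoder
        self.head_spec = head
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.seed = seed
        c1, c2 = encoder.channels
        h1, h2 = head.fc_hidden
        feat = encoder.feature_dim(n_channels, n_samples)
        rng = np.random.default_rng(seed)
        hi = _nn.he_init
        self.params: dict[str, np.ndarray] = {
            "conv1.W": hi(rng, (c1, 1, 3, 3), 9),
            "conv1.b": np.zeros(c1, np.float32),
            "bn1.gamma": np.ones(c1, np.float32),
            "bn1.beta": np.zeros(c1, np.float32),
            "conv2.W": hi(rng, (c2, c1, 3, 3), 9 * c1),
            "conv2.b": np.zeros(c2, np.float32),
            "bn2.gamma": np.ones(c2, np.float32),
            "bn2.beta": np.zeros(c2, np.float32),
            "fc1.W": hi(rng, (feat, h1), feat),
            "fc1.b": np.zeros(h1, np.float32),
            "bnf1.gamma": np.ones(h1, np.float32),
            "bnf1.beta": np.zeros(h1, np.float32),
            "fc2.W": hi(rng, (h1, h2), h1),
            "fc2.b": np.zeros(h2, np.float32),
            "bnf2.gamma": np.ones(h2, np.float32),
            "bnf2.beta": np.zeros(h2, np.float32),
            "out.W": hi(rng, (h2, 2), h2),
            "out.b": np.zeros(2, np.float32),
        }
        self.buffers: dict[str, np.ndarray] = {}
        for name, dim in (("bn1", c1), ("bn2", c2), ("bnf1", h1), ("bnf2", h2)):
            self.buffers[f"{name}.mean"] = np.zeros(dim, np.float32)
            self.buffers[f"{name}.var"] = np.ones(dim, np.float32)

    # -- helpers ----------------------------------------------------------
    @property
    def feature_dim(self) -> int:
        return self.encoder_spec.feature_dim(self.n_channels, self.n_samples)

    def param_names(self, groups: tuple[str, ...] | None = None) -> list[str]:
        if groups is None:
            return list(self.params)
        return [n for n in self.params if n.split(".")[0] in groups]

    def encoder_params(self) -> dict[str, np.ndarray]:
        enc = {n: self.params[n] for n in self.param_names(ENCODER_GROUPS)}
        enc.update({k: v for k, v in self.buffers.items()
                    if k.split(".")[0] in ENCODER_GROUPS})
        return enc

    def _bn(self, name, x, train):
        return _nn.bn_forward(
            x, self.params[f"{name}.gamma"], self.params[f"{name}.beta"],
            self.buffers[f"{name}.mean"], self.buffers[f"{name}.var"], train,
        )

    # -- forward ----------------------------------------------------------
    @staticmethod
    def _standardize_input(x: np.ndarray) -> np.ndarray:
        """Per-window, per-channel standardization before the first conv.

        Makes the encoder invariant to slow gain drift and to the overall
        scale of the recording a window came from, leaving spectral shape
        and cross-channel structure as the only cues.
        """
        mu = x.mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1, keepdims=True)
        return ((x - mu) / (sd + 1e-6)).astype(np.float32)

    def encoder_forward(self, x, train=False, rng=None):
        p = self.params
        x = self._standardize_input(x)
        cache: dict = {"x": x}
        c1 = _nn.conv3x3_forward(x, p["conv1.W"], p["conv1.b"])
        b1, cache["bn1"] = self._bn("bn1", c1, train)
        r1, cache["relu1"] = _nn.relu_forward(b1)
        d1, cache["drop1"] = _nn.dropout_forward(
            r1, self.encoder_spec.conv_dropout, train, rng)
        cache["d1"] = d1
        c2 = _nn.conv3x3_forward(d1, p["conv2.W"], p["conv2.b"])
        b2, cache["bn2"] = self._bn("bn2", c2, train)
        r2, cache["relu2"] = _nn.relu_forward(b2)
        d2, cache["drop2"] = _nn.dropout_forward(
            r2, self.encoder_spec.conv_dropout, train, rng)
        pooled, cache["pool"] = _nn.maxpool2x2_forward(d2)
        feats = pooled.reshape(pooled.shape[0], -1)
        cache["pooled_shape"] = pooled.shape
        return feats, cache

    def head_forward(self, feats, train=False, rng=None):
        p = self.params
        cache: dict = {"feats": feats}
        h = _nn.dense_forward(feats, p["fc1.W"], p["fc1.b"])
        h, cache["bnf1"] = self._bn("bnf1", h, train)
        h, cache["relu1"] = _nn.relu_forward(h)
        h, cache["drop1"] = _nn.dropout_forward(
            h, self.head_spec.fc_dropout, train, rng)
        cache["a1"] = h
        h2 = _nn.dense_forward(h, p["fc2.W"], p["fc2.b"])
        h2, cache["bnf2"] = self._bn("bnf2", h2, train)
        h2, cache["relu2"] = _nn.relu_forward(h2)
        h2, cache["drop2"] = _nn.dropout_forward(
            h2, self.head_spec.fc_dropout, train, rng)
        cache["a2"] = h2
        logits = _nn.dense_forward(h2, p["out.W"], p["out.b"])
        return logits, cache

    def forward(self, x, train=False, rng=None):
        feats, enc_cache = self.encoder_forward(x, train, rng)
        logits, head_cache = self.head_forward(feats, train, rng)
        return logits, (enc_cache, head_cache)

    # -- backward ---------------------------------------------------------
    def head_backward(self, dlogits, cache):
        p = self.params
        g: dict[str, np.ndarray] = {}
        d, g["out.W"], g["out.b"] = _nn.dense_backward(
            cache["a2"], p["out.W"], dlogits)
        if cache["drop2"] is not None:
            d = d * cache["drop2"]
        d = d * cache["relu2"]
        d, g["bnf2.gamma"], g["bnf2.beta"] = _nn.bn_backward(d, cache["bnf2"])
        d, g["fc2.W"], g["fc2.b"] = _nn.dense_backward(
            cache["a1"], p["fc2.W"], d)
        if cache["drop1"] is not None:
            d = d * cache["drop1"]
        d = d * cache["relu1"]
        d, g["bnf1.gamma"], g["bnf1.beta"] = _nn.bn_backward(d, cache["bnf1"])
        dfeats, g["fc1.W"], g["fc1.b"] = _nn.dense_backward(
            cache["feats"], p["fc1.W"], d)
        return dfeats, g

    def encoder_backward(self, dfeats, cache):
        p = self.params
        g: dict[str, np.ndarray] = {}
        d = _nn.maxpool2x2_backward(
            dfeats.reshape(cache["pooled_shape"]), cache["pool"])
        if cache["drop2"] is not None:
            d = d * cache["drop2"]
        d = d * cache["relu2"]
        d, g["bn2.gamma"], g["bn2.beta"] = _nn.bn_backward(d, cache["bn2"])
        d, g["conv2.W"], g["conv2.b"] = _nn.conv3x3_backward(
            cache["d1"], p["conv2.W"], d)
        if cache["drop1"] is not None:
            d = d * cache["drop1"]
        d = d * cache["relu1"]
        d, g["bn1.gamma"], g["bn1.beta"] = _nn.bn_backward(d, cache["bn1"])
        _, g["conv1.W"], g["conv1.b"] = _nn.conv3x3_backward(
            cache["x"], p["conv1.W"], d)
        return g

    def backward(self, dlogits, cache):
        enc_cache, head_cache = cache
        dfeats, grads = self.head_backward(dlogits, head_cache)
        grads.update(self.encoder_backward(dfeats, enc_cache))
        return grads

    # -- inference --------------------------------------------------------
    def encode(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        """Eval-mode encoder features, batched; x is (N, 1, H, W)."""
        out = []
        for i in range(0, x.shape[0], batch):
            feats, _ = self.encoder_forward(x[i:i + batch], train=False)
            out.append(feats)
        return np.concatenate(out, axis=0)

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        """Eval-mode softmax probabilities (N, 2)."""
        out = []
        for i in range(0, x.shape[0], batch):
            logits, _ = self.forward(x[i:i + batch], train=False)
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            out.append(ez / ez.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def state(self):
        return (copy.deepcopy(self.params), copy.deepcopy(self.buffers))

    def load_state(self, state) -> None:
        params, buffers = state
        self.params = copy.deepcopy(params)
        self.buffers = copy.deepcopy(buffers)


def build_encoder(spec: EncoderSpec = EncoderSpec(), head: HeadSpec = HeadSpec(),
                  n_channels: int = 16, n_samples: int = 1280,
                  seed: int = 0) -> ConvNet:
    """Deterministically initialized, untrained network for the given specs."""
    return ConvNet(spec, head, n_channels, n_samples, seed)


@dataclass
class ModelBundle:
    """A trained encoder plus classifier head, with provenance.

    ``svm`` is the fitted scikit-learn estimator when the head kind is
    ``"svm"`` (the net's own FC head was then only a training scaffold).
    ``frozen_mask`` names the parameter groups held fixed by the last
    training step (empty for the generalizable fit).
    """

    encoder_spec: EncoderSpec
    head_spec: HeadSpec
    net: ConvNet
    svm: object | None = None
    frozen_mask: frozenset = frozenset()
    train_meta: dict = field(default_factory=dict)

    def encoder_params(self) -> dict[str, np.ndarray]:
        return self.net.encoder_params()

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self.net.encode(np.asarray(X, np.float32))

    def predict_scores(self, segments) -> np.ndarray:
        return predict_scores(self, segments)


def _as_batch(segments) -> np.ndarray:
    if isinstance(segments, SegmentSet):
        X = segments.X
    else:
        X = np.asarray(segments, np.float32)
    if X.ndim == 3:
        X = X[:, None, :, :]
    if X.ndim != 4:
        raise ValueError(f"expected (n, channels, samples) segments, got {X.shape}")
    return X


def predict_scores(bundle: ModelBundle, segments) -> np.ndarray:
    """Per-segment preictal score, in input order.

    FC head: softmax probability of the preictal class (in [0, 1]).
    SVM head: decision-function value (any real; monotone in confidence).
    """
    X = _as_batch(segments)
    if X.shape[2] != bundle.net.n_channels or X.shape[3] != bundle.net.n_samples:
        raise ValueError(
            f"segment shape {X.shape[2:]} does not match model input "
            f"({bundle.net.n_channels}, {bundle.net.n_samples})"
        )
    if bundle.head_spec.kind == "svm":
        feats = bundle.net.encode(X)
        return np.asarray(bundle.svm.decision_function(feats))
    return bundle.net.predict_proba(X)[:, 1]


def _stratified_split(y: np.ndarray, val_fraction: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * idx.size))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(train_idx), np.sort(val_idx)


def _run_epochs(net, X, y, Xval, yval, cfg: TrainConfig, trainable: list[str],
                lr: float, epochs: int, rng: np.random.Generator,
                forward, backward):
    """Shared mini-batch loop for full training and head fine-tuning."""
    opt = _nn.Adam(lr=lr)
    train_losses, val_losses = [], []
    best = (np.inf, net.state(), 0)
    for epoch in range(epochs):
        order = rng.permutation(X.shape[0])
        losses = []
        for i in range(0, order.size, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            if idx.size < 2:
                continue  # batch norm needs >= 2 samples
            logits, cache = forward(X[idx], True, rng)
            loss, _, dlogits = _nn.softmax_xent(logits, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            grads = backward(dlogits, cache)
            opt.step(net.params, {k: grads[k] for k in trainable})
            losses.append(loss)
        train_losses.append(float(np.mean(losses)))
        if Xval is not None and len(yval):
            logits, _ = forward(Xval, False, None)
            vloss, _, _ = _nn.softmax_xent(logits, yval)
        else:
            vloss = train_losses[-1]
        val_losses.append(float(vloss))
        if vloss < best[0] - 1e-6:
            best = (vloss, net.state(), epoch)
        elif epoch - best[2] >= cfg.early_stop_patience:
            break
    net.load_state(best[1])
    return train_losses, val_losses


def train_generalizable(
    train_set: SegmentSet,
    cfg: TrainConfig = TrainConfig(),
    head: HeadSpec = HeadSpec(),
    encoder: EncoderSpec = EncoderSpec(),
) -> ModelBundle:
    """Fit the end-to-end classifier on a balanced training SegmentSet.

    The encoder+FC stack is always trained jointly with cross-entropy;
    for an SVM head the FC stack is a scaffold and the SVM is then fitted
    on the frozen flattened features. Fully deterministic under
    ``cfg.seed``.
    """
    if train_set.split != "train":
        raise ValueError("train_generalizable requires a split='train' SegmentSet")
    n_pre, n_int = train_set.count("preictal"), train_set.count("interictal")
    if n_pre != n_int:
        raise ValueError(f"unbalanced training set: {n_pre} preictal vs "
                         f"{n_int} interictal")
    X = train_set.X[:, None, :, :]
    y = train_set.y
    net = ConvNet(encoder, head, X.shape[2], X.shape[3], seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    tr, va = _stratified_split(y, cfg.val_fraction, rng)
    train_losses, val_losses = _run_epochs(
        net, X[tr], y[tr], X[va] if va.size else None, y[va],
        cfg, net.param_names(), cfg.learning_rate, cfg.epochs, rng,
        net.forward, net.backward,
    )
    bundle = ModelBundle(
        encoder_spec=encoder, head_spec=head, net=net,
        train_meta={
            "seed": cfg.seed,
            "epochs_run": len(train_losses),
            "train_losses": train_losses,
            "val_losses": val_losses,
        },
    )
    if head.kind == "svm":
        from sklearn.svm import SVC

        feats = net.encode(X)
        svm = SVC(kernel=head.svm_kernel, C=head.svm_C, random_state=cfg.seed)
        svm.fit(feats, y)
        bundle.svm = svm
    return bundle


# ---------------------------------------------------------------------------
# persistence

def save_bundle(bundle: ModelBundle, out_dir: str | Path) -> Path:
    """Serialize a bundle to a directory (arrays + JSON metadata)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = dict(bundle.net.params)
    arrays.update({f"buffer::{k}": v for k, v in bundle.net.buffers.items()})
    np.savez(out_dir / "params.npz", **arrays)
    meta = {
        "encoder_spec": asdict(bundle.encoder_spec),
        "head_spec": asdict(bundle.head_spec),
        "n_channels": bundle.net.n_channels,
        "n_samples": bundle.net.n_samples,
        "seed": bundle.net.seed,
        "frozen_mask": sorted(bundle.frozen_mask),
        "train_meta": bundle.train_meta,
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1))
    if bundle.svm is not None:
        import joblib

        joblib.dump(bundle.svm, out_dir / "svm.joblib")
    return out_dir


def load_bundle(in_dir: str | Path) -> ModelBundle:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    enc = EncoderSpec(**{**meta["encoder_spec"],
                         "channels": tuple(meta["encoder_spec"]["channels"])})
    head = HeadSpec(**{**meta["head_spec"],
                       "fc_hidden": tuple(meta["head_spec"]["fc_hidden"])})
    net = ConvNet(enc, head, meta["n_channels"], meta["n_samples"], meta["seed"])
    with np.load(in_dir / "params.npz") as arrays:
        for k in arrays.files:
            if k.startswith("buffer::"):
                net.buffers[k.removeprefix("buffer::")] = arrays[k]
            else:
                net.params[k] = arrays[k]
    svm = None
    if (in_dir / "svm.joblib").exists():
        import joblib

        svm = joblib.load(in_dir / "svm.joblib")
    return ModelBundle(
        encoder_spec=enc, head_spec=head, net=net, svm=svm,
        frozen_mask=frozenset(meta["frozen_mask"]),
        train_meta=meta["train_meta"],
    )
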
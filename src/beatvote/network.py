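"""The residual 1-D convolutional base classifier.

Nine stride-1 convolutional layers with kernel size 17 act on the raw
beat window (no filtering or standardisation).  The first five layers
have 20 filters, the last four 40.  Every convolution is followed by
batch normalisation; the first layer uses Tanh, all others ReLU; a 40%
dropout follows layers 3–9.  Skip connections span consecutive pairs of
layers (2-3, 4-5, 6-7, 8-9), with a 1x1 projection on the single 20->40
channel transition; after the last skip a further batch-norm + ReLU is
applied, then global average pooling and a fully connected layer produce
the 5-way softmax.

The network is implemented directly on the numpy layer primitives in
``beatvote._nn``; everything — initialisation, dropout, batching — is
driven by explicit seeds, so two builds from the same seed are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from . import _nn
from .dataset import AAMI_CLASSES, AamiClass
from .losses import FocalLossParams, focal_loss_and_grad
from .sampling import TrainingSet
from .segmentation import BeatSegment

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "TrainedClassifier",
    "ResidualConvNet",
    "build_model",
    "train",
    "predict",
    "predict_proba_batch",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer plan of the base network.

    ``filters[i]`` is the output width of conv layer ``i+1``; dropout is
    applied after the conv layers listed in ``dropout_layers`` (1-based).
    """

    kernel_size: int = 17
    filters: tuple[int, ...] = (20, 20, 20, 20, 20, 40, 40, 40, 40)
    dropout_rate: float = 0.40
    dropout_layers: frozenset[int] = frozenset(range(3, 10))
    n_classes: int = 5

    def __post_init__(self) -> None:
        if len(self.filters) != 9:
            raise ValueError("the base network has exactly 9 conv layers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def default(cls) -> "ArchitectureSpec":
        return cls()

    @classmethod
    def scaled_down(cls) -> "ArchitectureSpec":
        """Same topology, thinner layers (8/16 filters) for small studies."""
        return cls(filters=(8, 8, 8, 8, 8, 16, 16, 16, 16))


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyper-parameters (none are dictated by the model)."""

    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 60
    patience: int = 8
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")


class ResidualConvNet:
    """Forward/backward implementation of the 9-layer residual ConvNet."""

    def __init__(self, input_length: int, spec: ArchitectureSpec, seed: int,
                 dtype=np.float32):
        if input_length < spec.kernel_size:
            raise ValueError(
                f"input_length {input_length} shorter than one kernel "
                f"({spec.kernel_size})"
            )
        self.input_length = input_length
        self.spec = spec
        self.dtype = dtype
        rng = np.random.Generator(np.random.PCG64(seed))
        f = spec.filters
        k = spec.kernel_size

        def drop(layer_no: int):
            if layer_no in spec.dropout_layers and spec.dropout_rate > 0:
                return _nn.Dropout(spec.dropout_rate, rng)
            return None

        # layer 1: the stem
        self.conv1 = _nn.Conv1D(1, f[0], k, rng, dtype)
        self.bn1 = _nn.BatchNorm1D(f[0], dtype=dtype)
        self.tanh = _nn.Tanh()

        # residual blocks over layer pairs (2,3), (4,5), (6,7), (8,9)
        self.blocks = []
        c_in = f[0]
        for bi, (la, lb) in enumerate([(2, 3), (4, 5), (6, 7), (8, 9)]):
            c_mid, c_out = f[la - 1], f[lb - 1]
            block = {
                "conv_a": _nn.Conv1D(c_in, c_mid, k, rng, dtype),
                "bn_a": _nn.BatchNorm1D(c_mid, dtype=dtype),
                "relu_a": _nn.ReLU(),
                "drop_a": drop(la),
                "conv_b": _nn.Conv1D(c_mid, c_out, k, rng, dtype),
                "bn_b": _nn.BatchNorm1D(c_out, dtype=dtype),
                "proj": _nn.Conv1D(c_in, c_out, 1, rng, dtype) if c_in != c_out else None,
                "relu_out": _nn.ReLU(),
                "drop_out": drop(lb),
                "last": bi == 3,
            }
            self.blocks.append(block)
            c_in = c_out

        # head: BN + ReLU after the final skip, layer-9 dropout, GAP, FC
        self.bn_head = _nn.BatchNorm1D(c_in, dtype=dtype)
        self.relu_head = _nn.ReLU()
        self.drop_head = drop(9)
        self.gap = _nn.GlobalAvgPool()
        self.dense = _nn.Dense(c_in, spec.n_classes, rng, dtype)

    # -- plumbing ---------------------------------------------------------

    def _layers(self):
        yield self.conv1
        yield self.bn1
        for blk in self.blocks:
            yield blk["conv_a"]
            yield blk["bn_a"]
            yield blk["conv_b"]
            yield blk["bn_b"]
            if blk["proj"] is not None:
                yield blk["proj"]
        yield self.bn_head
        yield self.dense

    def param_pairs(self):
        pairs = []
        for layer in self._layers():
            pairs.extend(layer.params())
        return pairs

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.param_pairs())

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(batch, input_length) raw windows -> (batch, 5) probabilities."""
        if x.ndim != 2 or x.shape[1] != self.input_length:
            raise ValueError(
                f"expected input of shape (batch, {self.input_length}), got {x.shape}"
            )
        h = np.ascontiguousarray(x, dtype=self.dtype)[:, :, None]
        h = self.tanh.forward(self.bn1.forward(self.conv1.forward(h, training), training), training)
        for blk in self.blocks:
            a = blk["bn_a"].forward(blk["conv_a"].forward(h, training), training)
            a = blk["relu_a"].forward(a, training)
            if blk["drop_a"] is not None:
                a = blk["drop_a"].forward(a, training)
            s = blk["bn_b"].forward(blk["conv_b"].forward(a, training), training)
            s = s + (h if blk["proj"] is None else blk["proj"].forward(h, training))
            if blk["last"]:
                h = s
            else:
                h = blk["relu_out"].forward(s, training)
                if blk["drop_out"] is not None:
                    h = blk["drop_out"].forward(h, training)
        h = self.relu_head.forward(self.bn_head.forward(h, training), training)
        if self.drop_head is not None:
            h = self.drop_head.forward(h, training)
        g = self.gap.forward(h, training)
        logits = self.dense.forward(g, training)
        return _nn.softmax(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        dg = self.dense.backward(dlogits)
        dh = self.gap.backward(dg)
        if self.drop_head is not None:
            dh = self.drop_head.backward(dh)
        ds = self.bn_head.backward(self.relu_head.backward(dh))
        for blk in reversed(self.blocks):
            if not blk["last"]:
                if blk["drop_out"] is not None:
                    ds = blk["drop_out"].backward(ds)
                ds = blk["relu_out"].backward(ds)
            dpath = blk["conv_b"].backward(blk["bn_b"].backward(ds))
            if blk["drop_a"] is not None:
                dpath = blk["drop_a"].backward(dpath)
            dpath = blk["conv_a"].backward(
                blk["bn_a"].backward(blk["relu_a"].backward(dpath))
            )
            dskip = ds if blk["proj"] is None else blk["proj"].backward(ds)
            ds = dpath + dskip
        dstem = self.bn1.backward(self.tanh.backward(ds))
        self.conv1.backward(dstem)

    def zero_grad(self) -> None:
        for _, g in self.param_pairs():
            g[...] = 0.0


@dataclass
class TrainedClassifier:
    """A trained base network plus its training history and provenance."""

    model: ResidualConvNet
    history: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def input_length(self) -> int:
        return self.model.input_length

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba_batch(self, X)


def build_model(
    input_length: int,
    spec: ArchitectureSpec | None = None,
    seed: int = 0,
) -> ResidualConvNet:
    """Construct the untrained base network; deterministic under ``seed``."""
    return ResidualConvNet(input_length, spec or ArchitectureSpec.default(), seed)


def _stack_training_set(
    training_set: TrainingSet, input_length: int
) -> tuple[np.ndarray, np.ndarray]:
    lengths = {len(s.samples) for s in training_set.segments}
    if lengths and lengths != {input_length}:
        raise ValueError(
            f"training segments of lengths {sorted(lengths)} do not match "
            f"model input_length {input_length}"
        )
    X = np.stack([s.samples for s in training_set.segments])
    class_index = {cls: i for i, cls in enumerate(AAMI_CLASSES)}
    y = np.array([class_index[s.label] for s in training_set.segments])
    return X, y


def train(
    model: ResidualConvNet,
    training_set: TrainingSet,
    loss_params: FocalLossParams | None = None,
    config: TrainingConfig | None = None,
) -> TrainedClassifier:
    """Train one base classifier with Adam on the focal loss.

    A seeded ``val_fraction`` split is held out for early stopping (the
    epoch loop stops once validation loss has not improved for
    ``patience`` epochs); set ``val_fraction=0`` to train on everything
    for the full epoch budget.
    """
    loss_params = loss_params or FocalLossParams()
    config = config or TrainingConfig()
    if not training_set.segments:
        raise ValueError("training set is empty")
    X, y = _stack_training_set(training_set, model.input_length)
    rng = np.random.Generator(np.random.PCG64(config.seed))

    n_val = int(round(len(X) * config.val_fraction))
    order = rng.permutation(len(X))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    X_tr, y_tr, X_val, y_val = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    optimiser = _nn.Adam(model.param_pairs(), lr=config.learning_rate)
    history: list[dict] = []
    best_val, best_epoch = np.inf, -1
    for epoch in range(config.epochs):
        perm = rng.permutation(len(X_tr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(X_tr), config.batch_size):
            idx = perm[start : start + config.batch_size]
            probs = model.forward(X_tr[idx], training=True)
            loss, dlogits = focal_loss_and_grad(probs, y_tr[idx], loss_params)
            model.zero_grad()
            model.backward(dlogits)
            optimiser.step()
            epoch_loss += loss
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if n_val:
            val_probs = model.forward(X_val, training=False)
            val_loss, _ = focal_loss_and_grad(val_probs, y_val, loss_params)
            entry["val_loss"] = val_loss
            if val_loss < best_val - 1e-6:
                best_val, best_epoch = val_loss, epoch
            elif epoch - best_epoch >= config.patience:
                history.append(entry)
                break
        history.append(entry)

    return TrainedClassifier(
        model=model,
        history=history,
        provenance={
            "training_config": {
                "learning_rate": config.learning_rate,
                "batch_size": config.batch_size,
                "epochs": config.epochs,
                "patience": config.patience,
                "val_fraction": config.val_fraction,
                "seed": config.seed,
            },
            "loss": {
                "gamma": loss_params.gamma,
                "class_weights": {
                    c.value: loss_params.class_weights[c] for c in AAMI_CLASSES
                },
            },
            "training_set": dict(training_set.provenance),
            "class_counts": {
                c.value: training_set.class_counts.get(c, 0) for c in AAMI_CLASSES
            },
        },
    )


def predict(classifier: TrainedClassifier, segment: BeatSegment) -> dict[AamiClass, float]:
    """Class-probability map for a single beat segment."""
    if len(segment.samples) != classifier.input_length:
        raise ValueError(
            f"segment length {len(segment.samples)} does not match model "
            f"input_length {classifier.input_length}"
        )
    probs = classifier.model.forward(segment.samples[None, :], training=False)[0]
    return {cls: float(p) for cls, p in zip(AAMI_CLASSES, probs)}


def predict_proba_batch(
    classifier: TrainedClassifier, X: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """(n, input_length) -> (n, 5) probabilities, evaluated in batches."""
    outs = [
        classifier.model.forward(X[i : i + batch_size], training=False)
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(outs) if outs else np.empty((0, len(AAMI_CLASSES)))


# -- persistence ----------------------------------------------------------

def _state_arrays(model: ResidualConvNet) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}
    for li, layer in enumerate(model._layers()):
        for pi, (p, _) in enumerate(layer.params()):
            arrays[f"layer{li}/param{pi}"] = p
        if isinstance(layer, _nn.BatchNorm1D):
            arrays[f"layer{li}/running_mean"] = layer.running_mean
            arrays[f"layer{li}/running_var"] = layer.running_var
    return arrays


def save_classifier(classifier: TrainedClassifier, path) -> None:
    """Persist weights (.npz) plus a JSON provenance sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    model = classifier.model
    np.savez(path.with_suffix(".npz"), **_state_arrays(model))
    meta = {
        "input_length": model.input_length,
        "dtype": np.dtype(model.dtype).name,
        "architecture": {
            "kernel_size": model.spec.kernel_size,
            "filters": list(model.spec.filters),
            "dropout_rate": model.spec.dropout_rate,
            "dropout_layers": sorted(model.spec.dropout_layers),
            "n_classes": model.spec.n_classes,
        },
        "history": classifier.history,
        "provenance": classifier.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_classifier(path) -> TrainedClassifier:
    """Inverse of :func:`save_classifier`."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arch = meta["architecture"]
    spec = ArchitectureSpec(
        kernel_size=arch["kernel_size"],
        filters=tuple(arch["filters"]),
        dropout_rate=arch["dropout_rate"],
        dropout_layers=frozenset(arch["dropout_layers"]),
        n_classes=arch["n_classes"],
    )
    model = ResidualConvNet(
        meta["input_length"], spec, seed=0, dtype=np.dtype(meta["dtype"]).type
    )
    with np.load(path.with_suffix(".npz")) as data:
        for li, layer in enumerate(model._layers()):
            for pi, (p, _) in enumerate(layer.params()):
                p[...] = data[f"layer{li}/param{pi}"]
            if isinstance(layer, _nn.BatchNorm1D):
                layer.running_mean = data[f"layer{li}/running_mean"]
                layer.running_var = data[f"layer{li}/running_var"]
    return TrainedClassifier(
        model=model, history=meta["history"], provenance=meta["provenance"]
    )
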
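"""Gait-phase classifiers behind one train/predict interface.

The primary model is a pooling-free convolutional network: the 20 x 13
feature image is low-dimensional already, so pooling would discard signal
rather than nuisance resolution — the stack is convolution layers only
(32 then 64 filters, 3x3 kernels, ReLU, stride 1, same padding), a flatten,
one 128-unit dense layer and a 4-way softmax head, trained with Adam on the
cross-entropy loss.  Baselines: an RBF-kernel SVM (scikit-learn) on the
flattened image, a one-hidden-layer back-propagation network (BPNN), and a
64-unit LSTM over the 20-step sequence.

All network models share the training regime (epochs, batch size, Adam
learning rate) of :class:`TrainConfig`; the default epoch count is 50 for
desk-scale runs, with ``strict_regime`` restoring the full 300/100/0.001
regime.  One integer seed drives initialization and batch shuffling, so
same-platform reruns reproduce loss histories exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _nn
from ._nn import cross_entropy, softmax  # re-exported model math
from .errors import ConfigError, DataError
from .features_fusion import FeatureDataset
from .phase_labeler import N_PHASES

__all__ = [
    "TrainConfig", "ModelSpec", "TrainedModel", "softmax", "cross_entropy",
    "build_model", "train", "predict", "MODEL_KINDS",
]

MODEL_KINDS = ("cnn", "svm", "bpnn", "lstm")

REFERENCE_EPOCHS = 300
DEFAULT_EPOCHS = 50
REFERENCE_BATCH = 100
REFERENCE_LR = 0.001


@dataclass
class TrainConfig:
    epochs: int = DEFAULT_EPOCHS
    batch_size: int = REFERENCE_BATCH
    learning_rate: float = REFERENCE_LR
    optimizer: str = "adam"
    seed: int = 0
    loss: str = "cross_entropy"

    def validate(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("epochs >= 0, batch_size >= 1, learning_rate > 0 required")
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ConfigError(f"unsupported loss {self.loss!r}")

    def strict_regime(self) -> "TrainConfig":
        return replace(self, epochs=REFERENCE_EPOCHS, batch_size=REFERENCE_BATCH,
                       learning_rate=REFERENCE_LR)


@dataclass
class ModelSpec:
    """Architecture selector.  ``params`` overrides per-kind defaults:

    cnn:  conv_filters=(32, 64), kernel=3, dense_units=128
    svm:  c=1.0, gamma="scale"
    bpnn: hidden_units=128
    lstm: hidden_units=64
    """

    kind: str = "cnn"
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ConfigError(f"unknown model kind {self.kind!r}; pick from {MODEL_KINDS}")
        if self.kind == "cnn" and self.params.get("pooling"):
            raise ConfigError("the cnn spec is pooling-free by construction")


@dataclass
class TrainedModel:
    spec: ModelSpec
    impl: object
    history: list[float]
    class_codes: tuple = tuple(range(N_PHASES))
    input_shape: tuple = ()
    config: TrainConfig | None = None


class _NetModel:
    """Common fit/predict wrapper for the NumPy networks."""

    kind = "net"

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        self.net: _nn.Network | None = None

    def _build(self, input_shape: tuple, rng: np.random.Generator) -> _nn.Network:
        raise NotImplementedError

    def _prep(self, x: np.ndarray) -> np.ndarray:
        return x

    def fit(self, x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> list[float]:
        rng = np.random.default_rng(cfg.seed)
        self.input_shape = x.shape[1:]
        self.net = self._build(x.shape[1:], rng)
        return self.net.fit(self._prep(x), y, cfg.epochs, cfg.batch_size,
                            cfg.learning_rate, rng)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.net is None:
            raise DataError("model is untrained")
        return self.net.predict_proba(self._prep(x))


class _CnnModel(_NetModel):
    kind = "cnn"

    def _prep(self, x):
        return x[..., None]  # (N, H, W) -> single-channel image

    def _build(self, input_shape, rng):
        h, w = input_shape
        filters = tuple(self.spec.params.get("conv_filters", (32, 64)))
        kernel = int(self.spec.params.get("kernel", 3))
        dense_units = int(self.spec.params.get("dense_units", 128))
        layers: list[_nn.Layer] = []
        c_in = 1
        for c_out in filters:
            layers += [_nn.Conv2D(c_in, c_out, rng, kernel), _nn.ReLU()]
            c_in = c_out
        layers += [_nn.Flatten(),
                   _nn.Dense(h * w * c_in, dense_units, rng), _nn.ReLU(),
                   _nn.Dense(dense_units, N_PHASES, rng)]
        return _nn.Network(layers, N_PHASES)


class _BpnnModel(_NetModel):
    kind = "bpnn"

    def _prep(self, x):
        return x.reshape(x.shape[0], -1)

    def _build(self, input_shape, rng):
        n_in = int(np.prod(input_shape))
        hidden = int(self.spec.params.get("hidden_units", 128))
        return _nn.Network([
            _nn.Dense(n_in, hidden, rng), _nn.ReLU(),
            _nn.Dense(hidden, N_PHASES, rng),
        ], N_PHASES)


class _LstmModel(_NetModel):
    kind = "lstm"

    def _build(self, input_shape, rng):
        _, c = input_shape
        hidden = int(self.spec.params.get("hidden_units", 64))
        return _nn.Network([
            _nn.LSTMLast(c, hidden, rng),
            _nn.Dense(hidden, N_PHASES, rng),
        ], N_PHASES)


class _SvmModel:
    """RBF-kernel SVM on the flattened image (scikit-learn backend).

    Per-class scores come from the one-vs-rest decision function pushed
    through a softmax; iterative epoch training does not apply, so the
    history is empty.
    """

    kind = "svm"

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        self.clf = None
        self._trained_classes: np.ndarray | None = None

    def fit(self, x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> list[float]:
        from sklearn.svm import SVC

        if np.unique(y).size < 2:  # degenerate fold: constant predictor
            self.clf = "constant"
            self._trained_classes = np.unique(y)
            return []
        self.clf = SVC(C=float(self.spec.params.get("c", 1.0)),
                       gamma=self.spec.params.get("gamma", "scale"),
                       kernel="rbf", decision_function_shape="ovr",
                       random_state=cfg.seed)
        self.clf.fit(x.reshape(x.shape[0], -1), y)
        self._trained_classes = self.clf.classes_
        return []

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.clf is None:
            raise DataError("model is untrained")
        if isinstance(self.clf, str):  # constant single-class predictor
            probs = np.zeros((x.shape[0], N_PHASES))
            probs[:, self._trained_classes[0]] = 1.0
            return probs
        scores = self.clf.decision_function(x.reshape(x.shape[0], -1))
        if scores.ndim == 1:  # two trained classes -> single margin column
            scores = np.column_stack([-scores, scores])
        probs = np.zeros((x.shape[0], N_PHASES))
        probs[:, self._trained_classes] = softmax(scores)
        return probs


_MODEL_CLASSES = {"cnn": _CnnModel, "svm": _SvmModel,
                  "bpnn": _BpnnModel, "lstm": _LstmModel}


def build_model(spec: ModelSpec | str):
    """Instantiate an untrained model of the requested kind."""
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    spec.validate()
    return _MODEL_CLASSES[spec.kind](spec)


def _dataset_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, FeatureDataset):
        return data.images, data.labels
    x, y = data
    return np.asarray(x, dtype=float), np.asarray(y, dtype=np.int64)


def train(model, train_data, cfg: TrainConfig | None = None) -> TrainedModel:
    """Fit a model on a feature dataset (or an (images, labels) pair)."""
    cfg = cfg or TrainConfig()
    cfg.validate()
    if cfg.epochs == 0 and getattr(model, "kind", None) != "svm":
        raise ConfigError("epochs=0 would leave the network untrained")
    x, y = _dataset_arrays(train_data)
    if x.shape[0] == 0:
        raise DataError("empty training set")
    if x.ndim != 3:
        raise DataError(f"expected (n, length, channels) images, got shape {x.shape}")
    history = model.fit(x, y, cfg)
    return TrainedModel(model.spec, model, list(history),
                        input_shape=x.shape[1:], config=cfg)


def predict(trained: TrainedModel, images: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted phase codes and per-class probabilities for a batch.

    The label is the argmax of the probability row; ties break to the
    lowest class code.  An empty batch yields empty outputs.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:  # single image
        images = images[None]
    if images.shape[0] == 0:
        return np.empty(0, dtype=np.int64), np.empty((0, N_PHASES))
    if images.shape[1:] != tuple(trained.input_shape):
        raise DataError(
            f"image shape {images.shape[1:]} does not match the model's "
            f"training shape {tuple(trained.input_shape)}"
        )
    probs = trained.impl.predict_proba(images)
    return probs.argmax(axis=1).astype(np.int64), probs


def save_model(trained: TrainedModel, path: str) -> None:
    """Persist a trained model (spec, parameters, class codes, config echo)
    to a single container file."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump(trained, fh)


def load_model(path: str) -> TrainedModel:
    import pickle

    with open(path, "rb") as fh:
        trained = pickle.load(fh)
    if not isinstance(trained, TrainedModel):
        raise DataError(f"{path} does not contain a trained gait model")
    return trained
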
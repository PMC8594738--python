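import numpy as np
import pytest

from gaitfuse import _nn
from gaitfuse.classifiers import (
    ModelSpec,
    TrainConfig,
    build_model,
    cross_entropy,
    load_model,
    predict,
    save_model,
    softmax,
    train,
)
from gaitfuse.errors import ConfigError, DataError


# --------------------------------------------------------------------------
# softmax / cross-entropy closed forms and invariants
# --------------------------------------------------------------------------

def test_softmax_symmetry_and_normalization():
    np.testing.assert_allclose(softmax(np.zeros(4)), np.full(4, 0.25))
    np.testing.assert_allclose(softmax(np.array([3.7])), [1.0])


def test_softmax_closed_form():
    np.testing.assert_allclose(softmax(np.array([0.0, np.log(2.0)])),
                               [1 / 3, 2 / 3], rtol=1e-12)


def test_softmax_shift_invariance_and_stability():
    logits = np.array([1.0, -2.0, 0.5, 3.0])
    np.testing.assert_allclose(softmax(logits), softmax(logits + 123.4), rtol=1e-12)
    extreme = softmax(np.array([1e4, -1e4, 0.0, 1e4]))
    assert np.all(np.isfinite(extreme)) and extreme.sum() == pytest.approx(1.0)


def test_softmax_empty_input_errors():
    with pytest.raises(DataError):
        softmax(np.array([]))


def test_cross_entropy_closed_forms():
    eye = np.eye(4)
    assert cross_entropy(eye, eye) == pytest.approx(0.0, abs=1e-10)
    uniform = np.full((8, 4), 0.25)
    onehot = np.eye(4)[np.arange(8) % 4]
    assert cross_entropy(uniform, onehot) == pytest.approx(np.log(4.0), rel=1e-12)
    probs = np.array([[1.0, 0.0], [0.5, 0.5]])
    labels = np.array([[1.0, 0.0], [1.0, 0.0]])
    assert cross_entropy(probs, labels) == pytest.approx(np.log(2.0) / 2, rel=1e-12)


def test_cross_entropy_clamps_zero_probability():
    probs = np.array([[0.0, 1.0]])
    labels = np.array([[1.0, 0.0]])
    assert np.isfinite(cross_entropy(probs, labels))


# --------------------------------------------------------------------------
# layer gradients vs finite differences (independent oracle for backprop)
# --------------------------------------------------------------------------

def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


@pytest.mark.parametrize("layer_fn,x_shape", [
    (lambda rng: _nn.Conv2D(2, 3, rng), (2, 5, 4, 2)),
    (lambda rng: _nn.Dense(6, 3, rng), (4, 6)),
    (lambda rng: _nn.LSTMLast(3, 4, rng), (2, 6, 3)),
])
def test_layer_gradients_match_finite_differences(layer_fn, x_shape):
    rng = np.random.default_rng(0)
    layer = layer_fn(rng)
    x = rng.standard_normal(x_shape)
    w = rng.standard_normal(layer.forward(x).shape)  # random loss direction

    def loss():
        return float(np.sum(layer.forward(x) * w))

    loss()  # populate caches
    dx = layer.backward(w)
    np.testing.assert_allclose(dx, _num_grad(loss, x), atol=1e-5)
    for p, g in zip(layer.params, layer.grads):
        loss()
        layer.backward(w)
        np.testing.assert_allclose(g, _num_grad(loss, p), atol=1e-5)


# --------------------------------------------------------------------------
# build/train/predict contracts
# --------------------------------------------------------------------------

def _toy_data(n=60, length=20, channels=13, seed=0):
    """Linearly separable 4-class images: class mean stamped on channel 0."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 4
    x = 0.1 * rng.standard_normal((n, length, channels))
    x[:, :, 0] += y[:, None] * 2.0
    return x, y


@pytest.mark.parametrize("kind", ["cnn", "svm", "bpnn", "lstm"])
def test_forward_pass_probability_rows(kind):
    x, y = _toy_data()
    cfg = TrainConfig(epochs=2, batch_size=16, seed=0)
    trained = train(build_model(kind), (x, y), cfg)
    labels, probs = predict(trained, x[:5])
    assert probs.shape == (5, 4)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(probs > -1e-12)
    np.testing.assert_array_equal(labels, probs.argmax(axis=1))


def test_cnn_spec_is_pooling_free():
    x, y = _toy_data(n=16)
    trained = train(build_model("cnn"), (x, y),
                    TrainConfig(epochs=1, batch_size=8, seed=0))
    layer_types = {type(l).__name__ for l in trained.impl.net.layers}
    assert "Conv2D" in layer_types
    assert not any("pool" in t.lower() for t in layer_types)
    with pytest.raises(ConfigError):
        build_model(ModelSpec("cnn", {"pooling": "max"}))


def test_bpnn_flattened_input_size():
    x, y = _toy_data(n=16)
    trained = train(build_model("bpnn"), (x, y),
                    TrainConfig(epochs=1, batch_size=8, seed=0))
    assert trained.impl.net.layers[0].w.shape[0] == 20 * 13  # 260-vector


def test_unknown_kind_rejected():
    with pytest.raises(ConfigError):
        build_model("transformer")


@pytest.mark.parametrize("kind", ["bpnn", "lstm"])
def test_training_is_deterministic_under_seed(kind):
    x, y = _toy_data()
    cfg = TrainConfig(epochs=3, batch_size=16, seed=11)
    h1 = train(build_model(kind), (x, y), cfg).history
    h2 = train(build_model(kind), (x, y), cfg).history
    assert h1 == h2
    assert len(h1) == 3
    h3 = train(build_model(kind), (x, y),
               TrainConfig(epochs=3, batch_size=16, seed=12)).history
    assert h1 != h3


@pytest.mark.parametrize("kind", ["cnn", "svm", "bpnn", "lstm"])
def test_separable_data_learned(kind):
    x, y = _toy_data(n=120, seed=1)
    cfg = TrainConfig(epochs=30, batch_size=30, seed=0)
    trained = train(build_model(kind), (x, y), cfg)
    labels, _ = predict(trained, x)
    assert np.mean(labels == y) > 0.95
    if trained.history:
        assert trained.history[-1] <= trained.history[0]


def test_zero_epochs_rejected():
    x, y = _toy_data(n=8)
    with pytest.raises(ConfigError):
        train(build_model("bpnn"), (x, y), TrainConfig(epochs=0))


def test_empty_training_set_rejected():
    with pytest.raises(DataError):
        train(build_model("bpnn"),
              (np.empty((0, 20, 13)), np.empty(0, dtype=int)),
              TrainConfig(epochs=1))


def test_predict_empty_batch_and_shape_mismatch():
    x, y = _toy_data(n=16)
    trained = train(build_model("bpnn"), (x, y),
                    TrainConfig(epochs=1, batch_size=8, seed=0))
    labels, probs = predict(trained, np.empty((0, 20, 13)))
    assert labels.size == 0 and probs.shape == (0, 4)
    with pytest.raises(DataError):
        predict(trained, np.zeros((3, 20, 12)))


def test_model_container_round_trip(tmp_path):
    x, y = _toy_data(n=24)
    trained = train(build_model("bpnn"), (x, y),
                    TrainConfig(epochs=2, batch_size=8, seed=0))
    path = str(tmp_path / "model.pkl")
    save_model(trained, path)
    back = load_model(path)
    l1, p1 = predict(trained, x)
    l2, p2 = predict(back, x)
    np.testing.assert_array_equal(l1, l2)
    np.testing.assert_allclose(p1, p2)
    assert back.config.epochs == 2
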
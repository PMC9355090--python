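"""Training-loop behaviour on small synthetic datasets."""

import numpy as np
import pytest

from seedlingscreen.cnn_screen import (
    TrainingConfig,
    build_custom_net,
    load_checkpoint,
    load_split_arrays,
    save_checkpoint,
)
from seedlingscreen.cnn_screen.train import cross_entropy, predict, softmax, train
from seedlingscreen.synthdata import generate_dataset


@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    """48 margin-separated frames (16/class) at reduced frame size."""
    out = tmp_path_factory.mktemp("synth_small")
    manifest = generate_dataset(16, seed=9, out_dir=out, frame_size=(320, 240))
    x, y = load_split_arrays(manifest, "train", out)
    xv, yv = load_split_arrays(manifest, "val", out)
    # pool everything; individual tests slice what they need
    return np.concatenate([x, xv]), np.concatenate([y, yv])


def test_cross_entropy_gradient_matches_softmax(rng):
    logits = rng.normal(size=(5, 3)).astype(np.float32)
    targets = np.array([0, 1, 2, 1, 0])
    loss, grad = cross_entropy(logits, targets)
    probs = softmax(logits)
    expected = probs.copy()
    expected[np.arange(5), targets] -= 1
    np.testing.assert_allclose(grad, expected / 5, rtol=1e-5)
    assert loss > 0


def test_training_fits_separable_classes(small_dataset):
    """Well-separated classes are fit to ≥99% training accuracy."""
    x, y = small_dataset
    model = build_custom_net(seed=3)
    result = train(model, (x, y), None, TrainingConfig(learning_rate=1e-3, epochs=12, seed=3))
    assert max(result.history["train_accuracy"]) >= 0.99


def test_frozen_weights_give_constant_loss(small_dataset):
    x, y = small_dataset
    model = build_custom_net(seed=0)
    cfg = TrainingConfig(learning_rate=1e-3, epochs=3, seed=0, freeze=True)
    result = train(model, (x[:24], y[:24]), None, cfg)
    losses = result.history["train_loss"]
    assert losses[0] == pytest.approx(losses[1]) == pytest.approx(losses[2])


def test_low_learning_rate_gives_smoother_loss(small_dataset):
    """Per-epoch loss at lr 1e-5 shows fewer upward jumps than at 1e-3."""
    x, y = small_dataset

    def flips(lr):
        model = build_custom_net(seed=5)
        cfg = TrainingConfig(learning_rate=lr, batch_size=8, epochs=8, seed=5)
        result = train(model, (x, y), None, cfg)
        diffs = np.diff(result.history["train_loss"])
        return int((np.sign(diffs[1:]) != np.sign(diffs[:-1])).sum())

    assert flips(1e-5) <= flips(1e-3)


def test_missing_class_rejected(small_dataset):
    x, y = small_dataset
    keep = y != 2
    with pytest.raises(ValueError, match="missing classes"):
        train(build_custom_net(), (x[keep], y[keep]), None, TrainingConfig(epochs=1))


def test_divergence_aborts_with_diagnostic(small_dataset):
    x, y = small_dataset
    sel = np.concatenate([np.where(y == c)[0][:3] for c in range(3)])
    x, y = x[sel], y[sel]
    model = build_custom_net(seed=1)
    # overflowed head weights produce non-finite logits on the first batch
    model.fc.params["weight"][:] = np.float32(1e38)
    with pytest.raises(RuntimeError, match="non-finite"):
        train(model, (x, y), None, TrainingConfig(epochs=1))


def test_predict_contract():
    model = build_custom_net(seed=2)
    image = np.full((224, 224, 3), 255, dtype=np.uint8)
    label, probs = predict(model, image)
    assert label in ("healthy", "unhealthy", "none")
    assert probs.shape == (3,)
    assert probs.sum() == pytest.approx(1.0, abs=1e-5)
    with pytest.raises(ValueError):
        predict(model, np.zeros((100, 100, 3), dtype=np.uint8))


def test_predict_tie_breaks_to_lowest_class_index():
    model = build_custom_net(seed=2)
    model.fc.params["weight"][:] = 0.0
    model.fc.params["bias"][:] = 0.0  # all logits tie at zero
    label, probs = predict(model, np.zeros((224, 224, 3), dtype=np.uint8))
    assert label == "healthy"
    np.testing.assert_allclose(probs, [1 / 3] * 3, atol=1e-6)


def test_checkpoint_roundtrip(tmp_path):
    model = build_custom_net(seed=4)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    other = build_custom_net(seed=99)
    load_checkpoint(other, path)
    a, b = model.state_dict(), other.state_dict()
    assert all(np.array_equal(a[k], b[k]) for k in a)


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(batch_size=0)
    cfg = TrainingConfig()
    assert cfg.batch_size == 32
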
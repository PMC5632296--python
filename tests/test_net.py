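"""Network architecture contracts, training behaviour, inference invariants."""

import numpy as np
import pytest

from tipscan import net
from tipscan.net import (TrainConfig, build_root_network, build_shoot_network,
                         classify, learning_rate_at, load_model, save_model,
                         spatial_trace)


# --- architecture ------------------------------------------------------------

def test_root_network_spatial_trace_reaches_one():
    spec = build_root_network()
    assert spatial_trace(spec) == [32, 30, 28, 14, 12, 10, 5, 3, 1]


def test_root_network_filter_ramp_and_output_width():
    spec = build_root_network()
    convs = [l.size for l in spec.layers if l.kind == "conv3x3"]
    assert convs[0] == 64 and max(convs) == 256
    assert convs == [64, 64, 128, 128, 256, 256]
    fcs = [l.size for l in spec.layers if l.kind == "fully_connected"]
    assert len(fcs) == 3 and fcs[-1] == 2


def test_shoot_network_trace_every_prepool_side_even():
    spec = build_shoot_network()
    trace = spatial_trace(spec)
    assert trace[0] == 64 and trace[-1] == 1
    # Each pool halves an even side.
    side = 64
    for layer in spec.layers:
        if layer.kind == "conv3x3":
            side -= 2
        elif layer.kind == "maxpool2x2":
            assert side % 2 == 0
            side //= 2
    assert side == 1


def test_shoot_network_filter_ramp_and_classes():
    spec = build_shoot_network()
    convs = [l.size for l in spec.layers if l.kind == "conv3x3"]
    assert convs[0] == 64 and max(convs) == 512
    fcs = [l.size for l in spec.layers if l.kind == "fully_connected"]
    assert fcs[-1] == 5
    assert spec.n_classes == 5


def test_dropout_only_between_fully_connected_layers():
    for spec in (build_root_network(), build_shoot_network()):
        first_fc = min(i for i, l in enumerate(spec.layers)
                       if l.kind == "fully_connected")
        for i, l in enumerate(spec.layers):
            if l.kind == "dropout":
                assert i > first_fc


# --- learning-rate schedule ---------------------------------------------------

def test_learning_rate_step_schedule():
    cfg = TrainConfig()
    assert learning_rate_at(cfg, 0) == pytest.approx(0.1)
    assert learning_rate_at(cfg, 19_999) == pytest.approx(0.1)
    assert learning_rate_at(cfg, 20_000) == pytest.approx(0.01)
    assert learning_rate_at(cfg, 40_000) == pytest.approx(0.001)


# --- training behaviour -------------------------------------------------------

def test_toy_task_reaches_99_percent_within_500_iterations(toy_trained_model):
    _, history, _ = toy_trained_model
    assert history[-1]["iteration"] <= 500
    assert max(h["val_accuracy"] for h in history) >= 99.0


def test_trained_model_memorizes_training_patch(toy_trained_model):
    model, _, (x, y) = toy_trained_model
    crops = x[:20, 5:37, 5:37]
    probs = classify(model, crops)
    assert np.all(np.argmax(probs, axis=1) == y[:20])


def test_training_determinism_same_seed_same_history():
    rng = np.random.default_rng(1)
    x = np.clip(rng.normal(0, 8, (120, 32, 32, 3)) + 128, 0, 255).astype(np.uint8)
    y = (x.mean(axis=(1, 2, 3)) > 128).astype(int)
    spec = build_root_network(base_filters=2)
    cfg = dict(initial_lr=0.01, max_iterations=60, val_interval=20,
               mean_color=(128.0, 128.0, 128.0), rng_seed=7)
    _, h1 = net.train(spec, x[:100], y[:100], x[100:], y[100:], TrainConfig(**cfg))
    _, h2 = net.train(spec, x[:100], y[:100], x[100:], y[100:], TrainConfig(**cfg))
    assert h1 == h2


@pytest.mark.filterwarnings("ignore::RuntimeWarning")  # overflow is the point
def test_divergence_aborts_with_diagnostic():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 255, (64, 32, 32, 3), dtype=np.uint8)
    y = rng.integers(0, 2, 64)
    spec = build_root_network(base_filters=2)
    cfg = TrainConfig(initial_lr=1e9, max_iterations=50, val_interval=50,
                      mean_color=(0.0, 0.0, 0.0), rng_seed=0)
    with pytest.raises(net.TrainingDivergedError):
        net.train(spec, x, y, x, y, cfg)


# --- inference invariants -----------------------------------------------------

def test_probabilities_normalized_and_batch_invariant(tiny_root_model):
    rng = np.random.default_rng(5)
    patches = rng.integers(0, 255, (30, 32, 32, 3), dtype=np.uint8)
    probs = classify(tiny_root_model, patches)
    assert probs.shape == (30, 2)
    assert np.all(probs >= 0)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    # Same rows regardless of batching.
    probs_small = tiny_root_model.predict_proba(patches, batch_size=7)
    assert np.allclose(probs, probs_small, atol=1e-6)


def test_zeroed_final_layer_gives_uniform_probabilities(tiny_root_model):
    import copy
    model = copy.deepcopy(tiny_root_model)
    final_dense = [l for l in model.layers if isinstance(l, net._Dense)][-1]
    final_dense.W[...] = 0
    final_dense.b[...] = 0
    rng = np.random.default_rng(0)
    probs = classify(model, rng.integers(0, 255, (5, 32, 32, 3), dtype=np.uint8))
    assert np.allclose(probs, 0.5, atol=1e-7)


def test_size_mismatch_rejected(tiny_root_model):
    with pytest.raises(ValueError):
        classify(tiny_root_model, np.zeros((2, 40, 40, 3), np.uint8))


def test_mean_subtraction_internal_equals_explicit(tiny_root_model):
    import copy
    rng = np.random.default_rng(9)
    patches = rng.integers(0, 255, (8, 32, 32, 3), dtype=np.uint8)
    internal = classify(tiny_root_model, patches)
    zero_mean = copy.deepcopy(tiny_root_model)
    zero_mean.mean_color = (0.0, 0.0, 0.0)
    explicit = classify(zero_mean,
                        patches.astype(np.float32)
                        - np.asarray(tiny_root_model.mean_color, np.float32))
    assert np.allclose(internal, explicit, atol=1e-6)


def test_checkpoint_round_trip(tmp_path, tiny_root_model):
    path = save_model(tiny_root_model, tmp_path / "model")
    back = load_model(path)
    assert back.spec == tiny_root_model.spec
    assert back.mean_color == tiny_root_model.mean_color
    assert back.class_names == tiny_root_model.class_names
    rng = np.random.default_rng(4)
    patches = rng.integers(0, 255, (6, 32, 32, 3), dtype=np.uint8)
    assert np.allclose(classify(back, patches),
                       classify(tiny_root_model, patches), atol=1e-7)


def test_checkpoint_spec_hash_validated(tmp_path, tiny_root_model):
    import json
    path = save_model(tiny_root_model, tmp_path / "model")
    sidecar_path = path.with_suffix(".json")
    doc = json.loads(sidecar_path.read_text())
    doc["spec_hash"] = "0" * 64
    sidecar_path.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match="hash"):
        load_model(path)
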
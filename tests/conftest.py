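import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def root_scene():
    """One deterministic root scene with a rich set of annotated tips."""
    from tipscan.fixtures import RootSceneParams, generate_root_image

    return generate_root_image(RootSceneParams(seed=7))


@pytest.fixture(scope="session")
def tiny_root_model():
    """An untrained (seed-initialised) width-2 root network.

    Deterministic outputs; useful for geometry/equivalence tests that need a
    real classifier but not a trained one.
    """
    from tipscan import net

    spec = net.build_root_network(base_filters=2)
    layers = net._build_layers(spec, np.random.default_rng(123))
    return net.TrainedModel(spec=spec, layers=layers,
                            mean_color=(128.0, 128.0, 128.0),
                            class_names=("root_tip", "negative"))


@pytest.fixture(scope="session")
def toy_trained_model():
    """A model trained to separate two solid-colour classes.

    Session-scoped because several behavioural tests reuse it.
    """
    from tipscan import net

    rng = np.random.default_rng(0)
    n = 200
    a = np.clip(rng.normal(0, 6, (n, 42, 42, 3)) + [200, 50, 50], 0, 255)
    b = np.clip(rng.normal(0, 6, (n, 42, 42, 3)) + [50, 50, 200], 0, 255)
    x = np.concatenate([a, b]).astype(np.uint8)
    y = np.array([0] * n + [1] * n)
    order = rng.permutation(len(x))
    x, y = x[order], y[order]
    cfg = net.TrainConfig(initial_lr=0.01, max_iterations=500, val_interval=100,
                          mean_color=(125.0, 50.0, 125.0), rng_seed=0)
    spec = net.build_root_network(base_filters=4)
    model, history = net.train(spec, x[:320], y[:320], x[320:], y[320:], cfg,
                               class_names=("red", "blue"))
    return model, history, (x, y)
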
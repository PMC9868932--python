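import numpy as np
import pytest

from leafdet.synth import Scene, SynthConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scenes():
    """A handful of small synthetic scenes shared across tests."""
    cfg = SynthConfig(
        image_size=96,
        num_classes=4,
        lesions_per_image=(2, 4),
        lesion_size_range=(60, 200),
        seed=5,
    )
    gen = np.random.default_rng(5)
    return [generate_scene(cfg, gen) for _ in range(6)]
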
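import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_sample():
    """One default-size phantom, shared across tests (generation is pure)."""
    from pcgnet.phantoms import PhantomConfig, generate_phantom

    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def tiny_trained_segmenter():
    """A very small segmenter trained for two epochs; reused by several tests."""
    from pcgnet.estimators import PCGNetSegmenter
    from pcgnet.phantoms import PhantomConfig, generate_dataset

    cfg = PhantomConfig(image_size=48, seed=11)
    train = generate_dataset(10, cfg, "train")
    val = generate_dataset(3, cfg, "val")
    est = PCGNetSegmenter(level="baseline", image_size=48, epochs=2, seed=0)
    est.fit(
        np.stack([s.image for s in train]),
        np.stack([s.label for s in train]),
        np.stack([s.image for s in val]),
        np.stack([s.label for s in val]),
    )
    return est
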
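import numpy as np
import pytest

from cervicad.labels import OTHERS, OrdinalLabel
from cervicad.phantom import PhantomConfig, generate_phantom_slide


@pytest.fixture(scope="session")
def small_cfg() -> PhantomConfig:
    """Desk-scale phantom: one fragment on a 640x480 canvas, thin ribbon."""
    return PhantomConfig(image_size=(640, 480), fragments_per_slide=(1, 1),
                         ribbon_thickness=(24, 40), seed=0)


@pytest.fixture(scope="session")
def phantom_bank(small_cfg):
    """Nine graded phantoms (3 per grade), shared across tests."""
    labels = [OrdinalLabel.NNEO, OrdinalLabel.LSIL, OrdinalLabel.HSIL]
    return [generate_phantom_slide(small_cfg, labels[i % 3], seed=500 + i)
            for i in range(9)]


@pytest.fixture(scope="session")
def others_phantom(small_cfg):
    return generate_phantom_slide(small_cfg, OTHERS, seed=77)


class StubTileModel:
    """predict_proba_tiles stub returning pre-set probability rows."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba_tiles(self, tiles):
        return self.probs[: len(tiles)]
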
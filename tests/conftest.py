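import numpy as np
import pytest

from hemilat.atlas_io import HomotopicAtlas
from hemilat.synthetic import make_atlas


@pytest.fixture
def tiny_atlas() -> HomotopicAtlas:
    """Two homotopic pairs: (L0,R1) in LAN, (L2,R3) in LAN."""
    return HomotopicAtlas(
        vertex_id=np.arange(4),
        hemisphere=np.array(["L", "R", "L", "R"], dtype=object),
        pair_id=np.array([0, 0, 1, 1]),
        network=np.array(["LAN", "LAN", "LAN", "LAN"], dtype=object),
    )


@pytest.fixture
def small_atlas() -> HomotopicAtlas:
    """Seven networks x 5 pairs + 2 unlabeled pairs = 74 vertices."""
    counts = {n: 5 for n in ("SMN", "AUD", "LAN", "DAN", "CON", "FPN", "DMN")}
    counts["NONE"] = 2
    return make_atlas(counts, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
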
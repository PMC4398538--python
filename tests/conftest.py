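import numpy as np
import pytest

from agingnet.atlas import Atlas, default_atlas


@pytest.fixture(scope="session")
def atlas72():
    return default_atlas()


def make_atlas(entries):
    """Build an atlas from (name, hemisphere, lobe) triples."""
    return Atlas.from_dict(
        [{"name": n, "hemisphere": h, "lobe": l} for n, h, l in entries]
    )


@pytest.fixture
def toy_atlas6():
    """3 names x 2 hemispheres: prefrontal, occipital, lateral temporal."""
    return make_atlas(
        [
            ("front", "lh", "prefrontal"),
            ("occ", "lh", "occipital"),
            ("temp", "lh", "lateral_temporal"),
            ("front", "rh", "prefrontal"),
            ("occ", "rh", "occipital"),
            ("temp", "rh", "lateral_temporal"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
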
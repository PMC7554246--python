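import numpy as np
import pytest

from ubisite import embedding, synthetic
from ubisite.seq_data import ProteinRecord, SiteFragment


@pytest.fixture(scope="session")
def vocab():
    return embedding.build_vocab(2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def moderate_fragments():
    """2000+2000 fragments with the moderate (x3) plant-like R motif."""
    return synthetic.gen_labeled_fragments(
        2000, 2000, synthetic.plant_motif(3.0), seed=777
    )


def make_fragment(sequence: str, label: str = "unknown") -> SiteFragment:
    return SiteFragment("frag", (len(sequence) + 1) // 2, sequence, label)


@pytest.fixture()
def toy_protein():
    return ProteinRecord("toy", "MKVACDKWKLL")
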
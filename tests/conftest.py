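import numpy as np
import pytest

from metamec import io as mio
from metamec import synthetic


@pytest.fixture(scope="session")
def bpti_pairs():
    return mio.bpti_hbond_pairs()


@pytest.fixture(scope="session")
def helix_peptide():
    return synthetic.make_toy_peptide(10, "helix", seed=4)


@pytest.fixture(scope="session")
def extended_peptide():
    return synthetic.make_toy_peptide(10, "extended", seed=4)


@pytest.fixture(scope="session")
def small_ensemble():
    """A 1e4-frame synthetic metastatistics with known ground truth."""
    spec = synthetic.SyntheticEnsembleSpec(n_frames=10_000, seed=21)
    return spec, synthetic.sample_metastatistics(spec)
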
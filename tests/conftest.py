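import numpy as np
import pytest

from sncsec.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20201210)


@pytest.fixture
def small_cfg():
    """Small but structurally complete study configuration."""
    return SimConfig(
        n_features=40,
        n_secreted=8,
        nb_dispersion=0.3,
        baseline_mean=200.0,
        effect_log2fc=2.0,
        n_transcripts=4,
        transcript_length=600,
        n_planted_sites=3,
        seed=11,
    )
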
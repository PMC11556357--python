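import numpy as np
import pytest

from binocgain.gain_model import MEESE_2006, OcularArrangement, PUBLISHED_PARAMS


@pytest.fixture(scope="session")
def meese_params():
    """Canonical achromatic-grating parameter set."""
    return MEESE_2006


@pytest.fixture(scope="session")
def arrangements():
    return {
        tag: OcularArrangement(tag)
        for tag in ("monocular", "binocular", "half_binocular", "dichoptic")
    }


@pytest.fixture(scope="session")
def bayes_mechs():
    """Per-pathway parameter sets used as the cross-pathway backbone."""
    return (
        PUBLISHED_PARAMS["bayes_achromatic"],
        PUBLISHED_PARAMS["bayes_lm"],
        PUBLISHED_PARAMS["bayes_s"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
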
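import numpy as np
import pytest

from healthvuln import datasets


@pytest.fixture(scope="session")
def reference_components():
    """Published weighted component scores, overall scores, archetypes."""
    return datasets.load_weighted_components()


@pytest.fixture(scope="session")
def reference_levels():
    """47 x 4 integer exposure levels recovered from the published
    component scores."""
    return datasets.load_reference_levels()


@pytest.fixture(scope="session")
def reference_weights():
    return datasets.reference_weights()


@pytest.fixture(scope="session")
def method_scores():
    """Published overall V-scores under each weighting variant."""
    return datasets.load_method_scores()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
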
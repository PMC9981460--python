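import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dilac.isotope_model import LabelScheme, lysine_13c_scheme

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def scheme() -> LabelScheme:
    """The reference labelling scheme: 13C glucose feed, variable 13C6-lysine."""
    return lysine_13c_scheme()


@pytest.fixture
def unlabelled_scheme() -> LabelScheme:
    """Variable lysine, no fixed labels (isolates the target-site shift)."""
    return LabelScheme(target_residue="K", fixed_labelled_residues=frozenset())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230216)
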
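import numpy as np
import pytest

from ssnmrdyn.constants import FieldContext, InteractionConstants


@pytest.fixture(scope="session")
def field14():
    return FieldContext.from_tesla(14.09)


@pytest.fixture(scope="session")
def k14(field14):
    return InteractionConstants.for_field(field14)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
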
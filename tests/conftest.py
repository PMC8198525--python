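import numpy as np
import pytest

from deliq.components import builtin_components


@pytest.fixture(scope="session")
def cs():
    """The bundled parameter set (water + eight crystalline compounds)."""
    return builtin_components()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210526)
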
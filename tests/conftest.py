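import numpy as np
import pytest

from gstcurate.simulate import FamilySpec, generate_family


@pytest.fixture(scope="session")
def small_family():
    """A compact template family with all six classes and spliced genes."""
    spec = FamilySpec(genes_per_cluster=(11, 3, 4, 4, 1, 2), seed=9)
    return generate_family(spec)


@pytest.fixture(scope="session")
def plain_family():
    """A template family without spliced genes (single-transcript only)."""
    spec = FamilySpec(genes_per_cluster=(4, 4, 3, 3, 1, 2), spliced={},
                      seed=17)
    return generate_family(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
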
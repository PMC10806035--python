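import pytest

from mbsoc import generate_odor_library
from mbsoc.params import reference_optimum

MOTIFS = ("m1", "m2", "m3", "m4", "m5")


@pytest.fixture(scope="session")
def library():
    """Default three-odor library: disjoint 200-KC patterns, seed 999."""
    return generate_odor_library(seed=999)


@pytest.fixture(scope="session")
def optima():
    """Reference (most central optimal learner) combos per motif."""
    return {m: reference_optimum(m) for m in MOTIFS}
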
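import numpy as np
import pytest

from ligandpath import synthetic as syn


@pytest.fixture(scope="session")
def receptor():
    """Toy receptor with a 5 A cavity at the origin (shared, read-only)."""
    return syn.make_toy_receptor(900, seed=7)


@pytest.fixture(scope="session")
def site_coord(receptor):
    return np.asarray(receptor.metadata["cavity_center"], dtype=float)
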
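import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hldakin import default_toy_spec


@pytest.fixture(scope="session")
def toy_spec():
    return default_toy_spec()


@pytest.fixture(scope="session")
def ten_atom_frames():
    """Two 10-atom reference structures (compact vs extended) used across
    the structural tests."""
    rng = np.random.default_rng(42)
    folded = rng.normal(scale=0.5, size=(10, 3))
    unfolded = np.column_stack(
        [np.linspace(0, 3.0, 10), 0.2 * rng.standard_normal(10), np.zeros(10)]
    )
    return folded, unfolded
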
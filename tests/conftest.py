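import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from splicemaps.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across read-only tests."""
    return simulate_study(SimConfig(n_events=60, depth=150, seed=42))
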
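import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from acumine import PrescriptionDataset, load_registry

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture
def tiny_dataset():
    """Four hand-countable prescriptions."""
    return PrescriptionDataset(
        [
            frozenset({"LI4", "ST36"}),
            frozenset({"LI4", "ST36"}),
            frozenset({"LI4"}),
            frozenset({"ST36"}),
        ]
    )
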
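import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from orthoswift.search import AlignmentParams


@pytest.fixture(scope="session")
def params() -> AlignmentParams:
    """Default BLOSUM62 scoring (shared so numba compiles once)."""
    return AlignmentParams()


FIG1_SCORES = {
    # four-gene toy: A1-B1 reciprocal best, within-taxon pairs score higher,
    # A2 reaches both B genes but neither reciprocally
    ("A|A1", "B|B1"): 100.0,
    ("A|A1", "A|A2"): 150.0,
    ("B|B1", "B|B2"): 120.0,
    ("A|A2", "B|B1"): 80.0,
    ("A|A2", "B|B2"): 60.0,
}


@pytest.fixture()
def fig1_table():
    table = {}
    for (a, b), s in FIG1_SCORES.items():
        table[(a, b)] = s
        table[(b, a)] = s
    return table
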
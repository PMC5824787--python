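import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ancestlib.models import poisson_model, wag_model
from ancestlib.simulate import FamilySimSpec, ToyStructureSpec, \
    make_toy_structure, simulate_family


@pytest.fixture(scope="session")
def wag():
    return wag_model()


@pytest.fixture(scope="session")
def poisson():
    return poisson_model()


@pytest.fixture(scope="session")
def demo_family():
    """The bundled fixture: 12 taxa, 60 residues, WAG, depth 0.25."""
    return simulate_family(FamilySimSpec(seed=0))


@pytest.fixture(scope="session")
def toy_helix():
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVHHH"
    seq = seq[:29] + "H" + seq[30:]  # catalytic His at position 30
    assert len(seq) == 60
    spec = ToyStructureSpec(seq, geometry="helix", catalytic_position=30)
    pdb_text, truth = make_toy_structure(spec)
    return spec, pdb_text, truth
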
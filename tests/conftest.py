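import numpy as np
import pytest

from htfunclib.energy import generate_landscape
from htfunclib.epinnet import SiteNeighborhood
from htfunclib.pipeline import make_fixture


@pytest.fixture(scope="session")
def design_demo(tmp_path_factory):
    """Synthetic design fixture: toy PDB, MSA, planted landscape, ground truth."""
    out = tmp_path_factory.mktemp("design_demo")
    truth = make_fixture("design-demo", seed=7, out_dir=out)
    return out, truth


@pytest.fixture(scope="session")
def counts_demo(tmp_path_factory):
    out = tmp_path_factory.mktemp("counts_demo")
    truth = make_fixture("counts-demo", seed=7, out_dir=out)
    return out, truth


@pytest.fixture(scope="session")
def two_island(tmp_path_factory):
    out = tmp_path_factory.mktemp("two_island")
    truth = make_fixture("two-island", seed=7, out_dir=out)
    return out, truth


@pytest.fixture
def additive_landscape():
    """Purely additive 3-position landscape: no couplings, no planted pairs."""
    reference = {1: "A", 2: "C", 3: "D"}
    allowed = {1: {"G", "S"}, 2: {"W"}, 3: {"H", "K"}}
    return generate_landscape(
        reference, allowed, contacts=[(1, 2), (2, 3)],
        field_scale=1.0, coupling_scale=0.0, seed=3,
    )


@pytest.fixture
def chain_neighborhoods():
    """Three positions in a contact chain 1-2-3."""
    return [
        SiteNeighborhood(1, (1, 2)),
        SiteNeighborhood(2, (2, 1, 3)),
        SiteNeighborhood(3, (3, 2)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
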
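import numpy as np
import pytest

from energyscape.bln import BLN69_SEQUENCE, Conformation, parse_bln_sequence
from energyscape.database import LandscapeDatabase, Minimum, TransitionState
from energyscape.geometry import zigzag_chain
from energyscape.synthetic import FunnelSpec, generate_funnel_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def bln69():
    return parse_bln_sequence(BLN69_SEQUENCE)


@pytest.fixture
def bln69_conformation(bln69):
    rng = np.random.default_rng(7)
    coords = zigzag_chain(69) + rng.normal(0.0, 0.05, size=(69, 3))
    return Conformation(coords=coords, sequence=bln69)


@pytest.fixture
def toy_database():
    """Five minima on a path with one cross edge; hand-checkable barriers."""
    minima = [Minimum(index=k + 1, energy=e)
              for k, e in enumerate([-5.0, -4.0, -4.5, -3.0, -4.8])]
    tss = [
        TransitionState(energy=-2.0, i=1, j=2),
        TransitionState(energy=-1.0, i=2, j=3),
        TransitionState(energy=-2.5, i=3, j=4),
        TransitionState(energy=-0.5, i=4, j=5),
        TransitionState(energy=-2.2, i=1, j=5),
    ]
    return LandscapeDatabase(minima, tss)


@pytest.fixture(scope="session")
def funnel_landscape():
    spec = FunnelSpec(n_funnels=3, minima_per_funnel=20, seed=11)
    db, truth = generate_funnel_landscape(spec)
    return spec, db, truth
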
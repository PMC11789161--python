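import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cspcompare import synth
from cspcompare.synth import FixtureSpec, Placement


@pytest.fixture(scope="session")
def toy_p1():
    """One planar asymmetric molecule in a P1 box."""
    return synth.make_toy_crystal(FixtureSpec())


@pytest.fixture(scope="session")
def toy_p21c():
    """Chiral four-atom molecule on a general position of P2(1)/c."""
    return synth.make_toy_crystal(FixtureSpec(
        template="tiny4", spacegroup="P 21/c", cell=(9, 9, 9, 90, 100, 90),
        placements=[Placement(position=(0.15, 0.1, 0.2),
                              orientation=(10, 20, 30))],
        name="toy_p21c"))


@pytest.fixture(scope="session")
def cocrystal_p1():
    """Two chemically distinct molecules in one P1 cell."""
    return synth.make_toy_crystal(FixtureSpec(
        spacegroup="P 1", cell=(9.5, 9.5, 7.0, 90, 90, 90),
        placements=[Placement(template="ring6", position=(0.25, 0.25, 0.3)),
                    Placement(template="diamine", position=(0.75, 0.7, 0.72),
                              orientation=(40, 10, 0))],
        name="cocrystal"))


@pytest.fixture(scope="session")
def polytype_pair():
    return synth.make_polytypes(synth.LayerSpec(), 6)


@pytest.fixture(scope="session")
def disorder_trio():
    return synth.make_disorder_pair()


@pytest.fixture(scope="session")
def conformer_pair():
    a = synth.make_toy_crystal(FixtureSpec(
        template="core_sub", cell=(11, 11, 7.5, 90, 90, 90), name="conf_a"))
    b = synth.make_toy_crystal(FixtureSpec(
        template="core_sub_b", cell=(11, 11, 7.5, 90, 90, 90), name="conf_b"))
    return a, b


@pytest.fixture(scope="session")
def decoy(toy_p1):
    return synth.make_decoy(123, avoid=[toy_p1])
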
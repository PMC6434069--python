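import pytest

from ddgscan.mutant import RotamerLibrary
from ddgscan.synthetic import HelixSpec, make_dimer, make_helix, make_pocket


@pytest.fixture(scope="session")
def library():
    return RotamerLibrary.default()


@pytest.fixture(scope="session")
def helix():
    """A 12-residue mixed-sequence ideal alpha-helix."""
    return make_helix(HelixSpec("ALKAAEQFLAKA"))


def dimer_with_contacts():
    seq = ["G"] * 24
    seq[5], seq[11], seq[17] = "S", "F", "L"
    seq = "".join(seq)
    return make_dimer(
        HelixSpec(seq, chain_id="A"), HelixSpec(seq, chain_id="B"),
        contacts=[(6, 6, "hbond"), (12, 12, "ring_stack"), (18, 18, "proximal")])


@pytest.fixture(scope="session")
def dimer():
    return dimer_with_contacts()


@pytest.fixture(scope="session")
def pocket():
    return make_pocket(["hbond", "pi_stack", "metal", "proximal", "hbond"])
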
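from pathlib import Path

import pytest

from ringmetrics.anchors import builtin_anchor_set
from ringmetrics.synthetic import DnaSpec, RingSpec, make_bdna, make_ring

# Deposited coordinate files (e.g. 9nul.cif), if the user has fetched
# them, live here; integration tests run only when they are present.
DEPOSITION_DIR = Path(__file__).resolve().parent.parent / "depositions"


def deposition(pdb_id: str) -> Path | None:
    for suffix in (".cif", ".cif.gz", ".pdb"):
        p = DEPOSITION_DIR / f"{pdb_id.lower()}{suffix}"
        if p.exists():
            return p
    return None


@pytest.fixture(scope="session")
def archaeal_anchors():
    return builtin_anchor_set("archaeal_chimera")


@pytest.fixture(scope="session")
def uniform_ring():
    """C6-symmetric ring: all twists 0, all interfaces (5.0, 7.0)."""
    model, truth = make_ring(RingSpec(seed=11))
    return model, truth


@pytest.fixture()
def asym_ring():
    """Ring with distinguishable subunits (varied twists and distances)."""
    spec = RingSpec(
        per_subunit_twist=[0.0, -5.0, 12.0, -20.0, 4.0, 9.0],
        interface_atp_distances=[5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
        interface_h2i_distances=[7.0, 7.5, 8.0, 8.5, 9.0, 9.5],
        seed=23,
    )
    return make_ring(spec)


@pytest.fixture(scope="session")
def duplex_21():
    """Fully paired 21-bp idealized duplex."""
    return make_bdna(DnaSpec(sequence="ACTGACTGACTGACTGACTGA"))


@pytest.fixture(scope="session")
def melted_duplex():
    """21-bp duplex with 4 melted 5'-terminal tracked-strand nucleotides."""
    return make_bdna(DnaSpec(sequence="ACTGACTGACTGACTGACTGA", melted_5prime=4))
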
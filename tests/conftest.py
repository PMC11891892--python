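import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from alchemid import MoleculeRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def rec(smiles: str, name: str = "") -> MoleculeRecord:
    return MoleculeRecord.from_smiles(smiles, name or smiles)


@pytest.fixture
def three_site_pair():
    """Benzene core; parent A bears (F, CH3, OCH3), parent B (Cl, H, NH2)."""
    return rec("Fc1cc(C)cc(OC)c1", "A"), rec("Clc1cccc(N)c1", "B")


@pytest.fixture
def fused_pair():
    """Parent B closes a saturated ring over two adjacent core positions
    where parent A carries two independent substituents."""
    return rec("c1cc(C)c(CC)cc1O", "A"), rec("c1cc2c(cc1N)CCC2", "B")


@pytest.fixture
def stereo_junction_pair():
    """F vs Cl substituted directly at a shared stereocenter."""
    return (
        rec("N[C@H](F)c1ccc(C)cc1", "A"),
        rec("N[C@H](Cl)c1ccc(OC)cc1", "B"),
    )
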
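import numpy as np
import pytest

from dehalokit import nac, structure


@pytest.fixture
def default_site() -> nac.CatalyticSiteSpec:
    """Catalytic-site declaration matching the synthetic receptor layout."""
    return nac.CatalyticSiteSpec(
        nucleophile_oxygens=[nac.AtomRef("A", 95, "OD1"),
                             nac.AtomRef("A", 95, "OD2")],
        stabilizer_donors=[nac.AtomRef("A", 96, "HE1"),
                           nac.AtomRef("A", 28, "HD21")],
        ligand_carbon=nac.AtomRef("L", 1, "C2"),
    )


@pytest.fixture
def chain_selector():
    def make(chain_id: str) -> structure.AtomSelector:
        return structure.AtomSelector(chain_ids=frozenset(chain_id))
    return make


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
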
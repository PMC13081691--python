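import numpy as np
import pytest

from foldscreen.model import Atom, Chain, ComplexModel, ConfidenceBundle, Residue, attach
from foldscreen.model import ONE_TO_THREE
from foldscreen.synthetic_data import SyntheticSpec, make_dimer

_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_line_chain(chain_id, length, rng, origin=(0.0, 0.0, 0.0), spacing=3.8):
    """Minimal CA-only chain along x, for PAE-only score tests."""
    residues = []
    for i in range(length):
        aa = _AA[int(rng.integers(0, 20))]
        x = origin[0] + i * spacing
        residues.append(Residue(
            index=i + 1, name=ONE_TO_THREE[aa],
            atoms=[Atom("CA", x, origin[1], origin[2])],
            plddt=80.0,
        ))
    return Chain(chain_id=chain_id, residues=residues)


def make_pae_pair(la, lb, rng, pae=None):
    """A paired model over arbitrary (possibly random) PAE, geometry
    irrelevant: chains are CA lines far apart."""
    model = ComplexModel(model_id="pae_fixture", chains=[
        make_line_chain("A", la, rng),
        make_line_chain("B", lb, rng, origin=(0.0, 100.0, 0.0)),
    ])
    n = la + lb
    if pae is None:
        pae = rng.uniform(0.0, 30.0, size=(n, n))
        np.fill_diagonal(pae, 0.0)
    bundle = ConfidenceBundle(
        pae=np.asarray(pae, dtype=float),
        residue_chain=[(c.chain_id, r.index) for c in model.chains
                       for r in c.residues],
        ptm=0.7, iptm=0.6,
    )
    return attach(model, bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def docked_dimer():
    """Deterministic true-like synthetic dimer with its bundle."""
    return make_dimer(SyntheticSpec(seed=11, pae_inter_base=3.0,
                                    pae_noise_sd=0.0, plddt_noise_sd=0.0))


@pytest.fixture
def docked_pair(docked_dimer):
    model, bundle = docked_dimer
    return attach(model, bundle)
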
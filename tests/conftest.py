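import numpy as np
import pytest

from mechbond.structio import Atom, Frame

#: printed per-run interface-bond occupancy table (percent) of the three
#: equilibrium replicas, with the published mean ± SD columns
TABLE1_ROWS = [
    ("ASP740", "TRP359", (97.1, 97.1, 91.8), 95.3, 3.10),
    ("ALA742", "LYS357", (46.3, 71.9, 5.4), 41.2, 33.5),
    ("ASN744", "ILE356", (39.3, 72.2, 27.0), 46.2, 23.4),
    ("ASN744", "THR354", (20.1, 53.9, 0.0), 24.7, 23.9),
    ("TYR747", "ASN355", (28.1, 13.1, 18.5), 19.9, 7.60),
    ("GLU749", "LYS357", (6.0, 17.9, 0.0), 8.00, 8.40),
]

RUN2 = (0.971, 0.719, 0.722, 0.539, 0.131, 0.179)


def dha_frame(d_pos, h_pos, a_pos, donor_chain="L", acceptor_chain="R"):
    """Minimal two-chain frame: one N–H donor and one carbonyl-O acceptor."""
    atoms = [
        Atom(serial=1, name="N", element="N", resname="GLY", resid=1, chain=donor_chain),
        Atom(serial=2, name="H", element="H", resname="GLY", resid=1, chain=donor_chain),
        Atom(serial=3, name="O", element="O", resname="GLY", resid=2, chain=acceptor_chain),
    ]
    return Frame(atoms, np.array([d_pos, h_pos, a_pos], dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
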
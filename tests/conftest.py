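import numpy as np
import pytest

from pdmsite.atom_types import default_atom_type_table
from pdmsite.sasa import compute_sasa
from pdmsite.structure import assign_atom_types, label_ppi_atoms, select_prediction_atoms
from pdmsite.synthetic import ToyComplexSpec, generate_reference_set, generate_toy_complex


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix via QR with sign fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def typed_reference_set():
    """Two small toy globules, typed and SASA-labeled."""
    refs = generate_reference_set(2, seed=11, layers=3, strands=4, length=4)
    table = default_atom_type_table()
    for st in refs:
        assign_atom_types(st, table)
        compute_sasa(st, n_points=256)
    return refs


@pytest.fixture(scope="session")
def labeled_complex():
    """One toy complex through typing, SASA, dSASA labeling and selection."""
    unbound, complexed, interface = generate_toy_complex(ToyComplexSpec(seed=5))
    table = default_atom_type_table()
    assign_atom_types(unbound, table)
    assign_atom_types(complexed, table)
    compute_sasa(unbound, n_points=256)
    compute_sasa(complexed, n_points=256)
    label_ppi_atoms(unbound, complexed)
    predictable = select_prediction_atoms(unbound)
    return unbound, complexed, interface, predictable
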
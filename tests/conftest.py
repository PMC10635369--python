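import numpy as np
import pytest

from helixcontact.contact_map import candidate_pairs
from helixcontact.structure_io import AtomRecord, ChainStructure, Residue
from helixcontact.synthetic import BundleSpec, helix_bundle, ideal_helix


def make_residue(seq_index, atom_coords, aa="A", author_number=None, names=None):
    """Residue with arbitrary atom coordinates; names default C1, C2, ..."""
    if names is None:
        names = [f"C{k + 1}" for k in range(len(atom_coords))]
    atoms = [
        AtomRecord(name=n, element="C", coords=c)
        for n, c in zip(names, atom_coords)
    ]
    return Residue(
        seq_index=seq_index,
        author_number=author_number if author_number is not None else seq_index + 1,
        aa_code=aa,
        atoms=atoms,
    )


def random_rotation(rng):
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_chain(chain, rot, shift):
    residues = []
    for r in chain.residues:
        atoms = [
            AtomRecord(name=a.name, element=a.element,
                       coords=rot @ a.coords + shift,
                       occupancy=a.occupancy, altloc=a.altloc)
            for a in r.atoms
        ]
        residues.append(Residue(seq_index=r.seq_index, author_number=r.author_number,
                                aa_code=r.aa_code, atoms=atoms))
    return ChainStructure(chain_id=chain.chain_id, residues=residues,
                          source_tag=chain.source_tag)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def helix12():
    chain, axis = ideal_helix(12, seed=1)
    return chain, axis


@pytest.fixture(scope="session")
def tight_bundle():
    """Two 15-residue helices 8 A apart: guaranteed contacts."""
    return helix_bundle(BundleSpec(n_helices=2, residues_per_helix=15,
                                   inter_axial_distance=8.0, seed=3))


@pytest.fixture(scope="session")
def tight_bundle_pairs(tight_bundle):
    chain, ann = tight_bundle
    return candidate_pairs(chain, ann)


@pytest.fixture(scope="session")
def distant_bundle():
    """Two helices 40 A apart: no contacts possible."""
    return helix_bundle(BundleSpec(n_helices=2, residues_per_helix=15,
                                   inter_axial_distance=40.0, seed=3))
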
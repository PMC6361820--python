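import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")

from znsites.detection import detect_sites
from znsites.structure import (
    Atom,
    Chain,
    Residue,
    STANDARD_AMINO_ACIDS,
    StructureModel,
)

THREE_LETTER = {one: three for three, one in STANDARD_AMINO_ACIDS.items()}

TET = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)

#: ligand atom placed for each 1-letter code in site-model construction
LIGAND_ATOM = {
    "C": ("SG", "S", 2.33),
    "H": ("NE2", "N", 2.12),
    "D": ("OD1", "O", 2.10),
    "E": ("OE1", "O", 2.10),
}


def protein_residue(chain_id, number, name, base, side_atoms=()):
    base = np.asarray(base, dtype=float)
    label = str(number)
    offsets = [
        ("N", "N", (-1.2, 0.7, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.3, 0.6, 0.0)),
        ("O", "O", (1.4, 1.8, 0.0)),
        ("CB", "C", (-0.3, -1.4, 0.2)),
        ("CG", "C", (-0.6, -2.7, 0.5)),
    ]
    atoms = [
        Atom(name=n, element=e, position=base + np.array(off),
             source_id=(chain_id, label, n))
        for n, e, off in offsets
    ]
    atoms += [
        Atom(name=n, element=e, position=np.asarray(p, dtype=float),
             source_id=(chain_id, label, n))
        for n, e, p in side_atoms
    ]
    return Residue(id=(chain_id, number, ""), name=name, atoms=atoms, is_protein=True)


def zinc_residue(chain_id="A", number=101, position=(0.0, 0.0, 0.0)):
    return Residue(
        id=(chain_id, number, ""),
        name="ZN",
        atoms=[Atom(name="ZN", element="Zn", position=np.asarray(position, dtype=float),
                    source_id=(chain_id, str(number), "ZN"))],
    )


def make_site_model(pdb_id, sequence, ligand_idx, resolution=2.0, chain_id="A"):
    """A model with one chain of ``sequence``; the residues at the 0-based
    ``ligand_idx`` positions coordinate a zinc at the origin through the
    side-chain atom matching their one-letter code."""
    residues = []
    directions = iter(TET)
    for i, letter in enumerate(sequence):
        base = np.array([-30.0 + 4.5 * i, 25.0, 0.0])
        side = ()
        if i in ligand_idx:
            atom_name, element, dist = LIGAND_ATOM[letter]
            side = ((atom_name, element, next(directions) * dist),)
        residues.append(
            protein_residue(chain_id, i + 1, THREE_LETTER[letter], base, side)
        )
    return StructureModel(
        pdb_id=pdb_id,
        chains=[Chain(id=chain_id, residues=residues)],
        hetero_residues=[zinc_residue(chain_id)],
        resolution=resolution,
    )


def detect_single_site(model):
    sites, exclusions = detect_sites(model)
    assert len(sites) == 1 and not exclusions
    return sites[0]


@pytest.fixture
def site_model_factory():
    return make_site_model
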
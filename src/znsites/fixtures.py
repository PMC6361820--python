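"""Synthetic PDB fixtures with constructively known ground truth.

Each scenario builds a small structure whose detection outcome is known by
construction — the geometry is placed so that every rule (distance cutoff,
angle filter, salt thresholds, symmetry deduplication, assembly expansion,
chain clustering) fires or does not fire by design.  The ground truth
returned alongside the PDB text is therefore *not* produced by running the
detector; it is what the generator placed.

Scenarios
---------
SALT            zinc coordinated by waters only -> excluded as a salt
C4_SITE         one zinc tetrahedrally bound by four cysteine thiolates
BIDENTATE       zinc bound by two histidines and a bidentate aspartate
ANGLE_PROBE     two carboxylate oxygens of one residue at a chosen angle
INTERFACE       a 3-fold assembly site: one histidine per chain copy
COACTIVE        multi-metal site bridged to zinc by histidines
DUPLICATED_ASU  several chain copies in the asymmetric unit, assembly
                keeps one (the rest excluded), or -- with ``expand`` --
                one chain expanded into several identical site copies
BACKBONE_ONLY   a C-alpha/backbone-only file, undetectable side chains
FAMILY          k protein families of mutated chain copies (sequences
                only), for chain-cluster recovery

Every fixture is written through the regular PDB writer at 3-decimal
coordinate precision; scene placement (random rotation/translation per
seed) keeps all constructed distances and angles far enough from the rule
boundaries that rounding cannot flip an outcome.
"""

from __future__ import annotations

import dataclasses
import string
from typing import Any

import numpy as np

from znsites.structure import (
    AssemblyGenerator,
    AssemblyInstruction,
    Atom,
    Chain,
    Residue,
    StructureModel,
    STANDARD_AMINO_ACIDS,
    write_pdb,
)

__all__ = ["FixtureSpec", "make_fixture", "make_angle_probe", "SCENARIOS"]

SCENARIOS = (
    "SALT",
    "C4_SITE",
    "BIDENTATE",
    "ANGLE_PROBE",
    "INTERFACE",
    "COACTIVE",
    "DUPLICATED_ASU",
    "BACKBONE_ONLY",
    "FAMILY",
)

_THREE_LETTER = {one: three for three, one in STANDARD_AMINO_ACIDS.items()}
_FILLER = ["SER", "VAL", "LEU", "THR", "PHE", "ILE", "LYS", "PRO"]
_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

# characteristic metal-ligand distances (Angstrom) used as generator defaults
_D_S = 2.33   # thiolate sulphur
_D_N = 2.12   # imidazole nitrogen
_D_O = 2.10   # water / carboxylate oxygen

_TET = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)


@dataclasses.dataclass
class FixtureSpec:
    """A request for one synthetic structure.

    ``params`` carries the per-scenario knobs, e.g. ``theta`` for
    ANGLE_PROBE, ``n_transforms`` for INTERFACE, ``elements`` for COACTIVE,
    ``n_copies``/``expand`` for DUPLICATED_ASU, ``k``/``mutation_rate`` for
    FAMILY.  ``resolution`` is stamped into REMARK 2.
    """

    scenario: str
    seed: int = 0
    resolution: float | None = 2.0
    params: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid: {', '.join(SCENARIOS)}"
            )


def make_angle_probe(theta: float, d1: float = 2.0, d2: float = 2.2) -> dict[str, np.ndarray]:
    """Coordinates for a metal and two same-residue oxygens at angle ``theta``.

    The metal sits at the origin, the first oxygen at ``d1`` along +x and
    the second at ``d2`` in the xy-plane so that the metal-vertex angle
    equals ``theta`` degrees.
    """
    if not 0 < theta < 180:
        raise ValueError(f"theta must be in (0, 180), got {theta}")
    if not 0 < d1 <= d2:
        raise ValueError("distances must satisfy 0 < d1 <= d2")
    rad = np.radians(theta)
    return {
        "metal": np.zeros(3),
        "o1": np.array([d1, 0.0, 0.0]),
        "o2": np.array([d2 * np.cos(rad), d2 * np.sin(rad), 0.0]),
    }


# ---------------------------------------------------------------------------
# low-level construction helpers


def _residue(chain_id: str, number: int, name: str, base: np.ndarray,
             side_atoms: list[tuple[str, str, np.ndarray]] | None = None,
             with_cb: bool = True) -> Residue:
    label = str(number)
    offsets = [
        ("N", "N", np.array([-1.2, 0.7, 0.0])),
        ("CA", "C", np.zeros(3)),
        ("C", "C", np.array([1.3, 0.6, 0.0])),
        ("O", "O", np.array([1.4, 1.8, 0.0])),
    ]
    if with_cb:
        offsets.append(("CB", "C", np.array([-0.3, -1.4, 0.2])))
        if name not in ("GLY", "ALA"):
            # a gamma carbon so the structure is not mistaken for a backbone trace
            offsets.append(("CG", "C", np.array([-0.6, -2.7, 0.5])))
    atoms = [
        Atom(name=n, element=e, position=base + off,
             source_id=(chain_id, label, n))
        for n, e, off in offsets
    ]
    for n, e, pos in side_atoms or []:
        atoms.append(Atom(name=n, element=e, position=np.asarray(pos, dtype=float),
                          source_id=(chain_id, label, n)))
    return Residue(id=(chain_id, number, ""), name=name, atoms=atoms, is_protein=True)


def _chain(rng: np.random.Generator, chain_id: str, n_residues: int,
           ligands: dict[int, tuple[str, list[tuple[str, str, np.ndarray]]]],
           base: np.ndarray, with_cb: bool = True,
           names: list[str] | None = None) -> Chain:
    """A chain of ``n_residues``; ``ligands`` maps residue number -> (name, side atoms).

    Backbone runs along +x from ``base``, safely away from the site region.
    """
    residues = []
    for i in range(1, n_residues + 1):
        pos = base + np.array([4.5 * (i - 1), 0.0, 0.0])
        if i in ligands:
            name, side = ligands[i]
            residues.append(_residue(chain_id, i, name, pos, side, with_cb))
        else:
            name = names[i - 1] if names else _FILLER[rng.integers(len(_FILLER))]
            residues.append(_residue(chain_id, i, name, pos, with_cb=with_cb))
    return Chain(id=chain_id, residues=residues)


def _het(chain_id: str, number: int, name: str, atoms: list[tuple[str, str, np.ndarray]],
         is_water: bool = False) -> Residue:
    label = str(number)
    return Residue(
        id=(chain_id, number, ""), name=name,
        atoms=[Atom(name=n, element=e, position=np.asarray(p, dtype=float),
                    source_id=(chain_id, label, n)) for n, e, p in atoms],
        is_water=is_water,
    )


def _zinc(chain_id: str, number: int, position: np.ndarray) -> Residue:
    return _het(chain_id, number, "ZN", [("ZN", "Zn", position)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _apply_scene(model: StructureModel, rot: np.ndarray, shift: np.ndarray) -> None:
    """Rigidly move the whole scene; assembly operators are conjugated so the
    assembly still reproduces the same geometry in the new frame."""
    for residue in model.residues():
        for atom in residue.atoms:
            atom.position = rot @ atom.position + shift
    for asm in model.assemblies:
        for gen in asm.generators:
            gen.transforms = [
                (rot @ s @ rot.T, shift - (rot @ s @ rot.T) @ shift + rot @ v)
                for s, v in gen.transforms
            ]
    for residue in model.residues():
        for atom in residue.atoms:
            atom.position = np.round(atom.position, 3)


def _jitter(rng: np.random.Generator, nominal: float, spread: float = 0.04) -> float:
    return float(nominal + rng.uniform(-spread, spread))


def _model(spec: FixtureSpec, chains: list[Chain], hetero: list[Residue],
           assemblies: list[AssemblyInstruction] | None = None,
           molecule_name: str = "SYNTHETIC ZINC PROTEIN") -> StructureModel:
    return StructureModel(
        pdb_id=f"Z{spec.seed % 1000:03d}",
        chains=chains,
        hetero_residues=hetero,
        resolution=spec.resolution,
        molecule_name=molecule_name,
        assemblies=assemblies or [],
    )


def _site_truth(signature: str | None, n_metals: int, n_contacts: int,
                copies: int = 1, coordination: int | None = None) -> dict:
    return {
        "signature": signature,
        "n_metals": n_metals,
        "n_contacts": n_contacts,
        "copies": copies,
        "coordination": coordination,
    }


# ---------------------------------------------------------------------------
# scenarios


def _scenario_salt(spec: FixtureSpec, rng: np.random.Generator):
    waters = [
        _het("A", 201 + i, "HOH", [("O", "O", _TET[i] * _jitter(rng, _D_O))], is_water=True)
        for i in range(4)
    ]
    chain = _chain(rng, "A", 6, {}, base=np.array([-30.0, 25.0, 0.0]))
    model = _model(spec, [chain], [_zinc("A", 101, np.zeros(3))] + waters,
                   molecule_name="ZINC CHLORIDE SOAK")
    truth = {"n_sites": 0, "sites": [], "exclusions": ["TOO_FEW_RESIDUES"]}
    return model, truth


def _scenario_c4(spec: FixtureSpec, rng: np.random.Generator):
    ligands = {
        2 * i + 2: ("CYS", [("SG", "S", _TET[i] * _jitter(rng, _D_S))])
        for i in range(4)
    }
    chain = _chain(rng, "A", 9, ligands, base=np.array([-30.0, 25.0, 0.0]))
    model = _model(spec, [chain], [_zinc("A", 101, np.zeros(3))],
                   molecule_name="SYNTHETIC ZINC FINGER")
    truth = {
        "n_sites": 1,
        "sites": [_site_truth("C4", 1, 4, coordination=4)],
        "exclusions": [],
    }
    return model, truth


def _scenario_bidentate(spec: FixtureSpec, rng: np.random.Generator):
    # aspartate donates both carboxylate oxygens 60 degrees apart (kept, >= 45)
    rad = np.radians(60.0)
    od1 = np.array([_jitter(rng, 2.0), 0.0, 0.0])
    od2 = _jitter(rng, 2.2) * np.array([np.cos(rad), np.sin(rad), 0.0])
    ligands = {
        2: ("HIS", [("NE2", "N", np.array([-1.0, 0.0, 0.0]) * _jitter(rng, _D_N))]),
        4: ("ASP", [("OD1", "O", od1), ("OD2", "O", od2)]),
        6: ("HIS", [("NE2", "N", np.array([0.0, -1.0, 0.0]) * _jitter(rng, _D_N))]),
    }
    chain = _chain(rng, "A", 7, ligands, base=np.array([-30.0, 25.0, 0.0]))
    model = _model(spec, [chain], [_zinc("A", 101, np.zeros(3))],
                   molecule_name="SYNTHETIC HYDROLASE")
    truth = {
        "n_sites": 1,
        "sites": [_site_truth("D1H2", 1, 4, coordination=4)],
        "exclusions": [],
    }
    return model, truth


def _scenario_angle_probe(spec: FixtureSpec, rng: np.random.Generator):
    theta = float(spec.params.get("theta", 30.0))
    d1 = float(spec.params.get("d1", 2.0))
    d2 = float(spec.params.get("d2", 2.2))
    probe = make_angle_probe(theta, d1, d2)
    od1 = np.round(probe["o1"], 3)
    od2 = np.round(probe["o2"], 3)
    ligands = {
        2: ("HIS", [("NE2", "N", np.array([0.0, 0.0, 1.0]) * _D_N)]),
        4: ("ASP", [("OD1", "O", od1), ("OD2", "O", od2)]),
        6: ("HIS", [("NE2", "N", np.array([0.0, 0.0, -1.0]) * _D_N)]),
    }
    chain = _chain(rng, "A", 7, ligands, base=np.array([-30.0, 25.0, 0.0]))
    model = _model(spec, [chain], [_zinc("A", 101, np.zeros(3))],
                   molecule_name="SYNTHETIC ANGLE PROBE")
    # truth from the rounded, as-written geometry
    cos = np.dot(od1, od2) / (np.linalg.norm(od1) * np.linalg.norm(od2))
    written_theta = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    both_kept = not written_theta < 45.0 - 1e-9
    asp_atoms = 2 if both_kept else 1
    n_contacts = 2 + asp_atoms
    signature = "D1H2"
    truth = {
        "n_sites": 1,
        "sites": [_site_truth(signature, 1, n_contacts, coordination=n_contacts)],
        "exclusions": [],
        "asp_atoms_kept": asp_atoms,
    }
    return model, truth


def _scenario_interface(spec: FixtureSpec, rng: np.random.Generator):
    n = int(spec.params.get("n_transforms", 3))
    if n < 2:
        raise ValueError("INTERFACE needs at least 2 transforms")
    # one histidine per chain copy; the zinc sits on the n-fold z-axis
    phi = np.radians(70.0)
    d = _jitter(rng, _D_N, 0.02)
    ne2 = d * np.array([np.sin(phi), 0.0, np.cos(phi)])
    ligands = {3: ("HIS", [("NE2", "N", ne2)])}
    chain = _chain(rng, "A", 5, ligands, base=np.array([-30.0, 25.0, 6.0]))
    transforms = []
    for k in range(n):
        a = 2 * np.pi * k / n
        transforms.append((
            np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]]),
            np.zeros(3),
        ))
    assembly = AssemblyInstruction(
        id="1", generators=[AssemblyGenerator(chain_ids=("A",), transforms=transforms)]
    )
    model = _model(spec, [chain], [_zinc("A", 101, np.zeros(3))], [assembly],
                   molecule_name="SYNTHETIC TRIMERIC HORMONE")
    if n >= 3:
        sites = [_site_truth(f"H{n}", 1, n, coordination=n)]
        exclusions: list[str] = []
    else:  # two histidines give two residues but only two protein atoms
        sites, exclusions = [], ["TOO_FEW_ATOMS"]
    truth = {
        "n_sites": len(sites),
        "sites": sites,
        "exclusions": exclusions,
        "asu": {"n_sites": 0, "exclusions": ["TOO_FEW_RESIDUES"]},
    }
    return model, truth


def _scenario_coactive(spec: FixtureSpec, rng: np.random.Generator):
    elements = tuple(spec.params.get("elements", ("Cu",)))
    if not 1 <= len(elements) <= 2:
        raise ValueError("COACTIVE supports 1 or 2 extra metals")
    hetero = [_zinc("A", 101, np.zeros(3))]
    ligands = {
        2: ("CYS", [("SG", "S", _TET[0] * _jitter(rng, _D_S))]),
        4: ("CYS", [("SG", "S", _TET[1] * _jitter(rng, _D_S))]),
    }
    # each extra metal is bridged to the zinc by its own histidine
    for j, element in enumerate(elements):
        v = _TET[2 + j]
        w = np.cross(v, np.array([0.0, 0.0, 1.0]))
        w /= np.linalg.norm(w)
        metal_pos = 4.1 * v
        hetero.append(
            _het("A", 201 + j, element.upper(),
                 [(element.upper(), element.capitalize(), metal_pos)])
        )
        ligands[6 + 2 * j] = (
            "HIS",
            [("NE2", "N", _jitter(rng, 2.05, 0.02) * v),
             ("ND1", "N", metal_pos - 2.0 * w)],
        )
    chain = _chain(rng, "A", 6 + 2 * len(elements) + 1, ligands,
                   base=np.array([-40.0, 25.0, 0.0]))
    model = _model(spec, [chain], hetero, molecule_name="SYNTHETIC OXIDOREDUCTASE")
    n_metals = 1 + len(elements)
    # zinc sees 2 SG + one NE2 per bridge; each extra metal sees its ND1 + NE2
    n_contacts = (2 + len(elements)) + 2 * len(elements)
    signature = f"C2H{len(elements)}"
    coactive: dict[str, list[int]] = {}
    for element in elements:
        sym = element.capitalize()
        extra = coactive.setdefault(sym, [0, 0])
        extra[0] += 1
        extra[1] = 1
    truth = {
        "n_sites": 1,
        "sites": [_site_truth(signature, n_metals, n_contacts)],
        "exclusions": [],
        "coactive": {k: tuple(v) for k, v in coactive.items()},
    }
    return model, truth


def _scenario_duplicated_asu(spec: FixtureSpec, rng: np.random.Generator):
    n = int(spec.params.get("n_copies", 4))
    expand = bool(spec.params.get("expand", False))
    if n < 2:
        raise ValueError("DUPLICATED_ASU needs at least 2 copies")

    def c4_chain(chain_id: str, center: np.ndarray) -> tuple[Chain, Residue]:
        ligands = {
            2 * i + 2: ("CYS", [("SG", "S", center + _TET[i] * _jitter(rng, _D_S))])
            for i in range(4)
        }
        chain = _chain(rng, chain_id, 9, ligands,
                       base=center + np.array([-30.0, 25.0, 0.0]))
        return chain, _zinc(chain_id, 101, center)

    if expand:
        # one chain in the file; the assembly stamps out n translated copies,
        # each an identical-by-source site, merged with a copy counter
        chain, zn = c4_chain("A", np.zeros(3))
        transforms = [
            (np.eye(3), np.array([0.0, 0.0, 60.0 * k])) for k in range(n)
        ]
        assembly = AssemblyInstruction(
            id="1", generators=[AssemblyGenerator(chain_ids=("A",), transforms=transforms)]
        )
        model = _model(spec, [chain], [zn], [assembly],
                       molecule_name="SYNTHETIC ZINC FINGER")
        truth = {
            "n_sites": 1,
            "sites": [_site_truth("C4", 1, 4, copies=n, coordination=4)],
            "exclusions": [],
        }
        return model, truth

    # n identical chains in the asymmetric unit; the assembly keeps only A
    chains, hetero = [], []
    seq_names = [_FILLER[rng.integers(len(_FILLER))] for _ in range(9)]
    for k in range(n):
        cid = _CHAIN_IDS[k]
        center = np.array([0.0, 0.0, 60.0 * k])
        ligands = {
            2 * i + 2: ("CYS", [("SG", "S", center + _TET[i] * _jitter(rng, _D_S))])
            for i in range(4)
        }
        chains.append(_chain(rng, cid, 9, ligands,
                             base=center + np.array([-30.0, 25.0, 0.0]),
                             names=seq_names))
        hetero.append(_zinc(cid, 101, center))
    assembly = AssemblyInstruction(
        id="1", generators=[AssemblyGenerator(chain_ids=("A",), transforms=[(np.eye(3), np.zeros(3))])]
    )
    model = _model(spec, chains, hetero, [assembly], molecule_name="SYNTHETIC ZINC FINGER")
    truth = {
        "n_sites": 1,
        "sites": [_site_truth("C4", 1, 4, coordination=4)],
        "exclusions": ["NOT_IN_ASSEMBLY"] * (n - 1),
        "asu": {"n_sites": n, "exclusions": []},
    }
    return model, truth


def _scenario_backbone_only(spec: FixtureSpec, rng: np.random.Generator):
    chain = _chain(rng, "A", 8, {}, base=np.array([-20.0, 4.0, 0.0]), with_cb=False)
    model = _model(spec, [chain], [_zinc("A", 101, np.zeros(3))],
                   molecule_name="CALPHA TRACE")
    truth = {"n_sites": 0, "sites": [], "exclusions": ["NO_SIDECHAINS"]}
    return model, truth


def _mutate(rng: np.random.Generator, sequence: str, n_mutations: int) -> str:
    letters = sorted(STANDARD_AMINO_ACIDS.values())
    positions = rng.choice(len(sequence), size=n_mutations, replace=False)
    out = list(sequence)
    for p in positions:
        choices = [c for c in letters if c != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _scenario_family(spec: FixtureSpec, rng: np.random.Generator):
    k = int(spec.params.get("k", 3))
    n_per = int(spec.params.get("n_per", 5))
    rate = float(spec.params.get("mutation_rate", 0.05))
    length = int(spec.params.get("length", 60))
    if not 2 <= k <= 6:
        raise ValueError("FAMILY supports k in 2..6")
    if not 0 < rate < 0.10:
        raise ValueError("mutation_rate must be in (0, 0.10)")
    if k * n_per > len(_CHAIN_IDS):
        raise ValueError("too many chains for PDB chain identifiers")

    letters = sorted(STANDARD_AMINO_ACIDS.values())
    parents: list[str] = []
    while len(parents) < k:
        candidate = "".join(letters[i] for i in rng.integers(len(letters), size=length))
        # keep parents well below the clustering threshold of each other
        if all(
            sum(a == b for a, b in zip(candidate, p)) / length < 0.5 for p in parents
        ):
            parents.append(candidate)

    n_mut = max(1, int(rate * length))
    chains, families = [], {}
    idx = 0
    for f, parent in enumerate(parents):
        for j in range(n_per):
            cid = _CHAIN_IDS[idx]
            idx += 1
            seq = parent if j == 0 else _mutate(rng, parent, n_mut)
            names = [_THREE_LETTER[c] for c in seq]
            chains.append(
                _chain(rng, cid, length, {}, base=np.array([-150.0, 12.0 * idx, 0.0]),
                       with_cb=False, names=names)
            )
            families[cid] = f
    model = _model(spec, chains, [], molecule_name="SYNTHETIC PROTEIN FAMILIES")
    truth = {
        "n_sites": 0,
        "sites": [],
        "exclusions": [],
        "n_chain_clusters": k,
        "families": families,
    }
    return model, truth


_BUILDERS = {
    "SALT": _scenario_salt,
    "C4_SITE": _scenario_c4,
    "BIDENTATE": _scenario_bidentate,
    "ANGLE_PROBE": _scenario_angle_probe,
    "INTERFACE": _scenario_interface,
    "COACTIVE": _scenario_coactive,
    "DUPLICATED_ASU": _scenario_duplicated_asu,
    "BACKBONE_ONLY": _scenario_backbone_only,
    "FAMILY": _scenario_family,
}

# scenarios whose rule-boundary geometry must be written exactly as built
_NO_SCENE = {"ANGLE_PROBE", "FAMILY"}


def make_fixture(spec: FixtureSpec) -> tuple[str, dict]:
    """Generate PDB text plus its machine-readable ground truth.

    The truth dict records, constructively, the expected detection outcome:
    ``n_sites``, per-site ``signature``/``n_metals``/``n_contacts``/
    ``copies``/``coordination``, the expected ``exclusions`` (reason enum
    names), and scenario-specific extras (``asu`` for the asymmetric-unit
    outcome, ``n_chain_clusters`` for FAMILY, ...).
    """
    rng = np.random.default_rng(spec.seed)
    model, truth = _BUILDERS[spec.scenario](spec, rng)
    if spec.scenario in _NO_SCENE:
        shift = np.round(rng.uniform(-8, 8, size=3), 3)
        _apply_scene(model, np.eye(3), shift)
    else:
        _apply_scene(model, _random_rotation(rng), rng.uniform(-8, 8, size=3))
    truth = {"scenario": spec.scenario, "seed": spec.seed, **truth}
    return write_pdb(model), truth
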
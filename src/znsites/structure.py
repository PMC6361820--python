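"""Structure data model: PDB parsing, biological assembly generation.

The parser is a thin layer over :mod:`gemmi` that normalises a structure into
the small object model the detection pipeline needs: chains of protein
residues, hetero residues (metals, ligands, waters), the resolution, the
molecule name and the biological-assembly instructions (REMARK 350).  Only
the first model of multi-model (NMR) files is used, and for alternate
locations only the highest-occupancy conformer is kept (ties resolved in
favour of altloc 'A').

Every atom carries a ``source_id`` — the (chain id, residue label, atom
name) triple of the asymmetric-unit atom it came from — which survives
assembly expansion unchanged.  This is the key used later to recognise
symmetry-duplicated metals and symmetry-duplicated binding sites.
"""

from __future__ import annotations

import dataclasses
import datetime
from collections.abc import Iterator, Mapping

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "AssemblyGenerator",
    "AssemblyInstruction",
    "StructureModel",
    "PDBParseError",
    "EmptyStructureError",
    "parse_structure",
    "write_pdb",
    "select_assembly",
    "build_assembly",
    "chain_sequence",
    "METAL_ELEMENTS",
    "STANDARD_AMINO_ACIDS",
]


class PDBParseError(ValueError):
    """A fixed-column record could not be parsed; the message names the line."""


class EmptyStructureError(ValueError):
    """The input contains no ATOM or HETATM records."""


#: Every metallic element symbol (alkali, alkaline-earth, transition,
#: post-transition, lanthanide/actinide), per gemmi's periodic table.
METAL_ELEMENTS: frozenset[str] = frozenset(
    gemmi.Element(z).name for z in range(1, 119) if gemmi.Element(z).is_metal
)

STANDARD_AMINO_ACIDS: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "DOD", "WAT"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "CB"}


@dataclasses.dataclass(eq=False)
class Atom:
    """One atom; ``source_id`` identifies its asymmetric-unit original."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float | None = 1.0
    altloc: str = ""
    source_id: tuple[str, str, str] = ("", "", "")
    copy_index: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.element:
            raise ValueError(f"atom {self.name!r} has no element")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r} has non-finite coordinates")
        if self.occupancy is not None and not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r} occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_metal(self) -> bool:
        return self.element in METAL_ELEMENTS


@dataclasses.dataclass(eq=False)
class Residue:
    """A residue: ``id`` is (chain id, residue number, insertion code)."""

    id: tuple[str, int, str]
    name: str
    atoms: list[Atom]
    is_water: bool = False
    is_protein: bool = False
    copy_index: int = 0

    def __post_init__(self) -> None:
        if self.is_water and self.is_protein:
            raise ValueError(f"residue {self.id} cannot be both water and protein")

    @property
    def chain_id(self) -> str:
        return self.id[0]

    @property
    def label(self) -> str:
        """Residue number + insertion code, e.g. ``'101'`` or ``'52A'``."""
        return f"{self.id[1]}{self.id[2]}".strip()

    @property
    def one_letter(self) -> str:
        """One-letter code; ``X`` for a non-standard amino acid."""
        return STANDARD_AMINO_ACIDS.get(self.name, "X")

    @property
    def key(self) -> tuple[tuple[str, int, str], int]:
        """Identity of this residue instance within an (expanded) model."""
        return (self.id, self.copy_index)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.id} has no atom {name!r}")


@dataclasses.dataclass(eq=False)
class Chain:
    """An ordered run of protein residues sharing one chain identifier.

    ``copy_index`` is 0 for the asymmetric-unit original and k for the copy
    produced by the k-th assembly transform.
    """

    id: str
    residues: list[Residue]
    copy_index: int = 0

    @property
    def sequence(self) -> str:
        return chain_sequence(self)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclasses.dataclass(eq=False)
class AssemblyGenerator:
    """One block of transforms applied to one set of chains."""

    chain_ids: tuple[str, ...]
    transforms: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        self.transforms = [
            (np.asarray(r, dtype=float), np.asarray(t, dtype=float))
            for r, t in self.transforms
        ]
        for rot, _ in self.transforms:
            if np.abs(rot @ rot.T - np.eye(3)).max() > 1e-4:
                raise ValueError("assembly rotation matrix is not orthonormal")


@dataclasses.dataclass(eq=False)
class AssemblyInstruction:
    """A biological-assembly recipe (REMARK 350 biomolecule).

    ``energy`` is an optional annotation (kcal/mol) used to pick among
    several zinc-containing assemblies; PDB files do not carry it, so it is
    usually absent and the first-listed zinc-containing assembly wins.
    """

    id: str
    generators: list[AssemblyGenerator]
    energy: float | None = None

    def __post_init__(self) -> None:
        if not any(g.transforms for g in self.generators):
            raise ValueError(f"assembly {self.id!r} declares no transforms")

    @property
    def transforms(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [t for g in self.generators for t in g.transforms]

    @property
    def chain_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.generators:
            for c in g.chain_ids:
                seen.setdefault(c)
        return tuple(seen)


@dataclasses.dataclass(eq=False)
class StructureModel:
    """A parsed structure (or an expanded biological assembly of one)."""

    pdb_id: str
    chains: list[Chain]
    hetero_residues: list[Residue]
    resolution: float | None = None
    molecule_name: str = ""
    assemblies: list[AssemblyInstruction] = dataclasses.field(default_factory=list)
    assembly_id: str | None = None

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")

    @property
    def backbone_only(self) -> bool:
        """True iff the file carries no side chain beyond CB (C-alpha traces)."""
        protein = [r for c in self.chains for r in c.residues]
        if not protein:
            return False
        return all(
            a.name in _BACKBONE_NAMES for r in protein for a in r.atoms if a.element != "H"
        )

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues
        yield from self.hetero_residues

    def atoms(self) -> Iterator[Atom]:
        for residue in self.residues():
            yield from residue.atoms

    def metal_atoms(self) -> list[Atom]:
        return [a for r in self.hetero_residues for a in r.atoms if a.is_metal]

    def zinc_atoms(self) -> list[Atom]:
        return [a for a in self.metal_atoms() if a.element == "Zn"]

    def chain(self, chain_id: str, copy_index: int = 0) -> Chain:
        for c in self.chains:
            if c.id == chain_id and c.copy_index == copy_index:
                return c
        raise KeyError(f"no chain {chain_id!r} (copy {copy_index}) in {self.pdb_id}")

    def residue_of_atom(self, atom: Atom) -> Residue:
        for residue in self.residues():
            if any(a is atom for a in residue.atoms):
                return residue
        raise KeyError(f"atom {atom.source_id} not found in {self.pdb_id}")


def chain_sequence(chain: Chain) -> str:
    """One character per protein residue in residue order; X for non-standard."""
    return "".join(r.one_letter for r in chain.residues if r.is_protein)


# ---------------------------------------------------------------------------
# parsing


def _validate_fixed_columns(text: str) -> int:
    """Check coordinate records column-wise; return the number of atom lines."""
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n_atoms += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record shorter than 54 columns")
        try:
            int(line[6:11])
        except ValueError:
            raise PDBParseError(f"line {lineno}: bad atom serial {line[6:11]!r}") from None
        try:
            int(line[22:26])
        except ValueError:
            raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from None
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: bad {what} coordinate {line[lo:hi]!r}"
                ) from None
        if len(line) >= 60 and line[54:60].strip():
            try:
                float(line[54:60])
            except ValueError:
                raise PDBParseError(f"line {lineno}: bad occupancy {line[54:60]!r}") from None
    return n_atoms


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; on a tie the alphabetically first altloc ('A')
    return min(atoms, key=lambda a: (-(a.occ if a.occ else 0.0), a.altloc or "~"))


def _molecule_name(text: str) -> str:
    names = []
    for line in text.splitlines():
        if line.startswith("COMPND") and "MOLECULE:" in line:
            value = line.split("MOLECULE:", 1)[1].strip()
            names.append(value.rstrip(";").strip())
    return "; ".join(names)


def _header_pdb_id(text: str) -> str:
    for line in text.splitlines():
        if line.startswith("HEADER") and len(line) >= 66:
            code = line[62:66].strip()
            if code:
                return code
    return ""


def parse_structure(
    pdb_text: str,
    pdb_id: str | None = None,
    assembly_energies: Mapping[str, float] | None = None,
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Parameters
    ----------
    pdb_text:
        The content of a PDB file (must contain at least one ATOM/HETATM).
    pdb_id:
        Accession to record; defaults to the HEADER id code when present.
    assembly_energies:
        Optional map of assembly id -> energy (kcal/mol) to annotate onto
        the parsed assembly instructions.
    """
    n_atoms = _validate_fixed_columns(pdb_text)
    if n_atoms == 0:
        raise EmptyStructureError("no ATOM or HETATM records in input")

    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    model = st[0]  # multi-model files: first model only

    chains: list[Chain] = []
    hetero: list[Residue] = []
    for gchain in model:
        protein_residues: list[Residue] = []
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            rid = (gchain.name, gres.seqid.num, icode)
            label = f"{gres.seqid.num}{icode}"
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(ga.occ, 1.0) if ga.occ is not None else None,
                        altloc=(ga.altloc or "").strip("\x00"),
                        source_id=(gchain.name, label, name),
                    )
                )
            info = gemmi.find_tabulated_residue(gres.name)
            is_water = gres.is_water() or gres.name in _WATER_NAMES
            is_protein = bool(info and info.is_amino_acid()) and not is_water
            residue = Residue(
                id=rid, name=gres.name, atoms=atoms,
                is_water=is_water, is_protein=is_protein,
            )
            if is_protein:
                protein_residues.append(residue)
            else:
                hetero.append(residue)
        if protein_residues:
            protein_residues.sort(key=lambda r: (r.id[1], r.id[2]))
            chains.append(Chain(id=gchain.name, residues=protein_residues))

    assemblies = []
    for gasm in st.assemblies:
        generators = []
        for gen in gasm.generators:
            transforms = []
            for op in gen.operators:
                t = op.transform
                transforms.append(
                    (np.array(t.mat.tolist()), np.array(t.vec.tolist()))
                )
            if transforms:
                generators.append(
                    AssemblyGenerator(chain_ids=tuple(gen.chains), transforms=transforms)
                )
        if generators:
            energy = (assembly_energies or {}).get(gasm.name)
            assemblies.append(
                AssemblyInstruction(id=gasm.name, generators=generators, energy=energy)
            )

    return StructureModel(
        pdb_id=pdb_id or _header_pdb_id(pdb_text) or "XXXX",
        chains=chains,
        hetero_residues=hetero,
        resolution=st.resolution if st.resolution and st.resolution > 0 else None,
        molecule_name=_molecule_name(pdb_text),
        assemblies=assemblies,
    )


# ---------------------------------------------------------------------------
# writing (used by the fixture generator and for round-trip checks)


def _format_atom_line(record: str, serial: int, atom: Atom, residue: Residue) -> str:
    name = atom.name
    if len(name) < 4:
        # single-letter elements are indented one column by PDB convention
        name_field = f"{name:<4}" if len(atom.element) == 2 else f" {name:<3}"
    else:
        name_field = name
    chain_id, number, icode = residue.id
    if len(chain_id) != 1:
        raise ValueError(f"PDB chain id must be one character, got {chain_id!r}")
    occ = atom.occupancy if atom.occupancy is not None else 1.0
    x, y, z = atom.position
    return (
        f"{record:<6}{serial:>5} {name_field}{atom.altloc or ' ':1}"
        f"{residue.name:>3} {chain_id}{number:>4}{icode or ' ':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          "
        f"{atom.element.upper():>2}"
    )


def write_pdb(model: StructureModel) -> str:
    """Serialize a model to PDB-format text (HEADER, REMARKs, coordinates)."""
    lines: list[str] = []
    date = datetime.date(2000, 1, 1).strftime("%d-%b-%y").upper()
    lines.append(f"HEADER    {'METAL BINDING PROTEIN':<40}{date:<9}   {model.pdb_id[:4]:<4}")
    if model.molecule_name:
        lines.append("COMPND    MOL_ID: 1;")
        lines.append(f"COMPND   2 MOLECULE: {model.molecule_name};")
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model.resolution:7.2f} ANGSTROMS.")
    for asm in model.assemblies:
        lines.append(f"REMARK 350 BIOMOLECULE: {asm.id}")
        serial = 0
        for gen in asm.generators:
            lines.append(
                "REMARK 350 APPLY THE FOLLOWING TO CHAINS: " + ", ".join(gen.chain_ids)
            )
            for rot, vec in gen.transforms:
                serial += 1
                for row in range(3):
                    r = rot[row]
                    lines.append(
                        f"REMARK 350   BIOMT{row + 1}{serial:>4}"
                        f"{r[0]:10.6f}{r[1]:10.6f}{r[2]:10.6f}{vec[row]:15.5f}"
                    )
    serial = 0
    for chain in model.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                serial += 1
                lines.append(_format_atom_line("ATOM", serial, atom, residue))
        serial += 1
        last = chain.residues[-1]
        lines.append(
            f"{'TER':<6}{serial:>5}      {last.name:>3} {last.id[0]}{last.id[1]:>4}"
        )
    for residue in model.hetero_residues:
        for atom in residue.atoms:
            serial += 1
            lines.append(_format_atom_line("HETATM", serial, atom, residue))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# biological assembly


def _assembly_contains_zinc(model: StructureModel, asm: AssemblyInstruction) -> bool:
    zinc_chains = {
        r.chain_id for r in model.hetero_residues
        if any(a.element == "Zn" for a in r.atoms)
    }
    return bool(zinc_chains.intersection(asm.chain_ids))


def select_assembly(model: StructureModel) -> AssemblyInstruction | None:
    """Pick the biological assembly to analyse.

    Among assemblies whose expanded content would contain at least one zinc,
    the one with the lowest energy annotation wins; with no annotations the
    first-listed zinc-containing assembly is used.  If no assembly contains
    zinc the first assembly is returned, and ``None`` (meaning: use the
    asymmetric unit) when the file declares no assemblies at all.
    """
    if not model.assemblies:
        return None
    candidates = [a for a in model.assemblies if _assembly_contains_zinc(model, a)]
    if not candidates:
        return model.assemblies[0]
    with_energy = [a for a in candidates if a.energy is not None]
    if with_energy:
        return min(with_energy, key=lambda a: a.energy)
    return candidates[0]


def _transform_residue(residue: Residue, rot: np.ndarray, vec: np.ndarray,
                       copy_index: int) -> Residue:
    atoms = [
        Atom(
            name=a.name,
            element=a.element,
            position=rot @ a.position + vec,
            occupancy=a.occupancy,
            altloc=a.altloc,
            source_id=a.source_id,
            copy_index=copy_index,
        )
        for a in residue.atoms
    ]
    return Residue(
        id=residue.id, name=residue.name, atoms=atoms,
        is_water=residue.is_water, is_protein=residue.is_protein,
        copy_index=copy_index,
    )


def build_assembly(model: StructureModel, instruction: AssemblyInstruction) -> StructureModel:
    """Expand an assembly instruction into a new model.

    Each listed chain (and its hetero residues) is duplicated once per
    transform; ``copy_index`` records which transform produced each copy and
    every atom's ``source_id`` is preserved unchanged.
    """
    known = {c.id for c in model.chains} | {r.chain_id for r in model.hetero_residues}
    for gen in instruction.generators:
        for cid in gen.chain_ids:
            if cid not in known:
                raise KeyError(f"assembly {instruction.id!r} references unknown chain {cid!r}")

    new_chains: list[Chain] = []
    new_hetero: list[Residue] = []
    copy_index = 0
    for gen in instruction.generators:
        targets = set(gen.chain_ids)
        for rot, vec in gen.transforms:
            for chain in model.chains:
                if chain.id in targets:
                    new_chains.append(
                        Chain(
                            id=chain.id,
                            copy_index=copy_index,
                            residues=[
                                _transform_residue(r, rot, vec, copy_index)
                                for r in chain.residues
                            ],
                        )
                    )
            for residue in model.hetero_residues:
                if residue.chain_id in targets:
                    new_hetero.append(_transform_residue(residue, rot, vec, copy_index))
            copy_index += 1

    return StructureModel(
        pdb_id=model.pdb_id,
        chains=new_chains,
        hetero_residues=new_hetero,
        resolution=model.resolution,
        molecule_name=model.molecule_name,
        assemblies=model.assemblies,
        assembly_id=instruction.id,
    )
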
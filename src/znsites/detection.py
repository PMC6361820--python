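"""Zinc binding-site detection.

The pipeline mirrors how a structural biologist separates genuine zinc
binding sites from crystallisation artefacts:

1. analyse the biological assembly, not the asymmetric unit, because zinc
   sites frequently sit at interfaces between chain copies;
2. a metal's liganding atoms are the non-carbon, non-hydrogen atoms within
   3 A (centre to centre) that survive a 45-degree angle filter against
   closer liganding atoms of the same residue (a carboxylate oxygen hiding
   behind its partner is not an independent ligand);
3. metals sharing a liganding residue belong to one (co-active) site;
4. metal copies superposed by a symmetry rotation are collapsed;
5. a zinc with fewer than two protein liganding residues or fewer than
   three protein liganding atoms is presumed to be a salt and excluded;
6. sites duplicated verbatim by assembly expansion are stored once with a
   copy counter.

Every zinc atom of the input file is accounted for: it ends up either in a
binding site or in an :class:`ExclusionRecord` giving the reason it was
left out.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Mapping, Sequence

import numpy as np

from znsites.structure import (
    Atom,
    Residue,
    StructureModel,
    build_assembly,
    select_assembly,
)

__all__ = [
    "DetectionParameters",
    "LigandContact",
    "ExclusionReason",
    "ExclusionRecord",
    "BindingSite",
    "find_liganding_contacts",
    "cluster_metal_centers",
    "remove_symmetry_duplicates",
    "classify_zinc",
    "deduplicate_identical_sites",
    "detect_sites",
]


@dataclasses.dataclass(frozen=True)
class DetectionParameters:
    """Tunable thresholds of the detection rules.

    cutoff:
        Maximum metal-ligand centre-to-centre distance in Angstrom
        (inclusive).
    min_angle:
        Minimum angle in degrees, at the metal vertex, between two liganding
        atoms of the same residue; the farther atom of a pair below this is
        discarded.
    min_protein_residues / min_protein_atoms:
        A zinc below either threshold is classified as a salt.
    duplicate_tolerance:
        Metal copies with the same source atom closer than this are
        symmetry duplicates.
    """

    cutoff: float = 3.0
    min_angle: float = 45.0
    min_protein_residues: int = 2
    min_protein_atoms: int = 3
    duplicate_tolerance: float = 0.5
    metal_elements: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if not 0 <= self.min_angle < 180:
            raise ValueError("min_angle must be in [0, 180)")
        if not self.duplicate_tolerance < self.cutoff:
            raise ValueError("duplicate_tolerance must be below the distance cutoff")

    def is_metal(self, element: str) -> bool:
        if self.metal_elements is not None:
            return element in self.metal_elements
        from znsites.structure import METAL_ELEMENTS

        return element in METAL_ELEMENTS


@dataclasses.dataclass(eq=False)
class LigandContact:
    """One metal-to-atom coordination link."""

    metal: Atom
    atom: Atom
    residue: Residue
    distance: float


class ExclusionReason(enum.Enum):
    """Why a zinc atom was not assigned to a binding site."""

    NOT_IN_ASSEMBLY = "Not in the biological assembly"
    TOO_FEW_RESIDUES = "Too few liganding residues"
    TOO_FEW_ATOMS = "Too few liganding atoms"
    NO_SIDECHAINS = "No side chain information"


@dataclasses.dataclass(eq=False)
class ExclusionRecord:
    zinc: Atom
    reason: ExclusionReason


@dataclasses.dataclass(eq=False)
class BindingSite:
    """A cluster of one or more metals (at least one zinc) plus its ligands.

    ``copies`` counts how many identical symmetry copies of the site the
    biological assembly produced; the site itself is stored once.
    """

    metals: list[Atom]
    contacts: list[LigandContact]
    residues: list[Residue]
    structure: StructureModel
    copies: int = 1

    def __post_init__(self) -> None:
        if not any(m.element == "Zn" for m in self.metals):
            raise ValueError("a binding site must contain at least one zinc")

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_protein]

    @property
    def zincs(self) -> list[Atom]:
        return [m for m in self.metals if m.element == "Zn"]


# Guard for the strict angle comparison: an angle constructed to sit exactly
# on the boundary must not flip sides through float round-off.
_ANGLE_EPS = 1e-9


def _angle_deg(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a - vertex, b - vertex
    cos = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def find_liganding_contacts(
    metal: Atom, model: StructureModel, params: DetectionParameters | None = None
) -> list[LigandContact]:
    """Liganding contacts of one metal, sorted by increasing distance.

    Candidates are the non-carbon, non-hydrogen, non-metal atoms within
    ``params.cutoff`` of the metal.  Within each residue, candidates are
    examined nearest-first and one is discarded when its angle at the metal
    to any closer retained atom of the same residue is below
    ``params.min_angle`` (strictly).
    """
    params = params or DetectionParameters()
    if not any(a is metal for a in model.atoms()):
        raise KeyError(f"metal atom {metal.source_id} is not part of the model")

    by_residue: dict[Residue, list[tuple[float, Atom]]] = {}
    for residue in model.residues():
        for atom in residue.atoms:
            if atom is metal or atom.element in ("C", "H", "D"):
                continue
            if params.is_metal(atom.element):
                continue
            dist = float(np.linalg.norm(atom.position - metal.position))
            if dist <= params.cutoff:
                by_residue.setdefault(residue, []).append((dist, atom))

    contacts: list[LigandContact] = []
    for residue, candidates in by_residue.items():
        candidates.sort(key=lambda pair: pair[0])
        retained: list[tuple[float, Atom]] = []
        for dist, atom in candidates:
            blocked = any(
                _angle_deg(metal.position, atom.position, kept.position)
                < params.min_angle - _ANGLE_EPS
                for _, kept in retained
            )
            if not blocked:
                retained.append((dist, atom))
        contacts.extend(
            LigandContact(metal=metal, atom=a, residue=residue, distance=d)
            for d, a in retained
        )
    contacts.sort(key=lambda c: c.distance)
    return contacts


def cluster_metal_centers(
    metals: Sequence[Atom], contact_map: Mapping[Atom, Sequence[LigandContact]]
) -> list[list[Atom]]:
    """Partition metals: two metals sharing a liganding residue are grouped.

    Sharing is transitive (union-find); a chain A-B, B-C puts A, B and C in
    one group even if A and C share nothing directly.  Groups and their
    members are ordered by source id for determinism.
    """
    parent = {m: m for m in metals}

    def find(m: Atom) -> Atom:
        while parent[m] is not m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    def union(a: Atom, b: Atom) -> None:
        ra, rb = find(a), find(b)
        if ra is not rb:
            parent[rb] = ra

    residue_owner: dict[Residue, Atom] = {}
    for metal in metals:
        for contact in contact_map[metal]:
            other = residue_owner.setdefault(contact.residue, metal)
            if other is not metal:
                union(other, metal)

    groups: dict[Atom, list[Atom]] = {}
    for metal in metals:
        groups.setdefault(find(metal), []).append(metal)
    ordered = [
        sorted(g, key=lambda m: (m.source_id, m.copy_index)) for g in groups.values()
    ]
    ordered.sort(key=lambda g: (g[0].source_id, g[0].copy_index))
    return ordered


def remove_symmetry_duplicates(metals: Sequence[Atom], tolerance: float = 0.5) -> list[Atom]:
    """Drop metal copies superposed by a symmetry rotation.

    Atoms that share a ``source_id`` and lie within ``tolerance`` of an
    already-kept copy are duplicates; the copy with the lowest
    ``copy_index`` survives.  Atoms with distinct sources, or same-source
    copies genuinely moved apart by a transform, are untouched.
    """
    kept_by_source: dict[tuple[str, str, str], list[Atom]] = {}
    kept: list[Atom] = []
    for metal in sorted(metals, key=lambda m: m.copy_index):
        group = kept_by_source.setdefault(metal.source_id, [])
        if any(
            np.linalg.norm(metal.position - other.position) <= tolerance for other in group
        ):
            continue
        group.append(metal)
        kept.append(metal)
    order = {id(m): i for i, m in enumerate(metals)}
    kept.sort(key=lambda m: order[id(m)])
    return kept


def classify_zinc(
    zinc: Atom,
    contacts: Sequence[LigandContact],
    model: StructureModel,
    params: DetectionParameters | None = None,
    *,
    in_assembly: bool = True,
) -> ExclusionRecord | None:
    """Salt filter: ``None`` when the zinc is eligible for a binding site.

    Waters and non-protein hetero ligands never count toward the residue
    and atom thresholds.  Checks are ordered: missing side chains, absence
    from the assembly, then residue count before atom count.
    """
    params = params or DetectionParameters()
    if model.backbone_only:
        return ExclusionRecord(zinc, ExclusionReason.NO_SIDECHAINS)
    if not in_assembly:
        return ExclusionRecord(zinc, ExclusionReason.NOT_IN_ASSEMBLY)
    protein_contacts = [c for c in contacts if c.residue.is_protein]
    n_residues = len({c.residue for c in protein_contacts})
    if n_residues < params.min_protein_residues:
        return ExclusionRecord(zinc, ExclusionReason.TOO_FEW_RESIDUES)
    if len(protein_contacts) < params.min_protein_atoms:
        return ExclusionRecord(zinc, ExclusionReason.TOO_FEW_ATOMS)
    return None


def _site_identity_key(site: BindingSite) -> tuple:
    entries = [("M", m.source_id[0], m.source_id[1], m.element) for m in site.metals]
    entries += [("R", r.chain_id, r.label, r.name) for r in site.residues]
    return tuple(sorted(entries))


def deduplicate_identical_sites(sites: Sequence[BindingSite]) -> list[BindingSite]:
    """Merge sites that are assembly copies of the same source atoms.

    Two sites are identical when the multisets of (source chain id, residue
    id, residue name) of their metals and liganding residues agree, copy
    indices ignored.  One survives with ``copies`` set to the group size.
    """
    groups: dict[tuple, list[BindingSite]] = {}
    for site in sites:
        groups.setdefault(_site_identity_key(site), []).append(site)
    out = []
    for group in groups.values():
        keeper = min(group, key=lambda s: min(m.copy_index for m in s.metals))
        keeper.copies = len(group)
        out.append(keeper)
    order = {id(s): i for i, s in enumerate(sites)}
    out.sort(key=lambda s: order[id(s)])
    return out


def detect_sites(
    model: StructureModel,
    params: DetectionParameters | None = None,
    *,
    use_assembly: bool = True,
) -> tuple[list[BindingSite], list[ExclusionRecord]]:
    """Run the full detection pipeline on one structure.

    Returns the binding sites and the exclusion records; together they
    account for every zinc atom in the file exactly once.

    With ``use_assembly=False`` the asymmetric unit is analysed as-is
    (chiefly useful to demonstrate why assembly expansion matters).
    """
    params = params or DetectionParameters()
    au_zincs = model.zinc_atoms()
    exclusions: list[ExclusionRecord] = []

    if model.backbone_only:
        return [], [
            ExclusionRecord(z, ExclusionReason.NO_SIDECHAINS) for z in au_zincs
        ]

    instruction = select_assembly(model) if use_assembly else None
    if instruction is not None:
        working = build_assembly(model, instruction)
        included = set(instruction.chain_ids)
        for zinc in au_zincs:
            if zinc.source_id[0] not in included:
                exclusions.append(
                    ExclusionRecord(zinc, ExclusionReason.NOT_IN_ASSEMBLY)
                )
    else:
        working = model

    metals = [m for m in working.metal_atoms() if params.is_metal(m.element)]
    metals = remove_symmetry_duplicates(metals, params.duplicate_tolerance)
    contact_map = {m: find_liganding_contacts(m, working, params) for m in metals}
    groups = cluster_metal_centers(metals, contact_map)

    sites: list[BindingSite] = []
    rejected: dict[tuple[str, str, str], ExclusionRecord] = {}
    for group in groups:
        zincs = [m for m in group if m.element == "Zn"]
        if not zincs:
            continue  # metal sites without zinc are out of scope
        verdicts = {z: classify_zinc(z, contact_map[z], model, params) for z in zincs}
        if any(v is None for v in verdicts.values()):
            contacts = sorted(
                (c for m in group for c in contact_map[m]), key=lambda c: c.distance
            )
            residues: list[Residue] = []
            for contact in contacts:
                if contact.residue not in residues:
                    residues.append(contact.residue)
            residues.sort(key=lambda r: (r.chain_id, r.id[1], r.id[2], r.copy_index))
            sites.append(
                BindingSite(
                    metals=group, contacts=contacts, residues=residues, structure=model
                )
            )
        else:
            for zinc, record in verdicts.items():
                rejected.setdefault(zinc.source_id, record)

    sites = deduplicate_identical_sites(sites)

    in_site_sources = {z.source_id for s in sites for z in s.zincs}
    already = {e.zinc.source_id for e in exclusions}
    for source_id, record in rejected.items():
        if source_id not in in_site_sources and source_id not in already:
            exclusions.append(record)

    return sites, exclusions
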
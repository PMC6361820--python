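"""Liganding contacts, metal clustering, salt filtering, deduplication."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from znsites.detection import (
    BindingSite,
    DetectionParameters,
    ExclusionReason,
    LigandContact,
    classify_zinc,
    cluster_metal_centers,
    deduplicate_identical_sites,
    detect_sites,
    find_liganding_contacts,
    remove_symmetry_duplicates,
)
from znsites.fixtures import FixtureSpec, make_angle_probe, make_fixture
from znsites.structure import Atom, Chain, Residue, StructureModel, parse_structure

from conftest import make_site_model, protein_residue, zinc_residue
from oracles import transitive_groups, vector_angle_deg


def _model_with(hetero, chains=()):
    return StructureModel(
        pdb_id="TEST", chains=list(chains), hetero_residues=list(hetero)
    )


def _atom(name, element, pos, chain="A", label="1", copy=0):
    return Atom(name=name, element=element, position=np.asarray(pos, dtype=float),
                source_id=(chain, label, name), copy_index=copy)


class TestLigandingContacts:
    def test_nothing_within_cutoff(self):
        model = make_site_model("T", "SVLS", set())
        zinc = model.zinc_atoms()[0]
        assert find_liganding_contacts(zinc, model) == []

    def test_carbon_is_never_a_ligand(self):
        his = protein_residue(
            "A", 1, "HIS", (-30, 25, 0),
            side_atoms=[("NE2", "N", (2.10, 0, 0)), ("CD2", "C", (2.4, 1.2, 0))],
        )
        model = _model_with([zinc_residue()], [Chain(id="A", residues=[his])])
        contacts = find_liganding_contacts(model.zinc_atoms()[0], model)
        assert [c.atom.name for c in contacts] == ["NE2"]

    @pytest.mark.parametrize("theta,expected", [(30.0, 1), (60.0, 2)])
    def test_angle_filter_on_carboxylate_pair(self, theta, expected):
        probe = make_angle_probe(theta, 2.0, 2.2)
        assert vector_angle_deg(probe["metal"], probe["o1"], probe["o2"]) == pytest.approx(theta)
        asp = protein_residue(
            "A", 1, "ASP", (-30, 25, 0),
            side_atoms=[("OD1", "O", probe["o1"]), ("OD2", "O", probe["o2"])],
        )
        model = _model_with([zinc_residue()], [Chain(id="A", residues=[asp])])
        contacts = find_liganding_contacts(model.zinc_atoms()[0], model)
        assert len(contacts) == expected
        assert contacts[0].atom.name == "OD1"  # the closer oxygen always survives

    def test_contacts_sorted_by_distance(self):
        site = make_site_model("T", "SCSCSHS", {1, 3, 5})
        zinc = site.zinc_atoms()[0]
        distances = [c.distance for c in find_liganding_contacts(zinc, site)]
        assert distances == sorted(distances)

    def test_metal_absent_from_model_is_an_error(self):
        model = make_site_model("T", "SCSC", {1, 3})
        stray = _atom("ZN", "Zn", (50, 50, 50))
        with pytest.raises(KeyError):
            find_liganding_contacts(stray, model)

    def test_metals_never_ligand_each_other(self):
        near = Residue(id=("A", 102, ""), name="NA", atoms=[_atom("NA", "Na", (2.0, 0, 0), label="102")])
        model = _model_with([zinc_residue(), near])
        assert find_liganding_contacts(model.zinc_atoms()[0], model) == []

    @given(st.integers(0, 2**31 - 1))
    def test_dropping_angle_rule_never_removes_contacts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        atoms = [
            ("O%d" % i, "O", rng.normal(size=3) * rng.uniform(0.5, 1.4))
            for i in range(n)
        ]
        res = protein_residue("A", 1, "ASP", (-30, 25, 0), side_atoms=atoms)
        model = _model_with([zinc_residue()], [Chain(id="A", residues=[res])])
        zinc = model.zinc_atoms()[0]
        with_rule = find_liganding_contacts(zinc, model, DetectionParameters())
        without = find_liganding_contacts(zinc, model, DetectionParameters(min_angle=0))
        assert len(with_rule) <= len(without)

    @given(st.integers(0, 2**31 - 1))
    def test_raising_cutoff_never_removes_contacts(self, seed):
        rng = np.random.default_rng(seed)
        atoms = [("O%d" % i, "O", rng.normal(size=3) * 1.8) for i in range(5)]
        res = protein_residue("A", 1, "ASP", (-30, 25, 0), side_atoms=atoms)
        model = _model_with([zinc_residue()], [Chain(id="A", residues=[res])])
        zinc = model.zinc_atoms()[0]
        n_small = len(find_liganding_contacts(zinc, model, DetectionParameters(cutoff=2.2)))
        n_large = len(find_liganding_contacts(zinc, model, DetectionParameters(cutoff=3.0)))
        assert n_small <= n_large


class TestMetalClustering:
    @staticmethod
    def _residue(i):
        return Residue(id=("A", i, ""), name="HIS", atoms=[], is_protein=True)

    def _contact(self, metal, residue):
        return LigandContact(metal=metal, atom=_atom("X", "N", (0, 0, 0)),
                             residue=residue, distance=2.0)

    def test_disjoint_residues_stay_apart(self):
        m1, m2 = _atom("ZN", "Zn", (0, 0, 0)), _atom("ZN", "Zn", (9, 0, 0), label="2")
        r1, r2 = self._residue(1), self._residue(2)
        groups = cluster_metal_centers(
            [m1, m2], {m1: [self._contact(m1, r1)], m2: [self._contact(m2, r2)]}
        )
        assert len(groups) == 2

    def test_shared_histidine_bridges_zinc_and_copper(self):
        zn, cu = _atom("ZN", "Zn", (0, 0, 0)), _atom("CU", "Cu", (4, 0, 0), label="2")
        his = self._residue(1)
        groups = cluster_metal_centers(
            [zn, cu], {zn: [self._contact(zn, his)], cu: [self._contact(cu, his)]}
        )
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_transitive_chain(self):
        a, b, c = (_atom("ZN", "Zn", (i, 0, 0), label=str(i)) for i in range(3))
        r_ab, r_bc = self._residue(1), self._residue(2)
        groups = cluster_metal_centers(
            [a, b, c],
            {a: [self._contact(a, r_ab)],
             b: [self._contact(b, r_ab), self._contact(b, r_bc)],
             c: [self._contact(c, r_bc)]},
        )
        assert len(groups) == 1 and len(groups[0]) == 3

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_transitive_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        n_res = int(rng.integers(1, 9))
        residues = [self._residue(i) for i in range(n_res)]
        metals = [_atom("ZN", "Zn", (i, 0, 0), label=str(i)) for i in range(n)]
        contact_map = {
            m: [self._contact(m, residues[j])
                for j in range(n_res) if rng.random() < 0.25]
            for m in metals
        }
        groups = cluster_metal_centers(metals, contact_map)
        index = {id(m): i for i, m in enumerate(metals)}
        got = sorted(
            (frozenset(index[id(m)] for m in g) for g in groups), key=sorted
        )
        shared = {
            (i, j)
            for i, mi in enumerate(metals)
            for j, mj in enumerate(metals)
            if i < j
            and {c.residue for c in contact_map[mi]} & {c.residue for c in contact_map[mj]}
        }
        assert got == sorted(transitive_groups(n, shared), key=sorted)


class TestSymmetryDuplicates:
    def test_coincident_copies_collapse_to_lowest_copy(self):
        copies = [_atom("ZN", "Zn", (0, 0, 0), copy=k) for k in (2, 0, 1)]
        kept = remove_symmetry_duplicates(copies)
        assert len(kept) == 1 and kept[0].copy_index == 0

    def test_distinct_zincs_survive(self):
        a = _atom("ZN", "Zn", (0, 0, 0), label="1")
        b = _atom("ZN", "Zn", (4, 0, 0), label="2")
        assert remove_symmetry_duplicates([a, b]) == [a, b]

    def test_near_axis_displacement_within_tolerance(self):
        a = _atom("ZN", "Zn", (0, 0, 0), copy=0)
        b = _atom("ZN", "Zn", (0.3, 0, 0), copy=1)
        kept = remove_symmetry_duplicates([a, b], tolerance=0.5)
        assert kept == [a]

    def test_same_source_far_apart_both_kept(self):
        a = _atom("ZN", "Zn", (0, 0, 0), copy=0)
        b = _atom("ZN", "Zn", (40, 0, 0), copy=1)
        assert remove_symmetry_duplicates([a, b]) == [a, b]


class TestSaltClassification:
    @staticmethod
    def _contacts(zinc, residues_atoms):
        contacts = []
        for residue, names in residues_atoms:
            for name in names:
                contacts.append(
                    LigandContact(metal=zinc, atom=_atom(name, "O", (2, 0, 0)),
                                  residue=residue, distance=2.0)
                )
        return contacts

    def test_water_only_is_a_salt(self):
        model = make_site_model("T", "SVL", set())
        zinc = model.zinc_atoms()[0]
        water = Residue(id=("A", 201, ""), name="HOH", atoms=[], is_water=True)
        record = classify_zinc(zinc, self._contacts(zinc, [(water, ["O"])] * 4), model)
        assert record.reason is ExclusionReason.TOO_FEW_RESIDUES

    def test_two_residues_two_atoms_fails_atom_count(self):
        model = make_site_model("T", "SVL", set())
        zinc = model.zinc_atoms()[0]
        h1 = Residue(id=("A", 1, ""), name="HIS", atoms=[], is_protein=True)
        h2 = Residue(id=("A", 2, ""), name="HIS", atoms=[], is_protein=True)
        record = classify_zinc(
            zinc, self._contacts(zinc, [(h1, ["NE2"]), (h2, ["NE2"])]), model
        )
        assert record.reason is ExclusionReason.TOO_FEW_ATOMS

    def test_bidentate_aspartate_plus_histidine_is_eligible(self):
        model = make_site_model("T", "SVL", set())
        zinc = model.zinc_atoms()[0]
        asp = Residue(id=("A", 1, ""), name="ASP", atoms=[], is_protein=True)
        his = Residue(id=("A", 2, ""), name="HIS", atoms=[], is_protein=True)
        verdict = classify_zinc(
            zinc, self._contacts(zinc, [(asp, ["OD1", "OD2"]), (his, ["NE2"])]), model
        )
        assert verdict is None

    def test_raising_atom_threshold_never_rescues(self):
        model = make_site_model("T", "SVL", set())
        zinc = model.zinc_atoms()[0]
        asp = Residue(id=("A", 1, ""), name="ASP", atoms=[], is_protein=True)
        his = Residue(id=("A", 2, ""), name="HIS", atoms=[], is_protein=True)
        contacts = self._contacts(zinc, [(asp, ["OD1", "OD2"]), (his, ["NE2"])])
        for threshold in (3, 4, 5):
            params = DetectionParameters(min_protein_atoms=threshold)
            if classify_zinc(zinc, contacts, model, params) is None:
                assert classify_zinc(zinc, contacts, model,
                                     DetectionParameters(min_protein_atoms=threshold - 1)) is None


class TestIdenticalSiteDedup:
    def test_expanded_copies_merge_with_counter(self):
        text, truth = make_fixture(
            FixtureSpec("DUPLICATED_ASU", seed=5, params={"n_copies": 2, "expand": True})
        )
        sites, exclusions = detect_sites(parse_structure(text))
        assert len(sites) == 1 and not exclusions
        assert sites[0].copies == 2

    def test_three_identical_one_distinct(self):
        def site(chain, copy):
            zinc = _atom("ZN", "Zn", (0, 0, 0), chain=chain, label="101", copy=copy)
            res = Residue(id=(chain, 1, ""), name="CYS", atoms=[], is_protein=True,
                          copy_index=copy)
            contact = LigandContact(metal=zinc, atom=_atom("SG", "S", (2, 0, 0), chain=chain),
                                    residue=res, distance=2.3)
            return BindingSite(metals=[zinc], contacts=[contact], residues=[res],
                               structure=_model_with([]))

        sites = [site("A", 0), site("A", 1), site("A", 2), site("B", 0)]
        out = deduplicate_identical_sites(sites)
        assert sorted(s.copies for s in out) == [1, 3]

    def test_distinct_source_chains_stay_apart(self):
        text, _ = make_fixture(FixtureSpec("DUPLICATED_ASU", seed=5, params={"n_copies": 2}))
        sites, _ = detect_sites(parse_structure(text), use_assembly=False)
        assert len(sites) == 2
        assert all(s.copies == 1 for s in sites)


class TestDetectPipeline:
    def test_salt_fixture(self):
        text, _ = make_fixture(FixtureSpec("SALT", seed=0))
        sites, exclusions = detect_sites(parse_structure(text))
        assert sites == []
        assert [e.reason for e in exclusions] == [ExclusionReason.TOO_FEW_RESIDUES]

    def test_c4_fixture(self):
        from znsites.analytics import residue_signature

        text, _ = make_fixture(FixtureSpec("C4_SITE", seed=0))
        sites, exclusions = detect_sites(parse_structure(text))
        assert len(sites) == 1 and not exclusions
        assert residue_signature(sites[0]) == "C4"

    def test_interface_requires_assembly(self):
        text, _ = make_fixture(FixtureSpec("INTERFACE", seed=0, params={"n_transforms": 3}))
        model = parse_structure(text)
        asu_sites, asu_excl = detect_sites(model, use_assembly=False)
        assert asu_sites == [] and asu_excl[0].reason is ExclusionReason.TOO_FEW_RESIDUES
        sites, exclusions = detect_sites(model)
        assert len(sites) == 1 and not exclusions
        assert len(sites[0].protein_residues) == 3

    @pytest.mark.parametrize(
        "scenario,params",
        [
            ("SALT", {}),
            ("C4_SITE", {}),
            ("BIDENTATE", {}),
            ("INTERFACE", {"n_transforms": 3}),
            ("COACTIVE", {"elements": ("Zn", "Zn")}),
            ("DUPLICATED_ASU", {"n_copies": 4}),
            ("BACKBONE_ONLY", {}),
        ],
    )
    @pytest.mark.parametrize("seed", [0, 11, 23])
    def test_every_zinc_is_accounted_for(self, scenario, params, seed):
        """#zinc sources in sites + #exclusions = #zinc atoms in the file."""
        text, _ = make_fixture(FixtureSpec(scenario, seed=seed, params=params))
        model = parse_structure(text)
        sites, exclusions = detect_sites(model)
        in_sites = {z.source_id for s in sites for z in s.zincs}
        excluded = {e.zinc.source_id for e in exclusions}
        assert not in_sites & excluded
        assert len(in_sites) + len(excluded) == len(model.zinc_atoms())

    def test_invariant_under_chain_relabeling(self):
        text, _ = make_fixture(FixtureSpec("DUPLICATED_ASU", seed=2, params={"n_copies": 3}))
        # consistent renaming A->X, B->Y, C->Z in the fixed chain-id column
        relabeled = "".join(
            line[:21] + {"A": "X", "B": "Y", "C": "Z"}.get(line[21], line[21]) + line[22:]
            if line.startswith(("ATOM", "HETATM", "TER")) else
            line.replace("CHAINS: A", "CHAINS: X")
            for line in text.splitlines(keepends=True)
        )
        s1, e1 = detect_sites(parse_structure(text))
        s2, e2 = detect_sites(parse_structure(relabeled))
        assert len(s1) == len(s2)
        assert sorted((e.reason for e in e1), key=lambda r: r.name) == sorted(
            (e.reason for e in e2), key=lambda r: r.name
        )
        assert sorted(len(s.contacts) for s in s1) == sorted(len(s.contacts) for s in s2)
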
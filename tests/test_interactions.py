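"""Hydropathy classes, charge groups, rings, pi labels and hydrogen bonds."""

import numpy as np
import pytest

from molcontact import (
    contact_list,
    contact_map,
    detect_hbonds,
    distance_matrix,
    electrostatic_label,
    filter_contacts,
    find_charge_groups,
    find_rings,
    hydropathy_class,
    hydropathy_pair_label,
    label_contacts,
    make_fixture,
    parse_pdb,
    pi_labels,
)
from molcontact.config import DEFAULT_THRESHOLDS
from molcontact.contacts import Contact
from molcontact.interactions import (
    ACCEPTORS,
    AMPHIPATHIC,
    DONORS,
    HYDROPHILIC,
    HYDROPHOBIC,
)

from conftest import make_chain, make_residue, random_rotation


class TestHydropathy:
    def test_three_classes_partition_the_twenty_amino_acids(self):
        assert len(HYDROPHOBIC) == 7
        assert len(AMPHIPATHIC) == 4
        assert len(HYDROPHILIC) == 9
        assert not (HYDROPHOBIC & AMPHIPATHIC)
        assert not (HYDROPHOBIC & HYDROPHILIC)
        assert not (AMPHIPATHIC & HYDROPHILIC)
        assert len(HYDROPHOBIC | AMPHIPATHIC | HYDROPHILIC) == 20

    @pytest.mark.parametrize("name, cls", [
        ("GLY", "hydrophobic"), ("LYS", "amphipathic"), ("CYS", "hydrophilic"),
        ("PHE", "hydrophobic"), ("TRP", "amphipathic"), ("HIS", "hydrophilic"),
    ])
    def test_class_assignments(self, name, cls):
        assert hydropathy_class(name) == cls

    def test_nucleotides_are_not_classifiable(self):
        assert hydropathy_class("DA") is None
        assert hydropathy_class("HOH") is None

    @pytest.mark.parametrize("a, b, label", [
        ("LEU", "VAL", "hydrophobic"),
        ("ASP", "ARG", "hydrophilic"),
        ("TRP", "TYR", "amphipathic"),
        ("LEU", "ASP", "mixed-hydropathy"),
        ("LYS", "PHE", "mixed-hydropathy"),
    ])
    def test_pair_labels(self, a, b, label):
        ra = make_residue(a, seq=1, atoms={"CA": (0, 0, 0)})
        rb = make_residue(b, seq=2, atoms={"CA": (3, 0, 0)})
        c = Contact(ra, rb, 3.0, ("CA", "CA"))
        assert hydropathy_pair_label(c) == label

    def test_no_label_for_nucleic_partner(self):
        ra = make_residue("LEU", seq=1, atoms={"CA": (0, 0, 0)})
        rb = make_residue("DA", seq=2, atoms={"C1'": (3, 0, 0)})
        assert hydropathy_pair_label(Contact(ra, rb, 3.0, ("CA", "C1'"))) is None


class TestChargeGroups:
    def test_arginine_hosts_one_cation_at_guanidinium_centroid(self):
        r = make_residue("ARG", atoms={
            "CZ": (4.06, 0, 0), "NH1": (3.43, 1.08, 0), "NH2": (3.43, -1.08, 0),
            "NE": (5.39, 0, 0), "CA": (9, 2, 0),
        })
        groups = find_charge_groups(r)
        assert [g.kind for g in groups] == ["cation"]
        np.testing.assert_allclose(groups[0].point, [4.0775, 0, 0], atol=1e-6)

    def test_nucleotide_hosts_phosphate_anion_and_base_dipole(self):
        r = make_residue("DG", atoms={
            "P": (0, 0, 0), "OP1": (1.3, 0.6, 0), "OP2": (-0.7, 1.2, 0),
            "N1": (5, 0, 0), "N2": (6, 1, 0), "O6": (5, 2, 0),
            "N3": (6, -1, 0), "N7": (7, 0, 0),
        })
        kinds = sorted(g.kind for g in find_charge_groups(r))
        assert kinds == ["anion", "dipole"]

    def test_alanine_hosts_nothing(self):
        r = make_residue("ALA", atoms={"CA": (0, 0, 0), "CB": (1.5, 0, 0)})
        assert find_charge_groups(r) == []


class TestElectrostaticLabel:
    def _groups(self, name, atoms):
        return find_charge_groups(make_residue(name, atoms=atoms))

    def test_precedence_ion_ion_over_dipole(self):
        arg = self._groups("ARG", {"CZ": (0, 0, 0), "NH1": (0.6, 1, 0), "NH2": (0.6, -1, 0), "NE": (-1.3, 0, 0)})
        asp = self._groups("ASP", {"CG": (3.5, 0, 0), "OD1": (4.1, 1, 0), "OD2": (4.1, -1, 0)})
        label, dist = electrostatic_label(arg, asp)
        assert label == "ion-ion"
        assert dist == pytest.approx(3.7, abs=0.5)

    def test_ion_dipole_and_dipole_dipole(self):
        arg = self._groups("ARG", {"CZ": (0, 0, 0), "NH1": (0.6, 1, 0), "NH2": (0.6, -1, 0), "NE": (-1.3, 0, 0)})
        ser = self._groups("SER", {"OG": (3.0, 0, 0)})
        thr = self._groups("THR", {"OG1": (6.0, 0, 0)})
        assert electrostatic_label(arg, ser)[0] == "ion-dipole"
        assert electrostatic_label(ser, thr)[0] == "dipole-dipole"

    def test_too_distant_groups_give_no_label(self):
        ser = self._groups("SER", {"OG": (0, 0, 0)})
        thr = self._groups("THR", {"OG1": (9.0, 0, 0)})
        assert electrostatic_label(ser, thr) == (None, None)

    def test_invariant_under_group_order_permutation(self):
        asp = self._groups("ASP", {"CG": (0, 0, 0), "OD1": (0.6, 1, 0), "OD2": (0.6, -1, 0)})
        arg = self._groups("ARG", {"CZ": (3.5, 0, 0), "NH1": (4.1, 1, 0), "NH2": (4.1, -1, 0), "NE": (4.8, 0, 0)})
        lys = self._groups("LYS", {"NZ": (2.5, 1.5, 0)})
        cats = arg + lys
        assert electrostatic_label(asp, cats) == electrostatic_label(asp, cats[::-1])


class TestRings:
    def _hexagon(self, rot=None, center=(0, 0, 0)):
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        atoms = {}
        for k, n in enumerate(names):
            a = np.radians(60 * k)
            p = np.array([1.39 * np.cos(a), 1.39 * np.sin(a), 0.0])
            if rot is not None:
                p = rot @ p
            atoms[n] = tuple(np.asarray(center) + p)
        return make_residue("PHE", atoms=atoms)

    def test_planar_hexagon_centroid_and_normal(self):
        rings = find_rings(self._hexagon(center=(2, 1, -3)))
        assert len(rings) == 1
        np.testing.assert_allclose(rings[0].centroid, [2, 1, -3], atol=1e-9)
        assert abs(abs(rings[0].normal[2]) - 1.0) < 1e-9

    def test_normal_rotates_with_the_ring(self):
        R = random_rotation(42)
        fitted_then_rotated = R @ find_rings(self._hexagon())[0].normal
        rotated_then_fitted = find_rings(self._hexagon(rot=R))[0].normal
        # normals are defined up to sign
        dot = abs(np.dot(fitted_then_rotated, rotated_then_fitted))
        assert dot == pytest.approx(1.0, abs=1e-9)

    def test_no_ring_for_alanine(self):
        assert find_rings(make_residue("ALA", atoms={"CA": (0, 0, 0)})) == []

    def test_ring_missing_two_atoms_is_skipped_with_warning(self):
        r = self._hexagon()
        r.atoms = r.atoms[:-2]
        warnings = []
        assert find_rings(r, warn=warnings) == []
        assert warnings

    def test_tryptophan_and_purines_have_two_rings(self):
        trp_atoms = {n: (i * 1.0, (i % 3) * 0.9, 0.0) for i, n in enumerate(
            ["CG", "CD1", "NE1", "CE2", "CD2", "CZ2", "CH2", "CZ3", "CE3"])}
        assert len(find_rings(make_residue("TRP", atoms=trp_atoms))) == 2
        pur_atoms = {n: (i * 1.0, (i % 3) * 0.9, 0.0) for i, n in enumerate(
            ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"])}
        assert len(find_rings(make_residue("DA", atoms=pur_atoms))) == 2


class TestPiLabels:
    def test_parallel_stack_is_pipi(self):
        st = parse_pdb(make_fixture("aromatic_stack", orientation="parallel"))
        a, b = st.model()
        labels, geom = pi_labels(find_rings(a.residues[0]), find_rings(b.residues[0]), [], [])
        assert labels == {"pi-pi"}
        assert geom["pipi_dist"] == pytest.approx(3.8, abs=1e-3)
        assert geom["pipi_angle"] == pytest.approx(0.0, abs=0.5)

    def test_tshaped_stack_is_pipi(self):
        st = parse_pdb(make_fixture("aromatic_stack", orientation="tshaped"))
        a, b = st.model()
        labels, geom = pi_labels(find_rings(a.residues[0]), find_rings(b.residues[0]), [], [])
        assert labels == {"pi-pi"}
        assert geom["pipi_angle"] == pytest.approx(90.0, abs=0.5)

    def test_axial_cation_is_cation_pi_and_inplane_is_not(self):
        for axial, expected in ((True, {"cation-pi"}), (False, set())):
            st = parse_pdb(make_fixture("cation_pi", axial=axial))
            phe = st.chain("A").residues[0]
            lys = st.chain("B").residues[0]
            labels, _ = pi_labels(find_rings(phe), [],
                                  [], find_charge_groups(lys))
            assert labels == expected

    def test_labels_survive_rigid_motion(self):
        st = parse_pdb(make_fixture("cation_pi", axial=True))
        phe, lys = st.chain("A").residues[0], st.chain("B").residues[0]
        R, t = random_rotation(7), np.array([4.0, -9.0, 2.5])
        for r in (phe, lys):
            for a in r.atoms:
                a.coords = R @ a.coords + t
        labels, _ = pi_labels(find_rings(phe), [], [], find_charge_groups(lys))
        assert labels == {"cation-pi"}


class TestHBonds:
    def _nh_o(self, d, angle_deg=180.0, with_h=True):
        # donor N at origin with H along +x; acceptor O at distance d
        h = np.array([1.0, 0.0, 0.0])
        ang = np.radians(180.0 - angle_deg)
        o = h + (d - 1.0) * np.array([np.cos(ang), np.sin(ang), 0.0])
        don_atoms = {"N": (0, 0, 0), "CA": (-1.4, 0.4, 0)}
        if with_h:
            don_atoms["H"] = tuple(h)
        don = make_residue("GLY", seq=1, atoms=don_atoms, element_map={"H": "H"})
        acc = make_residue("GLY", chain_id="B", seq=2,
                           atoms={"O": tuple(o), "C": tuple(o + np.array([0.8, 1.0, 0]))})
        return don, acc

    def test_good_geometry_detected(self):
        don, acc = self._nh_o(2.9, 180.0)
        hbs = detect_hbonds([don], [acc])
        assert len(hbs) == 1
        assert hbs[0].distance == pytest.approx(2.9, abs=1e-6)
        assert hbs[0].angle == pytest.approx(180.0, abs=1e-3)

    def test_long_distance_rejected(self):
        don, acc = self._nh_o(3.6, 180.0)
        assert detect_hbonds([don], [acc]) == []

    def test_bent_angle_rejected_when_hydrogen_present(self):
        don, acc = self._nh_o(3.2, 90.0)
        assert detect_hbonds([don], [acc]) == []

    def test_distance_only_criterion_without_hydrogens(self):
        don, acc = self._nh_o(3.2, 90.0, with_h=False)
        assert len(detect_hbonds([don], [acc])) == 1

    def test_helix_without_hydrogens_matches_bruteforce_scan(self):
        st = parse_pdb(make_fixture("helix", n=8))
        residues = st.model()[0].residues
        got = {(h.donor_res, h.donor_atom, h.acceptor_res, h.acceptor_atom)
               for h in detect_hbonds(residues)}
        expected = set()
        for rd in residues:
            for dn in DONORS(rd):
                for ra in residues:
                    if ra.id == rd.id:
                        continue
                    for an in ACCEPTORS(ra):
                        d = np.linalg.norm(rd.atom(dn).coords - ra.atom(an).coords)
                        if 0.5 <= d <= 3.5:
                            expected.add((rd.id, dn, ra.id, an))
        assert got == expected
        assert expected  # the ideal helix does form i->i+4 bonds

    def test_symmetric_under_argument_swap(self):
        st = parse_pdb(make_fixture("salt_bridge"))
        a, b = st.model()
        ab = detect_hbonds(a.residues, b.residues)
        ba = detect_hbonds(b.residues, a.residues)
        assert {(h.donor_res, h.donor_atom, h.acceptor_res, h.acceptor_atom) for h in ab} \
            == {(h.donor_res, h.donor_atom, h.acceptor_res, h.acceptor_atom) for h in ba}


class TestLabelContacts:
    def _contacts(self, fixture_kind, cutoff=5.0, **kw):
        st = parse_pdb(make_fixture(fixture_kind, **kw))
        chains = st.model()
        out = []
        for i, a in enumerate(chains):
            for b in chains[i + 1:]:
                out += contact_list(contact_map(distance_matrix(a, b), cutoff))
        return label_contacts(out, chains)

    def test_salt_bridge_is_multivalent(self):
        contacts = self._contacts("salt_bridge")
        assert len(contacts) == 1
        assert {"ion-ion", "hbond"} <= contacts[0].labels

    def test_apolar_pair_gets_only_hydrophobic(self):
        leu = make_residue("LEU", chain_id="A", atoms={
            "CA": (0, 0, 0), "CB": (1.5, 0, 0), "CG": (2.3, 1.2, 0),
            "CD1": (3.8, 1.2, 0), "CD2": (2.0, 2.5, 0.5),
        })
        val = make_residue("VAL", chain_id="B", atoms={
            "CA": (7.5, 1.2, 0), "CB": (6.3, 2.0, 0), "CG1": (5.2, 1.2, 0),
            "CG2": (6.6, 3.4, 0.4),
        })
        a, b = make_chain([leu], "A"), make_chain([val], "B")
        contacts = contact_list(contact_map(distance_matrix(a, b), 5.0))
        labeled = label_contacts(contacts, [a, b])
        assert len(labeled) == 1
        assert labeled[0].labels == {"hydrophobic"}

    def test_filter_returns_subset(self):
        contacts = self._contacts("salt_bridge")
        for label in ("ion-ion", "hbond", "pi-pi"):
            sub = filter_contacts(contacts, label)
            assert set(id(c) for c in sub) <= set(id(c) for c in contacts)
        assert filter_contacts(contacts, "pi-pi") == []

    def test_every_contact_is_covered_by_label_union(self):
        st = parse_pdb(make_fixture("ring_assembly", k=5))
        chains = st.model()
        contacts = []
        for i, a in enumerate(chains):
            for b in chains[i + 1:]:
                contacts += contact_list(contact_map(distance_matrix(a, b), 5.0))
        labeled = label_contacts(contacts, chains)
        all_labels = set().union(*(c.labels for c in labeled)) if labeled else set()
        covered = [c for c in labeled if not c.labels] + \
                  [c for L in all_labels for c in filter_contacts(labeled, L)]
        assert {id(c) for c in covered} == {id(c) for c in labeled}
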
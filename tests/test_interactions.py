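import numpy as np
import pytest

from ddgscan._geometry import rotation_about_axis
from ddgscan.interactions import (InteractionError, detect_interactions,
                                  diff_networks, find_interface_residues,
                                  find_ligand_binding_residues)
from ddgscan.mutant import _template, build_mutant
from ddgscan.structure import (Atom, Residue, SiteSelection, StructureModel,
                               assign_pharmacophores)


def residue_from_template(aa3, chain, seq_num, rotation=np.eye(3), translation=(0, 0, 0)):
    names, coords, _ = _template(aa3)
    atoms = [Atom(str(n), "S" if str(n).startswith("S") else str(n)[0],
                  c @ rotation.T + np.asarray(translation, dtype=float))
             for n, c in zip(names, coords)]
    return Residue(chain, seq_num, "", aa3, atoms)


def ring_frame(res):
    from ddgscan._geometry import fit_plane
    names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    pts = np.array([res.atom(n).coords for n in names])
    return fit_plane(pts)


def two_phe_structure(separation=3.8, tilt_deg=0.0, lateral_offset=0.0):
    """Two Phe residues whose rings form a controlled geometry."""
    res_a = residue_from_template("PHE", "A", 1)
    centroid, normal = ring_frame(res_a)
    res_b = residue_from_template("PHE", "A", 50)
    cen_b, norm_b = ring_frame(res_b)
    # align ring B normal with ring A, then tilt and offset as requested
    cross = np.cross(norm_b, normal)
    dot = float(np.dot(norm_b, normal))
    if np.linalg.norm(cross) > 1e-9:
        rot = rotation_about_axis(cross, float(np.degrees(np.arctan2(np.linalg.norm(cross), dot))))
    else:
        rot = np.eye(3)
    for a in res_b.atoms:
        a.coords = (a.coords - cen_b) @ rot.T + cen_b
    if tilt_deg:
        in_plane = np.cross(normal, [0.17, 0.8, 0.57])
        in_plane /= np.linalg.norm(in_plane)
        tilt = rotation_about_axis(in_plane, tilt_deg)
        cen_b2, _ = ring_frame(res_b)
        for a in res_b.atoms:
            a.coords = (a.coords - cen_b2) @ tilt.T + cen_b2
    lateral = np.cross(normal, [0.0, 0.0, 1.0])
    if np.linalg.norm(lateral) < 1e-6:
        lateral = np.array([1.0, 0.0, 0.0])
    lateral /= np.linalg.norm(lateral)
    cen_b3, _ = ring_frame(res_b)
    target = centroid + separation * normal + lateral_offset * lateral
    shift = target - cen_b3
    for a in res_b.atoms:
        a.coords = a.coords + shift
    model = StructureModel(chains={"A": [res_a, res_b]})
    return assign_pharmacophores(model)


class TestRingGeometryClasses:
    def test_parallel_stack_is_ff_parallel(self):
        net = detect_interactions(two_phe_structure(3.8, 0.0, 0.5))
        rr = [r for r in net.records if r.itype == "ring_ring"]
        assert len(rr) == 1
        assert rr[0].subtype == "FF_parallel"
        assert rr[0].distance == pytest.approx(np.hypot(3.8, 0.5), abs=0.05)

    def test_parallel_displaced_is_offset(self):
        net = detect_interactions(two_phe_structure(3.6, 5.0, 2.5))
        rr = [r for r in net.records if r.itype == "ring_ring"]
        assert rr and rr[0].subtype == "OF_offset"

    def test_tilted_ring_is_edge_tilted(self):
        net = detect_interactions(two_phe_structure(4.6, 45.0, 0.0))
        rr = [r for r in net.records if r.itype == "ring_ring"]
        assert rr and rr[0].subtype == "ET_edge_tilted"

    def test_perpendicular_face_approach_is_edge_face(self):
        net = detect_interactions(two_phe_structure(5.0, 90.0, 0.0))
        rr = [r for r in net.records if r.itype == "ring_ring"]
        assert rr and rr[0].subtype == "EF_edge_face"

    def test_distant_rings_are_silent(self):
        net = detect_interactions(two_phe_structure(8.0, 0.0, 0.0))
        assert not [r for r in net.records if r.itype == "ring_ring"]


class TestPairTyping:
    def test_ser_hydroxyl_to_backbone_oxygen_is_hydrogen_bond(self):
        ser = residue_from_template("SER", "A", 1)
        og = ser.atom("OG")
        cb = ser.atom("CB")
        direction = og.coords - cb.coords
        direction /= np.linalg.norm(direction)
        gly = residue_from_template("GLY", "A", 30,
                                    translation=og.coords + 25.0 * direction)
        shift = (og.coords + 2.9 * direction) - gly.atom("O").coords
        for a in gly.atoms:
            a.coords = a.coords + shift
        model = assign_pharmacophores(StructureModel(chains={"A": [ser, gly]}))
        recs = detect_interactions(model).by_pair(ser.rid, gly.rid)
        hb = [r for r in recs if r.itype == "hydrogen_bond"]
        assert len(hb) == 1
        assert hb[0].distance == pytest.approx(2.9, abs=1e-6)

    def test_zinc_bridging_two_histidines_gives_two_coordination_records(self):
        his1 = residue_from_template("HIS", "A", 1)
        ne2 = his1.atom("NE2").coords
        cd2 = his1.atom("CD2").coords
        out = ne2 - cd2
        out /= np.linalg.norm(out)
        zn_pos = ne2 + 2.2 * out
        # second histidine: the first one rotated 180 deg about an axis
        # through the zinc, so its NE2 also sits 2.2 A away on the far side
        perp = np.cross(out, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.array([1.0, 0.0, 0.0])
        flip = rotation_about_axis(perp, 180.0)
        his2 = residue_from_template("HIS", "A", 40)
        for a, src in zip(his2.atoms, his1.atoms):
            a.coords = (src.coords - zn_pos) @ flip.T + zn_pos
        zn = Residue("M", 900, "", "ZN", [Atom("ZN", "ZN", zn_pos)], is_het=True)
        model = assign_pharmacophores(
            StructureModel(chains={"A": [his1, his2]}, metals=[zn]))
        mc = [r for r in detect_interactions(model).records
              if r.itype == "metal_coordination"]
        assert len(mc) == 2
        partners = {r.res_a if r.res_b == zn.rid else r.res_b for r in mc}
        assert partners == {his1.rid, his2.rid}

    def test_everything_beyond_all_cutoffs_is_silent(self):
        res_a = residue_from_template("LEU", "A", 1)
        res_b = residue_from_template("LEU", "A", 30, translation=(30, 0, 0))
        model = assign_pharmacophores(StructureModel(chains={"A": [res_a, res_b]}))
        assert len(detect_interactions(model)) == 0

    def test_no_atom_pair_carries_two_types(self, dimer):
        model, _, _ = dimer
        seen = {}
        for rec in detect_interactions(model).records:
            if len(rec.atoms_a) == 1 and len(rec.atoms_b) == 1:
                key = frozenset([(rec.res_a, rec.atoms_a[0]),
                                 (rec.res_b, rec.atoms_b[0])])
                assert key not in seen, (seen[key], rec.itype)
                seen[key] = rec.itype

    def test_rigid_body_motion_changes_no_record(self, dimer):
        import copy
        model, _, _ = dimer
        before = {r.signature() for r in detect_interactions(model).records}
        moved = copy.deepcopy(model)
        rot = rotation_about_axis(np.array([1.0, 2.0, 3.0]), 37.0)
        shift = np.array([5.0, -3.0, 11.0])
        for res in moved.all_residues():
            for a in res.atoms:
                a.coords = a.coords @ rot.T + shift
        after = {r.signature() for r in detect_interactions(moved).records}
        assert before == after


class TestResidueSetDetection:
    def test_engineered_pocket_residues_recovered(self, pocket):
        model, truth = pocket
        found = find_ligand_binding_residues(model, "LIG")
        assert list(found.ids) == list(truth.ids)

    def test_displaced_ligand_yields_empty_selection(self, pocket):
        import copy
        model, _ = pocket
        moved = copy.deepcopy(model)
        for a in moved.ligands[0].atoms:
            a.coords = a.coords + np.array([50.0, 0, 0])
        assert len(find_ligand_binding_residues(moved, "LIG")) == 0

    def test_binding_selection_monotone_in_cutoff(self, pocket):
        model, _ = pocket
        tight = set(find_ligand_binding_residues(model, "LIG", contact_cutoff=4.5).ids)
        loose = set(find_ligand_binding_residues(model, "LIG", contact_cutoff=5.5).ids)
        assert tight <= loose

    def test_unknown_ligand_raises(self, pocket):
        with pytest.raises(InteractionError):
            find_ligand_binding_residues(pocket[0], "XYZ")

    def test_engineered_interface_recovered_exactly(self, dimer):
        model, truth_a, truth_b = dimer
        sel_a, sel_b = find_interface_residues(model, "A", "B", cutoff=5.0)
        assert list(sel_a.ids) == list(truth_a.ids)
        assert list(sel_b.ids) == list(truth_b.ids)

    def test_separated_chains_have_empty_interface(self, dimer):
        import copy
        model, _, _ = dimer
        moved = copy.deepcopy(model)
        for res in moved.chains["B"]:
            for a in res.atoms:
                a.coords = a.coords + np.array([50.0, 0.0, 0.0])
        sel_a, sel_b = find_interface_residues(moved, "A", "B", cutoff=5.0)
        assert len(sel_a) == 0 and len(sel_b) == 0

    def test_interface_monotone_in_cutoff(self, dimer):
        model, _, _ = dimer
        tight_a, tight_b = find_interface_residues(model, "A", "B", cutoff=5.0)
        loose_a, loose_b = find_interface_residues(model, "A", "B", cutoff=6.0)
        assert set(tight_a.ids) <= set(loose_a.ids)
        assert set(tight_b.ids) <= set(loose_b.ids)

    def test_identical_chain_ids_raise(self, dimer):
        with pytest.raises(InteractionError):
            find_interface_residues(dimer[0], "A", "A")


class TestNetworkDiff:
    def test_identical_structures_retain_everything(self, pocket):
        model, truth = pocket
        site = truth.ids[0]
        focus = SiteSelection([site])
        net1 = detect_interactions(model, focus=focus)
        net2 = detect_interactions(model, focus=focus)
        diff = diff_networks(net1, net2, site)
        assert diff.lost == [] and diff.gained == []
        assert len(diff.retained) == len(net1.touching(site))

    def test_truncation_to_glycine_loses_sidechain_contacts(self, pocket):
        model, truth = pocket
        site = truth.ids[0]  # the engineered Ser H-bond donor
        mut = build_mutant(model, site, "G")
        focus = SiteSelection([site])
        wt_net = detect_interactions(model, focus=focus)
        mut_net = detect_interactions(mut.structure, focus=focus)
        diff = diff_networks(wt_net, mut_net, site)
        lost_types = {r.itype for r in diff.lost}
        assert "hydrogen_bond" in lost_types

    def test_structures_differing_outside_site_raise(self, pocket):
        import copy
        model, truth = pocket
        site = truth.ids[0]
        other = copy.deepcopy(model)
        stray = other.chains[site[0]][-1].atoms[0]
        stray.coords = stray.coords + 0.5
        focus = SiteSelection([site])
        with pytest.raises(InteractionError):
            diff_networks(detect_interactions(model, focus=focus),
                          detect_interactions(other, focus=focus), site)

    def test_focus_on_absent_residue_raises(self, pocket):
        with pytest.raises(ValueError):
            detect_interactions(pocket[0], focus=SiteSelection([("A", 999, "")]))
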
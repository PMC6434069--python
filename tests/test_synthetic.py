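import numpy as np
import pytest

from ddgscan.stability import _backbone_dihedrals
from ddgscan.structure import read_structure
from ddgscan.synthetic import (FamilySpec, HelixSpec, SyntheticError,
                               make_dimer, make_esst_family, make_families,
                               make_helix, make_ligand_template,
                               make_mutation_table, make_paralog_pair,
                               make_pocket, random_structure,
                               write_fixture_files)


class TestHelixGeometry:
    def test_dihedrals_match_the_spec(self):
        h = make_helix(HelixSpec("AAAAAAAAAAAA"))
        for res in h.chains["A"][1:-1]:
            phi, psi = _backbone_dihedrals(h, res)
            assert phi == pytest.approx(-57.0, abs=1.0)
            assert psi == pytest.approx(-47.0, abs=1.0)

    def test_consecutive_ca_distance_is_ideal(self):
        h = make_helix(HelixSpec("AAAAAAAA"))
        ca = np.array([r.atom("CA").coords for r in h.chains["A"]])
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.allclose(steps, 3.8, atol=0.05)

    def test_helical_hydrogen_bond_geometry(self):
        h = make_helix(HelixSpec("AAAAAAAAAAAA"))
        residues = h.chains["A"]
        for i in range(len(residues) - 4):
            d = np.linalg.norm(residues[i].atom("O").coords
                               - residues[i + 4].atom("N").coords)
            assert d <= 3.5

    def test_empty_or_nonstandard_sequence_rejected(self):
        with pytest.raises(SyntheticError):
            HelixSpec("")
        with pytest.raises(SyntheticError):
            HelixSpec("AXB")


class TestDimer:
    def test_ground_truth_matches_engineering(self, dimer):
        model, sel_a, sel_b = dimer
        assert [rid[1] for rid in sel_a.ids] == [6, 12, 18]
        assert [rid[1] for rid in sel_b.ids] == [6, 12, 18]

    def test_engineered_stack_is_parallel_ring_pair(self, dimer):
        from ddgscan.interactions import detect_interactions
        model, _, _ = dimer
        rr = [r for r in detect_interactions(model).records
              if r.itype == "ring_ring"]
        assert len(rr) == 1
        assert rr[0].subtype == "FF_parallel"

    def test_distant_helices_have_no_interface(self):
        seq = "G" * 12
        model, sel_a, sel_b = make_dimer(
            HelixSpec(seq, chain_id="A"), HelixSpec(seq, chain_id="B"),
            interaxial_distance=50.0, contacts=[])
        assert len(sel_a) == 0 and len(sel_b) == 0

    def test_wrong_residue_type_at_contact_rejected(self):
        seq = "G" * 12
        with pytest.raises(SyntheticError, match="requires"):
            make_dimer(HelixSpec(seq, chain_id="A"), HelixSpec(seq, chain_id="B"),
                       contacts=[(6, 6, "hbond")])


class TestPocket:
    def test_ligand_template_has_an_aromatic_ring(self):
        from ddgscan.structure import het_aromatic_rings
        lig = make_ligand_template()
        rings = het_aromatic_rings(lig)
        assert len(rings) == 1 and len(rings[0]) == 6

    def test_metal_contact_engineered_at_coordination_distance(self, pocket):
        model, _ = pocket
        zn = model.metals[0].atoms[0]
        lig = model.ligands[0]
        dmin = min(np.linalg.norm(zn.coords - a.coords) for a in lig.atoms)
        assert dmin == pytest.approx(2.05, abs=0.01)

    def test_removing_the_ligand_removes_all_ligand_records(self, pocket):
        import copy

        from ddgscan.interactions import detect_interactions
        model, _ = pocket
        bare = copy.deepcopy(model)
        bare.ligands.clear()
        lig_rid = model.ligands[0].rid
        records = detect_interactions(bare).records
        assert not [r for r in records if lig_rid in (r.res_a, r.res_b)]

    def test_unknown_interaction_kind_rejected(self):
        with pytest.raises(SyntheticError):
            make_pocket(["covalent"])


class TestFamilies:
    def test_zero_offdiagonal_probability_copies_the_ancestor(self):
        spec = FamilySpec(ancestral_sequence="MKTAYIAK",
                          substitution_matrices={"coil_exposed": np.eye(20)},
                          env_labels=["coil_exposed"] * 8,
                          n_homologs=25, seed=4)
        assert set(make_families(spec)) == {"MKTAYIAK"}

    def test_seed_reproducibility(self):
        spec, _ = make_esst_family(seed=9, n_homologs=40, columns_per_env=10)
        assert make_families(spec) == make_families(spec)

    def test_column_frequencies_within_binomial_ci(self):
        spec, matrices = make_esst_family(seed=2, n_homologs=400,
                                          columns_per_env=12)
        homologs = make_families(spec)
        aa_order = "ACDEFGHIKLMNPQRSTVWY"
        # pick a few columns and compare empirical vs generating frequencies
        rng = np.random.default_rng(0)
        checked = violations = 0
        for j in rng.choice(len(spec.ancestral_sequence), size=10, replace=False):
            a = spec.ancestral_sequence[j]
            env = spec.env_labels[j]
            row = matrices[env][aa_order.index(a)]
            observed = np.zeros(20)
            for h in homologs:
                observed[aa_order.index(h[j])] += 1
            n = len(homologs)
            for b in range(20):
                p = row[b]
                if p == 0:
                    assert observed[b] == 0
                    continue
                se = np.sqrt(p * (1 - p) / n)
                checked += 1
                # 99% binomial CI (2.58 sigma) per cell; across ~200 cells a
                # few one-percent-tail excursions are statistically expected
                if abs(observed[b] / n - p) > max(2.58 * se, 3.0 / n):
                    violations += 1
        assert checked > 100
        assert violations <= max(3, int(0.03 * checked))


class TestMutationTable:
    def test_exact_largest_remainder_allocation(self, helix):
        table, labels = make_mutation_table(
            helix, n=100,
            proportions={"stabilizing": 0.1, "slightly_destabilizing": 0.7,
                         "highly_destabilizing": 0.2}, seed=1)
        assert len(table) == 100
        from collections import Counter
        counts = Counter(labels)
        assert counts == {"stabilizing": 10, "slightly_destabilizing": 70,
                          "highly_destabilizing": 20}

    def test_seed_reproducibility(self, pocket):
        t1, l1 = make_mutation_table(pocket[0], 30, {"x": 1.0}, seed=8)
        t2, l2 = make_mutation_table(pocket[0], 30, {"x": 1.0}, seed=8)
        assert [m.key for m in t1] == [m.key for m in t2] and l1 == l2

    def test_specs_never_silent(self, pocket):
        table, _ = make_mutation_table(pocket[0], 50, {"x": 1.0}, seed=3)
        assert all(m.wt_aa != m.mut_aa for m in table)

    def test_invalid_inputs_rejected(self, pocket):
        with pytest.raises(SyntheticError):
            make_mutation_table(pocket[0], 0, {"x": 1.0}, seed=1)
        with pytest.raises(SyntheticError):
            make_mutation_table(pocket[0], 5, {"x": 0.5}, seed=1)
        with pytest.raises(SyntheticError, match="unique"):
            make_mutation_table(pocket[0], 100, {"x": 1.0}, seed=1)


class TestParalogPair:
    def test_seed_reproducible(self):
        assert make_paralog_pair(length=200, seed=5) == \
            make_paralog_pair(length=200, seed=5)

    def test_truth_tracks_substitution_load(self):
        _, _, truth_high = make_paralog_pair(length=400, identity=0.9, seed=1)
        _, _, truth_low = make_paralog_pair(length=400, identity=0.6, seed=1)
        assert truth_high > truth_low


def test_fixture_files_are_readable_structures(tmp_path):
    paths = write_fixture_files(tmp_path, seed=3)
    for path in paths:
        assert path.exists()
    model = read_structure(tmp_path / "dimer.pdb")
    assert set(model.chains) == {"A", "B"}
    pocket_model = read_structure(tmp_path / "pocket.pdb")
    assert pocket_model.ligands and pocket_model.metals


def test_random_structures_are_small_and_seeded():
    for seed in (0, 1, 2):
        first = random_structure(seed)
        second = random_structure(seed)
        assert first.n_atoms() == second.n_atoms() <= 500
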
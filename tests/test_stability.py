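import copy
import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddgscan._geometry import rotation_about_axis
from ddgscan.stability import (ESST, EnvironmentClass, ScoringError,
                               classify_ddg, classify_environment,
                               compute_signature, consensus, default_esst,
                               default_model, derive_esst, esst_score,
                               predict_ddg, relative_solvent_accessibility,
                               signature_feature_names)
from ddgscan.synthetic import (FamilySpec, HelixSpec, make_esst_family,
                               make_families, make_helix)


def mut(chain, pos, wt, mt, icode=""):
    return SimpleNamespace(chain=chain, position=pos, icode=icode,
                           wt_aa=wt, mut_aa=mt)


class TestEnvironment:
    def test_middle_of_helix_is_helix(self, helix):
        env = classify_environment(helix, helix.chains["A"][5], rsa=0.5)
        assert env.secondary_structure == "helix"

    def test_chain_termini_fall_back_to_coil(self, helix):
        env = classify_environment(helix, helix.chains["A"][0], rsa=0.5,
                                   with_hbond_flag=False)
        assert env.secondary_structure == "coil"

    def test_extended_chain_is_strand_and_exposed(self):
        extended = make_helix(HelixSpec("AAAAAAAA", phi=-139.0, psi=135.0))
        rsa = relative_solvent_accessibility(extended)
        res = extended.chains["A"][4]
        env = classify_environment(extended, res, rsa=rsa[res.rid],
                                   with_hbond_flag=False)
        assert env.secondary_structure == "strand"
        assert env.accessibility == "exposed"

    def test_core_of_helix_bundle_is_buried(self):
        # a central helix surrounded by six parallel neighbors
        chains = {}
        center = make_helix(HelixSpec("AAAAAAAAAAAA", chain_id="Z"))
        chains["Z"] = center.chains["Z"]
        for k in range(6):
            ang = math.radians(60.0 * k)
            cid = chr(ord("A") + k)
            shell = make_helix(HelixSpec("AAAAAAAAAAAA", chain_id=cid,
                                         origin=(9.0 * math.cos(ang),
                                                 9.0 * math.sin(ang), 0.0)))
            chains[cid] = shell.chains[cid]
        from ddgscan.structure import StructureModel, assign_pharmacophores
        bundle = assign_pharmacophores(StructureModel(chains=chains))
        rsa = relative_solvent_accessibility(bundle)
        mid = bundle.chains["Z"][6]
        env = classify_environment(bundle, mid, rsa=rsa[mid.rid],
                                   with_hbond_flag=False)
        assert env == EnvironmentClass("helix", "buried")

    def test_isolated_residue_is_fully_exposed(self, helix):
        from ddgscan.structure import StructureModel, assign_pharmacophores
        lone = assign_pharmacophores(StructureModel(
            chains={"A": [copy.deepcopy(helix.chains["A"][0])]}))
        rsa = relative_solvent_accessibility(lone)
        assert rsa[lone.chains["A"][0].rid] > 0.9


class TestESST:
    def _hand_built(self, lf, lu, scale):
        envs = {f"{ss}_{acc}": np.full((20, 20), lf)
                for ss in ("helix", "strand", "coil")
                for acc in ("buried", "partial", "exposed")}
        return ESST(environments=envs, background=np.full((20, 20), lu),
                    scale=scale)

    def test_hand_built_arithmetic(self):
        table = self._hand_built(lf=-1.0, lu=-0.5, scale=2.0)
        env = EnvironmentClass("helix", "buried")
        assert esst_score("L", "D", env, table) == pytest.approx(-1.0)

    def test_identity_with_equal_tables_is_zero(self):
        table = self._hand_built(lf=-0.7, lu=-0.7, scale=3.0)
        assert esst_score("A", "V", EnvironmentClass("coil", "exposed"),
                          table) == pytest.approx(0.0)

    def test_depleted_substitution_scores_negative(self):
        # hydrophobic -> charged is depleted in buried helix by construction
        table = default_esst()
        env = EnvironmentClass("helix", "buried")
        assert esst_score("L", "D", env, table) < 0
        assert esst_score("I", "K", env, table) < 0

    def test_non_standard_amino_acid_rejected(self):
        table = self._hand_built(-1.0, -0.5, 1.0)
        with pytest.raises(ScoringError):
            esst_score("X", "A", EnvironmentClass("helix", "buried"), table)

    def test_round_trip_through_text_format(self, tmp_path):
        table = default_esst()
        path = tmp_path / "esst.txt"
        table.write(path)
        back = ESST.read(path)
        assert back.scale == pytest.approx(table.scale)
        for key in table.environments:
            assert np.allclose(back.environments[key], table.environments[key],
                               atol=1e-6)

    def test_zero_offdiagonal_family_yields_diagonal_dominance(self):
        identity = np.eye(20)
        spec = FamilySpec(ancestral_sequence="ACDEF",
                          substitution_matrices={"helix_buried": identity},
                          env_labels=["helix_buried"] * 5,
                          n_homologs=30, seed=0)
        homologs = make_families(spec)
        assert all(h == "ACDEF" for h in homologs)
        table = derive_esst([("ACDEF", homologs, spec.env_labels)])
        block = table.environments["helix_buried"]
        for aa in "ACDEF":
            i = "ACDEFGHIKLMNPQRSTVWY".index(aa)
            assert block[i, i] == block[i].max()

    def test_derived_probabilities_recover_generators(self):
        spec, matrices = make_esst_family(seed=23, n_homologs=150,
                                          columns_per_env=30)
        homologs = make_families(spec)
        table = derive_esst([(spec.ancestral_sequence, homologs,
                              spec.env_labels)])
        env = "helix_buried"
        cols = [j for j, e in enumerate(spec.env_labels) if e == env]
        aa_order = "ACDEFGHIKLMNPQRSTVWY"
        checked = 0
        for a in set(spec.ancestral_sequence[j] for j in cols):
            i = aa_order.index(a)
            n = sum(1 for j in cols if spec.ancestral_sequence[j] == a) * 150
            probs = np.exp(table.environments[env][i])
            for b in range(20):
                p = matrices[env][i, b]
                if p * n < 5:
                    continue
                se = math.sqrt(p * (1 - p) / n)
                assert abs(probs[b] - p) <= 3 * se + 25.0 / n, (a, aa_order[b])
                checked += 1
        assert checked > 20


class TestSignature:
    def test_identity_substitution_has_zero_delta(self, pocket):
        model, truth = pocket
        site = truth.ids[0]
        res = model.get_residue(*site)
        sig = compute_signature(model, mut(site[0], site[1], res.aa1, res.aa1),
                                rsa=0.5)
        delta = [v for n, v in zip(sig.feature_names, sig.values)
                 if n.startswith("delta_")]
        assert np.allclose(delta, 0.0)

    def test_counts_match_brute_force_at_largest_cutoff(self, pocket):
        model, truth = pocket
        site = truth.ids[1]
        sig = compute_signature(model, mut(site[0], site[1], "F", "A"), rsa=0.5)
        res = model.get_residue(*site)
        anchor = (res.atom("CB") or res.atom("CA")).coords
        brute = 0
        for other in model.all_residues():
            if other is res:
                continue
            for a in other.atoms:
                if np.linalg.norm(a.coords - anchor) <= 10.0:
                    brute += len(a.pharmacophores)
        total = sum(v for n, v in zip(sig.feature_names, sig.values)
                    if (n.startswith("env_") or n.startswith("partner_"))
                    and n.endswith("_r10"))
        assert total == brute

    def test_counts_monotone_in_cutoff(self, pocket):
        model, truth = pocket
        site = truth.ids[2]
        sig = compute_signature(model, mut(site[0], site[1], "H", "A"), rsa=0.5)
        by_class = {}
        for n, v in zip(sig.feature_names, sig.values):
            for prefix in ("env_", "pair_", "partner_"):
                if n.startswith(prefix):
                    stem, radius = n.rsplit("_r", 1)
                    by_class.setdefault(stem, []).append((float(radius), v))
        for stem, series in by_class.items():
            series.sort()
            values = [v for _, v in series]
            assert values == sorted(values), stem

    def test_rigid_body_invariance(self, pocket):
        model, truth = pocket
        site = truth.ids[0]
        m = mut(site[0], site[1], "S", "A")
        before = compute_signature(model, m, mode="ligand", rsa=0.4).values
        moved = copy.deepcopy(model)
        rot = rotation_about_axis(np.array([0.3, -1.0, 0.8]), 51.0)
        for res in moved.all_residues():
            for a in res.atoms:
                a.coords = a.coords @ rot.T + np.array([7.0, 1.0, -4.0])
        after = compute_signature(moved, m, mode="ligand", rsa=0.4).values
        assert np.allclose(before, after, atol=1e-6)

    def test_monomer_has_empty_interface_channel(self, helix):
        sig = compute_signature(helix, mut("A", 6, "E", "Q"), mode="ppi", rsa=0.6)
        partner = [v for n, v in zip(sig.feature_names, sig.values)
                   if n.startswith("partner_")]
        assert np.allclose(partner, 0.0)

    def test_bad_grid_rejected(self, helix):
        with pytest.raises(ScoringError):
            compute_signature(helix, mut("A", 6, "E", "Q"), grid=(6.0, 4.0), rsa=0.5)
        with pytest.raises(ScoringError):
            compute_signature(helix, mut("A", 6, "E", "Q"), grid=(), rsa=0.5)


class TestRegressor:
    def test_zero_vector_through_zero_model_is_zero(self, helix):
        sig = compute_signature(helix, mut("A", 6, "E", "Q"), rsa=0.0)
        model = {"feature_names": sig.feature_names,
                 "coef": [0.0] * len(sig.values), "intercept": 0.0}
        sig.values = np.zeros_like(sig.values)
        assert predict_ddg(sig, model) == 0.0

    def test_dimension_mismatch_rejected(self, helix):
        sig = compute_signature(helix, mut("A", 6, "E", "Q"), rsa=0.5)
        with pytest.raises(ScoringError):
            predict_ddg(sig, {"feature_names": ["x"], "coef": [1.0],
                              "intercept": 0.0})

    def test_identical_signatures_predict_identically(self, helix):
        model = default_model()
        a = compute_signature(helix, mut("A", 6, "E", "Q"), rsa=0.5)
        b = compute_signature(helix, mut("A", 6, "E", "Q"), rsa=0.5)
        assert predict_ddg(a, model) == predict_ddg(b, model)

    def test_packaged_training_rows_repredicted_within_stored_residual(self):
        from pathlib import Path

        from ddgscan.pipeline import MutationSpec
        from ddgscan.synthetic import make_dimer, make_pocket

        model = default_model()
        data_dir = Path(__file__).resolve().parent.parent / "src" / "ddgscan" / "data"
        training = pd.read_csv(data_dir / "signature_training.csv")
        pocket, _ = make_pocket(["hbond", "pi_stack", "metal", "proximal", "hbond"])
        seq = ["G"] * 18
        seq[7], seq[13] = "S", "F"
        seq = "".join(seq)
        dimer, _, _ = make_dimer(HelixSpec(seq, chain_id="A"),
                                 HelixSpec(seq, chain_id="B"),
                                 contacts=[(8, 8, "hbond"), (14, 14, "ring_stack")])
        structures = {"ligand": pocket, "ppi": dimer}
        for _, row in training.sample(6, random_state=0).iterrows():
            st_model = structures[row["mode"]]
            spec = MutationSpec(chain=row["chain"], position=int(row["position"]),
                                wt_aa=row["wt"], mut_aa=row["mut"], source="user")
            sig = compute_signature(st_model, spec, mode=row["mode"],
                                    rsa=float(row["rsa"]))
            pred = predict_ddg(sig, model)
            assert abs(pred - row["label"]) <= model["max_training_residual"] + 1e-3


class TestConsensusAndClassification:
    def test_equal_weights_mean(self):
        assert consensus(-1.0, -2.0) == pytest.approx(-1.5)

    def test_degenerate_weights_pass_through(self):
        assert consensus(-1.0, -2.0, weights=(1.0, 0.0)) == pytest.approx(-1.0)

    def test_single_available_score_passes_through(self):
        assert consensus(None, -2.0) == pytest.approx(-2.0)

    def test_both_missing_is_an_error(self):
        with pytest.raises(ScoringError):
            consensus(None, None)

    @given(st.floats(-6, 3), st.floats(-6, 3))
    @settings(max_examples=50, derandomize=True)
    def test_consensus_between_inputs(self, a, b):
        lo, hi = sorted((a, b))
        assert lo - 1e-9 <= consensus(a, b) <= hi + 1e-9

    @pytest.mark.parametrize("ddg, label", [
        (-4.978, "highly_destabilizing"),   # deepest ligand-affinity change
        (-1.381, "slightly_destabilizing"),
        (-2.548, "highly_destabilizing"),   # interface-destabilizing case
        (0.0, "stabilizing"),
        (-2.0, "slightly_destabilizing"),   # band boundary is inclusive
        (1.7, "stabilizing"),
    ])
    def test_band_examples(self, ddg, label):
        assert classify_ddg(ddg) == label

    @given(st.floats(allow_nan=False, allow_infinity=False, width=32))
    @settings(max_examples=200, derandomize=True)
    def test_every_finite_value_gets_exactly_one_label(self, ddg):
        assert classify_ddg(ddg) in ("stabilizing", "slightly_destabilizing",
                                     "highly_destabilizing")

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), None])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ScoringError):
            classify_ddg(bad)


def test_feature_names_are_stable_and_unique():
    names = signature_feature_names()
    assert len(names) == len(set(names))
    assert names == default_model()["feature_names"]
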
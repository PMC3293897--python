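"""Feature typing, interface-derived models, and RMSd matching."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import helixscreen as hs
from helixscreen.geometry import rotation_about_axis, superpose
from helixscreen.pharmacophore import Feature, match_pharmacophore


# --- independent superposition + assignment oracle -------------------------

def kabsch_oracle(mobile, target):
    """Independent SVD-based proper-rotation superposition RMSD."""
    P = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    Q = np.asarray(target, float) - np.mean(target, axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = P @ R.T
    return float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))


def brute_force_min_rmsd(features, model):
    """Oracle: scan every injective kind-compatible assignment."""
    best = float("inf")
    kinds = [f.kind for f in features]
    cands = [[j for j, k in enumerate(kinds) if k == mf.kind]
             for mf in model.features]
    for combo in itertools.product(*cands):
        if len(set(combo)) != len(combo):
            continue
        lig_pts = np.array([features[j].position for j in combo])
        best = min(best, kabsch_oracle(lig_pts, model.positions))
    return best


def _rdkit_ligand(smiles, name, seed=7):
    from rdkit import Chem
    from rdkit.Chem import AllChem
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    import tempfile, os
    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "m.sdf")
        w = Chem.SDWriter(path)
        mol.SetProp("_Name", name)
        w.write(mol)
        w.close()
        return hs.read_sdf(path)[0]


class TestTyping:
    def test_diphenyl_urea_presents_donor_acceptor_hydrophobic(self):
        lig = _rdkit_ligand("O=C(Nc1ccccc1)Nc1ccccc1", "dpu")
        kinds = [f.kind for f in hs.type_ligand_features(lig)]
        assert kinds.count("HD") >= 2   # two urea N-H
        assert kinds.count("HA") >= 1   # urea carbonyl
        assert kinds.count("HY") == 2   # two phenyl centroids

    def test_methane_has_no_features(self):
        lig = _rdkit_ligand("C", "methane")
        assert hs.type_ligand_features(lig) == []

    def test_nitrobenzene_two_acceptors_one_ring(self):
        lig = _rdkit_ligand("O=[N+]([O-])c1ccccc1", "nitrobenzene")
        kinds = [f.kind for f in hs.type_ligand_features(lig)]
        assert kinds.count("HA") == 2   # both nitro oxygens
        assert kinds.count("HY") == 1   # one carbocycle
        assert kinds.count("HD") == 0

    def test_counts_are_conformer_independent(self, library):
        lig = library[0]
        k0 = sorted(f.kind for f in hs.type_ligand_features(lig, 0))
        k1 = sorted(f.kind for f in hs.type_ligand_features(lig, 1))
        assert k0 == k1


class TestDerivation:
    def test_five_point_model_matches_planted_pattern(self, model):
        kinds = [f.kind for f in model.features]
        assert len(kinds) == 5
        # two protein donors -> HA, two acceptor oxygens -> HD, one patch -> HY
        assert sorted(kinds) == ["HA", "HA", "HD", "HD", "HY"]

    def test_features_lie_near_their_source_residues(self, dimer, model):
        structure, _ = dimer
        for feat in model.features:
            resnum = int("".join(c for c in feat.source.split("/")[0]
                                 if c.isdigit()))
            res = structure.residue("A", resnum)
            dmin = min(np.linalg.norm(a.coords - feat.position)
                       for a in res.atoms)
            assert dmin <= 5.0

    def test_glycine_only_hotspots_cannot_form_model(self, dimer):
        structure, _ = dimer
        gly = structure.residue("A", 210)
        with pytest.raises(ValueError, match=">= 3"):
            hs.derive_interface_pharmacophore(structure, [gly])

    def test_empty_hotspot_list_rejected(self, dimer):
        structure, _ = dimer
        with pytest.raises(ValueError, match="empty"):
            hs.derive_interface_pharmacophore(structure, [])

    def test_yaml_round_trip(self, model, tmp_path):
        path = tmp_path / "model.yaml"
        model.save(path)
        back = hs.Pharmacophore.load(path)
        assert [f.kind for f in back.features] == [f.kind for f in model.features]
        assert np.allclose(back.positions, model.positions)
        assert all(f.direction is not None for f in back.features)


class TestMatching:
    def _exact_features(self, model):
        return [Feature(f.kind, f.position.copy()) for f in model.features]

    def test_identity_configuration_matches_exactly(self, model):
        res = match_pharmacophore(self._exact_features(model), model)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.accepted

    def test_rigidly_moved_ligand_still_matches(self, model):
        R = rotation_about_axis(np.array([0.0, 1.0, 0.0]), 90.0)
        t = np.array([10.0, 0.0, 0.0])
        feats = [Feature(f.kind, R @ f.position + t) for f in model.features]
        res = match_pharmacophore(feats, model)
        assert res.rmsd < 1e-6
        assert res.accepted
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_one_displaced_feature_rejected_at_gate(self, model):
        # optimal superposition absorbs a surprising share of a single
        # displacement (translation alone leaves rmsd = 0.4 d on 5 points),
        # so a clear rejection needs a displacement well beyond the gate
        feats = self._exact_features(model)
        hy = next(i for i, f in enumerate(feats) if f.kind == "HY")
        feats[hy].position = feats[hy].position + np.array([6.0, 0.0, 0.0])
        res = match_pharmacophore(feats, model)
        assert res.rmsd > 1.0
        assert not res.accepted
        assert res.rmsd == pytest.approx(brute_force_min_rmsd(feats, model),
                                         abs=1e-9)

    def test_no_kind_compatible_assignment_gives_inf(self, model):
        feats = [Feature("HY", f.position.copy()) for f in model.features]
        res = match_pharmacophore(feats, model)
        assert res.rmsd == float("inf")
        assert not res.accepted

    def test_matcher_equals_permutation_oracle_on_random_instances(self, model):
        rng = np.random.default_rng(42)
        for _ in range(10):
            feats = [Feature(f.kind, f.position + rng.normal(0, 1.0, 3))
                     for f in model.features]
            # add one distractor of each kind
            for kind in ("HD", "HA", "HY"):
                feats.append(Feature(kind, rng.uniform(-5, 15, 3)))
            res = match_pharmacophore(feats, model)
            assert res.rmsd == pytest.approx(brute_force_min_rmsd(feats, model),
                                             abs=1e-9)

    def test_gate_monotonicity(self, model, library):
        for lig in library[:6] + library[-6:]:
            feats = hs.type_ligand_features(lig, 0)
            accepted = {}
            for gate in (0.25, 0.5, 1.0, 2.0):
                accepted[gate] = match_pharmacophore(feats, model, gate).accepted
            # accepted set can only grow with the gate
            for lo, hi in [(0.25, 0.5), (0.5, 1.0), (1.0, 2.0)]:
                assert (not accepted[lo]) or accepted[hi]

    def test_mirror_image_is_not_matched_by_proper_rotation(self):
        # a chiral 4-point arrangement and its mirror image cannot be
        # superposed with det(R) = +1
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0], [0, 0, 2.0]])
        kinds = ["HD", "HA", "HY", "HD"]
        target = hs.Pharmacophore([Feature(k, p) for k, p in zip(kinds, pts)])
        mirror = pts * np.array([1.0, 1.0, -1.0])
        res = match_pharmacophore([Feature(k, p) for k, p in zip(kinds, mirror)],
                                  target)
        assert res.rmsd > 0.5


class TestSuperposition:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_rmsd_zero_under_any_proper_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 5, (6, 3))
        axis = rng.normal(size=3)
        R = rotation_about_axis(axis, float(rng.uniform(0, 360)))
        t = rng.normal(0, 10, 3)
        _, _, rmsd = superpose(pts @ R.T + t, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_rmsd_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 3, (5, 3))
        b = rng.normal(0, 3, (5, 3))
        _, _, r_ab = superpose(a, b)
        _, _, r_ba = superpose(b, a)
        assert r_ab >= 0
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_matches_independent_kabsch_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 3, (7, 3))
        b = rng.normal(0, 3, (7, 3))
        _, _, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(kabsch_oracle(a, b), abs=1e-9)
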
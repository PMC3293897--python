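"""Empirical score, generalized-Born/SASA solvation, group electrostatics."""
import numpy as np
import pytest

import helixscreen as hs
from helixscreen.constants import COULOMB_K
from helixscreen.geometry import rotation_about_axis
from helixscreen.scoring import DEFAULT_WEIGHTS

from conftest import make_point_atom, single_atom_structure


@pytest.fixture(scope="module")
def scored_pose(library, model, receptor_a):
    ranking = hs.screen_library(library, model, receptor_a)
    pose = ranking.entries[0].pose
    return hs.local_minimize(pose, receptor_a, steps=50)


class TestEmpiricalScore:
    def test_distant_pose_scores_rotor_term_only(self, library, receptor_a):
        lig = library[0]
        pose = hs.identity_pose(lig)  # scattered ~40 Å from the site
        s = hs.empirical_score(pose, receptor_a)
        assert s.vdw_term == pytest.approx(0.0, abs=1e-6)
        assert s.hbond_term == 0.0
        assert s.hydrophobic_term == 0.0
        assert s.rotor_term == -0.5 * lig.n_rotatable
        assert s.total == pytest.approx(DEFAULT_WEIGHTS["rotor"] * s.rotor_term)

    def test_single_ideal_hbond_contributes_exactly_one(self):
        # ligand amine N-H aimed at an isolated carbonyl O at 2.9 Å / 180 deg
        n = make_point_atom(1, "N", [0.0, 0.0, 0.0], name="N1")
        h = make_point_atom(2, "H", [1.0, 0.0, 0.0], name="H1")
        lig = hs.Ligand("probe", [n, h], [(0, 1, 1.0)],
                        [np.array([[0.0, 0, 0], [1.0, 0, 0]])])
        hs.assign_parameters(lig)
        o = make_point_atom(1, "O", [2.9, 0.0, 0.0], name="O")
        c = make_point_atom(2, "C", [2.9, 1.23, 0.0], name="C")
        receptor = hs.Structure({"R": [hs.Residue("R", 1, "UNK", [o, c])]})
        s = hs.empirical_score(hs.identity_pose(lig), receptor)
        assert s.hbond_term == pytest.approx(1.0, abs=1e-9)
        # moving the acceptor out of range removes exactly w_hb * 1
        o2 = make_point_atom(1, "O", [20.0, 0.0, 0.0], name="O")
        c2 = make_point_atom(2, "C", [20.0, 1.23, 0.0], name="C")
        far = hs.Structure({"R": [hs.Residue("R", 1, "UNK", [o2, c2])]})
        s_far = hs.empirical_score(hs.identity_pose(lig), far)
        assert s.total - s_far.total == pytest.approx(
            DEFAULT_WEIGHTS["hbond"] * 1.0
            + DEFAULT_WEIGHTS["vdw"] * (s.vdw_term - s_far.vdw_term))

    def test_score_invariant_under_global_rigid_motion(self, scored_pose, receptor_a):
        s0 = hs.empirical_score(scored_pose, receptor_a)
        R = rotation_about_axis(np.array([1.0, 1.0, 0.0]), 37.0)
        t = np.array([3.0, -7.0, 11.0])
        moved_rec = receptor_a.subset(["A"])
        moved_rec.frames[0] = receptor_a.frames[0] @ R.T + t
        moved_pose = hs.Pose(scored_pose.ligand, scored_pose.conformer,
                             scored_pose.rotation, scored_pose.translation,
                             scored_pose.coords_placed @ R.T + t,
                             scored_pose.pharm_rmsd, scored_pose.clash_count)
        s1 = hs.empirical_score(moved_pose, moved_rec)
        assert s1.total == pytest.approx(s0.total, abs=1e-6)

    def test_total_is_weighted_sum_of_terms(self, scored_pose, receptor_a):
        w = {"vdw": 0.01, "hbond": 1.0, "hydrophobic": 0.2, "rotor": 0.3}
        s = hs.empirical_score(scored_pose, receptor_a, w)
        expected = (0.01 * s.vdw_term + 1.0 * s.hbond_term
                    + 0.2 * s.hydrophobic_term + 0.3 * s.rotor_term)
        assert s.total == pytest.approx(expected, abs=1e-12)


class TestSolvation:
    @pytest.mark.parametrize("radius", [1.0, 2.0, 3.5, 5.0])
    @pytest.mark.parametrize("charge", [1.0, -2.0])
    def test_single_ion_matches_born_closed_form(self, radius, charge):
        gb = hs.gb_polar_energy(np.zeros((1, 3)), np.array([charge]),
                                np.array([radius]))
        born = -0.5 * COULOMB_K * (1 - 1 / 80.0) * charge ** 2 / radius
        assert abs(gb - born) / abs(born) < 1e-3

    def test_reference_ion_value(self):
        # q = +1 e, Born radius 2.0 Å, eps_w = 80:
        # -166 * (1 - 1/80) / 2.0 = -81.96 kcal/mol
        gb = hs.gb_polar_energy(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]))
        assert gb == pytest.approx(-81.96, abs=0.05)

    @pytest.mark.parametrize("radius", [1.2, 1.7, 2.8])
    def test_isolated_sphere_sasa_closed_form(self, radius):
        sasa = hs.shrake_rupley_sasa(np.zeros((1, 3)), np.array([radius]))
        exact = 4 * np.pi * (radius + 1.4) ** 2
        assert abs(sasa - exact) / exact < 0.02

    def test_buried_sphere_has_zero_sasa(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0.1]])
        sasa_pair = hs.shrake_rupley_sasa(coords, np.array([1.0, 4.0]))
        sasa_big = hs.shrake_rupley_sasa(np.array([[0.0, 0, 0.1]]), np.array([4.0]))
        assert sasa_pair == pytest.approx(sasa_big, rel=0.02)


class TestMMGBSA:
    def test_total_is_sum_of_reported_terms(self, scored_pose, receptor_a):
        mm = hs.mmpbsa_energy(scored_pose, receptor_a)
        assert mm.total == pytest.approx(
            mm.e_vdw + mm.e_elec + mm.g_polar + mm.g_nonpolar, abs=1e-6)
        assert mm.entropy_included is False

    def test_separated_complex_has_vanishing_binding_terms(self, library, receptor_a):
        pose = hs.identity_pose(library[0])  # ~40 Å away
        mm = hs.mmpbsa_energy(pose, receptor_a)
        assert abs(mm.e_vdw) < 1e-3
        assert abs(mm.e_elec) < 1.0   # long-range Coulomb tail only
        assert abs(mm.g_nonpolar) < 1e-6
        assert abs(mm.total) < abs(mm.e_elec) + 0.5

    def test_terms_invariant_under_global_rigid_motion(self, scored_pose, receptor_a):
        mm0 = hs.mmpbsa_energy(scored_pose, receptor_a)
        R = rotation_about_axis(np.array([0.0, 1.0, 1.0]), 55.0)
        t = np.array([-4.0, 9.0, 1.0])
        moved_rec = receptor_a.subset(["A"])
        moved_rec.frames[0] = receptor_a.frames[0] @ R.T + t
        moved = hs.Pose(scored_pose.ligand, scored_pose.conformer,
                        scored_pose.rotation, scored_pose.translation,
                        scored_pose.coords_placed @ R.T + t,
                        scored_pose.pharm_rmsd, scored_pose.clash_count)
        mm1 = hs.mmpbsa_energy(moved, moved_rec)
        assert mm1.e_vdw == pytest.approx(mm0.e_vdw, abs=1e-6)
        assert mm1.e_elec == pytest.approx(mm0.e_elec, abs=1e-6)
        assert mm1.g_polar == pytest.approx(mm0.g_polar, abs=1e-6)
        assert mm1.g_nonpolar == pytest.approx(mm0.g_nonpolar, abs=1e-4)

    def test_overlapping_pose_rejected(self, receptor_a):
        atom = make_point_atom(1, "C", receptor_a.coords(0)[0])
        lig = hs.Ligand("clash", [atom], [], [atom.coords[None, :]])
        with pytest.raises(FloatingPointError):
            hs.mmpbsa_energy(hs.identity_pose(lig), receptor_a)


class TestGroupElectrostatics:
    def test_partition_sums_to_mm_elec(self, scored_pose, receptor_a):
        mm = hs.mmpbsa_energy(scored_pose, receptor_a)
        groups = hs.remainder_group(scored_pose.ligand, scored_pose.ligand.groups)
        contributions = hs.group_electrostatics(scored_pose, receptor_a, groups)
        assert sum(g.e_elec_group for g in contributions) == pytest.approx(
            mm.e_elec, abs=1e-6)

    def test_whole_ligand_group_equals_mm_elec(self, scored_pose, receptor_a):
        mm = hs.mmpbsa_energy(scored_pose, receptor_a)
        (g,) = hs.group_electrostatics(
            scored_pose, receptor_a,
            {"all": list(range(len(scored_pose.ligand.atoms)))})
        assert g.e_elec_group == pytest.approx(mm.e_elec, abs=1e-6)

    def test_zero_charge_group_contributes_nothing(self, model, receptor_a):
        t2f = hs.make_t2f_analog(model, seed=1)
        pose = hs.identity_pose(t2f)
        (g,) = hs.group_electrostatics(pose, receptor_a,
                                       {"nitro": t2f.groups["nitro"]})
        assert g.e_elec_group == pytest.approx(0.0, abs=1e-9)

    def test_overlapping_groups_rejected(self, scored_pose, receptor_a):
        with pytest.raises(ValueError, match="more than one group"):
            hs.group_electrostatics(scored_pose, receptor_a,
                                    {"a": [0, 1], "b": [1, 2]})

    def test_charged_group_near_lysine_dominates(self, model, receptor_a):
        """The nitro group planted against the lysine ammonium carries the
        most negative per-group electrostatics of any group."""
        act = hs.make_active_in_site(model, seed=2)
        pose = hs.identity_pose(act)
        groups = hs.remainder_group(act, act.groups)
        per_atom = {}
        for i in range(len(act.atoms)):
            (g,) = hs.group_electrostatics(pose, receptor_a, {"one": [i]})
            per_atom[i] = g.e_elec_group
        nitro = act.groups["nitro"]
        nitro_sum = sum(per_atom[i] for i in nitro)
        contributions = {g.group: g.e_elec_group
                         for g in hs.group_electrostatics(pose, receptor_a, groups)}
        assert contributions["nitro"] == pytest.approx(nitro_sum, abs=1e-6)
        assert contributions["nitro"] < 0
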
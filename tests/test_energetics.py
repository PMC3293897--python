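"""Residue-pair energies, interface matrix, H-bonds and hot-spot ranking."""
import numpy as np
import pytest

import helixscreen as hs
from helixscreen.constants import COULOMB_K
from helixscreen.energetics import DielectricModel

from conftest import make_point_atom


def _pair_structure(xyz_a, xyz_b, q=(0.0, 0.0), eps=(0.0, 0.0), rmh=(1.9, 1.9)):
    a = make_point_atom(1, "C", xyz_a, q[0], eps[0], rmh[0])
    b = make_point_atom(2, "C", xyz_b, q[1], eps[1], rmh[1])
    ra = hs.Residue("A", 1, "UNK", [a])
    rb = hs.Residue("B", 1, "UNK", [b])
    return ra, rb


def brute_force_total(structure, chain_a, chain_b, frame, dielectric):
    """Independent oracle: one pass over every inter-chain atom pair."""
    idx = structure.atom_indices()
    coords = structure.frames[frame]
    atoms_a = [(a, idx[id(a)]) for r in structure.chains[chain_a] for a in r.atoms]
    atoms_b = [(b, idx[id(b)]) for r in structure.chains[chain_b] for b in r.atoms]
    total = 0.0
    for a, ia in atoms_a:
        for b, ib in atoms_b:
            r = float(np.linalg.norm(coords[ia] - coords[ib]))
            eps = np.sqrt(a.lj_epsilon * b.lj_epsilon)
            rmin = a.lj_rmin_half + b.lj_rmin_half
            total += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            screen = 4.0 * r if dielectric.kind == "4r" else dielectric.constant
            total += COULOMB_K * a.charge * b.charge / (screen * r)
    return total


class TestPairEnergy:
    def test_unit_charges_at_coulomb_distance_give_minus_100(self):
        # k q1 q2 / r = 332.0637 * (+1)(-1) / 3.320637 = -100 at eps = 1
        ra, rb = _pair_structure([0, 0, 0], [3.320637, 0, 0], q=(1.0, -1.0))
        e_vdw, e_elec = hs.pair_energy(ra, rb, dielectric=DielectricModel(constant=1.0))
        assert e_elec == pytest.approx(-100.0, abs=1e-9)
        assert e_vdw == 0.0

    def test_lj_pair_at_rmin_gives_minus_epsilon(self):
        ra, rb = _pair_structure([0, 0, 0], [3.8, 0, 0], eps=(0.25, 0.25),
                                 rmh=(1.9, 1.9))
        e_vdw, e_elec = hs.pair_energy(ra, rb)
        assert e_vdw == pytest.approx(-0.25, abs=1e-12)
        assert e_elec == 0.0

    def test_both_terms_vanish_at_huge_separation(self):
        ra, rb = _pair_structure([0, 0, 0], [1e4, 0, 0], q=(1.0, 1.0),
                                 eps=(0.2, 0.2))
        # default distance-dependent dielectric: Coulomb decays as 1/r^2
        e_vdw, e_elec = hs.pair_energy(ra, rb)
        assert abs(e_vdw) < 1e-6 and abs(e_elec) < 1e-6

    def test_overlapping_atoms_raise_numeric_guard(self):
        ra, rb = _pair_structure([0, 0, 0], [0, 0, 0])
        with pytest.raises(FloatingPointError, match="overlap"):
            hs.pair_energy(ra, rb)

    def test_same_chain_rejected(self):
        a = make_point_atom(1, "C", [0, 0, 0])
        b = make_point_atom(2, "C", [3, 0, 0])
        with pytest.raises(ValueError, match="different chains"):
            hs.pair_energy(hs.Residue("A", 1, "UNK", [a]),
                           hs.Residue("A", 2, "UNK", [b]))


class TestInterfaceMatrix:
    def test_identical_frames_equal_single_frame_and_zero_sd(self, dimer):
        structure, _ = dimer
        rep = hs.Structure(structure.chains, [structure.frames[0]] * 5)
        m1 = hs.interface_matrix(structure, "A", "B")
        m5 = hs.interface_matrix(rep, "A", "B")
        for key, p in m1.entries.items():
            assert m5.entries[key].e_total == pytest.approx(p.e_total, abs=1e-12)
            assert m5.entries[key].sd_total == pytest.approx(0.0, abs=1e-12)

    def test_planted_salt_bridge_is_most_negative_elec_entry(self, dimer):
        structure, _ = dimer
        m = hs.interface_matrix(structure, "A", "B")
        elec = {key: p.e_elec for key, p in m.entries.items()}
        best = min(elec, key=elec.get)
        # Lys+ ... Glu- bridges: A204-B207 or B204-A207 (transposed key order)
        assert best in ((("A", 204), ("B", 207)), (("A", 207), ("B", 204)))

    def test_swapping_chains_transposes_matrix(self, dimer):
        structure, _ = dimer
        mab = hs.interface_matrix(structure, "A", "B")
        mba = hs.interface_matrix(structure, "B", "A")
        for (ka, kb), p in mab.entries.items():
            q = mba.entries[(kb, ka)]
            assert q.e_vdw == pytest.approx(p.e_vdw, abs=1e-9)
            assert q.e_elec == pytest.approx(p.e_elec, abs=1e-9)

    def test_matrix_total_matches_single_pass_oracle(self, ensemble):
        diel = DielectricModel()
        m = hs.interface_matrix(ensemble, "A", "B")
        oracle = np.mean([brute_force_total(ensemble, "A", "B", k, diel)
                          for k in range(ensemble.n_frames)])
        assert m.total() == pytest.approx(oracle, abs=1e-6)

    def test_per_residue_totals_equal_row_and_column_sums(self, dimer):
        structure, _ = dimer
        m = hs.interface_matrix(structure, "A", "B")
        for r in m.rows:
            row_sum = sum(m.entries[(r, c)].e_total for c in m.cols)
            assert m.per_residue_totals[r] == pytest.approx(row_sum, abs=1e-6)
        for c in m.cols:
            col_sum = sum(m.entries[(r, c)].e_total for r in m.rows)
            assert m.per_residue_totals[c] == pytest.approx(col_sum, abs=1e-6)

    def test_energies_invariant_under_global_rigid_motion(self, dimer):
        structure, _ = dimer
        rot = hs.superpose(np.eye(3), np.eye(3))[0]  # identity warm-up
        from helixscreen.geometry import rotation_about_axis
        R = rotation_about_axis(np.array([1.0, 2.0, 3.0]), 73.0)
        t = np.array([5.0, -8.0, 2.5])
        moved = hs.Structure(structure.chains, [structure.frames[0] @ R.T + t])
        # rebuild atom coords for the moved copy
        m0 = hs.interface_matrix(structure, "A", "B")
        m1 = hs.interface_matrix(moved, "A", "B")
        assert m1.total() == pytest.approx(m0.total(), abs=1e-9)

    def test_frame_averaging_is_linear(self, ensemble):
        m_all = hs.interface_matrix(ensemble, "A", "B")
        per_frame = [hs.interface_matrix(ensemble, "A", "B", frames=[k])
                     for k in range(ensemble.n_frames)]
        for key in m_all.entries:
            mean = np.mean([m.entries[key].e_total for m in per_frame])
            assert m_all.entries[key].e_total == pytest.approx(mean, abs=1e-9)

    def test_empty_frame_selection_rejected(self, dimer):
        structure, _ = dimer
        with pytest.raises(ValueError, match="frame"):
            hs.interface_matrix(structure, "A", "B", frames=[])


class TestHBonds:
    def _nh_o_structure(self, n_o_dist, angle_deg=180.0):
        """Amide N-H on chain A, carbonyl O on chain B, tunable geometry."""
        n = make_point_atom(1, "N", [0, 0, 0], name="N")
        h = make_point_atom(2, "H", [1.0, 0, 0], name="H")
        ang = np.deg2rad(180.0 - angle_deg)
        o_xyz = np.array([1.0, 0, 0]) + (n_o_dist - 1.0) * np.array(
            [np.cos(ang), np.sin(ang), 0.0])
        o = make_point_atom(3, "O", o_xyz, name="O")
        c = make_point_atom(4, "C", o_xyz + np.array([0.0, 1.4, 0.0]), name="C")
        return hs.Structure({
            "A": [hs.Residue("A", 1, "UNK", [n, h])],
            "B": [hs.Residue("B", 1, "UNK", [o, c])],
        })

    def test_ideal_geometry_detected_with_full_occupancy(self):
        s = self._nh_o_structure(2.9, 180.0)
        events, occ = hs.detect_hbonds(s)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(2.9, abs=1e-9)
        assert events[0].angle == pytest.approx(180.0, abs=1e-6)
        assert list(occ.values()) == [1.0]

    def test_long_distance_not_detected(self):
        s = self._nh_o_structure(4.5, 180.0)
        events, occ = hs.detect_hbonds(s)
        assert events == [] and occ == {}

    def test_bent_geometry_not_detected(self):
        s = self._nh_o_structure(2.9, 90.0)
        events, _ = hs.detect_hbonds(s)
        assert events == []

    def test_planted_contact_occupancy_over_jittered_ensemble(self, ensemble):
        _, occ = hs.detect_hbonds(ensemble)
        key = (("A", 203, "NE2"), ("B", 207, "OE1"))
        assert occ.get(key, 0.0) >= 0.9

    def test_structure_without_hydrogens_rejected(self, dimer):
        structure, _ = dimer
        stripped = {}
        for cid, residues in structure.chains.items():
            stripped[cid] = [
                hs.Residue(cid, r.number, r.name,
                           [a for a in r.atoms if not a.is_hydrogen])
                for r in residues
            ]
        with pytest.raises(ValueError, match="hydrogen"):
            hs.detect_hbonds(hs.Structure(stripped))


class TestHotspots:
    def test_planted_residues_occupy_top_ranks(self, ensemble):
        m = hs.interface_matrix(ensemble, "A", "B")
        _, occ = hs.detect_hbonds(ensemble)
        report = hs.rank_hotspots(m, occ, chain="A")
        top3 = {r["residue"][1] for r in report.ranked[:3]}
        assert top3 == {203, 204, 207}
        assert all(r["hotspot"] for r in report.ranked[:3])

    def test_missing_conservation_reported_as_not_evaluated(self, dimer):
        structure, _ = dimer
        m = hs.interface_matrix(structure, "A", "B")
        report = hs.rank_hotspots(m, {})
        assert all(r["conservation"] == "not evaluated" for r in report.ranked)

    def test_conservation_gate_applies_when_provided(self, ensemble):
        m = hs.interface_matrix(ensemble, "A", "B")
        _, occ = hs.detect_hbonds(ensemble)
        cons = {key: 0.0 for key in m.per_residue_totals}
        report = hs.rank_hotspots(m, occ, conservation=cons, chain="A")
        assert not any(r["hotspot"] for r in report.ranked)

    def test_inert_interface_has_no_hotspots(self):
        structure, _ = hs.make_toy_dimer(hs.DimerSpec(planted_contacts=[],
                                                      hydrophobic_patch=False))
        m = hs.interface_matrix(structure, "A", "B")
        assert all(v >= -0.5 for v in m.per_residue_totals.values())
        report = hs.rank_hotspots(m, {})
        assert not any(r["hotspot"] for r in report.ranked)
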
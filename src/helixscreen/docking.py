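"""Pharmacophore-constrained placement, steric filtering and screening.

Conformers are placed rigidly by the transform of an accepted pharmacophore
match; the steric filter then checks ligand-receptor heavy-atom pairs
against collision radii scaled to 60% (radii "reduced by 40%"), which
deliberately tolerates minor clashes as a crude stand-in for flexibility.
Survivors are ranked by pharmacophore RMSd first, empirical score second.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_K, RADIUS_SCALE, RMSD_GATE
from .geometry import apply_transform, rotation_about_axis
from .pharmacophore import MatchResult, Pharmacophore, match_pharmacophore, type_ligand_features
from .structures import Ligand, Structure


@dataclass
class Pose:
    ligand: Ligand
    conformer: int
    rotation: np.ndarray
    translation: np.ndarray
    coords_placed: np.ndarray
    pharm_rmsd: float
    clash_count: int = -1  # -1 = not yet checked

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords_placed[self.ligand.heavy_indices()]


@dataclass
class ScreenEntry:
    ligand: str
    conformer: int
    pharm_rmsd: float
    clash_count: int
    empirical_score: float | None = None
    pose: Pose | None = None


@dataclass
class ScreenRanking:
    entries: list[ScreenEntry]
    rejections: list[dict] = field(default_factory=list)
    criteria: dict = field(default_factory=dict)


def place_pose(ligand: Ligand, conformer: int, match: MatchResult) -> Pose:
    """Rigidly transform a whole conformer by an accepted match."""
    if not match.accepted:
        raise ValueError("cannot place a pose from an unaccepted match")
    coords = apply_transform(ligand.conformers[conformer], match.rotation, match.translation)
    return Pose(ligand, conformer, match.rotation.copy(), match.translation.copy(),
                coords, match.rmsd)


def identity_pose(ligand: Ligand, conformer: int = 0, pharm_rmsd: float = 0.0) -> Pose:
    """Pose at the conformer's own coordinates (no transform)."""
    return Pose(ligand, conformer, np.eye(3), np.zeros(3),
                np.array(ligand.conformers[conformer], dtype=float), pharm_rmsd)


def clash_check(pose: Pose, receptor: Structure,
                radius_scale: float = RADIUS_SCALE
                ) -> tuple[int, list[tuple[int, int, float]]]:
    """Count steric clashes between pose and receptor heavy atoms.

    A ligand heavy atom i and receptor heavy atom j clash iff
    d_ij < radius_scale * (r_i + r_j). Hydrogens are ignored. Returns the
    count and the offending (ligand index, receptor index, distance) list.
    Updates ``pose.clash_count``.
    """
    if not (0.0 < radius_scale <= 1.0):
        raise ValueError(f"radius_scale must be in (0, 1], got {radius_scale}")
    lig_idx = pose.ligand.heavy_indices()
    lig_coords = pose.coords_placed[lig_idx]
    lig_radii = np.array([pose.ligand.atoms[i].radius for i in lig_idx])
    rec_atoms = receptor.atoms
    rec_mask = [k for k, a in enumerate(rec_atoms) if not a.is_hydrogen]
    rec_coords = receptor.coords(0)[rec_mask]
    rec_radii = np.array([rec_atoms[k].radius for k in rec_mask])
    if np.any(lig_radii <= 0) or np.any(rec_radii <= 0):
        raise ValueError("clash_check needs parameterized collision radii on both sides")
    d = cdist(lig_coords, rec_coords)
    thresh = radius_scale * np.add.outer(lig_radii, rec_radii)
    ii, jj = np.where(d < thresh)
    pairs = [(lig_idx[i], rec_mask[j], float(d[i, j])) for i, j in zip(ii, jj)]
    pose.clash_count = len(pairs)
    return len(pairs), pairs


def intermolecular_energy(pose: Pose, receptor: Structure,
                          dielectric_constant: float = 1.0) -> float:
    """Intermolecular Lennard-Jones + Coulomb energy, kcal/mol (all atoms)."""
    lig = pose.ligand
    lq = np.array([a.charge for a in lig.atoms])
    leps = np.array([a.lj_epsilon for a in lig.atoms])
    lrmh = np.array([a.lj_rmin_half for a in lig.atoms])
    rec = receptor.atoms
    rq = np.array([a.charge for a in rec])
    reps = np.array([a.lj_epsilon for a in rec])
    rrmh = np.array([a.lj_rmin_half for a in rec])
    r = cdist(pose.coords_placed, receptor.coords(0))
    if np.any(r < 1e-6):
        raise FloatingPointError("overlapping ligand/receptor atoms; filter clashes first")
    eps_ij = np.sqrt(np.outer(leps, reps))
    ratio = np.add.outer(lrmh, rrmh) / r
    e_vdw = float(np.sum(eps_ij * (ratio ** 12 - 2.0 * ratio ** 6)))
    e_elec = float(COULOMB_K / dielectric_constant * np.sum(np.outer(lq, rq) / r))
    return e_vdw + e_elec


def local_minimize(pose: Pose, receptor: Structure, steps: int = 200,
                   step_size: float = 0.05, step_angle: float = 0.5,
                   dielectric_constant: float = 1.0) -> Pose:
    """Greedy rigid-body (6 DoF) descent on the intermolecular energy.

    Each iteration tries +/- translations along the axes (``step_size`` Å)
    and +/- rotations about the ligand centroid (``step_angle`` degrees)
    and takes the best improving move; stops when no move improves. Ligand
    internal geometry is untouched; the returned pose's energy never
    exceeds the input pose's.
    """
    coords = np.array(pose.coords_placed, dtype=float)
    work = Pose(pose.ligand, pose.conformer, pose.rotation.copy(),
                pose.translation.copy(), coords, pose.pharm_rmsd, pose.clash_count)
    e0 = intermolecular_energy(work, receptor, dielectric_constant)
    if not np.isfinite(e0):
        raise FloatingPointError("non-finite starting energy (overlap); filter clashes first")
    axes = np.eye(3)
    for _ in range(steps):
        centroid = work.coords_placed.mean(axis=0)
        best_coords, best_e = None, e0
        for ax in axes:
            for sgn in (1.0, -1.0):
                cand = work.coords_placed + sgn * step_size * ax
                e = _energy_at(cand, work, receptor, dielectric_constant)
                if e < best_e - 1e-12:
                    best_coords, best_e = cand, e
                rot = rotation_about_axis(ax, sgn * step_angle)
                cand = (work.coords_placed - centroid) @ rot.T + centroid
                e = _energy_at(cand, work, receptor, dielectric_constant)
                if e < best_e - 1e-12:
                    best_coords, best_e = cand, e
        if best_coords is None:
            break
        work.coords_placed = best_coords
        e0 = best_e
    return work


def _energy_at(coords: np.ndarray, pose: Pose, receptor: Structure,
               dielectric_constant: float) -> float:
    tmp = Pose(pose.ligand, pose.conformer, pose.rotation, pose.translation,
               coords, pose.pharm_rmsd)
    try:
        return intermolecular_energy(tmp, receptor, dielectric_constant)
    except FloatingPointError:
        return float("inf")


def screen_library(library: list[Ligand], model: Pharmacophore, receptor: Structure,
                   gate: float = RMSD_GATE, radius_scale: float = RADIUS_SCALE,
                   max_clashes: int = 0) -> ScreenRanking:
    """Pharmacophore-gated, clash-filtered screen of a conformer library.

    Every conformer of every ligand is typed, matched against the model,
    placed when the match passes the RMSd gate, and clash-filtered against
    the receptor. The best (lowest-RMSd) surviving conformer per ligand is
    kept. Entries sort by (pharm_rmsd asc, ligand name, conformer); every
    rejection is logged with a machine-readable reason code.
    """
    if not library:
        raise ValueError("empty ligand library")
    entries: list[ScreenEntry] = []
    rejections: list[dict] = []
    for lig in sorted(library, key=lambda l: l.name):
        best: ScreenEntry | None = None
        for k in range(len(lig.conformers)):
            feats = type_ligand_features(lig, k)
            match = match_pharmacophore(feats, model, gate=gate)
            if not match.accepted:
                rejections.append({"ligand": lig.name, "conformer": k,
                                   "reason": "pharmacophore_gate",
                                   "rmsd": match.rmsd})
                continue
            pose = place_pose(lig, k, match)
            n_clash, _ = clash_check(pose, receptor, radius_scale)
            if n_clash > max_clashes:
                rejections.append({"ligand": lig.name, "conformer": k,
                                   "reason": "steric_clash", "clash_count": n_clash})
                continue
            entry = ScreenEntry(lig.name, k, match.rmsd, n_clash, pose=pose)
            if best is None or entry.pharm_rmsd < best.pharm_rmsd:
                best = entry
        if best is not None:
            entries.append(best)
    entries.sort(key=lambda e: (e.pharm_rmsd, e.ligand, e.conformer))
    return ScreenRanking(entries, rejections,
                         criteria={"gate": gate, "radius_scale": radius_scale,
                                   "max_clashes": max_clashes})
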
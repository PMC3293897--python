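"""Empirical pose rescoring and MM-GBSA-style binding energies.

Two complementary estimates of pose quality:

* an empirical additive score (XSCORE-flavoured): soft van der Waals
  contact term, hydrogen-bond term with piecewise-linear distance/angle
  ramps, hydrophobic carbon-carbon contact count and a rotatable-bond
  penalty, combined with configurable weights. Absolute values are not
  comparable to any published scoring function's output.
* an end-point binding energy: intermolecular Lennard-Jones + Coulomb
  (interior dielectric 1), polar solvation from a pairwise generalized-Born
  model (Still-style f_GB, HCT-style pairwise descreened effective radii),
  and nonpolar solvation proportional to the buried solvent-accessible
  surface area (Shrake-Rupley sampling). The entropy contribution is
  omitted throughout.

Per-group electrostatic decomposition (e.g. a nitro group against the
whole receptor) uses the same Coulomb term as the MM part, so group
contributions over an exhaustive partition sum exactly to the reported
electrostatic energy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (COULOMB_K, INTERIOR_DIELECTRIC, PROBE_RADIUS, SASA_GAMMA,
                        SASA_N_POINTS, SOLVENT_DIELECTRIC, XH_BOND_MAX)
from .geometry import sphere_points
from .docking import Pose
from .structures import Structure

logger = logging.getLogger(__name__)

#: default empirical-score weights
DEFAULT_WEIGHTS = {"vdw": 0.004, "hbond": 0.5, "hydrophobic": 0.1, "rotor": 0.5}

#: HCT descreening scale applied to neighbour radii
GB_SCALE = 0.8


@dataclass
class EmpiricalScore:
    vdw_term: float
    hbond_term: float
    hydrophobic_term: float
    rotor_term: float
    weights: dict[str, float]

    @property
    def total(self) -> float:
        w = self.weights
        return (w["vdw"] * self.vdw_term + w["hbond"] * self.hbond_term
                + w["hydrophobic"] * self.hydrophobic_term + w["rotor"] * self.rotor_term)


@dataclass
class MMPBSAReport:
    e_vdw: float
    e_elec: float
    g_polar: float
    g_nonpolar: float
    entropy_included: bool = False

    @property
    def total(self) -> float:
        return self.e_vdw + self.e_elec + self.g_polar + self.g_nonpolar


@dataclass
class GroupElectrostatics:
    group: str
    e_elec_group: float


# ---------------------------------------------------------------------------
# Empirical score
# ---------------------------------------------------------------------------

def _ramp(x: float, full: float, zero: float) -> float:
    """1 on the 'full' side, 0 beyond 'zero', linear in between."""
    if full < zero:  # distance-type ramp
        if x <= full:
            return 1.0
        if x >= zero:
            return 0.0
        return (zero - x) / (zero - full)
    if x >= full:  # angle-type ramp
        return 1.0
    if x <= zero:
        return 0.0
    return (x - zero) / (full - zero)


def _ligand_donors_acceptors(lig):
    donors = []  # (heavy, h)
    has_h: dict[int, bool] = {}
    for i, a in enumerate(lig.atoms):
        if a.element in ("N", "O"):
            hs = [j for j in lig.neighbors(i) if lig.atoms[j].element == "H"]
            has_h[i] = bool(hs)
            donors.extend((i, j) for j in hs)
    acceptors = [i for i, a in enumerate(lig.atoms)
                 if (a.element == "O") or (a.element == "N" and not has_h.get(i, True))]
    return donors, acceptors


def _receptor_donors_acceptors(receptor: Structure):
    atoms = receptor.atoms
    coords = receptor.coords(0)
    res_of = {}
    for res in receptor.residues():
        for a in res.atoms:
            res_of[id(a)] = res
    heavy_no = [i for i, a in enumerate(atoms) if a.element in ("N", "O")]
    donors = []
    has_h = set()
    for hi, h in enumerate(atoms):
        if not h.is_hydrogen:
            continue
        cands = [i for i in heavy_no
                 if res_of[id(atoms[i])] is res_of[id(h)]
                 and np.linalg.norm(coords[i] - coords[hi]) <= XH_BOND_MAX]
        if cands:
            best = min(cands, key=lambda i: np.linalg.norm(coords[i] - coords[hi]))
            donors.append((best, hi))
            has_h.add(best)
    acceptors = [i for i in heavy_no if atoms[i].element == "O" or i not in has_h]
    return donors, acceptors


def hbond_strength(d: float, angle: float,
                   d_full: float = 3.0, d_zero: float = 3.5,
                   a_full: float = 150.0, a_zero: float = 120.0) -> float:
    """Piecewise-linear H-bond strength: 1 at ideal geometry, 0 at cutoffs."""
    return _ramp(d, d_full, d_zero) * _ramp(angle, a_full, a_zero)


def empirical_score(pose: Pose, receptor: Structure,
                    weights: dict[str, float] | None = None) -> EmpiricalScore:
    """Additive empirical score of a placed pose (higher = better).

    vdw_term: negated soft 8-4 contact sum over heavy ligand-receptor
    pairs (positive when favourable); hbond_term: sum of ramp products
    over intermolecular hydrogen bonds in both directions; hydrophobic
    term: count of carbon-carbon contacts within 4.5 Å; rotor_term:
    -0.5 per rotatable bond.
    """
    weights = dict(DEFAULT_WEIGHTS, **(weights or {}))
    lig = pose.ligand
    if any(a.radius <= 0 for a in lig.atoms if not a.is_hydrogen):
        raise ValueError("ligand is not parameterized; call assign_parameters first")
    rec_atoms = receptor.atoms
    rec_coords = receptor.coords(0)

    lig_heavy = lig.heavy_indices()
    rec_heavy = [i for i, a in enumerate(rec_atoms) if not a.is_hydrogen]
    lh_coords = pose.coords_placed[lig_heavy]
    rh_coords = rec_coords[rec_heavy]
    d = cdist(lh_coords, rh_coords)
    eps = np.sqrt(np.outer([lig.atoms[i].lj_epsilon for i in lig_heavy],
                           [rec_atoms[i].lj_epsilon for i in rec_heavy]))
    rmin = np.add.outer([lig.atoms[i].lj_rmin_half for i in lig_heavy],
                        [rec_atoms[i].lj_rmin_half for i in rec_heavy])
    ratio = rmin / np.maximum(d, 0.5)
    # contact term: pairs beyond 8 Å contribute nothing
    contact = eps * (ratio ** 8 - 2.0 * ratio ** 4)
    vdw_term = float(-np.sum(contact[d <= 8.0]))

    hbond = 0.0
    lig_don, lig_acc = _ligand_donors_acceptors(lig)
    rec_don, rec_acc = _receptor_donors_acceptors(receptor)
    for heavy, h in lig_don:
        for acc in rec_acc:
            dd = float(np.linalg.norm(pose.coords_placed[heavy] - rec_coords[acc]))
            if dd > 3.5:
                continue
            u = pose.coords_placed[heavy] - pose.coords_placed[h]
            v = rec_coords[acc] - pose.coords_placed[h]
            ang = float(np.degrees(np.arccos(np.clip(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))))
            hbond += hbond_strength(dd, ang)
    for heavy, h in rec_don:
        for acc in lig_acc:
            dd = float(np.linalg.norm(rec_coords[heavy] - pose.coords_placed[acc]))
            if dd > 3.5:
                continue
            u = rec_coords[heavy] - rec_coords[h]
            v = pose.coords_placed[acc] - rec_coords[h]
            ang = float(np.degrees(np.arccos(np.clip(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))))
            hbond += hbond_strength(dd, ang)

    lig_c = [i for i in lig_heavy if lig.atoms[i].element == "C"]
    rec_c = [i for i in rec_heavy if rec_atoms[i].element == "C"]
    phob = 0.0
    if lig_c and rec_c:
        dc = cdist(pose.coords_placed[lig_c], rec_coords[rec_c])
        phob = float(np.sum(dc <= 4.5))

    rotor_term = -0.5 * lig.n_rotatable
    return EmpiricalScore(vdw_term, hbond, phob, rotor_term, weights)


# ---------------------------------------------------------------------------
# Generalized Born + SASA
# ---------------------------------------------------------------------------

def effective_born_radii(coords: np.ndarray, radii: np.ndarray,
                         scale: float = GB_SCALE) -> np.ndarray:
    """HCT-style pairwise-descreened effective Born radii.

    The intrinsic radius of each atom is its collision radius; every
    neighbour j (radius scaled by ``scale``) descreens atom i through the
    analytic pairwise integral. An isolated atom's effective radius equals
    its intrinsic radius exactly.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    inv_r = 1.0 / radii
    for i in range(n):
        rho_i = radii[i]
        acc = 0.0
        for j in range(n):
            if j == i:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            sr = scale * radii[j]
            if r + sr <= rho_i:
                continue  # neighbour buried inside atom i
            L = rho_i if rho_i > r - sr else r - sr
            U = r + sr
            acc += 0.5 * (
                (1.0 / L - 1.0 / U)
                + (r / 4.0) * (1.0 / U ** 2 - 1.0 / L ** 2)
                + (1.0 / (2.0 * r)) * np.log(L / U)
                + (sr ** 2 / (4.0 * r)) * (1.0 / L ** 2 - 1.0 / U ** 2)
            )
        inv = inv_r[i] - acc
        inv_r[i] = max(inv, 1e-3)  # cap effective radii at 1000 Å
    return 1.0 / inv_r


def gb_polar_energy(coords: np.ndarray, charges: np.ndarray, radii: np.ndarray,
                    solvent_dielectric: float = SOLVENT_DIELECTRIC,
                    scale: float = GB_SCALE) -> float:
    """Generalized-Born polar solvation energy, kcal/mol.

    ΔG = -(k/2)(1 - 1/eps_w) ΣΣ q_i q_j / f_GB with the Still interpolation
    f_GB = sqrt(r² + R_i R_j exp(-r²/(4 R_i R_j))); the i = j terms are the
    Born self-energies, so a single ion reproduces the Born closed form.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    R = effective_born_radii(coords, np.asarray(radii, dtype=float), scale)
    r2 = cdist(coords, coords) ** 2
    RR = np.outer(R, R)
    f = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    qq = np.outer(charges, charges)
    return float(-0.5 * COULOMB_K * (1.0 - 1.0 / solvent_dielectric) * np.sum(qq / f))


def _body_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame fixed to the atom set.

    Principal axes of the coordinate covariance, with signs anchored to the
    first off-centroid atom so the frame co-rotates with the body. Makes
    quadrature grids rigid-motion invariant (up to exactly degenerate
    principal moments, where any consistent frame is returned).
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return np.eye(3)
    centered = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(centered.T @ centered)
    for k in range(3):
        for ref in centered:
            s = float(ref @ vecs[:, k])
            if abs(s) > 1e-8:
                if s < 0:
                    vecs[:, k] = -vecs[:, k]
                break
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = PROBE_RADIUS,
                       n_points: int = SASA_N_POINTS,
                       frame: np.ndarray | None = None) -> float:
    """Solvent-accessible surface area (Å²) by Shrake-Rupley sampling.

    Each atom's solvent sphere (radius + probe) is sampled on a
    deterministic golden-spiral lattice oriented in a body-fixed frame
    (so the area is invariant under global rigid motion); a point is
    accessible when it is outside every other atom's solvent sphere.
    Pass ``frame`` to reuse one orientation across related calculations.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    if frame is None:
        frame = _body_frame(coords)
    unit_pts = sphere_points(n_points) @ frame.T
    total = 0.0
    for i in range(len(radii)):
        pts = coords[i] + radii[i] * unit_pts
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(radii)):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) >= radii[i] + radii[j]:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= radii[j] ** 2
        total += 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return float(total)


def _mm_terms(pose: Pose, receptor: Structure,
              dielectric: float = INTERIOR_DIELECTRIC) -> tuple[float, float]:
    lig = pose.ligand
    r = cdist(pose.coords_placed, receptor.coords(0))
    if np.any(r < 1e-6):
        raise FloatingPointError("overlapping ligand/receptor atoms; minimize or filter first")
    eps = np.sqrt(np.outer([a.lj_epsilon for a in lig.atoms],
                           [a.lj_epsilon for a in receptor.atoms]))
    rmin = np.add.outer([a.lj_rmin_half for a in lig.atoms],
                        [a.lj_rmin_half for a in receptor.atoms])
    ratio = rmin / r
    e_vdw = float(np.sum(eps * (ratio ** 12 - 2.0 * ratio ** 6)))
    qq = np.outer([a.charge for a in lig.atoms], [a.charge for a in receptor.atoms])
    e_elec = float(COULOMB_K / dielectric * np.sum(qq / r))
    return e_vdw, e_elec


def mmpbsa_energy(pose: Pose, receptor: Structure,
                  solvent_dielectric: float = SOLVENT_DIELECTRIC,
                  sasa_gamma: float = SASA_GAMMA,
                  n_sasa_points: int = SASA_N_POINTS) -> MMPBSAReport:
    """End-point binding energy of a pose (entropy omitted).

    e_vdw / e_elec: intermolecular force-field terms at interior
    dielectric 1. g_polar: ΔG_GB(complex) - ΔG_GB(receptor) - ΔG_GB(ligand).
    g_nonpolar: γ·ΔSASA over heavy atoms with identical sampling grids for
    complex and parts (the per-state offset cancels in the difference).
    """
    if pose.clash_count not in (0,):
        logger.info("scoring a pose that was not clash-filtered/minimized "
                    "(clash_count=%s)", pose.clash_count)
    e_vdw, e_elec = _mm_terms(pose, receptor)

    lig = pose.ligand
    lc = pose.coords_placed
    lq = np.array([a.charge for a in lig.atoms])
    lr = np.array([max(a.radius, 1.0) for a in lig.atoms])
    rc = receptor.coords(0)
    ratoms = receptor.atoms
    rq = np.array([a.charge for a in ratoms])
    rr = np.array([max(a.radius, 1.0) for a in ratoms])

    gb_l = gb_polar_energy(lc, lq, lr, solvent_dielectric)
    gb_r = gb_polar_energy(rc, rq, rr, solvent_dielectric)
    gb_c = gb_polar_energy(np.vstack([rc, lc]), np.concatenate([rq, lq]),
                           np.concatenate([rr, lr]), solvent_dielectric)
    g_polar = gb_c - gb_r - gb_l

    lig_heavy = lig.heavy_indices()
    rec_heavy = [i for i, a in enumerate(ratoms) if not a.is_hydrogen]
    lhc, lhr = lc[lig_heavy], np.array([lig.atoms[i].radius for i in lig_heavy])
    rhc, rhr = rc[rec_heavy], np.array([ratoms[i].radius for i in rec_heavy])
    # one sampling orientation (the complex's body frame) for all three
    # states, so quadrature error cancels in the difference
    frame = _body_frame(np.vstack([rhc, lhc]))
    s_l = shrake_rupley_sasa(lhc, lhr, n_points=n_sasa_points, frame=frame)
    s_r = shrake_rupley_sasa(rhc, rhr, n_points=n_sasa_points, frame=frame)
    s_c = shrake_rupley_sasa(np.vstack([rhc, lhc]), np.concatenate([rhr, lhr]),
                             n_points=n_sasa_points, frame=frame)
    g_nonpolar = sasa_gamma * (s_c - s_r - s_l)
    return MMPBSAReport(e_vdw, e_elec, g_polar, g_nonpolar, entropy_included=False)


def group_electrostatics(pose: Pose, receptor: Structure,
                         groups: dict[str, list[int]],
                         dielectric: float = INTERIOR_DIELECTRIC
                         ) -> list[GroupElectrostatics]:
    """Coulomb energy of named ligand atom groups against the whole receptor.

    Uses the same dielectric as the MM electrostatic term, so groups that
    partition all ligand atoms sum exactly to the MM e_elec. Overlapping
    groups are rejected.
    """
    seen: set[int] = set()
    for name, idxs in groups.items():
        dup = seen.intersection(idxs)
        if dup:
            raise ValueError(f"atoms {sorted(dup)} assigned to more than one group")
        seen.update(idxs)
    rc = receptor.coords(0)
    rq = np.array([a.charge for a in receptor.atoms])
    out = []
    for name, idxs in groups.items():
        if not idxs:
            out.append(GroupElectrostatics(name, 0.0))
            continue
        lc = pose.coords_placed[list(idxs)]
        lq = np.array([pose.ligand.atoms[i].charge for i in idxs])
        r = cdist(lc, rc)
        e = float(COULOMB_K / dielectric * np.sum(np.outer(lq, rq) / r))
        out.append(GroupElectrostatics(name, e))
    return out


def remainder_group(ligand, groups: dict[str, list[int]],
                    name: str = "rest") -> dict[str, list[int]]:
    """Extend a group mapping with the remaining ligand atoms."""
    assigned = {i for idxs in groups.values() for i in idxs}
    rest = [i for i in range(len(ligand.atoms)) if i not in assigned]
    out = dict(groups)
    out[name] = rest
    return out
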
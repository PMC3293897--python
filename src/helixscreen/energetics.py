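"""Per-residue inter-chain interaction energies and hot-spot ranking.

The interaction between two residues on opposite chains is the pairwise
Lennard-Jones plus Coulomb energy over all atom pairs, with no distance
cutoff. Energies are averaged over an ensemble of coordinate frames and
aggregated per residue against the complete opposite chain; the most
negative totals, combined with hydrogen-bond occupancy and (optionally)
sequence conservation, select interface hot spots.

No 1-4 or intra-residue exclusions apply: all pairs are inter-chain, so
the residues never share bonds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_K, HBOND_ANGLE_MIN, HBOND_DIST_MAX, XH_BOND_MAX
from .structures import Residue, Structure


class DielectricModel:
    """Dielectric screening for the Coulomb term.

    ``DielectricModel("4r")`` gives the distance-dependent default
    eps(r) = 4r; ``DielectricModel(constant=1.0)`` a constant dielectric.
    """

    def __init__(self, kind: str = "4r", constant: float | None = None, factor: float = 4.0):
        if constant is not None:
            kind = "constant"
        if kind not in ("4r", "constant"):
            raise ValueError(f"unknown dielectric model {kind!r}")
        self.kind = kind
        self.factor = factor
        self.constant = constant if constant is not None else 1.0

    def screening(self, r: np.ndarray) -> np.ndarray:
        """eps(r)·r — the full denominator divided by r is eps(r)."""
        if self.kind == "4r":
            return self.factor * r
        return self.constant * np.ones_like(r)

    def describe(self) -> str:
        return f"eps(r)={self.factor:g}r" if self.kind == "4r" else f"eps={self.constant:g}"


@dataclass
class ResiduePairEnergy:
    res_a: tuple[str, int]
    res_b: tuple[str, int]
    e_vdw: float
    e_elec: float
    sd_total: float = 0.0

    @property
    def e_total(self) -> float:
        return self.e_vdw + self.e_elec


@dataclass
class InterfaceMatrix:
    rows: list[tuple[str, int]]
    cols: list[tuple[str, int]]
    entries: dict[tuple[tuple[str, int], tuple[str, int]], ResiduePairEnergy]
    per_residue_totals: dict[tuple[str, int], float] = field(default_factory=dict)

    def entry(self, row: tuple[str, int], col: tuple[str, int]) -> ResiduePairEnergy:
        return self.entries[(row, col)]

    def total(self) -> float:
        return sum(p.e_total for p in self.entries.values())

    def as_array(self, term: str = "total") -> np.ndarray:
        out = np.zeros((len(self.rows), len(self.cols)))
        for i, r in enumerate(self.rows):
            for j, c in enumerate(self.cols):
                p = self.entries[(r, c)]
                out[i, j] = {"total": p.e_total, "vdw": p.e_vdw, "elec": p.e_elec}[term]
        return out


@dataclass
class HBondEvent:
    donor_heavy: str
    hydrogen: str
    acceptor: str
    donor_res: tuple[str, int]
    acceptor_res: tuple[str, int]
    distance: float
    angle: float
    frame: int


@dataclass
class HotspotReport:
    ranked: list[dict]
    criteria: dict


def _pair_terms(coords_a, coords_b, q_a, q_b, eps_a, eps_b, rmh_a, rmh_b,
                dielectric: DielectricModel) -> tuple[float, float]:
    r = cdist(coords_a, coords_b)
    if np.any(r < 1e-6):
        ii, jj = np.unravel_index(int(np.argmin(r)), r.shape)
        raise FloatingPointError(
            f"overlapping atoms (pair {ii}, {jj}; r = {r[ii, jj]:.2e} Å); cannot evaluate energies"
        )
    eps_ij = np.sqrt(np.outer(eps_a, eps_b))
    rmin_ij = np.add.outer(rmh_a, rmh_b)
    with np.errstate(divide="ignore"):
        ratio = np.where(rmin_ij > 0, rmin_ij / r, 0.0)
    e_vdw = float(np.sum(eps_ij * (ratio ** 12 - 2.0 * ratio ** 6)))
    e_elec = float(COULOMB_K * np.sum(np.outer(q_a, q_b) / (dielectric.screening(r) * r)))
    return e_vdw, e_elec


def pair_energy(res_a: Residue, res_b: Residue, frame: np.ndarray | None = None,
                dielectric: DielectricModel | None = None,
                coords_a: np.ndarray | None = None,
                coords_b: np.ndarray | None = None) -> tuple[float, float]:
    """Lennard-Jones and Coulomb energy (kcal/mol) between two residues.

    All atom pairs, no cutoff. eps_ij = sqrt(eps_i eps_j),
    rmin_ij = rmin_half_i + rmin_half_j; Coulomb constant 332.0637.
    Coordinates default to the atoms' own (frame-0) positions; pass
    ``coords_a``/``coords_b`` to evaluate a different frame.
    """
    dielectric = dielectric or DielectricModel()
    if res_a.chain_id == res_b.chain_id:
        raise ValueError("pair_energy is defined for residues on different chains")
    if coords_a is None:
        coords_a = np.array([a.coords for a in res_a.atoms])
    if coords_b is None:
        coords_b = np.array([a.coords for a in res_b.atoms])
    return _pair_terms(
        coords_a, coords_b,
        np.array([a.charge for a in res_a.atoms]),
        np.array([a.charge for a in res_b.atoms]),
        np.array([a.lj_epsilon for a in res_a.atoms]),
        np.array([a.lj_epsilon for a in res_b.atoms]),
        np.array([a.lj_rmin_half for a in res_a.atoms]),
        np.array([a.lj_rmin_half for a in res_b.atoms]),
        dielectric,
    )


def interface_matrix(structure: Structure, chain_a: str, chain_b: str,
                     frames: list[int] | None = None,
                     dielectric: DielectricModel | None = None) -> InterfaceMatrix:
    """Ensemble-averaged residue-pair energies of chain A against chain B.

    Entries are means over the selected frames (default: all); sd_total is
    the standard deviation of the per-frame totals. Residues are ordered
    by (chain, residue number). Per-residue totals sum each residue's row
    or column across the complete opposite chain.
    """
    if chain_a == chain_b:
        raise ValueError("interface requires two distinct chains")
    dielectric = dielectric or DielectricModel()
    if frames is None:
        frames = list(range(structure.n_frames))
    if not frames:
        raise ValueError("empty frame selection")
    idx = structure.atom_indices()
    res_a = sorted(structure.residues(chain_a), key=lambda r: r.number)
    res_b = sorted(structure.residues(chain_b), key=lambda r: r.number)

    def cols_of(res: Residue) -> list[int]:
        return [idx[id(a)] for a in res.atoms]

    entries = {}
    for ra in res_a:
        ca = cols_of(ra)
        for rb in res_b:
            cb = cols_of(rb)
            vdw_frames, elec_frames = [], []
            for k in frames:
                fr = structure.frames[k]
                v, e = pair_energy(ra, rb, dielectric=dielectric,
                                   coords_a=fr[ca], coords_b=fr[cb])
                vdw_frames.append(v)
                elec_frames.append(e)
            totals = np.array(vdw_frames) + np.array(elec_frames)
            entries[(ra.key, rb.key)] = ResiduePairEnergy(
                ra.key, rb.key,
                e_vdw=float(np.mean(vdw_frames)),
                e_elec=float(np.mean(elec_frames)),
                sd_total=float(np.std(totals)),
            )
    totals: dict[tuple[str, int], float] = {}
    for ra in res_a:
        totals[ra.key] = sum(entries[(ra.key, rb.key)].e_total for rb in res_b)
    for rb in res_b:
        totals[rb.key] = sum(entries[(ra.key, rb.key)].e_total for ra in res_a)
    return InterfaceMatrix([r.key for r in res_a], [r.key for r in res_b], entries, totals)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _donors_acceptors(structure: Structure):
    """Rule-based donors (N/O with a covalently bonded H) and acceptors
    (O always; N only when it carries no H). Bonded hydrogens are found by
    distance (X-H <= 1.25 Å) since protein structures carry no bond list."""
    atoms = structure.atoms
    idx = structure.atom_indices()
    res_of = {}
    for res in structure.residues():
        for a in res.atoms:
            res_of[id(a)] = res
    coords = structure.coords(0)
    heavy_no = [(i, a) for i, a in enumerate(atoms) if a.element in ("N", "O")]
    hydrogens = [(i, a) for i, a in enumerate(atoms) if a.is_hydrogen]
    if heavy_no and not hydrogens:
        raise ValueError(
            "structure has no hydrogens; hydrogen-bond detection needs explicit-H input"
        )
    donors = []  # (heavy_idx, h_idx)
    has_h = set()
    for hi, h in hydrogens:
        best, best_d = None, XH_BOND_MAX
        for i, a in heavy_no:
            if res_of[id(a)] is not res_of[id(h)]:
                continue
            d = float(np.linalg.norm(coords[i] - coords[hi]))
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            donors.append((best, hi))
            has_h.add(best)
    acceptors = [i for i, a in heavy_no if a.element == "O" or i not in has_h]
    return donors, acceptors, res_of


def detect_hbonds(structure: Structure, frames: list[int] | None = None,
                  dist_max: float = HBOND_DIST_MAX,
                  angle_min: float = HBOND_ANGLE_MIN,
                  inter_chain_only: bool = True
                  ) -> tuple[list[HBondEvent], dict[tuple, float]]:
    """Geometric hydrogen bonds per frame plus per-pair occupancies.

    An event is recorded when donor-heavy -> acceptor distance <= dist_max
    and the donor-H-acceptor angle at the hydrogen >= angle_min. Occupancy
    is the fraction of selected frames in which a given
    (donor atom, acceptor atom) pair bonds.
    """
    if frames is None:
        frames = list(range(structure.n_frames))
    if not frames:
        raise ValueError("empty frame selection")
    atoms = structure.atoms
    donors, acceptors, res_of = _donors_acceptors(structure)
    events: list[HBondEvent] = []
    counts: dict[tuple, int] = {}
    for k in frames:
        fr = structure.frames[k]
        for d_heavy, d_h in donors:
            for acc in acceptors:
                if acc == d_heavy:
                    continue
                r_d = res_of[id(atoms[d_heavy])]
                r_a = res_of[id(atoms[acc])]
                if r_d is r_a:
                    continue
                if inter_chain_only and r_d.chain_id == r_a.chain_id:
                    continue
                dist = float(np.linalg.norm(fr[d_heavy] - fr[acc]))
                if dist > dist_max:
                    continue
                u = fr[d_heavy] - fr[d_h]
                v = fr[acc] - fr[d_h]
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if ang < angle_min:
                    continue
                key = (
                    (r_d.chain_id, r_d.number, atoms[d_heavy].name),
                    (r_a.chain_id, r_a.number, atoms[acc].name),
                )
                counts[key] = counts.get(key, 0) + 1
                events.append(HBondEvent(
                    donor_heavy=atoms[d_heavy].name, hydrogen=atoms[d_h].name,
                    acceptor=atoms[acc].name, donor_res=r_d.key, acceptor_res=r_a.key,
                    distance=dist, angle=ang, frame=k,
                ))
    occupancy = {key: c / len(frames) for key, c in counts.items()}
    return events, occupancy


def rank_hotspots(matrix: InterfaceMatrix, hbond_occupancy: dict[tuple, float],
                  conservation: dict[tuple[str, int], float] | None = None,
                  energy_max: float = -2.0, occupancy_min: float = 0.5,
                  conservation_min: float = 0.5,
                  chain: str | None = None) -> HotspotReport:
    """Rank residues by their total interaction energy with the opposite
    chain and flag hot-spot candidates.

    A residue is flagged when its mean energy <= energy_max AND it holds a
    hydrogen bond with occupancy >= occupancy_min (or its energy alone is
    twice the threshold, covering purely electrostatic/hydrophobic spots)
    AND, when a conservation map is supplied, conservation >=
    conservation_min. Ties in energy break by (occupancy desc, residue
    number asc).
    """
    keys = matrix.rows + matrix.cols
    if chain is not None:
        keys = [k for k in keys if k[0] == chain]
    res_occ: dict[tuple[str, int], float] = {}
    for (don, acc), occ in hbond_occupancy.items():
        for ckey in (don[:2], acc[:2]):
            res_occ[ckey] = max(res_occ.get(ckey, 0.0), occ)
    rows = []
    for key in keys:
        energy = matrix.per_residue_totals[key]
        occ = res_occ.get(key, 0.0)
        cons = conservation.get(key) if conservation else None
        passes = energy <= energy_max and (occ >= occupancy_min or energy <= 2 * energy_max)
        if conservation is not None:
            passes = passes and (cons is not None and cons >= conservation_min)
        rows.append({
            "residue": key, "energy": energy, "occupancy": occ,
            "conservation": cons if conservation is not None else "not evaluated",
            "hotspot": bool(passes),
        })
    rows.sort(key=lambda r: (r["energy"], -r["occupancy"], r["residue"][1]))
    return HotspotReport(
        ranked=rows,
        criteria={"energy_max": energy_max, "occupancy_min": occupancy_min,
                  "conservation_min": conservation_min},
    )
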
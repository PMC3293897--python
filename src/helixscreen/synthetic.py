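"""Deterministic generators for toy interfaces, ensembles and libraries.

The pipeline's fixtures are generated, never shipped: a two-helix
antiparallel coiled dimer with planted hydrogen-bond / salt-bridge
contacts and a hydrophobic patch (the Gln-donor / Lys-donor /
Glu-acceptor pattern of a transketolase-like dimer interface), Gaussian
jittered coordinate ensembles standing in for MD production frames, and
ligand libraries whose actives satisfy a reference pharmacophore by
construction while decoys violate it by construction.

Every generator is a pure function of its spec and seed. Side chains are
reduced pseudo-atom models (3-4 atoms) — enough to realize donors,
acceptors, charges and hydrophobic contacts geometrically; they are not
rotamer-accurate chemistry, and jitter is not dynamics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import unit
from .pharmacophore import Pharmacophore
from .structures import (Atom, Ligand, ParameterTable, Residue, Structure,
                         assign_parameters, builtin_protein_table)

HELIX_RISE = 1.5      # Å per residue
HELIX_TWIST = 100.0   # degrees per residue
HELIX_RADIUS = 2.3    # Å, C-alpha radius


@dataclass
class DimerSpec:
    """Layout of the synthetic antiparallel two-helix dimer.

    ``planted_contacts`` lists (donor residue kind, acceptor residue kind,
    target donor-heavy to acceptor N···O distance in Å); the default is
    the Gln->Glu and Lys->Glu pattern, realized symmetrically on both
    chains against a single shared glutamate acceptor.
    """

    n_res_per_helix: int = 11
    planted_contacts: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("GLN", "GLU", 2.9), ("LYS", "GLU", 2.9)])
    hydrophobic_patch: bool = True
    seed: int = 0
    helix_separation: float = 11.0
    start_number: int = 200

    def __post_init__(self) -> None:
        if self.n_res_per_helix < 8:
            raise ValueError("need at least 8 residues per helix")
        if len(self.planted_contacts) > 2:
            raise ValueError("at most 2 planted contacts share the glutamate acceptor")


@dataclass
class LibrarySpec:
    """Composition of the synthetic screening library."""

    n_actives: int = 10
    n_decoys: int = 40
    displacement_for_decoys: float = 3.5
    seed: int = 0
    noise: float = 0.15  # per-coordinate uniform feature noise on actives, Å


# ---------------------------------------------------------------------------
# Toy dimer
# ---------------------------------------------------------------------------

#: donor-residue atom layouts: (name, element, offset along contact axis)
_DONOR_ATOMS = {
    "GLN": [("CB", "C", 1.5), ("NE2", "N", 2.6), ("HE21", "H", 3.6)],
    "LYS": [("CB", "C", 1.5), ("NZ", "N", 2.6), ("HZ1", "H", 3.6)],
}
_ACCEPTOR_OXYGENS = {"GLU": ("OE1", "OE2", "CD", "CB"), "ASP": ("OD1", "OD2", "CG", "CB")}


def _helix_ca(k: int, chain: str, spec: DimerSpec) -> np.ndarray:
    theta = np.deg2rad(HELIX_TWIST * k + (60.0 if chain == "B" else 0.0))
    x = HELIX_RADIUS * np.cos(theta)
    y = HELIX_RADIUS * np.sin(theta)
    if chain == "A":
        return np.array([x, y, HELIX_RISE * k])
    z_off = HELIX_RISE * (spec.n_res_per_helix - 1)
    return np.array([spec.helix_separation + x, y, z_off - HELIX_RISE * k])


def _axis_outward(ca: np.ndarray, chain: str, spec: DimerSpec) -> np.ndarray:
    x0 = 0.0 if chain == "A" else spec.helix_separation
    radial = np.array([ca[0] - x0, ca[1], 0.0])
    return unit(radial)


def make_toy_dimer(spec: DimerSpec | None = None) -> tuple[Structure, ParameterTable]:
    """Two ideal antiparallel helices with planted inter-chain contacts.

    Donor residues occupy positions 3, 4, ... from the helix start, the
    shared glutamate acceptor position 7, the hydrophobic leucine position
    6; everything else is alanine (glycine last). Contact geometry is
    exact by construction: the donor heavy atom, its hydrogen and the
    acceptor oxygen are collinear at the target distance. All atoms are
    parameterized from the built-in table before return.
    """
    spec = spec or DimerSpec()
    n = spec.n_res_per_helix
    donor_kinds = [c[0] for c in spec.planted_contacts]
    acceptor_kind = spec.planted_contacts[0][1] if spec.planted_contacts else None
    donor_pos = {3 + i: kind for i, kind in enumerate(donor_kinds)}
    acceptor_pos = 7
    leu_pos = 6 if spec.hydrophobic_patch else None

    def seq(k: int) -> str:
        if k in donor_pos:
            return donor_pos[k]
        if spec.planted_contacts and k == acceptor_pos:
            return acceptor_kind
        if leu_pos is not None and k == leu_pos:
            return "LEU"
        return "GLY" if k == n - 1 else "ALA"

    # sanity of the contact span: donor chain CA -> acceptor antecedent
    for _, _, d in spec.planted_contacts:
        ca_a = _helix_ca(3, "A", spec)
        ca_b = _helix_ca(acceptor_pos, "B", spec)
        span = float(np.linalg.norm(ca_b - ca_a))
        reach = 2.6 + d + 1.3
        if not (0.5 <= span - reach <= 6.0):
            raise ValueError(
                f"planted contact at {d} Å is unrealizable at helix separation "
                f"{spec.helix_separation} Å (CA span {span:.1f} Å)")

    serial = [1]

    def atom(name: str, element: str, xyz: np.ndarray) -> Atom:
        a = Atom(serial[0], name, element, np.asarray(xyz, dtype=float))
        serial[0] += 1
        return a

    chains: dict[str, list[Residue]] = {"A": [], "B": []}
    # first pass: CA positions and default side chains
    ca_pos = {(c, k): _helix_ca(k, c, spec) for c in "AB" for k in range(n)}
    # donor atom coordinates per chain (needed to anchor acceptor oxygens)
    donor_geom: dict[tuple[str, int], dict] = {}
    # each contact aims at a laterally offset target near the acceptor CA so
    # that the two realized oxygens (and the incoming donor arms) stay apart
    n_contacts = max(len(spec.planted_contacts), 1)
    for c in "AB":
        other = "B" if c == "A" else "A"
        # offsets follow the donors' own z-order so the contact arms run in
        # parallel instead of crossing
        by_z = sorted(donor_pos, key=lambda p: ca_pos[(c, p)][2])
        lateral = {p: (i - (n_contacts - 1) / 2.0) * 2.8
                   for i, p in enumerate(by_z)}
        for k, kind in donor_pos.items():
            target = ca_pos[(other, acceptor_pos)] + np.array([0.0, 0.0, lateral[k]])
            u = unit(target - ca_pos[(c, k)])
            donor_geom[(c, k)] = {
                "u": u,
                "atoms": [(nm, el, ca_pos[(c, k)] + off * u)
                          for nm, el, off in _DONOR_ATOMS[kind]],
            }

    for c in "AB":
        other = "B" if c == "A" else "A"
        for k in range(n):
            name = seq(k)
            ca = ca_pos[(c, k)]
            atoms = [atom("CA", "C", ca)]
            out = _axis_outward(ca, c, spec)
            if (c, k) in donor_geom:
                for nm, el, xyz in donor_geom[(c, k)]["atoms"]:
                    atoms.append(atom(nm, el, xyz))
            elif spec.planted_contacts and k == acceptor_pos:
                o1n, o2n, cdn, cbn = _ACCEPTOR_OXYGENS[acceptor_kind]
                # oxygens sit on the incoming donors' axes at the target dist
                opos, odirs = [], []
                for (dk, _, d), (dc, dkpos) in zip(
                        spec.planted_contacts,
                        [(other, p) for p in sorted(donor_pos)]):
                    g = donor_geom[(dc, dkpos)]
                    heavy = g["atoms"][1][2]  # NE2/NZ position
                    opos.append(heavy + d * g["u"])
                    odirs.append(g["u"])
                if len(opos) == 1:
                    opos.append(opos[0] + np.array([0.0, 2.2, 0.0]))
                    odirs.append(odirs[0])
                # antecedent carbon sits well behind both oxygens relative
                # to their incoming donors, so each lone-pair axis (O - CD
                # reversed) points back into the interface space
                mid = np.mean(opos, axis=0)
                u_avg = unit(np.mean(odirs, axis=0))
                cd = mid + 2.0 * u_avg
                cb = ca + 1.5 * unit(cd - ca)
                atoms.append(atom(cbn, "C", cb))
                atoms.append(atom(cdn, "C", cd))
                atoms.append(atom(o1n, "O", opos[0]))
                atoms.append(atom(o2n, "O", opos[1]))
            elif name == "LEU":
                # terminal carbons reach toward the partner leucine
                target = (ca_pos[(c, k)] + ca_pos[(other, k)]) / 2.0
                u = unit(target - ca)
                span = float(np.linalg.norm(ca_pos[(other, k)] - ca))
                tip = (span - 4.0) / 2.0
                atoms.append(atom("CB", "C", ca + 1.5 * u))
                atoms.append(atom("CG", "C", ca + max(2.4, tip - 1.15) * u))
                atoms.append(atom("CD1", "C", ca + max(3.0, tip) * u))
            elif name == "ALA":
                atoms.append(atom("CB", "C", ca + 1.5 * out))
            chains[c].append(Residue(c, spec.start_number + k, name, atoms))

    structure = Structure(chains)
    table = builtin_protein_table()
    assign_parameters(structure, table)
    return structure, table


def jitter_ensemble(structure: Structure, sigma: float, n_frames: int,
                    seed: int = 0) -> Structure:
    """Gaussian-jittered coordinate ensemble (frame 0 = unjittered reference).

    Frame k >= 1 adds i.i.d. N(0, sigma²) noise per coordinate to the
    reference frame. A stand-in for MD production frames, not dynamics.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    ref = structure.frames[0]
    frames = [ref.copy()]
    for _ in range(max(n_frames - 1, 0)):
        frames.append(ref + rng.normal(0.0, sigma, size=ref.shape))
    chains = {cid: residues for cid, residues in structure.chains.items()}
    out = Structure(chains, frames)
    return out


# ---------------------------------------------------------------------------
# Ligand library
# ---------------------------------------------------------------------------

def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(unit(v), ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))


class _MolBuilder:
    def __init__(self) -> None:
        self.elements: list[str] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int, float]] = []
        self.formal: dict[int, int] = {}

    def add(self, element: str, xyz: np.ndarray, formal: int = 0) -> int:
        self.elements.append(element)
        self.coords.append(np.asarray(xyz, dtype=float))
        if formal:
            self.formal[len(self.elements) - 1] = formal
        return len(self.elements) - 1

    def bond(self, i: int, j: int, order: float = 1.0) -> None:
        self.bonds.append((i, j, order))

    def n_bonds(self, i: int) -> int:
        return sum(1 for a, b, _ in self.bonds if i in (a, b))

    def build(self, name: str, groups: dict[str, list[int]]) -> Ligand:
        atoms = [Atom(i + 1, f"{el}{i + 1}", el, xyz,
                      formal_charge=self.formal.get(i, 0))
                 for i, (el, xyz) in enumerate(zip(self.elements, self.coords))]
        return Ligand(name, atoms, list(self.bonds),
                      [np.array(self.coords)], groups=groups)


def _feature_direction(feat, centroid: np.ndarray) -> np.ndarray:
    """Outward direction at a feature: its provenance axis (which points
    away from the protein for interface-derived models), or away from the
    model centroid when no axis is stored."""
    if feat.direction is not None:
        return unit(feat.direction)
    v = feat.position - centroid
    n = np.linalg.norm(v)
    return v / n if n > 1e-6 else np.array([0.0, 0.0, 1.0])


def _build_ligand(name: str, model: Pharmacophore, rng: np.random.Generator,
                  noise: float, displaced: list[int] | None = None,
                  displacement: float = 0.0, kill_donors: bool = False,
                  neutral_tail: bool = False) -> Ligand:
    """Assemble one rigid valence-correct molecule around the model points.

    displaced: model feature indices whose realizing atoms are moved by
    ``displacement`` Å in a random direction. kill_donors replaces the
    donor nitrogens by ether oxygens (no HD features). neutral_tail
    replaces the nitro group by a methyl (zero-charge tail), emulating a
    derivative that lacks the charged-group contact.
    """
    centroid = model.positions.mean(axis=0)
    b = _MolBuilder()
    cc = b.add("C", centroid)
    linker = cc

    def attach(i: int) -> None:
        nonlocal linker
        if b.n_bonds(linker) >= 4:
            new = b.add("C", b.coords[linker] + np.array([0.0, 0.0, 1.4]))
            b.bond(linker, new)
            linker = new
        b.bond(linker, i)

    def site(k: int) -> np.ndarray:
        pos = model.features[k].position + rng.uniform(-noise, noise, 3)
        if displaced and k in displaced:
            v = rng.normal(size=3)
            pos = pos + displacement * (v / np.linalg.norm(v))
        return pos

    hd_idx = [k for k, f in enumerate(model.features) if f.kind == "HD"]
    ha_idx = [k for k, f in enumerate(model.features) if f.kind == "HA"]
    hy_idx = [k for k, f in enumerate(model.features) if f.kind == "HY"]
    groups: dict[str, list[int]] = {}

    # urea-like donor pairs (or ether oxygens for kind-swapped decoys)
    for p in range(0, len(hd_idx), 2):
        pair = hd_idx[p:p + 2]
        npos = [site(k) for k in pair]
        dirs = [_feature_direction(model.features[k], centroid) for k in pair]
        n_atoms = []
        for j, (pos, d) in enumerate(zip(npos, dirs)):
            if kill_donors:
                i = b.add("O", pos)
            else:
                i = b.add("N", pos)
                h1 = b.add("H", pos - 1.0 * d)  # H points at the protein acceptor
                b.bond(i, h1)
                if j > 0:  # the first N links to the scaffold instead
                    h2 = b.add("H", pos + 1.0 * _perp(d))
                    b.bond(i, h2)
            n_atoms.append(i)
        mid = np.mean([b.coords[i] for i in n_atoms], axis=0)
        davg = unit(np.mean(dirs, axis=0))
        c0 = b.add("C", mid + 1.2 * davg)
        o0 = b.add("O", mid + 2.4 * davg)
        b.bond(c0, o0, 2.0)
        for i in n_atoms:
            b.bond(c0, i)
        attach(n_atoms[0])

    # acceptors: the lysine-facing one is a nitro (or methyl tail), the
    # rest are aldehyde carbonyls
    nitro_k = None
    for k in ha_idx:
        if "LYS" in model.features[k].source or "NZ" in model.features[k].source:
            nitro_k = k
    if nitro_k is None and ha_idx:
        nitro_k = ha_idx[-1]
    for k in ha_idx:
        pos = site(k)
        d = _feature_direction(model.features[k], centroid)
        if k == nitro_k:
            if neutral_tail:
                c3 = b.add("C", pos)
                for w in (d, _perp(d), -_perp(d)):
                    h = b.add("H", pos + 1.0 * w)
                    b.bond(c3, h)
                attach(c3)
                groups["nitro"] = [c3, c3 + 1, c3 + 2, c3 + 3]
            else:
                o1 = b.add("O", pos)
                n3 = b.add("N", pos + 1.2 * d, formal=1)
                o2 = b.add("O", b.coords[n3] + 1.2 * unit(d + 1.2 * _perp(d)),
                           formal=-1)
                b.bond(n3, o1, 2.0)
                b.bond(n3, o2, 1.0)
                attach(n3)
                groups["nitro"] = [o1, n3, o2]
        else:
            o3 = b.add("O", pos)
            c4 = b.add("C", pos + 1.25 * d)
            h4 = b.add("H", b.coords[c4] + 1.0 * _perp(d))
            b.bond(c4, o3, 2.0)
            b.bond(c4, h4)
            attach(c4)

    # hydrophobic: kekulized benzene with centroid at the feature point
    for k in hy_idx:
        pos = site(k)
        d = _feature_direction(model.features[k], centroid)
        e1, e2 = _perp(d), unit(np.cross(d, _perp(d)))
        ring = []
        for t in range(6):
            ang = np.deg2rad(60.0 * t)
            ring.append(b.add("C", pos + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2)))
        for t in range(6):
            b.bond(ring[t], ring[(t + 1) % 6], 2.0 if t % 2 == 0 else 1.0)
        for t in range(1, 6):
            rv = unit(b.coords[ring[t]] - pos)
            h = b.add("H", b.coords[ring[t]] + 1.0 * rv)
            b.bond(ring[t], h)
        attach(ring[0])

    return b.build(name, groups)


def _scatter(lig: Ligand, rng: np.random.Generator) -> None:
    """Random rigid transform of all conformers (moves the library away
    from the binding site; matching is superposition-invariant)."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-20.0, 20.0, 3) + np.array([0.0, 0.0, 40.0])
    for k, conf in enumerate(lig.conformers):
        c = conf.mean(axis=0)
        lig.conformers[k] = (conf - c) @ rot.T + c + t
    for a, xyz in zip(lig.atoms, lig.conformers[0]):
        a.coords = xyz.copy()


def make_ligand_library(spec: LibrarySpec, model: Pharmacophore,
                        scatter: bool = True) -> list[Ligand]:
    """Actives that satisfy the model by construction plus decoys that
    violate it by construction.

    Actives realize every model feature within the noise bound. Half of
    the decoys are kind-swapped (donor nitrogens replaced by ethers, so no
    HD feature exists and no kind-compatible assignment is possible); the
    other half displace two feature-realizing groups by
    ``displacement_for_decoys`` Å. Each ligand gets a second, rigidly
    rotated conformer, and the whole library is rigidly scattered away
    from the site (disable with ``scatter=False`` for in-place poses).
    """
    if len(model.features) < 3:
        raise ValueError("model must have at least 3 features")
    rng = np.random.default_rng(spec.seed)
    ligands: list[Ligand] = []
    for i in range(spec.n_actives):
        ligands.append(_build_ligand(f"ACT-{i + 1:03d}", model, rng, spec.noise))
    n_kind = spec.n_decoys // 2
    for i in range(n_kind):
        ligands.append(_build_ligand(f"DECK-{i + 1:03d}", model, rng, spec.noise,
                                     kill_donors=True))
    hd_idx = [k for k, f in enumerate(model.features) if f.kind == "HD"]
    hy_idx = [k for k, f in enumerate(model.features) if f.kind == "HY"]
    move = (hy_idx[:1] + hd_idx[:1]) or [0, 1]
    from .pharmacophore import match_pharmacophore, type_ligand_features
    for i in range(spec.n_decoys - n_kind):
        # the displacement must defeat the matcher by construction: verify,
        # and grow the displacement if optimal superposition absorbs it
        displacement = spec.displacement_for_decoys
        for _attempt in range(6):
            lig = _build_ligand(f"DECD-{i + 1:03d}", model, rng, spec.noise,
                                displaced=move, displacement=displacement)
            mr = match_pharmacophore(type_ligand_features(lig, 0), model)
            if not mr.accepted:
                break
            displacement *= 1.5
        else:
            raise RuntimeError("could not construct a matcher-rejected decoy")
        ligands.append(lig)
    for lig in ligands:
        # second conformer: rigid rotation of the first (same molecule)
        conf = lig.conformers[0]
        c = conf.mean(axis=0)
        from .geometry import rotation_about_axis
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 45.0)
        lig.conformers.append((conf - c) @ rot.T + c)
        if scatter:
            _scatter(lig, rng)
        assign_parameters(lig)
    return ligands


def make_t2f_analog(model: Pharmacophore, seed: int = 0,
                    noise: float = 0.15) -> Ligand:
    """Active-like ligand whose charged (nitro) group is replaced by a
    neutral methyl tail — the derivative that lacks the charged-group
    contact. Built in the binding-site frame (no scatter)."""
    rng = np.random.default_rng(seed)
    lig = _build_ligand("T2F-ANALOG", model, rng, noise, neutral_tail=True)
    assign_parameters(lig)
    return lig


def make_active_in_site(model: Pharmacophore, seed: int = 0,
                        noise: float = 0.15) -> Ligand:
    """Single intact active built in the binding-site frame (no scatter)."""
    rng = np.random.default_rng(seed)
    lig = _build_ligand("ACT-SITE", model, rng, noise)
    assign_parameters(lig)
    return lig
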
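"""Pharmacophore features, interface-derived models, and RMSd matching.

A pharmacophore is an ordered set of typed 3-D points — hydrogen-bond
donor (HD), hydrogen-bond acceptor (HA), hydrophobic (HY) — that a ligand
conformer must present. Here the model is derived from the *protein* side
of an interface by complementarity: a protein donor projects a ligand HA
along its N-H (or O-H) direction, a protein acceptor projects a ligand HD
along its lone-pair direction, and a hydrophobic side chain projects a
ligand HY outward from the helix axis. Ligand conformers are matched by
exhaustive assignment enumeration plus least-squares rigid superposition,
and accepted when the minimal feature RMSd is within the gate
(default 1.0 Å).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import (FEATURE_TOLERANCE, HBOND_PROJECTION, HYDROPHOBIC_OFFSET,
                        RMSD_GATE, XH_BOND_MAX)
from .geometry import superpose, unit
from .structures import Ligand, Residue, Structure

FEATURE_KINDS = ("HD", "HA", "HY")

#: residue names whose side chains count as hydrophobic contacts
HYDROPHOBIC_RESIDUES = {"LEU", "ILE", "VAL", "PHE", "MET"}

MAX_ASSIGNMENTS = 10 ** 6


@dataclass
class Feature:
    """A typed pharmacophore point.

    ``direction`` is optional provenance geometry: for an HA feature the
    protein donor's X->H axis (pointing away from the protein), for an HD
    feature the acceptor lone-pair axis, for HY the outward normal. It is
    ignored by matching but lets generators orient chemistry sensibly.
    """

    kind: str
    position: np.ndarray
    tolerance: float = FEATURE_TOLERANCE
    source: str = ""
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be positive")
        self.position = np.asarray(self.position, dtype=float)
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)


@dataclass
class Pharmacophore:
    features: list[Feature]
    name: str = "pharmacophore"

    def __post_init__(self) -> None:
        if len(self.features) < 3:
            raise ValueError(
                f"a pharmacophore needs >= 3 features for rigid superposition; "
                f"got {len(self.features)}"
            )

    @property
    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features])

    def kinds(self) -> list[str]:
        return [f.kind for f in self.features]

    def save(self, path) -> None:
        doc = {"name": self.name, "features": []}
        for f in self.features:
            entry = {"kind": f.kind, "xyz": [float(x) for x in f.position],
                     "tolerance": float(f.tolerance), "source": f.source}
            if f.direction is not None:
                entry["direction"] = [float(x) for x in f.direction]
            doc["features"].append(entry)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Pharmacophore":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        feats = [Feature(d["kind"], np.array(d["xyz"], dtype=float),
                         d.get("tolerance", FEATURE_TOLERANCE), d.get("source", ""),
                         direction=(np.array(d["direction"], dtype=float)
                                    if "direction" in d else None))
                 for d in doc["features"]]
        return cls(feats, name=doc.get("name", "pharmacophore"))


@dataclass
class MatchResult:
    assignment: dict[int, int]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    accepted: bool
    gate: float = RMSD_GATE


# ---------------------------------------------------------------------------
# Ligand feature typing
# ---------------------------------------------------------------------------

def _rings(lig: Ligand) -> list[list[int]]:
    """Smallest rings, one per ring bond, deduplicated."""
    adj: dict[int, list[int]] = {i: [] for i in range(len(lig.atoms))}
    for i, j, _ in lig.bonds:
        adj[i].append(j)
        adj[j].append(i)
    rings: list[list[int]] = []
    seen: set[frozenset[int]] = set()
    for i, j, _ in lig.bonds:
        # shortest path i -> j not using the bond itself closes the smallest
        # ring through this bond
        prev = {i: None}
        queue = [i]
        while queue:
            u = queue.pop(0)
            if u == j:
                break
            for v in adj[u]:
                if u == i and v == j:
                    continue
                if v not in prev:
                    prev[v] = u
                    queue.append(v)
        if j in prev:
            path = [j]
            while path[-1] is not None and prev[path[-1]] is not None:
                path.append(prev[path[-1]])
            ring = frozenset(path)
            if ring not in seen and len(ring) >= 3:
                seen.add(ring)
                rings.append(sorted(ring))
    return rings


def type_ligand_features(lig: Ligand, conformer: int = 0) -> list[Feature]:
    """Rule-based feature typing of one ligand conformer.

    HD at every N/O carrying at least one hydrogen (feature at the heavy
    atom); HA at carbonyl oxygens, nitro oxygens, hydroxyl oxygens and
    pyridine-type ring nitrogens; HY at the centroid of each all-carbon
    ring and at halogen-substituted ring carbons. Kinds and counts are
    conformer-independent; positions follow the conformer coordinates.
    """
    coords = lig.conformers[conformer]
    feats: list[Feature] = []

    def elem(i: int) -> str:
        return lig.atoms[i].element

    def has_h(i: int) -> bool:
        return any(elem(j) == "H" for j in lig.neighbors(i))

    rings = _rings(lig)
    ring_atoms = {i for ring in rings for i in ring}

    for i, a in enumerate(lig.atoms):
        if a.element in ("N", "O") and has_h(i):
            feats.append(Feature("HD", coords[i], source=f"{lig.name}:{a.name}"))
    for i, a in enumerate(lig.atoms):
        src = f"{lig.name}:{a.name}"
        if a.element == "O":
            nbrs = lig.neighbors(i)
            heavies = [j for j in nbrs if elem(j) != "H"]
            hs = [j for j in nbrs if elem(j) == "H"]
            if len(heavies) == 1 and not hs:
                j = heavies[0]
                if elem(j) == "C" and lig.bond_order(i, j) == 2.0:
                    feats.append(Feature("HA", coords[i], source=src + " (carbonyl)"))
                elif elem(j) == "N":
                    n_term_o = sum(1 for k in lig.neighbors(j)
                                   if elem(k) == "O" and len(lig.neighbors(k)) == 1)
                    if n_term_o == 2:
                        feats.append(Feature("HA", coords[i], source=src + " (nitro)"))
            elif len(heavies) == 1 and len(hs) == 1:
                feats.append(Feature("HA", coords[i], source=src + " (hydroxyl)"))
        elif a.element == "N" and i in ring_atoms and not has_h(i):
            feats.append(Feature("HA", coords[i], source=src + " (pyridine-type)"))
    for ring in rings:
        if all(elem(i) == "C" for i in ring):
            centroid = coords[ring].mean(axis=0)
            feats.append(Feature("HY", centroid,
                                 source=f"{lig.name}:ring({','.join(str(i) for i in ring)})"))
            for i in ring:
                for j in lig.neighbors(i):
                    if elem(j) in ("Cl", "F", "Br", "I"):
                        feats.append(Feature("HY", coords[i],
                                             source=f"{lig.name}:{lig.atoms[i].name} (halo-aryl)"))
    return feats


# ---------------------------------------------------------------------------
# Interface-derived pharmacophore
# ---------------------------------------------------------------------------

def _helix_axis(structure: Structure, chain_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit principal axis of a chain (frame 0)."""
    idx = structure.atom_indices()
    cols = [idx[id(a)] for res in structure.chains[chain_id] for a in res.atoms]
    pts = structure.coords(0)[cols]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[0]


def derive_interface_pharmacophore(structure: Structure, hotspots: list[Residue],
                                   projection: float = HBOND_PROJECTION,
                                   hydrophobic_offset: float = HYDROPHOBIC_OFFSET,
                                   name: str = "interface",
                                   hydrophobic_residues: set[str] | None = None
                                   ) -> Pharmacophore:
    """Ligand-side pharmacophore complementary to protein hot spots.

    For every donor hydrogen on a hot-spot residue, an HA feature is
    projected ``projection`` Å (default 2.9) from the donor heavy atom
    along the X-H direction; for every acceptor oxygen, an HD feature is
    projected along the reversed acceptor->antecedent direction; for every
    hydrophobic side chain, an HY feature sits ``hydrophobic_offset`` Å
    (default 4.0) from the side-chain terminal-carbon centroid along the
    outward normal from the chain axis. Frame-0 coordinates are used.
    """
    if not hotspots:
        raise ValueError("hotspot residue list is empty")
    hydrophobic_residues = hydrophobic_residues or HYDROPHOBIC_RESIDUES
    chain = hotspots[0].chain_id
    if any(r.chain_id != chain for r in hotspots):
        raise ValueError("hotspot residues must belong to a single chain")
    axis_c, axis_u = _helix_axis(structure, chain)
    feats: list[Feature] = []
    for res in sorted(hotspots, key=lambda r: r.number):
        tag = f"{res.name}{res.number}/{res.chain_id}"
        heavies = res.heavy_atoms
        hydrogens = [a for a in res.atoms if a.is_hydrogen]
        donor_heavy_ids = set()
        for h in hydrogens:
            cands = [a for a in heavies if a.element in ("N", "O")
                     and np.linalg.norm(a.coords - h.coords) <= XH_BOND_MAX]
            if not cands:
                continue
            heavy = min(cands, key=lambda a: np.linalg.norm(a.coords - h.coords))
            donor_heavy_ids.add(id(heavy))
            axis = unit(h.coords - heavy.coords)
            pos = heavy.coords + projection * axis
            feats.append(Feature("HA", pos, source=f"{tag}:{heavy.name}-{h.name} donor",
                                 direction=axis))
        for a in heavies:
            if a.element != "O" or id(a) in donor_heavy_ids:
                continue
            others = [b for b in heavies if b is not a]
            if not others:
                continue
            antecedent = min(others, key=lambda b: np.linalg.norm(b.coords - a.coords))
            axis = unit(a.coords - antecedent.coords)
            pos = a.coords + projection * axis
            feats.append(Feature("HD", pos, source=f"{tag}:{a.name} acceptor",
                                 direction=axis))
        if res.name in hydrophobic_residues:
            term = [a for a in heavies if a.element == "C" and a.name not in ("CA", "CB")]
            if not term:
                term = [a for a in heavies if a.name == "CB"]
            centroid = np.mean([a.coords for a in term], axis=0)
            radial = centroid - axis_c
            radial = radial - np.dot(radial, axis_u) * axis_u
            radial = unit(radial)
            pos = centroid + hydrophobic_offset * radial
            feats.append(Feature("HY", pos, source=f"{tag} hydrophobic",
                                 direction=radial))
    return Pharmacophore(feats, name=name)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_pharmacophore(features: list[Feature], model: Pharmacophore,
                        gate: float = RMSD_GATE) -> MatchResult:
    """Best kind-compatible assignment of ligand features onto the model.

    Enumerates every injective assignment (model feature -> ligand feature
    of the same kind), superposes the assigned ligand points onto the
    model points with a proper rotation, and returns the assignment with
    minimal RMSd (lexicographic tie-break). Accepted iff rmsd <= gate.
    With no kind-compatible assignment the result carries rmsd = +inf.
    """
    m = len(model.features)
    candidates = [
        [j for j, f in enumerate(features) if f.kind == mf.kind]
        for mf in model.features
    ]
    bound = 1
    for c in candidates:
        bound *= max(len(c), 1)
    if bound > MAX_ASSIGNMENTS:
        raise RuntimeError(
            f"assignment enumeration bound {bound} exceeds {MAX_ASSIGNMENTS}; "
            "prune ligand features before matching"
        )
    if any(not c for c in candidates):
        return MatchResult({}, np.eye(3), np.zeros(3), float("inf"), False, gate)

    model_pts = model.positions
    lig_pts = np.array([f.position for f in features])
    best: MatchResult | None = None

    def recurse(k: int, used: set[int], assign: list[int]):
        nonlocal best
        if k == m:
            r, t, rmsd = superpose(lig_pts[assign], model_pts)
            if best is None or rmsd < best.rmsd - 1e-12:
                best = MatchResult(dict(enumerate(assign)), r, t, rmsd, rmsd <= gate, gate)
            return
        for j in candidates[k]:
            if j in used:
                continue
            recurse(k + 1, used | {j}, assign + [j])

    recurse(0, set(), [])
    if best is None:
        return MatchResult({}, np.eye(3), np.zeros(3), float("inf"), False, gate)
    return best
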
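"""Molecular data model and I/O.

Parameterized atoms grouped into residues and chains, with one or many
coordinate frames per structure (frame 0 is the reference; multi-frame
structures stand in for MD ensembles). Ligands carry an explicit bond list
and one or more conformers.

PDB files are read and written in the fixed-column ATOM/HETATM dialect with
MODEL/ENDMDL framing; SDF files go through RDKit (V2000, explicit
hydrogens). Force-field parameters (partial charge, Lennard-Jones well
depth and rmin/2, collision radius) come from a tab-separated parameter
table or from the built-in tables in this module.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdchem
from rdkit import RDLogger

from .constants import BONDI_RADII, LJ_BY_ELEMENT

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

_VALID_ELEMENTS = set(BONDI_RADII) | {"I", "B", "Se", "Si"}


class PDBParseError(ValueError):
    """Malformed PDB record; message names the offending line number."""


class StructureError(ValueError):
    """Frames/models are structurally inconsistent."""


class SDFParseError(ValueError):
    """Malformed SDF record."""


class ParameterLookupError(KeyError):
    """One or more atoms could not be resolved in the parameter table."""


@dataclass
class Atom:
    """A parameterized atom.

    charge in e; lj_epsilon in kcal/mol; lj_rmin_half (half the pair-minimum
    distance) and radius (collision radius) in Å.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    radius: float = 0.0
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.element not in _VALID_ELEMENTS:
            raise ValueError(f"atom {self.name}: invalid element symbol {self.element!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            # allowed transiently during construction; validated by Structure
            pass

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.number)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number}/{self.chain_id} has no atom {name!r}")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


class Structure:
    """Chains of residues plus one or more coordinate frames.

    Atom order is chains in insertion order, residues in list order, atoms
    in list order; this flat order is the frame column order and is stable
    across all operations (documented iteration contract).
    """

    def __init__(self, chains: dict[str, list[Residue]], frames: list[np.ndarray] | None = None):
        self.chains = chains
        atoms = self.atoms
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("atom serials must be unique within a frame")
        for cid, residues in chains.items():
            for res in residues:
                if not res.atoms:
                    raise StructureError(f"empty residue {res.name}{res.number} in chain {cid}")
                if res.chain_id != cid:
                    raise StructureError("residue chain_id does not match its chain")
        ref = np.array([a.coords for a in atoms], dtype=float)
        if frames is None:
            frames = [ref]
        for k, fr in enumerate(frames):
            if np.asarray(fr).shape != (len(atoms), 3):
                raise StructureError(
                    f"frame {k} has {np.asarray(fr).shape} coordinates; expected ({len(atoms)}, 3)"
                )
        self.frames = [np.array(fr, dtype=float) for fr in frames]

    @property
    def atoms(self) -> list[Atom]:
        out: list[Atom] = []
        for residues in self.chains.values():
            for res in residues:
                out.extend(res.atoms)
        return out

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def residues(self, chain_id: str | None = None) -> list[Residue]:
        if chain_id is not None:
            if chain_id not in self.chains:
                raise KeyError(f"no chain {chain_id!r} in structure")
            return list(self.chains[chain_id])
        return [r for residues in self.chains.values() for r in residues]

    def residue(self, chain_id: str, number: int) -> Residue:
        for r in self.chains[chain_id]:
            if r.number == number:
                return r
        raise KeyError(f"no residue {number} in chain {chain_id}")

    def atom_indices(self) -> dict[int, int]:
        """Map atom id() -> flat frame column index."""
        return {id(a): i for i, a in enumerate(self.atoms)}

    def coords(self, frame: int = 0) -> np.ndarray:
        return self.frames[frame]

    def subset(self, chain_ids: list[str]) -> "Structure":
        """New structure containing only the given chains (frames sliced)."""
        idx = self.atom_indices()
        keep_cols: list[int] = []
        chains: dict[str, list[Residue]] = {}
        for cid in chain_ids:
            new_residues = []
            for res in self.chains[cid]:
                new_atoms = []
                for a in res.atoms:
                    keep_cols.append(idx[id(a)])
                    new_atoms.append(
                        Atom(a.serial, a.name, a.element, a.coords.copy(), a.charge,
                             a.lj_epsilon, a.lj_rmin_half, a.radius, a.formal_charge)
                    )
                new_residues.append(Residue(cid, res.number, res.name, new_atoms))
            chains[cid] = new_residues
        frames = [fr[keep_cols] for fr in self.frames]
        return Structure(chains, frames)

    def set_reference_frame(self, frame: int) -> None:
        """Copy the coordinates of ``frame`` onto the atoms (frame 0 stays)."""
        fr = self.frames[frame]
        for a, xyz in zip(self.atoms, fr):
            a.coords = xyz.copy()


@dataclass
class Ligand:
    """A small molecule: atoms, explicit bonds, one or more conformers."""

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    conformers: list[np.ndarray]
    groups: dict[str, list[int]] = field(default_factory=dict)
    props: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise SDFParseError(f"ligand {self.name}: bond ({i}, {j}) references a nonexistent atom")
        for k, conf in enumerate(self.conformers):
            conf = np.asarray(conf, dtype=float)
            if conf.shape != (n, 3):
                raise ValueError(f"ligand {self.name}: conformer {k} has wrong atom count")
            self.conformers[k] = conf

    @property
    def n_rotatable(self) -> int:
        return count_rotatable(self)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def bond_order(self, i: int, j: int) -> float:
        for a, b, order in self.bonds:
            if {a, b} == {i, j}:
                return order
        raise KeyError(f"no bond {i}-{j}")

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    s = name.strip().lstrip("0123456789")
    if not s:
        return ""
    two = s[:2].capitalize()
    if two in ("Cl", "Br", "Se", "Si") and two in _VALID_ELEMENTS:
        return two
    return s[0].upper()


def read_pdb(path: str | Path, multi_model: bool = True) -> Structure:
    """Read a (possibly multi-MODEL) PDB file into a Structure.

    Each MODEL becomes one frame; all models must share atom count and
    ordering. Without MODEL records the file is a single frame.
    """
    path = Path(path)
    models: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                models.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    chain = line[21:22].strip() or "A"
                    resnum = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(f"{path.name}: malformed ATOM record at line {lineno}: {exc}") from exc
                element = line[76:78].strip().capitalize() or _element_from_name(name)
                if element not in _VALID_ELEMENTS:
                    raise PDBParseError(
                        f"{path.name}: invalid element {element!r} at line {lineno}"
                    )
                current.append((serial, name, resname, chain, resnum, (x, y, z), element))
                if not in_model and not saw_model:
                    pass
    if not saw_model:
        models = [current]
    elif in_model:
        raise PDBParseError(f"{path.name}: MODEL record without matching ENDMDL")
    if not models or not models[0]:
        raise PDBParseError(f"{path.name}: no ATOM records found")
    if not multi_model:
        models = models[:1]

    first = models[0]
    signature = [(rec[0], rec[1], rec[2], rec[3], rec[4]) for rec in first]
    for k, model in enumerate(models[1:], start=2):
        sig = [(rec[0], rec[1], rec[2], rec[3], rec[4]) for rec in model]
        if sig != signature:
            raise StructureError(
                f"{path.name}: MODEL {k} atom records differ from MODEL 1 "
                f"({len(model)} vs {len(first)} atoms or different ordering)"
            )

    chains: dict[str, list[Residue]] = {}
    res_map: dict[tuple[str, int], Residue] = {}
    for serial, name, resname, chain, resnum, xyz, element in first:
        key = (chain, resnum)
        if key not in res_map:
            res = Residue(chain, resnum, resname, [])
            res_map[key] = res
            chains.setdefault(chain, []).append(res)
        res_map[key].atoms.append(Atom(serial, name, element, np.array(xyz)))

    frames = [np.array([rec[5] for rec in model], dtype=float) for model in models]
    return Structure(chains, frames)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure in fixed-column PDB; one MODEL per frame if > 1."""
    path = Path(path)
    atoms = structure.atoms
    multi = structure.n_frames > 1
    with open(path, "w") as fh:
        for k, frame in enumerate(structure.frames):
            if multi:
                fh.write(f"MODEL {k + 1:>8}\n")
            i = 0
            for cid, residues in structure.chains.items():
                for res in residues:
                    for a in res.atoms:
                        x, y, z = frame[i]
                        name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
                        fh.write(
                            f"ATOM  {a.serial:>5} {name:<4}{'':1}{res.name:<3} {cid:1}"
                            f"{res.number:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
                            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2}\n"
                        )
                        i += 1
                fh.write("TER   \n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END   \n")


# ---------------------------------------------------------------------------
# SDF I/O (RDKit-backed)
# ---------------------------------------------------------------------------

_BOND_TYPES = {
    1.0: rdchem.BondType.SINGLE,
    2.0: rdchem.BondType.DOUBLE,
    3.0: rdchem.BondType.TRIPLE,
    1.5: rdchem.BondType.AROMATIC,
}


def _ligand_from_mol(mol: Chem.Mol, name: str) -> Ligand:
    conf = mol.GetConformer()
    atoms = []
    for idx, at in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(idx)
        atoms.append(
            Atom(idx + 1, f"{at.GetSymbol()}{idx + 1}", at.GetSymbol(),
                 np.array([pos.x, pos.y, pos.z]), formal_charge=at.GetFormalCharge())
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    groups: dict[str, list[int]] = {}
    props: dict[str, str] = {}
    for pname in mol.GetPropNames():
        if pname == "HS_GROUPS":
            groups = {k: list(map(int, v)) for k, v in json.loads(mol.GetProp(pname)).items()}
        elif pname == "HS_CHARGES":
            for a, q in zip(atoms, mol.GetProp(pname).split()):
                a.charge = float(q)
            props[pname] = mol.GetProp(pname)
        elif not pname.startswith("_"):
            props[pname] = mol.GetProp(pname)
    return Ligand(name, atoms, bonds, [coords], groups=groups, props=props)


def read_sdf(path: str | Path) -> list[Ligand]:
    """Read a multi-record V2000 SDF into Ligands.

    Consecutive records sharing molecule name and atom count merge as
    conformers of a single Ligand. An empty file yields an empty list with
    a logged warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("SDF file %s is empty; returning no ligands", path)
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    ligands: list[Ligand] = []
    for rec_idx, mol in enumerate(supplier):
        if mol is None:
            raise SDFParseError(f"{path.name}: unreadable SDF record {rec_idx + 1}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{rec_idx + 1}"
        lig = _ligand_from_mol(mol, name)
        if (
            ligands
            and ligands[-1].name == name
            and len(ligands[-1].atoms) == len(lig.atoms)
        ):
            ligands[-1].conformers.append(lig.conformers[0])
        else:
            ligands.append(lig)
    return ligands


def _mol_from_ligand(lig: Ligand, conformer: int) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in lig.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.formal_charge)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    for i, j, order in lig.bonds:
        rw.AddBond(i, j, _BOND_TYPES.get(order, rdchem.BondType.SINGLE))
    conf = Chem.Conformer(len(lig.atoms))
    for i, xyz in enumerate(lig.conformers[conformer]):
        conf.SetAtomPosition(i, tuple(map(float, xyz)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", lig.name)
    if lig.groups:
        mol.SetProp("HS_GROUPS", json.dumps(lig.groups, sort_keys=True))
    if any(a.charge != 0.0 for a in lig.atoms):
        mol.SetProp("HS_CHARGES", " ".join(f"{a.charge:.6f}" for a in lig.atoms))
    for k, v in lig.props.items():
        if k != "HS_CHARGES":
            mol.SetProp(k, v)
    return mol


def write_sdf(ligands: list[Ligand], path: str | Path) -> None:
    """Write ligands as multi-record V2000 SDF, one record per conformer."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for lig in ligands:
        for k in range(len(lig.conformers)):
            writer.write(_mol_from_ligand(lig, k))
    writer.close()


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

class ParameterTable:
    """(residue name, atom name) -> (charge, epsilon, rmin_half, radius).

    Tab-separated text format, one entry per line::

        residue  atom  charge  epsilon  rmin_half  radius

    A residue name of ``*`` matches any residue. Atoms not found in the
    table fall back to zero-charge element defaults (Lennard-Jones by
    element, Bondi radius) when ``element_fallback`` is enabled.
    """

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float, float, float]],
                 formal_charges: dict[str, float] | None = None,
                 element_fallback: bool = True):
        self.entries = dict(entries)
        self.formal_charges = dict(formal_charges or {})
        self.element_fallback = element_fallback

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterTable":
        entries = {}
        formal: dict[str, float] = {}
        for lineno, line in enumerate(open(path), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0] == "FORMAL":
                if len(parts) != 3:
                    raise ValueError(f"parameter table line {lineno}: FORMAL needs residue + charge")
                formal[parts[1]] = float(parts[2])
                continue
            if len(parts) != 6:
                raise ValueError(f"parameter table line {lineno}: expected 6 fields, got {len(parts)}")
            res, atom, q, eps, rmh, rad = parts
            entries[(res, atom)] = (float(q), float(eps), float(rmh), float(rad))
        return cls(entries, formal_charges=formal)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# residue\tatom\tcharge\tepsilon\trmin_half\tradius\n")
            fh.write("# FORMAL\tresidue\tformal_charge\n")
            for res, q in sorted(self.formal_charges.items()):
                fh.write(f"FORMAL\t{res}\t{q:+.0f}\n")
            for (res, atom), (q, eps, rmh, rad) in sorted(self.entries.items()):
                fh.write(f"{res}\t{atom}\t{q:.6f}\t{eps:.6f}\t{rmh:.6f}\t{rad:.6f}\n")

    def lookup(self, resname: str, atom: Atom) -> tuple[float, float, float, float] | None:
        for key in ((resname, atom.name), ("*", atom.name)):
            if key in self.entries:
                return self.entries[key]
        if self.element_fallback and atom.element in LJ_BY_ELEMENT:
            eps, rmh = LJ_BY_ELEMENT[atom.element]
            return (0.0, eps, rmh, BONDI_RADII[atom.element])
        return None


def _side_chain_entries(resname: str, formal: float,
                        spec: list[tuple[str, str, float]]) -> dict:
    """Build table entries for a reduced side-chain model; CA/CB carry 0 e."""
    entries = {(resname, "CA"): (0.0, *LJ_BY_ELEMENT["C"][:2], BONDI_RADII["C"])}
    for name, element, charge in spec:
        eps, rmh = LJ_BY_ELEMENT[element]
        entries[(resname, name)] = (charge, eps, rmh, BONDI_RADII[element])
    total = sum(c for _, _, c in spec)
    if abs(total - formal) > 1e-9:
        raise AssertionError(f"built-in table for {resname} sums to {total}, wants {formal}")
    return entries


def builtin_protein_table() -> ParameterTable:
    """Minimal parameter table for the reduced amino-acid models.

    Charges are Amber-flavoured but simplified so that every residue sums
    exactly to its formal charge; Lennard-Jones parameters and Bondi radii
    are assigned per element. Unlisted atoms resolve through the element
    fallback with zero charge.
    """
    entries: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    entries.update(_side_chain_entries("GLY", 0.0, []))
    entries.update(_side_chain_entries("ALA", 0.0, [("CB", "C", 0.0)]))
    entries.update(_side_chain_entries("LEU", 0.0, [("CB", "C", 0.0), ("CG", "C", 0.0),
                                                    ("CD1", "C", 0.0), ("CD2", "C", 0.0)]))
    entries.update(_side_chain_entries("VAL", 0.0, [("CB", "C", 0.0), ("CG1", "C", 0.0),
                                                    ("CG2", "C", 0.0)]))
    entries.update(_side_chain_entries("ILE", 0.0, [("CB", "C", 0.0), ("CG1", "C", 0.0),
                                                    ("CD1", "C", 0.0)]))
    entries.update(_side_chain_entries("MET", 0.0, [("CB", "C", 0.0), ("SD", "S", 0.0),
                                                    ("CE", "C", 0.0)]))
    entries.update(_side_chain_entries("PHE", 0.0, [("CB", "C", 0.0), ("CG", "C", 0.0),
                                                    ("CZ", "C", 0.0)]))
    entries.update(_side_chain_entries(
        "GLN", 0.0, [("CB", "C", 0.0), ("NE2", "N", -0.42), ("HE21", "H", 0.42)]))
    entries.update(_side_chain_entries(
        "ASN", 0.0, [("CB", "C", 0.0), ("ND2", "N", -0.42), ("HD21", "H", 0.42)]))
    entries.update(_side_chain_entries(
        "LYS", 1.0, [("CB", "C", 0.0), ("NZ", "N", 0.54), ("HZ1", "H", 0.46)]))
    entries.update(_side_chain_entries(
        "ARG", 1.0, [("CB", "C", 0.0), ("CZ", "C", 0.64), ("NH1", "N", -0.4),
                     ("HH11", "H", 0.38), ("NH2", "N", 0.0), ("HH21", "H", 0.38)]))
    entries.update(_side_chain_entries(
        "GLU", -1.0, [("CB", "C", 0.0), ("CD", "C", 0.6), ("OE1", "O", -0.8),
                      ("OE2", "O", -0.8)]))
    entries.update(_side_chain_entries(
        "ASP", -1.0, [("CB", "C", 0.0), ("CG", "C", 0.6), ("OD1", "O", -0.8),
                      ("OD2", "O", -0.8)]))
    entries.update(_side_chain_entries(
        "SER", 0.0, [("CB", "C", 0.2), ("OG", "O", -0.6), ("HG", "H", 0.4)]))
    entries.update(_side_chain_entries(
        "THR", 0.0, [("CB", "C", 0.2), ("OG1", "O", -0.6), ("HG1", "H", 0.4),
                     ("CG2", "C", 0.0)]))
    formal = {"LYS": 1.0, "ARG": 1.0, "GLU": -1.0, "ASP": -1.0}
    return ParameterTable(entries, formal_charges=formal)


def assign_parameters(obj, table: ParameterTable | None = None):
    """Assign charge / Lennard-Jones / radius parameters in place.

    For a :class:`Structure`, parameters come from the (residue, atom)
    table; residues fully resolved by explicit table entries must sum to
    the residue's formal charge (checked to 1e-6 e). For a
    :class:`Ligand`, charges come from the rule-based typer (or the
    ``HS_CHARGES`` SDF property if present), LJ/radii from element tables;
    explicit ``("*", atom_name)`` table entries override.

    Idempotent: reassignment from the same table yields identical values.
    Returns the object.
    """
    if isinstance(obj, Ligand):
        return _assign_ligand(obj, table)
    if not isinstance(obj, Structure):
        raise TypeError("assign_parameters expects a Structure or a Ligand")
    table = table or builtin_protein_table()
    missing: list[str] = []
    for res in obj.residues():
        explicit = True
        for a in res.atoms:
            params = table.lookup(res.name, a)
            if params is None:
                missing.append(f"{res.name}{res.number}/{res.chain_id}:{a.name}")
                continue
            if (res.name, a.name) not in table.entries and ("*", a.name) not in table.entries:
                explicit = False
            a.charge, a.lj_epsilon, a.lj_rmin_half, a.radius = params
        if explicit and not missing:
            formal = table.formal_charges.get(res.name, 0.0)
            total = sum(a.charge for a in res.atoms)
            if abs(total - formal) > 1e-6:
                raise ValueError(
                    f"residue {res.name}{res.number}/{res.chain_id}: charges sum to "
                    f"{total:.6f} e, formal charge is {formal:+.0f} e"
                )
    if missing:
        raise ParameterLookupError(
            "unresolvable atoms (not in table, element unknown): " + ", ".join(missing)
        )
    return obj


# --- ligand typer -----------------------------------------------------------

def _assign_ligand(lig: Ligand, table: ParameterTable | None) -> Ligand:
    for a in lig.atoms:
        if a.element not in LJ_BY_ELEMENT:
            raise ParameterLookupError(f"ligand {lig.name}: no parameters for element {a.element}")
        eps, rmh = LJ_BY_ELEMENT[a.element]
        a.lj_epsilon, a.lj_rmin_half, a.radius = eps, rmh, BONDI_RADII[a.element]
    if "HS_CHARGES" in lig.props:
        for a, q in zip(lig.atoms, lig.props["HS_CHARGES"].split()):
            a.charge = float(q)
    else:
        for i, q in type_ligand_charges(lig).items():
            lig.atoms[i].charge = q
    if table is not None:
        for a in lig.atoms:
            key = ("*", a.name)
            if key in table.entries:
                a.charge, a.lj_epsilon, a.lj_rmin_half, a.radius = table.entries[key]
    return lig


def type_ligand_charges(lig: Ligand) -> dict[int, float]:
    """Rule-based partial charges for ligand atoms (e).

    Group-neutral assignments: nitro (N +0.86, O -0.43 each), carboxylate
    (C +0.8, O -0.9 each; net -1), carbonyl (C +0.45, O -0.45), hydroxyl
    (O -0.6, H +0.4, carbon +0.2), N-H nitrogen (N -0.35 per H, H +0.35),
    pyridine-type ring N (-0.5, +0.25 on each ring neighbour). Atoms not
    covered by a rule are 0.
    """
    q = {i: 0.0 for i in range(len(lig.atoms))}
    consumed: set[int] = set()

    def elem(i: int) -> str:
        return lig.atoms[i].element

    # nitro: N bonded to exactly two O, both terminal
    for i, a in enumerate(lig.atoms):
        if a.element != "N" or i in consumed:
            continue
        onbrs = [j for j in lig.neighbors(i) if elem(j) == "O"
                 and len(lig.neighbors(j)) == 1]
        if len(onbrs) == 2:
            q[i] = 0.86
            for j in onbrs:
                q[j] = -0.43
            consumed.update([i, *onbrs])
    # carboxylate: C bonded to two terminal O (and not a nitro)
    for i, a in enumerate(lig.atoms):
        if a.element != "C" or i in consumed:
            continue
        onbrs = [j for j in lig.neighbors(i) if elem(j) == "O"
                 and len(lig.neighbors(j)) == 1 and j not in consumed]
        if len(onbrs) == 2:
            q[i] = 0.8
            for j in onbrs:
                q[j] = -0.9
            consumed.update([i, *onbrs])
    # carbonyl: terminal O double-bonded to C
    for i, a in enumerate(lig.atoms):
        if a.element != "O" or i in consumed:
            continue
        nbrs = lig.neighbors(i)
        if len(nbrs) == 1 and elem(nbrs[0]) == "C" and lig.bond_order(i, nbrs[0]) == 2.0:
            q[i] = -0.45
            q[nbrs[0]] += 0.45
            consumed.update([i, nbrs[0]])
    # hydroxyl: O with one H and one heavy neighbour
    for i, a in enumerate(lig.atoms):
        if a.element != "O" or i in consumed:
            continue
        nbrs = lig.neighbors(i)
        hs = [j for j in nbrs if elem(j) == "H"]
        heavies = [j for j in nbrs if elem(j) != "H"]
        if len(hs) == 1 and len(heavies) == 1:
            q[i] = -0.6
            q[hs[0]] = 0.4
            q[heavies[0]] += 0.2
            consumed.update([i, hs[0]])
    # N-H nitrogens (amine/amide/urea)
    for i, a in enumerate(lig.atoms):
        if a.element != "N" or i in consumed:
            continue
        hs = [j for j in lig.neighbors(i) if elem(j) == "H"]
        if hs:
            q[i] = -0.35 * len(hs)
            for j in hs:
                q[j] = 0.35
            consumed.update([i, *hs])
    # pyridine-type N: ring N, no H, two heavy neighbours
    ring_bonds = rings_bonds(lig)
    for i, a in enumerate(lig.atoms):
        if a.element != "N" or i in consumed:
            continue
        nbrs = lig.neighbors(i)
        if len(nbrs) == 2 and all(elem(j) != "H" for j in nbrs) and any(
            frozenset((i, j)) in ring_bonds for j in nbrs
        ):
            q[i] = -0.5
            for j in nbrs:
                q[j] += 0.25
            consumed.add(i)
    return q


def rings_bonds(lig: Ligand) -> set[frozenset[int]]:
    """Set of bonds (as index pairs) that lie in a ring.

    A bond is in a ring iff its endpoints stay connected after removing it.
    """
    adj: dict[int, set[int]] = {i: set() for i in range(len(lig.atoms))}
    for i, j, _ in lig.bonds:
        adj[i].add(j)
        adj[j].add(i)
    out: set[frozenset[int]] = set()
    for i, j, _ in lig.bonds:
        # BFS from i to j without using bond i-j
        seen = {i}
        stack = [i]
        found = False
        while stack and not found:
            u = stack.pop()
            for v in adj[u]:
                if u == i and v == j:
                    continue
                if v == j:
                    found = True
                    break
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if found:
            out.add(frozenset((i, j)))
    return out


def count_rotatable(lig: Ligand) -> int:
    """Count rotatable bonds: non-ring single bonds between two heavy atoms
    that each have at least one further heavy neighbour."""
    in_ring = rings_bonds(lig)

    def heavy_nbrs(i: int) -> int:
        return sum(1 for j in lig.neighbors(i) if not lig.atoms[j].is_hydrogen)

    n = 0
    for i, j, order in lig.bonds:
        if order != 1.0 or frozenset((i, j)) in in_ring:
            continue
        if lig.atoms[i].is_hydrogen or lig.atoms[j].is_hydrogen:
            continue
        if heavy_nbrs(i) >= 2 and heavy_nbrs(j) >= 2:
            n += 1
    return n
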
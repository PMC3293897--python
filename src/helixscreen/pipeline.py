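"""End-to-end orchestration: hot spots -> pharmacophore -> screen -> score.

A single validated configuration drives the five stages; every stage
writes its intermediates (TSV/YAML/PDB/SDF) into the output directory and
the run is deterministic for a given config + seed. Without explicit
receptor/library paths the synthetic generators supply the scene, which
makes ``helixscreen run`` self-contained.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import (HBOND_ANGLE_MIN, HBOND_DIST_MAX, RADIUS_SCALE, RMSD_GATE)
from .docking import local_minimize, screen_library
from .energetics import (DielectricModel, detect_hbonds, interface_matrix,
                         rank_hotspots)
from .pharmacophore import (HYDROPHOBIC_RESIDUES, Pharmacophore,
                            derive_interface_pharmacophore)
from .scoring import (empirical_score, group_electrostatics, mmpbsa_energy,
                      remainder_group)
from .structures import (ParameterTable, assign_parameters, read_pdb, read_sdf,
                         write_pdb, write_sdf)
from .synthetic import DimerSpec, LibrarySpec, jitter_ensemble, make_ligand_library, make_toy_dimer

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


#: key -> (default, validator, description)
_SCHEMA: dict[str, tuple] = {
    "receptor": (None, lambda v: v is None or isinstance(v, str), "PDB path or null for synthetic"),
    "library": (None, lambda v: v is None or isinstance(v, str), "SDF path or null for synthetic"),
    "parameter_table": (None, lambda v: v is None or isinstance(v, str), "TSV parameter table"),
    "pharmacophore": (None, lambda v: v is None or isinstance(v, str), "pharmacophore YAML (else derived)"),
    "out_dir": ("helixscreen_out", lambda v: isinstance(v, str), "output directory"),
    "chain_a": ("A", lambda v: isinstance(v, str), "first interface chain"),
    "chain_b": ("B", lambda v: isinstance(v, str), "second interface chain"),
    "frames": ("all", lambda v: v == "all" or isinstance(v, (list, str)), "frame selection"),
    "dielectric": ("4r", lambda v: v == "4r" or isinstance(v, (int, float)) and v > 0,
                   "interface dielectric model"),
    "hbond_dist_max": (HBOND_DIST_MAX, lambda v: 0 < v <= 6.0, "H-bond distance ceiling, Å"),
    "hbond_angle_min": (HBOND_ANGLE_MIN, lambda v: 0 <= v <= 180, "H-bond angle floor, deg"),
    "gate": (RMSD_GATE, lambda v: v >= 0, "pharmacophore RMSd gate, Å"),
    "radius_scale": (RADIUS_SCALE, lambda v: 0 < v <= 1, "clash radius scaling"),
    "max_clashes": (0, lambda v: isinstance(v, int) and v >= 0, "allowed residual clashes"),
    "minimize_steps": (200, lambda v: isinstance(v, int) and v >= 0, "rigid-body descent steps"),
    "step_size": (0.05, lambda v: v > 0, "descent translation step, Å"),
    "step_angle": (0.5, lambda v: v > 0, "descent rotation step, deg"),
    "score_weights": (None, lambda v: v is None or isinstance(v, dict), "empirical score weights"),
    "solvent_dielectric": (80.0, lambda v: v > 1, "GB solvent dielectric"),
    "energy_max": (-2.0, lambda v: v <= 0, "hot-spot energy threshold, kcal/mol"),
    "occupancy_min": (0.5, lambda v: 0 <= v <= 1, "hot-spot H-bond occupancy threshold"),
    "conservation_min": (0.5, lambda v: 0 <= v <= 1, "hot-spot conservation threshold"),
    "n_frames": (20, lambda v: isinstance(v, int) and v >= 1, "synthetic ensemble frames"),
    "jitter_sigma": (0.1, lambda v: v >= 0, "synthetic ensemble jitter, Å"),
    "n_actives": (10, lambda v: isinstance(v, int) and v >= 0, "synthetic actives"),
    "n_decoys": (40, lambda v: isinstance(v, int) and v >= 0, "synthetic decoys"),
    "seed": (0, lambda v: isinstance(v, int), "master seed"),
}


def validate_config(config: dict | None) -> dict:
    """Fill defaults, check ranges, reject unknown keys. Returns the
    normalized config; raises ConfigError listing every problem."""
    config = dict(config or {})
    errors = []
    for key in config:
        if key not in _SCHEMA:
            errors.append(f"unknown config key {key!r}")
    out = {}
    for key, (default, check, desc) in _SCHEMA.items():
        val = config.get(key, default)
        if val is not None or default is None:
            try:
                ok = val is None or check(val)
            except TypeError:
                ok = False
            if not ok:
                errors.append(f"config key {key!r} = {val!r} out of range ({desc})")
        out[key] = val
    if errors:
        raise ConfigError(errors)
    return out


class _DupKeyLoader(yaml.SafeLoader):
    pass


def _no_dup_constructor(loader, node):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node)
        if key in mapping:
            raise ConfigError([f"duplicate config key {key!r}"])
        mapping[key] = loader.construct_object(value_node)
    return mapping


_DupKeyLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_dup_constructor)


def load_config(path: str | Path) -> dict:
    """Load + validate a YAML run config (duplicate keys rejected)."""
    with open(path) as fh:
        doc = yaml.load(fh, Loader=_DupKeyLoader)
    return validate_config(doc or {})


@dataclass
class RunReport:
    counts: dict[str, int]
    ranking: list[dict]
    config: dict
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"counts": self.counts, "ranking": self.ranking,
                       "config": self.config, "version": self.version,
                       "outputs": self.outputs}, fh, indent=2, sort_keys=True)


def _parse_frames(spec, n_frames: int) -> list[int]:
    if spec == "all":
        return list(range(n_frames))
    if isinstance(spec, str):
        a, b = spec.split(":")
        return list(range(int(a), min(int(b), n_frames)))
    return [int(k) for k in spec]


def _select_pharm_residues(structure, report, chain_a):
    flagged = [r["residue"] for r in report.ranked if r["hotspot"] and r["residue"][0] == chain_a]
    if not flagged:
        flagged = [r["residue"] for r in report.ranked if r["residue"][0] == chain_a][:3]
    numbers = [n for _, n in flagged]
    lo, hi = min(numbers), max(numbers)
    chosen = list(flagged)
    for res in structure.chains[chain_a]:
        if res.name in HYDROPHOBIC_RESIDUES and lo <= res.number <= hi \
                and (chain_a, res.number) not in chosen:
            chosen.append((chain_a, res.number))
    return [structure.residue(chain_a, n) for _, n in sorted(chosen, key=lambda k: k[1])]


def run_pipeline(config: dict | None = None) -> RunReport:
    """Execute hot spots -> pharmacophore -> screen -> minimize -> score.

    All intermediates are written under ``out_dir``; the returned report
    carries the funnel counts and the final ranking. Deterministic for a
    given config + seed.
    """
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    dielectric = (DielectricModel("4r") if cfg["dielectric"] == "4r"
                  else DielectricModel(constant=float(cfg["dielectric"])))

    # --- stage 0: inputs -------------------------------------------------
    if cfg["receptor"]:
        structure = read_pdb(cfg["receptor"])
        table = (ParameterTable.from_file(cfg["parameter_table"])
                 if cfg["parameter_table"] else None)
        assign_parameters(structure, table)
    else:
        structure, table = make_toy_dimer(DimerSpec(seed=seed))
        structure = jitter_ensemble(structure, cfg["jitter_sigma"],
                                    cfg["n_frames"], seed=seed + 1)
        write_pdb(structure, out / "receptor.pdb")
        table.to_file(out / "parameters.tsv")

    frames = _parse_frames(cfg["frames"], structure.n_frames)
    chain_a, chain_b = cfg["chain_a"], cfg["chain_b"]

    # --- stage 1: interface energetics -----------------------------------
    matrix = interface_matrix(structure, chain_a, chain_b, frames, dielectric)
    _, occupancy = detect_hbonds(structure, frames, cfg["hbond_dist_max"],
                                 cfg["hbond_angle_min"])
    report = rank_hotspots(matrix, occupancy, energy_max=cfg["energy_max"],
                           occupancy_min=cfg["occupancy_min"],
                           conservation_min=cfg["conservation_min"])
    rows = sorted(matrix.rows)
    cols = sorted(matrix.cols)
    mat_df = pd.DataFrame(
        [[matrix.entry(r, c).e_total for c in cols] for r in rows],
        index=[f"{c}{n}" for c, n in rows], columns=[f"{c}{n}" for c, n in cols])
    mat_df.to_csv(out / "matrix.tsv", sep="\t", float_format="%.6f")
    pd.DataFrame([
        {"residue": f"{r['residue'][0]}{r['residue'][1]}", "energy": r["energy"],
         "occupancy": r["occupancy"], "conservation": r["conservation"],
         "hotspot": r["hotspot"]} for r in report.ranked
    ]).to_csv(out / "hotspots.tsv", sep="\t", index=False, float_format="%.6f")

    # --- stage 2: pharmacophore ------------------------------------------
    if cfg["pharmacophore"]:
        model = Pharmacophore.load(cfg["pharmacophore"])
    else:
        residues = _select_pharm_residues(structure, report, chain_a)
        model = derive_interface_pharmacophore(structure, residues)
    model.save(out / "pharmacophore.yaml")

    # --- stage 3: library + screen ---------------------------------------
    if cfg["library"]:
        library = read_sdf(cfg["library"])
        for lig in library:
            assign_parameters(lig, table if cfg["parameter_table"] else None)
    else:
        library = make_ligand_library(
            LibrarySpec(n_actives=cfg["n_actives"], n_decoys=cfg["n_decoys"],
                        seed=seed + 2), model)
        write_sdf(library, out / "library.sdf")
    n_conformers = sum(len(l.conformers) for l in library)
    receptor = structure.subset([chain_a])
    ranking = screen_library(library, model, receptor, gate=cfg["gate"],
                             radius_scale=cfg["radius_scale"],
                             max_clashes=cfg["max_clashes"])
    n_gate_rejected = sum(1 for r in ranking.rejections
                          if r["reason"] == "pharmacophore_gate")
    n_clash_rejected = sum(1 for r in ranking.rejections
                           if r["reason"] == "steric_clash")
    with open(out / "rejections.log", "w") as fh:
        for r in ranking.rejections:
            fh.write(json.dumps(r, sort_keys=True) + "\n")

    # --- stage 4+5: minimize + score -------------------------------------
    result_rows = []
    poses = []
    for entry in ranking.entries:
        pose = local_minimize(entry.pose, receptor, steps=cfg["minimize_steps"],
                              step_size=cfg["step_size"],
                              step_angle=cfg["step_angle"])
        pose.clash_count = entry.clash_count
        emp = empirical_score(pose, receptor, cfg["score_weights"])
        entry.empirical_score = emp.total
        mm = mmpbsa_energy(pose, receptor,
                           solvent_dielectric=cfg["solvent_dielectric"])
        groups = remainder_group(pose.ligand, pose.ligand.groups)
        gel = {g.group: g.e_elec_group
               for g in group_electrostatics(pose, receptor, groups)}
        row = {"ligand": entry.ligand, "conformer": entry.conformer,
               "pharm_rmsd": entry.pharm_rmsd, "clash_count": entry.clash_count,
               "empirical_score": emp.total, "e_vdw": mm.e_vdw,
               "e_elec": mm.e_elec, "g_polar": mm.g_polar,
               "g_nonpolar": mm.g_nonpolar, "mmgbsa_total": mm.total}
        for gname in sorted(gel):
            row[f"e_elec[{gname}]"] = gel[gname]
        result_rows.append(row)
        poses.append(pose)

    df = pd.DataFrame(result_rows)
    if not df.empty:
        df = df.sort_values(["pharm_rmsd", "empirical_score", "ligand"],
                            ascending=[True, False, True]).reset_index(drop=True)
    df.to_csv(out / "energies.tsv", sep="\t", index=False, float_format="%.6f")
    df_rank = df[["ligand", "conformer", "pharm_rmsd", "clash_count",
                  "empirical_score"]] if not df.empty else df
    df_rank.to_csv(out / "ranking.tsv", sep="\t", index=False, float_format="%.6f")
    if poses:
        posed = []
        for pose in poses:
            lig = pose.ligand
            plig = type(lig)(lig.name, lig.atoms, lig.bonds,
                             [pose.coords_placed], groups=lig.groups,
                             props=dict(lig.props,
                                        HS_PHARM_RMSD=f"{pose.pharm_rmsd:.4f}"))
            posed.append(plig)
        write_sdf(posed, out / "poses.sdf")

    counts = {
        "residue_pairs": len(matrix.entries),
        "frames_used": len(frames),
        "features": len(model.features),
        "ligands": len(library),
        "conformers": n_conformers,
        "gate_rejected": n_gate_rejected,
        "clash_rejected": n_clash_rejected,
        "accepted": len(ranking.entries),
        "scored": len(result_rows),
    }
    if not (counts["accepted"] <= counts["conformers"]):
        raise AssertionError("inconsistent funnel counts")
    rep = RunReport(counts=counts,
                    ranking=df.to_dict(orient="records") if not df.empty else [],
                    config=cfg,
                    outputs={p.name: str(p) for p in sorted(out.iterdir())})
    rep.save(out / "report.json")
    return rep
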
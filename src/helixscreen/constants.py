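"""Physical constants and default parameters shared across the package."""

#: Coulomb constant in kcal·Å/(mol·e²); used everywhere charges interact.
COULOMB_K = 332.0637

#: Solvent (water) relative dielectric for generalized-Born solvation.
SOLVENT_DIELECTRIC = 80.0

#: Interior dielectric for the molecular-mechanics terms of binding energies.
INTERIOR_DIELECTRIC = 1.0

#: Surface-tension coefficient for nonpolar solvation, kcal/mol/Å².
SASA_GAMMA = 0.00542

#: Per-state offset of the nonpolar solvation term, kcal/mol. Cancels in
#: complex-minus-parts differences.
SASA_BETA = 0.92

#: Solvent probe radius for Shrake-Rupley surface sampling, Å.
PROBE_RADIUS = 1.4

#: Number of sphere sample points per atom in Shrake-Rupley sampling.
SASA_N_POINTS = 960

#: Bondi collision radii by element symbol, Å.
BONDI_RADII = {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "Cl": 1.75,
    "F": 1.47,
    "Br": 1.85,
    "P": 1.8,
}

#: Lennard-Jones well depth (kcal/mol) and rmin/2 (Å) by element symbol.
#: Amber-style generic atom classes; hydrogens use the polar-H parameters.
LJ_BY_ELEMENT = {
    "H": (0.0157, 0.6),
    "C": (0.086, 1.908),
    "N": (0.17, 1.824),
    "O": (0.21, 1.6612),
    "S": (0.25, 2.0),
    "Cl": (0.265, 1.948),
    "F": (0.061, 1.75),
    "Br": (0.32, 2.02),
    "P": (0.2, 2.1),
}

#: Default hydrogen-bond geometric criteria: donor-heavy -> acceptor distance
#: ceiling (Å) and donor-H-acceptor angle floor at the hydrogen (degrees).
HBOND_DIST_MAX = 3.5
HBOND_ANGLE_MIN = 120.0

#: Pharmacophore defaults: per-feature tolerance (reporting only), the global
#: RMSd acceptance gate, H-bond projection distance for complementary
#: features, and hydrophobic-contact offset.
FEATURE_TOLERANCE = 1.5
RMSD_GATE = 1.0
HBOND_PROJECTION = 2.9
HYDROPHOBIC_OFFSET = 4.0

#: Steric-filter radius scaling: collision radii reduced by 40%.
RADIUS_SCALE = 0.6

#: Covalent X-H bond-length ceiling used to find bonded hydrogens when no
#: bond list is available (protein structures), Å.
XH_BOND_MAX = 1.25
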
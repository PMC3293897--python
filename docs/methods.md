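# Methods

## Scope and model

`helixscreen` implements an interface-targeted virtual-screening protocol
as a chain of well-defined geometric and energetic operations. The object
of study is a two-chain protein–protein interface represented by
parameterized atoms (partial charge q, Lennard-Jones well depth ε and
half-minimum distance r_min/2, collision radius) grouped into residues,
with one or many coordinate frames per structure. Frame 0 is the
reference; additional frames stand in for snapshots of a dynamics
trajectory. All coordinates are in Å, energies in kcal/mol, charges in e;
the Coulomb constant is 332.0637 kcal·Å/(mol·e²) everywhere.

## Interface energetics

The interaction energy of residue a (chain A) with residue b (chain B) is
the sum over all inter-residue atom pairs, with no distance cutoff, of

    E_vdw  = ε_ij [(r_min,ij / r)^12 − 2 (r_min,ij / r)^6]
    E_elec = 332.0637 q_i q_j / (ε(r) · r)

with ε_ij = √(ε_i ε_j) and r_min,ij = r_min,i/2 + r_min,j/2 (the Amber
combination rules). No 1–4 or intra-residue exclusions are needed: the
pairs are always inter-chain, so the atoms never share bonds. The default
dielectric is distance-dependent, ε(r) = 4r, a standard bounded choice
for scanning an unsolvated interface; a constant-ε option exists (and the
molecular-mechanics terms of the binding energies use ε = 1). Entries are
averaged over the selected frames; the per-residue total is the row (or
column) sum against the complete opposite chain. Residues are ordered by
(chain, number), ties in the hot-spot ranking break by (hydrogen-bond
occupancy descending, residue number ascending).

Hydrogen bonds are detected geometrically: donors are N/O with a
covalently attached hydrogen (X–H ≤ 1.25 Å, found by distance since
protein structures carry no bond list), acceptors are oxygens plus
nitrogens with no attached hydrogen. An event requires donor-heavy →
acceptor distance ≤ 3.5 Å and a donor–H–acceptor angle at the hydrogen
≥ 120°; occupancy is the fraction of frames with an event. Both
thresholds are arguments.

A residue is flagged as a hot spot when its mean total is below an energy
threshold (default −2 kcal/mol) and it either holds a hydrogen bond with
occupancy ≥ 0.5 or clears twice the energy threshold on energy alone
(covering purely electrostatic or hydrophobic spots); when a conservation
map is supplied, a conservation floor (default 0.5) applies as well.

## Pharmacophore derivation and matching

Features are typed points: HD (the ligand presents a donor), HA
(acceptor), HY (hydrophobic). The protein side projects its complement:

* each donor hydrogen on a hot-spot residue → HA at 2.9 Å from the donor
  heavy atom along the X–H axis;
* each acceptor oxygen → HD at 2.9 Å along the reversed
  acceptor→antecedent axis (a lone-pair approximation);
* each hydrophobic side chain (Leu/Ile/Val/Phe/Met) → HY at 4.0 Å from
  the side-chain terminal-carbon centroid along the outward normal from
  the chain's principal axis.

2.9 Å is a typical heavy-atom hydrogen-bond distance and 4.0 Å a typical
hydrophobic-contact offset; both are arguments. Each feature records its
provenance and projection axis; the axis is ignored by matching but lets
generators orient chemistry sensibly. A model needs ≥ 3 features (rigid
superposition is underdetermined below that); the canonical interface
model has five.

Ligand feature typing is rule-based on the bond graph: HD at N/O bearing
≥ 1 H; HA at carbonyl, nitro and hydroxyl oxygens and pyridine-type ring
nitrogens; HY at all-carbon ring centroids and halogen-substituted ring
carbons. Counts are conformer-independent by construction.

Matching enumerates every injective, kind-compatible assignment of model
features to ligand features (guarded at 10⁶ assignments), superposes the
assigned ligand points onto the model by least squares restricted to
proper rotations (chirality is never inverted), and keeps the assignment
with minimal RMSd, breaking ties lexicographically. A conformer is
accepted when RMSd ≤ the gate (default 1.0 Å). Per-feature tolerances
(default 1.5 Å) are stored for reporting only; the global RMSd gate is
the acceptance criterion. A caution from the geometry: optimal
superposition absorbs a surprising share of a single displaced feature —
on a five-point model, translation alone reduces a displacement d to an
RMSd of 0.4·d and rotation reduces it further — so a single 2.5 Å
displacement does *not* guarantee rejection at a 1.0 Å gate. The decoy
generator therefore verifies its constructions against the matcher (see
below).

## Docking stage

Accepted matches place the whole conformer rigidly. The steric filter
counts ligand–receptor heavy-atom pairs with d < s·(r_i + r_j); the
default scale s = 0.6 (radii reduced by 40%) deliberately tolerates minor
overlap as a crude proxy for flexibility, and the default residual-clash
allowance is 0 — the radius reduction itself is the tolerance. Hydrogens
are excluded (their radii are small and poorly defined). Screening keeps
the best surviving conformer per ligand, sorts by (pharmacophore RMSd,
ligand name, conformer), and logs every rejection with a machine-readable
reason code; output is invariant under library input order.

Pose relaxation is a greedy rigid-body descent (6 degrees of freedom) on
the intermolecular Lennard-Jones + Coulomb energy at ε = 1: each
iteration tries ± translations (0.05 Å) along the axes and ± rotations
(0.5°) about the ligand centroid and takes the best improving move, for
at most 200 iterations. Ligand internal geometry is frozen; the final
energy never exceeds the initial one. This is a deterministic, desk-scale
stand-in for a force-field minimizer, sufficient for single-point
end-point energies.

## Scoring

**Empirical score** (higher = better): an additive form with four terms —
a soft 8-4 contact sum over heavy pairs within 8 Å (negated so favourable
contacts score positive), a hydrogen-bond term summing
piecewise-linear ramps f(d)·g(θ) (1 below 3.0 Å / above 150°, 0 beyond
3.5 Å / below 120°) over intermolecular bonds in both directions, a count
of carbon–carbon contacts within 4.5 Å, and −0.5 per rotatable bond
(non-ring single bonds between heavy atoms each bearing another heavy
neighbour). Default weights 0.004 / 0.5 / 0.1 / 0.5. The absolute values
are not comparable to any published scoring function's output; only the
ranking within a run is meaningful.

**End-point binding energy** (entropy omitted):
ΔG = E_vdw + E_elec + ΔG_polar + ΔG_nonpolar, all terms
complex-minus-parts.

* E_vdw, E_elec: intermolecular force-field terms at interior
  dielectric 1.
* ΔG_polar: pairwise generalized-Born, ΔG_GB = −(k/2)(1 − 1/ε_w)
  ΣΣ q_i q_j / f_GB with the Still interpolation
  f_GB = √(r² + R_i R_j exp(−r²/4R_iR_j)) and ε_w = 80. Effective radii
  use the atom's collision radius as intrinsic radius with HCT-style
  analytic pairwise descreening (neighbour radii scaled by 0.8), so an
  isolated ion reproduces the Born closed form exactly — that limit is
  the model's test anchor.
* ΔG_nonpolar: γ·ΔSASA with γ = 0.00542 kcal/mol/Å², probe 1.4 Å,
  960-point Shrake–Rupley sampling over heavy atoms. The per-state
  constant offset (0.92 kcal/mol in the common parameterization) cancels
  identically in the complex-minus-parts difference and is therefore not
  reported. All three states share one sampling-grid orientation — the
  complex's principal-axes body frame, sign-anchored to the first
  off-centroid atom — which both cancels quadrature error in ΔSASA and
  makes the result invariant under global rigid motion (up to exactly
  degenerate principal moments).

**Group electrostatics**: the Coulomb sum of a named ligand atom group
(e.g. a nitro group) against the whole receptor, at the same dielectric
as the MM term — so groups that partition the ligand sum exactly to
E_elec. This is the decomposition that attributes binding differences
between congeneric ligands to a single chemical group.

## Synthetic scenes

The generators are pure functions of spec + seed and exist so that every
stage has inputs with known ground truth.

* **Dimer**: two ideal helices (rise 1.5 Å/residue, twist 100°, Cα radius
  2.3 Å) antiparallel at 11 Å separation, with reduced pseudo-atom side
  chains (3–4 atoms). The default plants the canonical contact pattern
  symmetrically: a glutamine N–H and a lysine N–H on each chain donate
  into the partner glutamate's two carboxylate oxygens, collinearly at
  2.9 Å (realized exactly by construction; each contact arm aims at a
  laterally offset target, offsets ordered by the donors' own z-positions
  so arms run parallel instead of crossing), plus facing leucine side
  chains as the hydrophobic patch. The glutamate antecedent carbon sits
  2 Å behind the oxygens along the mean incoming-donor axis so that the
  derived HD features project back into the interface space. Charges come
  from a built-in table (simplified Amber-flavoured values that sum
  exactly to each residue's formal charge; Lennard-Jones by element,
  Bondi radii), overridable by a user TSV table.
* **Ensembles**: i.i.d. Gaussian jitter (default σ = 0.1 Å) per
  coordinate around the reference, frame 0 left clean. This reproduces
  the *averaging* structure of trajectory analysis — occupancies,
  per-frame means, standard deviations — but none of its physics: no
  correlated motions, no side-chain rotamer flips, no drift. Tests passing
  on jittered ensembles show the bookkeeping and geometry are right, not
  that the method would identify hot spots in a real trajectory.
* **Libraries**: actives are rigid, valence-correct molecules assembled
  around the model points (urea-like donor pair, nitro group at the
  lysine-facing acceptor point, aldehyde carbonyl at the other, benzene
  ring at the hydrophobic point, all on a central scaffold carbon) with
  per-feature uniform noise < 0.3 Å — echoing the diphenyl-urea
  chemotype's feature layout, though bond lengths to the scaffold are
  stretched and make no claim of synthesizability. Decoys violate the
  model by construction: half have their donor nitrogens replaced by
  ether oxygens (no HD features → no kind-compatible assignment
  possible), half displace two feature groups by 3.5 Å — and because
  superposition can absorb displacement (see above), each displaced decoy
  is verified against the matcher at the 1.0 Å gate and rebuilt with a
  1.5× larger displacement if it slipped through, so the decoy label is
  guaranteed, not probabilistic. A neutral-tail analog (nitro → methyl)
  is generated for group-decomposition contrasts. Ligand partial charges
  come from a small rule-based typer (group-neutral nitro, carboxylate,
  carbonyl, hydroxyl, amine and pyridine assignments); an SDF property
  can override them.

## Numerical choices and degenerate inputs

Atom overlaps below 10⁻⁶ Å raise rather than return infinities; the
dielectric denominator is ε(r)·r, never clamped. Superposition uses
proper rotations only; reflections are never considered. The SASA grid is
a deterministic golden-spiral lattice; the sphere-count default (960)
puts the isolated-sphere quadrature error far below the 2% test bound.
Effective Born radii are capped at 1000 Å (the descreening sum can
otherwise cross zero for deeply buried atoms). Frame iteration, residue
ordering, screening order and all output tables are deterministic;
reruns of the pipeline with one config + seed are byte-identical, which
the test suite asserts.

Problem sizes throughout (11 residues per helix, 20-frame ensembles,
50-ligand libraries, 20-replicate recovery studies) are chosen so the
whole suite and the acceptance script each run in seconds on one core
while still exercising every code path at realistic interface geometry.

## Known limitations

* The energy model is a fixed-charge force field with simplified built-in
  parameters; no polarization, no explicit solvent, no protonation-state
  logic (inputs must carry explicit hydrogens).
* The polar solvation term is a generalized-Born model, not a
  finite-difference Poisson–Boltzmann solution; its anchor is the
  single-ion Born limit, and absolute solvation values for large systems
  inherit GB's known compression of charge–charge screening.
* Ligands are rigid at every stage; conformational strain and torsional
  entropy are invisible. Conformers must be supplied (or generated
  synthetically) — there is no conformer generator.
* The empirical score's weights are declared defaults, not fitted to any
  affinity data set.
* Hot-spot identification on jittered synthetic ensembles validates the
  computation, not the biology; real trajectory frames (supplied as
  multi-MODEL PDB) are the intended input for scientific use.
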
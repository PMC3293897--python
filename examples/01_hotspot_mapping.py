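"""Map interface hot spots on a synthetic two-helix dimer.

Builds the planted antiparallel dimer, jitters it into a 20-frame
ensemble (a stand-in for MD production frames), computes the
ensemble-averaged residue-pair interaction matrix with no distance
cutoff, and ranks residues by their total energy against the partner
chain. The planted glutamine/lysine/glutamate contact pattern should
dominate the ranking.
"""
import helixscreen as hs

structure, table = hs.make_toy_dimer()
ensemble = hs.jitter_ensemble(structure, sigma=0.1, n_frames=20, seed=1)

matrix = hs.interface_matrix(ensemble, "A", "B")
events, occupancy = hs.detect_hbonds(ensemble)
report = hs.rank_hotspots(matrix, occupancy, chain="A")

print(f"{matrix.rows and len(matrix.entries)} residue pairs evaluated over "
      f"{ensemble.n_frames} frames")
print(f"{len(occupancy)} inter-chain hydrogen-bond pairs detected\n")
print(f"{'residue':>8} {'E (kcal/mol)':>13} {'occupancy':>10} {'hotspot':>8}")
for row in report.ranked[:5]:
    chain, number = row["residue"]
    print(f"{chain}{number:>7} {row['energy']:>13.2f} {row['occupancy']:>10.2f} "
          f"{str(row['hotspot']):>8}")

# The three most negative totals are the planted hot spots: the glutamate
# salt-bridge acceptor (~ -15 kcal/mol), the lysine donor (~ -11) and the
# glutamine donor (~ -4); everything else is near zero.
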
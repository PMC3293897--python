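"""Run the five-stage pipeline end-to-end from one config.

With no receptor/library paths the synthetic scene is generated
in-place: hot-spot mapping, pharmacophore derivation, gated screening,
rigid-body minimization and rescoring, with every intermediate written
to the output directory. The run is deterministic for a given seed.
"""
import json

import helixscreen as hs

report = hs.run_pipeline({"out_dir": "pipeline_demo", "seed": 1})

print("funnel counts:")
print(json.dumps(report.counts, indent=2, sort_keys=True))
print("\ntop of the final ranking:")
for row in report.ranking[:3]:
    print(f"  {row['ligand']:10s} pharm_rmsd {row['pharm_rmsd']:.3f} Å  "
          f"mmgbsa {row['mmgbsa_total']:+.2f} kcal/mol")
print("\noutputs written to pipeline_demo/:",
      ", ".join(sorted(report.outputs)))

# 100 conformers enter, 80 fail the pharmacophore gate (the constructed
# decoys), 10 ligands are placed clash-free, minimized and scored; rerunning
# with the same seed reproduces every output byte for byte.
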
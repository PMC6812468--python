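"""Full pipeline on a simulated study with known ground truth.

Simulates 3 taxa x 20 gene families (15% speciation divergence, 30%
duplication) plus decoys, runs search -> inference -> clustering with both
algorithms, and scores the recovered groups against the planted families.
"""

import tempfile
from pathlib import Path

from sklearn.metrics import adjusted_rand_score

from orthoswift import PipelineConfig, run_pipeline, SimConfig, shuffle_decoys, simulate
from orthoswift.io import read_groups, write_fasta

cfg = SimConfig(n_taxa=3, n_families=20, seed=7)
records, truth = simulate(cfg)
records += shuffle_decoys(cfg, 9, truth)
print(f"simulated {len(records)} proteins in {cfg.n_taxa} taxa "
      f"({cfg.n_families} families, {len(truth.inparalog_pairs)} planted "
      "in-paralog pairs, 9 decoys)")

gene_ids = [r.full_id() for r in records]
reference = truth.labels(gene_ids)

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "sim.fasta"
    with open(fasta, "w") as fh:
        write_fasta(records, fh)
    for algo in ("mcl", "apc"):
        paths = run_pipeline(
            PipelineConfig(cluster_algo=algo), fasta, Path(tmp) / algo
        )
        assign = {}
        for grp in read_groups(paths["groups"]):
            for member in grp.members:
                assign[member] = grp.group_id
        predicted = [assign.get(g, f"singleton:{g}") for g in gene_ids]
        ari = adjusted_rand_score(reference, predicted)
        n_groups = len(read_groups(paths["groups"]))
        print(f"{algo}: {n_groups} groups, adjusted Rand vs planted "
              f"families = {ari:.3f}")

print("\nAdjusted Rand of 1.0 means the clustering reproduces the planted "
      "family partition exactly; affinity propagation with the default "
      "median preference splits families more finely than Markov clustering.")
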
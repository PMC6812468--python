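"""Spaced-seed homology search on a tiny three-gene database.

Builds a spaced k-mer index over two related sequences and one unrelated
decoy, then runs the seed-and-extend search and prints the m8 hit table.
"""

import numpy as np

from orthoswift import (
    SequenceRecord,
    dont_care_positions,
    parse_spaced_seed,
    search_all_vs_all,
)

rng = np.random.default_rng(42)
AA = list("ACDEFGHIKLMNPQRSTVWY")

seed = parse_spaced_seed("101101")
print(f"seed {seed.pattern}: weight {seed.weight}, length {seed.length}, "
      f"mismatches tolerated at positions {dont_care_positions(seed)}")

# one ancestral protein, a ~85%-identity relative in another taxon, one decoy
base = rng.choice(AA, size=120)
relative = base.copy()
for i in rng.choice(120, size=18, replace=False):
    relative[i] = rng.choice([a for a in AA if a != relative[i]])
decoy = rng.choice(AA, size=120)

db = [
    SequenceRecord(gene_id="g1", taxon="taxA", residues="".join(base)),
    SequenceRecord(gene_id="g1", taxon="taxB", residues="".join(relative)),
    SequenceRecord(gene_id="g9", taxon="taxB", residues="".join(decoy)),
]

print("\nqseqid  sseqid  pident  length  evalue  bitscore")
for hit in search_all_vs_all(db):  # default: both weight-8 spaced seeds
    print(f"{hit.query_id:8}{hit.subject_id:8}{hit.pct_identity:7.1f}"
          f"{hit.aln_length:7d}  {hit.evalue:.3g}  {hit.bit_score:.1f}")

print("\nThe two taxA/taxB copies of g1 find each other (plus their "
      "self-hits); the decoy g9 reports only itself. E-values are the "
      "expected number of chance hits of that bit score in this database.")
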
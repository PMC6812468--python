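"""Orthology classification on the four-gene worked example.

Two taxa A and B each carry a duplicated gene pair.  A1-B1 are reciprocal
best hits (orthologs); the within-taxon scores exceed the ortholog score
(in-paralogs); A2 reaches the B genes only through its in-paralogy to A1
(co-orthologs).  Edge weights are bit scores normalized per taxon pair /
per taxon.
"""

from orthoswift import build_store, infer
from orthoswift.search import HomologyHit

SCORES = {
    ("A|A1", "B|B1"): 100.0,   # reciprocal best between the taxa
    ("A|A1", "A|A2"): 150.0,   # above A1's ortholog score
    ("B|B1", "B|B2"): 120.0,   # above B1's ortholog score
    ("A|A2", "B|B1"): 80.0,
    ("A|A2", "B|B2"): 60.0,
}


def full_length_hit(q, s, bit):
    return HomologyHit(
        query_id=q, subject_id=s, pct_identity=90.0, aln_length=100,
        mismatches=10, gap_opens=0, q_start=1, q_end=100, s_start=1,
        s_end=100, evalue=1e-30, bit_score=bit,
    )


hits = []
for (a, b), score in SCORES.items():
    hits += [full_length_hit(a, b, score), full_length_hit(b, a, score)]
for g in sorted({g for pair in SCORES for g in pair}):
    hits.append(full_length_hit(g, g, 300.0))  # self-hits carry the lengths

with build_store(hits, coverage_min=0.5) as store:
    for rel in infer(store):
        print(f"{rel.gene_a:6} {rel.gene_b:6} {rel.rel_type:12} "
              f"bit={rel.bit_score:6.1f}  weight={rel.weight:.3f}")

print("\nFive relations: one RBH ortholog, two in-paralogs, and the two "
      "co-ortholog edges that in-paralogy induces.  Weights divide each bit "
      "score by the mean of its normalization class, so each class of edges "
      "averages to 1.")
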
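# Methods

This note records the models and algorithms orthoswift implements, the
parameters that matter, the numerical choices at the edges, and what the
synthetic benchmark does and does not demonstrate.

## Homology search

**Spaced seeds.** A seed is a pattern over {match, don't-care} written as
`1`/`0`; the k-mer key takes only the residues under the `1` positions, so a
window may mismatch freely at the `0` positions. The number of `1`s is the
seed's *weight*; a consecutive seed is the special case weight == length.
Patterns must start and end with `1` (an outer don't-care only shortens the
effective pattern and is rejected). Two weight-8 patterns,
`1110100010001011` and `11010110111`, are registered by default and their
matches are unioned; `seeds` accepts any comma-separated list such as
`1011111,11111`.

**Reduced alphabets.** Grouping residues by physico-chemical class raises
the per-position match probability of a seed and hence sensitivity, at the
cost of less specific keys. The default is the identity 20-letter alphabet;
`murphy10` and `murphy15` (Murphy, Wallqvist & Levy 2000) ship built-in, and
an explicit grouping string (`"KR,DE"`) defines a custom reduction whose
group letter is the group's first residue. Ambiguity codes
(`X B Z J U O *`) map to a wildcard group; windows whose match positions
touch the wildcard are not indexed, preventing spurious seed matches.
Reduction is idempotent: group letters map to themselves.

**Candidate generation.** An inverted index maps (seed, key) to postings of
(sequence, offset). A subject becomes a candidate when it shares at least
`min_shared_seeds` (default 2) seeded k-mer matches with the query — the
standard two-hit filter for long seeds, which controls extension cost. The
extension band is centered on the modal diagonal (query offset − subject
offset) of the shared seeds; its half-width is `band_k` plus the observed
spread of the shared-seed diagonals (capped at 16), so genuinely drifting
candidates get a little extra room. A query's self-match is always a
candidate, even for sequences shorter than every seed, so self-hits are
never lost.

**Banded Smith–Waterman.** Local alignment with affine gaps (a gap of
length L costs `gap_open + gap_extend·L`; BLOSUM62 with 11/1 by default,
the de-facto protein-search setting) restricted to cells whose diagonal lies
within the band. Storage is band-compressed — along a diagonal the band
coordinate is constant — so both time and memory are
O(band_width · min(n, m)). With a band covering the whole matrix the result
equals unrestricted Smith–Waterman (a property the tests assert against an
independent full-matrix implementation), and the score is non-decreasing in
band width. The kernel is compiled with numba; traceback over banded
pointer matrices yields identities, mismatches, gap opens and 1-based
coordinates. Percent identity uses the BLAST convention (gap columns count
in the denominator) so the m8 output is comparable to BLASTP's.

**Statistics.** `bit = (λ·S − ln K)/ln 2`, `E = m·n·2^(−bit)` with the
gapped Karlin–Altschul constants λ = 0.267, K = 0.041 matching BLOSUM62
11/1. The search space is query length × total database residues. E-values
are kept and serialized at full double precision (shortest round-trip
representation), never clamped: rounding deep E-values to zero makes
distinct scores tie and inflates reciprocal-best-hit calls downstream.
Hits pass at `E ≤ 1e−5` by default.

**Determinism and sharding.** Output is query-major in input order, then by
descending bit score, then subject id, so runs are byte-reproducible. The
query set may be partitioned into shards whose outputs concatenate to the
serial result; shards share only the immutable index.

## Orthology inference

**Coverage filter.** A hit survives when
`min(q_cov, s_cov) ≥ coverage_min` (default 0.5), where coverage is the
aligned span over the sequence length. Requiring the minimum of both sides
is the stricter reading; per-side thresholds are available on
`build_store`. m8 carries no sequence lengths, so lengths are taken from an
explicit mapping when available (the pipeline passes the FASTA lengths) and
otherwise inferred as the maximum end coordinate observed per gene — exact
whenever self-hits are present, as the search stage guarantees.

**Hit store.** Surviving hits (`query, subject, bit`) are sorted in
bounded-memory chunks, merged to one file, and queried by bisecting byte
offsets; duplicate (query, subject) pairs keep the maximum score and self
pairs are dropped. Point lookups and sorted scans never materialize the
store in memory, so inference scales to hit tables much larger than RAM.
A pair's score is the maximum over the two stored directions, making all
downstream rules direction-free.

**Rules.** Orthologs: reciprocal best hits per ordered taxon pair, where
"best" admits every subject within relative tolerance 1e−6 of the maximum
(floating-point-safe; exact ties yield multiple RBHs, matching
InParanoid-family behavior). In-paralogs: a within-taxon pair qualifies when
its score strictly exceeds every ortholog score of each member; equality
does not qualify (deterministic boundary). A gene with no ortholog anywhere
cannot seed a call but may partner a gene that has one. Co-orthologs: for
each ortholog (a, b), the in-paralog partners of a pair with b, those of b
with a, and the partners with each other — provided the pair has a surviving
hit and is not itself an ortholog.

**Weights.** Normalized bit scores, per class: each (co-)ortholog edge is
divided by the mean (co-)ortholog score of its taxon pair; each in-paralog
edge within taxon A by the mean score of subset S — the in-paralogs of A
with at least one endpoint holding an ortholog in another taxon. If S is
empty the taxon-wide in-paralog mean is used; if that too is empty, raw bit
scores are kept (and logged). Consequences asserted by the tests: each
normalization class has mean weight 1 to 1e−9, and weights are invariant
under rescaling all bit scores. The basis is the bit score, not
−log E-value, precisely because bit scores never saturate the way rounded
E-values do.

## Clustering

**MCL.** Per connected component (flow never crosses components, so the
whole-graph result provably equals the union of per-component results — also
a test): build the weighted adjacency with a self-loop per node at its
maximum incident weight (stabilizes the flow; a common choice), column
normalize, then iterate expansion (matrix squaring) and inflation
(elementwise power `inflation`, renormalize, prune entries < 1e−5,
renormalize) until the matrix changes by < 1e−6 or `max_iter` (100), in
which case the current partition is returned with a warning. Attractor rows
(positive diagonal mass) define clusters; overlapping attractor supports are
merged by union-find. Inflation defaults to 1.5; larger values give finer
groups.

**Affinity propagation.** Messages exist only on graph edges plus the
diagonal, stored in flat arrays sorted by (node, candidate); one sweep
updates every responsibility
`R(i,k) ← S(i,k) − max_{k'≠k}(A(i,k') + S(i,k'))`
and availability
`A(i,k) ← min(0, R(k,k) + Σ_{i'∉{i,k}} max(0, R(i',k)))` (the sum alone on
the diagonal), each damped with factor 0.5 by default — the printed update
equations are undamped, but undamped message passing oscillates on
symmetric graphs, so damping follows the Frey–Dueck convention. Work per
sweep is O(E). Iteration stops when the exemplar map is unchanged for 15
consecutive sweeps (or at `max_iter` 200 with a warning). Diagonal
preferences default to the median edge similarity; argmax ties break to the
smallest node id. Nodes whose chosen exemplar is not self-consistent are
reassigned to the most similar self-electing exemplar among their
neighbors, and isolated nodes become singletons. On complete graphs the
sparse implementation reproduces an independent dense reference exactly
(asserted on random ≤30-node graphs).

Granularity caveat: with the median preference, tight small components
(normalized weights near 1 throughout) often split into finer groups than
MCL produces — median preference sits at the same scale as the
similarities. Lowering the preference (e.g. toward the minimum similarity)
coarsens the clustering; the parameter is exposed on `apc_cluster` and the
CLI. A second degenerate regime is worth knowing: on *exactly* uniform
similarities the messages are perfectly symmetric and no self-consistent
exemplar emerges (the classical motivation for adding jitter); real weighted
graphs are never exactly uniform.

**Output.** Groups are written as `OG0000001: memberA memberB ...`, members
sorted, groups ordered by decreasing size then smallest member — fixed bytes
for fixed inputs.

## Evaluation

Each reference group is matched to the predicted group maximizing the
shared-gene count (ties: higher precision, then smaller predicted group,
then id); precision = shared/|predicted|, recall = shared/|reference|.
Macro averages (unweighted over reference groups) are the headline numbers;
micro averages (pooled counts) are also reported. Genes missing from all
predictions count against recall only.

## Synthetic data

Each family draws an ancestral protein uniformly over the 20 residues
(length uniform on 100–200 — typical single-domain scale); each taxon
receives a descendant by independent per-site substitution at
`speciation_divergence` (default 0.15, giving expected pairwise identity
(1−d)² + d²/19 ≈ 72% between siblings — comfortably inside the search's
sensitive range while far from trivial identity); with probability
`duplication_rate` (0.3) a taxon adds a duplicate mutated further at 0.05.
Decoys are uniform-random sequences assigned round-robin to taxa.
Substitution is uniform over the 19 alternatives, with no rate
heterogeneity, no domain structure, and no indels unless the small-indel
mode is enabled (which exists to exercise the aligner's gap handling).

What passing tests show: the seed/extend/classify/cluster machinery
recovers planted gene families essentially perfectly at these conditions
(adjusted Rand 1.0 for MCL; planted-pair recall ≈ 99% at the search stage),
and both clusterings agree on > 99% of gene co-membership pairs. What they
do not show: performance on real proteomes with domain shuffling, partial
homology, isoforms, or compositional bias — the generator has none of
these, so the synthetic results bound correctness of the implementation,
not biological accuracy.

## Problem sizes

The standard synthetic study used by the test suite and by
`scripts/acceptance.py` is 4 taxa × 50 families with 10 decoys per taxon
(~310 proteins, ~2,400 hits); the whole acceptance computation — two
pipeline runs per clustering algorithm — completes in a few seconds on one
CPU. Oracle-equivalence suites use 200 random sequence pairs (30–80
residues) for the aligner and 100 random score tables (≤4 taxa × ≤6 genes)
for the orthology rules.

## Known limitations

- Karlin–Altschul parameters are fixed constants for BLOSUM62 11/1; other
  matrices require supplying matching λ and K.
- No composition-based statistics, translated search, or DNA mode.
- The hit store's binary search assumes the m8 producer emits parseable
  `taxon|gene` identifiers; the delimiter is configurable but must be
  consistent across stages.
- MCL materializes one dense matrix per connected component; a single huge
  component (a real risk on promiscuous-domain proteomes) is better served
  by the affinity-propagation path, whose footprint is O(E).
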
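"""Orthology inference: RBH orthologs, in-paralogs, co-orthologs, edge weights.

The classification follows the InParanoid-style rules on an all-vs-all hit
table:

* two genes in different taxa are *orthologs* when each is among the other's
  best-scoring hits in that taxon (reciprocal best hit, with a relative
  tolerance so exact ties admit multiple reciprocal bests);
* two genes in the same taxon are *in-paralogs* when their mutual bit score
  strictly exceeds every ortholog score of each of them (a gene with no
  ortholog anywhere cannot seed a call but may partner a gene that has one);
* the in-paralog partners of an ortholog pair become *co-orthologs* of the
  opposite gene (and of each other) whenever the pair still has a surviving
  hit and is not itself an ortholog.

Edge weights are normalized bit scores: (co-)ortholog edges are divided by
the mean (co-)ortholog score of their taxon pair; in-paralog edges by the
mean score of the subset S of the taxon's in-paralogs that touch at least one
gene with an ortholog elsewhere.

Hits are kept in an external-sorted file and queried by binary search over
byte offsets, so peak memory stays far below the hit count.
"""

from __future__ import annotations

import heapq
import os
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from typing import (
    Dict,
    Iterable,
    Iterator,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
)

from .search import HomologyHit

__all__ = [
    "OrthologyRelation",
    "SortedHitStore",
    "build_store",
    "find_orthologs",
    "find_inparalogs",
    "find_coorthologs",
    "normalize_weights",
    "infer",
]

ORTHOLOG = "ortholog"
CO_ORTHOLOG = "co-ortholog"
IN_PARALOG = "in-paralog"

#: relative bit-score tolerance within which hits count as tied "best"
BEST_HIT_REL_TOL = 1e-6


@dataclass(frozen=True)
class OrthologyRelation:
    """A typed, weighted, undirected edge between two taxon-tagged genes.

    Stored once with ``gene_a < gene_b`` canonical ordering; in-paralogs join
    genes of one taxon, (co-)orthologs join different taxa.
    """

    gene_a: str
    gene_b: str
    rel_type: str
    bit_score: float
    weight: float = 0.0

    @staticmethod
    def make(
        x: str, y: str, rel_type: str, bit_score: float, weight: float = 0.0
    ) -> "OrthologyRelation":
        a, b = (x, y) if x < y else (y, x)
        return OrthologyRelation(a, b, rel_type, bit_score, weight)

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def to_tsv_line(self) -> str:
        return (
            f"{self.gene_a}\t{self.gene_b}\t{self.rel_type}"
            f"\t{repr(self.bit_score)}\t{repr(self.weight)}"
        )


def taxon_of(gene_id: str, delimiter: str = "|") -> str:
    """Taxon part of a taxon-tagged gene id like ``taxA|g1``."""
    tax, _, rest = gene_id.partition(delimiter)
    if not rest:
        raise ValueError(
            f"gene id {gene_id!r} lacks the taxon delimiter {delimiter!r}"
        )
    return tax


def _parse_m8_fields(line: str, lineno: int) -> Tuple[str, str, int, int, int, int, float]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 12:
        raise ValueError(
            f"line {lineno}: expected 12 tab-separated m8 columns, got {len(parts)}"
        )
    try:
        return (
            parts[0],
            parts[1],
            int(parts[6]),
            int(parts[7]),
            int(parts[8]),
            int(parts[9]),
            float(parts[11]),
        )
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparseable m8 fields ({exc})") from exc


class SortedHitStore:
    """Coverage-filtered hits, externally sorted, queried by binary search.

    Hit lines ``query<TAB>subject<TAB>bit_score`` are sorted lexicographically
    in bounded-memory chunks, merged onto disk, and looked up by bisecting
    byte offsets in the merged file, so a lookup never loads the store into
    memory.  Duplicate ``(query, subject)`` pairs keep the maximum bit score;
    self pairs are dropped at build time.
    """

    def __init__(self, path: str, delimiter: str, _tmpdir=None) -> None:
        self.path = path
        self.delimiter = delimiter
        self._tmpdir = _tmpdir  # keeps the backing TemporaryDirectory alive
        self._fh = open(path, "rb")
        self._fh.seek(0, os.SEEK_END)
        self._size = self._fh.tell()

    # -- binary search plumbing -------------------------------------------

    def _line_start_at_or_before(self, offset: int) -> int:
        """Offset of the first line boundary at or before ``offset``."""
        if offset <= 0:
            return 0
        back = min(offset, 4096)
        while True:
            self._fh.seek(offset - back)
            chunk = self._fh.read(back)
            nl = chunk.rfind(b"\n")
            if nl != -1:
                return offset - back + nl + 1
            if back == offset:
                return 0
            back = min(offset, back * 2)

    def _first_offset_ge(self, prefix: bytes) -> int:
        """Smallest line-start offset whose line sorts >= ``prefix``."""
        lo, hi = 0, self._size
        while lo < hi:
            mid = (lo + hi) // 2
            start = self._line_start_at_or_before(mid)
            self._fh.seek(start)
            line = self._fh.readline()
            if line.rstrip(b"\n") < prefix:
                nxt = start + len(line)
                lo = nxt if nxt > lo else lo + 1
            else:
                hi = start if start < hi else mid
        return self._line_start_at_or_before(lo)

    def _iter_lines_from(self, offset: int) -> Iterator[bytes]:
        self._fh.seek(offset)
        for line in self._fh:
            yield line

    # -- queries -----------------------------------------------------------

    def hits_of(self, gene: str) -> List[Tuple[str, float]]:
        """All ``(subject, bit_score)`` records for a query gene."""
        prefix = gene.encode() + b"\t"
        out: List[Tuple[str, float]] = []
        for raw in self._iter_lines_from(self._first_offset_ge(prefix)):
            if not raw.startswith(prefix):
                break
            _, subject, score = raw.decode().rstrip("\n").split("\t")
            out.append((subject, float(score)))
        return out

    def score(self, a: str, b: str) -> Optional[float]:
        """Bit score of the (a, b) pair: max over both stored directions."""
        best: Optional[float] = None
        for q, s in ((a, b), (b, a)):
            prefix = f"{q}\t{s}\t".encode()
            off = self._first_offset_ge(prefix)
            self._fh.seek(off)
            raw = self._fh.readline()
            if raw.startswith(prefix):
                val = float(raw.decode().rstrip("\n").split("\t")[2])
                best = val if best is None or val > best else best
        return best

    def has_pair(self, a: str, b: str) -> bool:
        return self.score(a, b) is not None

    def iter_queries(self) -> Iterator[Tuple[str, List[Tuple[str, float]]]]:
        """Stream ``(query, [(subject, score), ...])`` groups in sorted order.

        Uses its own file handle so point lookups (which seek the shared
        handle) remain safe while a scan is in progress.
        """
        current: Optional[str] = None
        bucket: List[Tuple[str, float]] = []
        with open(self.path, "rb") as fh:
            for raw in fh:
                q, s, score = raw.decode().rstrip("\n").split("\t")
                if q != current:
                    if current is not None:
                        yield current, bucket
                    current, bucket = q, []
                bucket.append((s, float(score)))
        if current is not None:
            yield current, bucket

    def genes(self) -> List[str]:
        return [q for q, _ in self.iter_queries()]

    def close(self) -> None:
        self._fh.close()
        if self._tmpdir is not None:
            self._tmpdir.cleanup()
            self._tmpdir = None

    def __enter__(self) -> "SortedHitStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _infer_lengths(
    hits: Sequence[Tuple[str, str, int, int, int, int, float]]
) -> Dict[str, int]:
    # An m8 file carries no sequence lengths; the self-hit (always emitted by
    # the search stage, full length) makes max(end coordinate) exact.
    lengths: Dict[str, int] = defaultdict(int)
    for q, s, qs, qe, ss, se, _ in hits:
        if qe > lengths[q]:
            lengths[q] = qe
        if se > lengths[s]:
            lengths[s] = se
    return dict(lengths)


def build_store(
    hits: Iterable,
    coverage_min: float = 0.5,
    lengths: Optional[Mapping[str, int]] = None,
    delimiter: str = "|",
    chunk_size: int = 100_000,
    workdir: Optional[str] = None,
) -> SortedHitStore:
    """Filter, sort and persist hits for binary-searchable lookup.

    ``hits`` may be :class:`~orthoswift.search.HomologyHit` objects or raw m8
    lines.  Hits failing ``min(q_cov, s_cov) >= coverage_min`` and self pairs
    are excluded.  Sequence lengths for coverage come from ``lengths`` when
    given, else from the maximum end coordinate seen per gene.
    """
    parsed: List[Tuple[str, str, int, int, int, int, float]] = []
    for lineno, h in enumerate(hits, start=1):
        if isinstance(h, HomologyHit):
            parsed.append(
                (h.query_id, h.subject_id, h.q_start, h.q_end,
                 h.s_start, h.s_end, h.bit_score)
            )
        else:
            text = str(h)
            if not text.strip():
                continue
            parsed.append(_parse_m8_fields(text, lineno))

    if lengths is None:
        lengths = _infer_lengths(parsed)

    tmpdir = tempfile.TemporaryDirectory(prefix="orthoswift-store-", dir=workdir)
    chunk_paths: List[str] = []
    chunk: List[str] = []

    def flush() -> None:
        if not chunk:
            return
        chunk.sort()
        path = os.path.join(tmpdir.name, f"chunk{len(chunk_paths):05d}.tsv")
        with open(path, "w") as fh:
            fh.write("".join(chunk))
        chunk_paths.append(path)
        chunk.clear()

    for q, s, qs, qe, ss, se, bit in parsed:
        if q == s:
            continue
        qlen = lengths.get(q, 0)
        slen = lengths.get(s, 0)
        if qlen <= 0 or slen <= 0:
            raise ValueError(f"no length known for hit {q} vs {s}")
        q_cov = (qe - qs + 1) / qlen
        s_cov = (se - ss + 1) / slen
        if min(q_cov, s_cov) < coverage_min:
            continue
        taxon_of(q, delimiter), taxon_of(s, delimiter)  # validate ids early
        chunk.append(f"{q}\t{s}\t{repr(bit)}\n")
        if len(chunk) >= chunk_size:
            flush()
    flush()

    merged_path = os.path.join(tmpdir.name, "store.tsv")
    files = [open(p) for p in chunk_paths]
    try:
        with open(merged_path, "w") as out:
            last_key: Optional[Tuple[str, str]] = None
            last_score = 0.0
            for line in heapq.merge(*files):
                q, s, score = line.rstrip("\n").split("\t")
                key = (q, s)
                val = float(score)
                if key == last_key:
                    if val > last_score:
                        last_score = val
                    continue
                if last_key is not None:
                    out.write(f"{last_key[0]}\t{last_key[1]}\t{repr(last_score)}\n")
                last_key, last_score = key, val
            if last_key is not None:
                out.write(f"{last_key[0]}\t{last_key[1]}\t{repr(last_score)}\n")
    finally:
        for fh in files:
            fh.close()
    for p in chunk_paths:
        os.unlink(p)

    return SortedHitStore(merged_path, delimiter, _tmpdir=tmpdir)


def _best_sets_by_taxon(
    store: SortedHitStore,
) -> Dict[str, Dict[str, Set[str]]]:
    """For each gene, the set of tied-best subjects per foreign taxon."""
    best: Dict[str, Dict[str, Set[str]]] = {}
    for gene, subjects in store.iter_queries():
        g_tax = taxon_of(gene, store.delimiter)
        per_taxon: Dict[str, List[Tuple[str, float]]] = defaultdict(list)
        for subject, score in subjects:
            s_tax = taxon_of(subject, store.delimiter)
            if s_tax != g_tax:
                per_taxon[s_tax].append((subject, score))
        best[gene] = {}
        for tax, pairs in per_taxon.items():
            top = max(score for _, score in pairs)
            tol = abs(top) * BEST_HIT_REL_TOL
            best[gene][tax] = {s for s, v in pairs if v >= top - tol}
    return best


def find_orthologs(store: SortedHitStore) -> Set[OrthologyRelation]:
    """Reciprocal-best-hit orthologs across every taxon pair."""
    best = _best_sets_by_taxon(store)
    out: Set[OrthologyRelation] = set()
    for a, per_taxon in best.items():
        a_tax = taxon_of(a, store.delimiter)
        for b_tax, candidates in per_taxon.items():
            for b in candidates:
                if a >= b:
                    continue  # each unordered pair once, from its smaller end
                if a in best.get(b, {}).get(a_tax, ()):  # reciprocal
                    score = store.score(a, b)
                    if score is not None:
                        out.add(OrthologyRelation.make(a, b, ORTHOLOG, score))
    return out


def _ortholog_partners(
    orthologs: Iterable[OrthologyRelation],
) -> Dict[str, List[Tuple[str, float]]]:
    partners: Dict[str, List[Tuple[str, float]]] = defaultdict(list)
    for rel in orthologs:
        partners[rel.gene_a].append((rel.gene_b, rel.bit_score))
        partners[rel.gene_b].append((rel.gene_a, rel.bit_score))
    return partners


def find_inparalogs(
    store: SortedHitStore, orthologs: Iterable[OrthologyRelation]
) -> Set[OrthologyRelation]:
    """Within-taxon pairs scoring strictly above each member's ortholog scores."""
    partners = _ortholog_partners(orthologs)
    thresholds: Dict[str, float] = {
        g: max(score for _, score in plist) for g, plist in partners.items()
    }
    out: Set[OrthologyRelation] = set()
    for gene, subjects in store.iter_queries():
        g_tax = taxon_of(gene, store.delimiter)
        for subject, _ in subjects:
            if gene >= subject:
                continue  # each unordered pair once, from its smaller end
            if taxon_of(subject, store.delimiter) != g_tax:
                continue
            if gene not in thresholds and subject not in thresholds:
                continue  # neither gene has an ortholog anywhere
            pair_score = store.score(gene, subject)
            if pair_score is None:
                continue
            ok = True
            for g in (gene, subject):
                if g in thresholds and not pair_score > thresholds[g]:
                    ok = False
                    break
            if ok:
                out.add(
                    OrthologyRelation.make(gene, subject, IN_PARALOG, pair_score)
                )
    return out


def find_coorthologs(
    store: SortedHitStore,
    orthologs: Iterable[OrthologyRelation],
    inparalogs: Iterable[OrthologyRelation],
) -> Set[OrthologyRelation]:
    """Cross-taxon pairs linked through an ortholog's in-paralogs."""
    ortholog_pairs = {rel.pair for rel in orthologs}
    inpar_partners: Dict[str, Set[str]] = defaultdict(set)
    for rel in inparalogs:
        inpar_partners[rel.gene_a].add(rel.gene_b)
        inpar_partners[rel.gene_b].add(rel.gene_a)

    out: Set[OrthologyRelation] = set()

    def consider(x: str, y: str) -> None:
        a, b = (x, y) if x < y else (y, x)
        if (a, b) in ortholog_pairs:
            return
        if taxon_of(a, store.delimiter) == taxon_of(b, store.delimiter):
            return
        score = store.score(a, b)
        if score is None:
            return
        out.add(OrthologyRelation.make(a, b, CO_ORTHOLOG, score))

    for rel in orthologs:
        a, b = rel.pair
        for a2 in inpar_partners.get(a, ()):
            consider(a2, b)
            for b2 in inpar_partners.get(b, ()):
                consider(a2, b2)
        for b2 in inpar_partners.get(b, ()):
            consider(a, b2)
    return out


def normalize_weights(
    relations: Iterable[OrthologyRelation], delimiter: str = "|"
) -> List[OrthologyRelation]:
    """Attach normalized bit-score weights to every relation.

    (Co-)ortholog edges between taxa A and B are divided by the mean
    (co-)ortholog bit score of that taxon pair.  In-paralog edges within a
    taxon are divided by the mean score of subset S — the taxon's in-paralogs
    with at least one endpoint having an ortholog in another taxon; if S is
    empty the taxon-wide in-paralog mean is used, and if that too is empty
    the raw bit scores are kept.
    """
    rels = list(relations)
    cross = [r for r in rels if r.rel_type in (ORTHOLOG, CO_ORTHOLOG)]
    intra = [r for r in rels if r.rel_type == IN_PARALOG]

    pair_mean: Dict[Tuple[str, str], float] = {}
    pair_scores: Dict[Tuple[str, str], List[float]] = defaultdict(list)
    for r in cross:
        key = tuple(sorted((taxon_of(r.gene_a, delimiter),
                            taxon_of(r.gene_b, delimiter))))
        pair_scores[key].append(r.bit_score)
    for key, scores in pair_scores.items():
        pair_mean[key] = sum(scores) / len(scores)

    has_ortholog: Set[str] = set()
    for r in rels:
        if r.rel_type == ORTHOLOG:
            has_ortholog.add(r.gene_a)
            has_ortholog.add(r.gene_b)

    s_scores: Dict[str, List[float]] = defaultdict(list)
    all_scores: Dict[str, List[float]] = defaultdict(list)
    for r in intra:
        tax = taxon_of(r.gene_a, delimiter)
        all_scores[tax].append(r.bit_score)
        if r.gene_a in has_ortholog or r.gene_b in has_ortholog:
            s_scores[tax].append(r.bit_score)
    intra_mean: Dict[str, Optional[float]] = {}
    for tax, scores in all_scores.items():
        subset = s_scores.get(tax)
        basis = subset if subset else scores
        intra_mean[tax] = sum(basis) / len(basis) if basis else None

    out: List[OrthologyRelation] = []
    for r in rels:
        if r.rel_type == IN_PARALOG:
            mean = intra_mean.get(taxon_of(r.gene_a, delimiter))
            weight = r.bit_score / mean if mean else r.bit_score
        else:
            key = tuple(sorted((taxon_of(r.gene_a, delimiter),
                                taxon_of(r.gene_b, delimiter))))
            weight = r.bit_score / pair_mean[key]
        out.append(
            OrthologyRelation(r.gene_a, r.gene_b, r.rel_type, r.bit_score, weight)
        )
    return out


def _relation_sort_key(r: OrthologyRelation, delimiter: str):
    taxa = tuple(sorted((taxon_of(r.gene_a, delimiter),
                         taxon_of(r.gene_b, delimiter))))
    return (taxa, r.gene_a, r.gene_b)


def infer(store: SortedHitStore) -> List[OrthologyRelation]:
    """Full classification with weights, deterministically ordered."""
    orthologs = find_orthologs(store)
    inparalogs = find_inparalogs(store, orthologs)
    coorthologs = find_coorthologs(store, orthologs, inparalogs)
    weighted = normalize_weights(
        list(orthologs) + list(inparalogs) + list(coorthologs),
        delimiter=store.delimiter,
    )
    weighted.sort(key=lambda r: _relation_sort_key(r, store.delimiter))
    return weighted
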
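"""All-vs-all protein homology search: seed, extend, score.

The search follows the seed-and-extension paradigm: spaced k-mers from a
reduced-alphabet view of every database sequence are indexed; a query's
candidates are the subjects sharing enough seeded k-mers; each candidate is
extended with a k-banded Smith-Waterman centered on the modal diagonal of the
shared seeds; alignments are scored with Karlin-Altschul statistics and hits
passing the E-value threshold are reported in BLAST-tabular (m8) semantics.

E-values are kept at full double precision (down to ~1e-308) — rounding them
to zero is a known source of false reciprocal-best-hit calls downstream.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from ._align import banded_sw
from .seeds import (
    ReducedAlphabet,
    SpacedSeed,
    default_seeds,
    identity_alphabet,
    iter_index_kmers,
)

__all__ = [
    "SequenceRecord",
    "AlignmentParams",
    "HomologyHit",
    "KmerIndex",
    "build_index",
    "find_candidates",
    "kbanded_smith_waterman",
    "score_statistics",
    "search_all_vs_all",
    "compute_coverage",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein with its taxon tag; ``(taxon, gene_id)`` is unique in a run."""

    gene_id: str
    taxon: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"{self.taxon}|{self.gene_id}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def length(self) -> int:
        return len(self.residues)

    def full_id(self, delimiter: str = "|") -> str:
        return f"{self.taxon}{delimiter}{self.gene_id}"


def _load_blosum62() -> Tuple[np.ndarray, str]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    arr = np.array(mat, dtype=np.int64)
    return arr, alphabet


_BLOSUM62, _BLOSUM62_ALPHABET = _load_blosum62()


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for extension and statistics.

    Defaults are the de-facto protein-search settings: BLOSUM62 with gap
    open 11 / extend 1 and the matching gapped Karlin-Altschul constants
    lambda = 0.267, K = 0.041.  ``band_k`` is the maximum number of gaps the
    banded extension allows (the band half-width grows from it).
    """

    matrix: np.ndarray = field(default_factory=lambda: _BLOSUM62, repr=False)
    matrix_alphabet: str = _BLOSUM62_ALPHABET
    gap_open: int = 11
    gap_extend: int = 1
    band_k: int = 32
    lambda_: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive (applied as costs)")
        if self.band_k < 0:
            raise ValueError("band_k must be >= 0")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def encode(self, residues: str) -> np.ndarray:
        """Map residues to matrix row indices; unknown letters become 'X'."""
        alpha = self.matrix_alphabet
        x = alpha.index("X") if "X" in alpha else 0
        lut = np.full(128, x, dtype=np.int64)
        for i, c in enumerate(alpha):
            lut[ord(c)] = i
        codes = np.frombuffer(residues.upper().encode("ascii"), dtype=np.uint8)
        return lut[codes]


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise local-alignment record in BLAST-tabular semantics."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def to_m8_line(self) -> str:
        return "\t".join(
            (
                self.query_id,
                self.subject_id,
                f"{self.pct_identity:.2f}",
                str(self.aln_length),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                repr(self.evalue),
                repr(self.bit_score),
            )
        )


@dataclass
class KmerIndex:
    """Inverted index: (seed ordinal, spaced k-mer key) → postings.

    Postings are ``(sequence ordinal, window position)`` pairs, sorted.
    ``total_residues`` is the summed database length used as the search-space
    size for E-values.
    """

    records: List[SequenceRecord]
    seeds: List[SpacedSeed]
    alphabet: ReducedAlphabet
    postings: Dict[Tuple[int, str], List[Tuple[int, int]]]
    total_residues: int

    def __len__(self) -> int:
        return len(self.records)


def build_index(
    db: Sequence[SequenceRecord],
    seeds: Optional[Sequence[SpacedSeed]] = None,
    alphabet: Optional[ReducedAlphabet] = None,
) -> KmerIndex:
    """Index every non-wildcard seeded k-mer of every sequence under every seed."""
    if not db:
        raise ValueError("cannot index an empty database")
    seen = set()
    for rec in db:
        key = (rec.taxon, rec.gene_id)
        if key in seen:
            raise ValueError(f"duplicate sequence id {rec.taxon}|{rec.gene_id}")
        seen.add(key)
    seeds = list(seeds) if seeds is not None else default_seeds()
    alphabet = alphabet if alphabet is not None else identity_alphabet()
    postings: Dict[Tuple[int, str], List[Tuple[int, int]]] = defaultdict(list)
    for ordinal, rec in enumerate(db):
        for si, key, pos in iter_index_kmers(rec.residues, seeds, alphabet):
            postings[(si, key)].append((ordinal, pos))
    for plist in postings.values():
        plist.sort()
    return KmerIndex(
        records=list(db),
        seeds=seeds,
        alphabet=alphabet,
        postings=dict(postings),
        total_residues=sum(r.length for r in db),
    )


def find_candidates(
    query: SequenceRecord,
    index: KmerIndex,
    min_shared_seeds: int = 2,
) -> List[Tuple[int, int]]:
    """Subjects sharing enough seeded k-mers with the query, plus modal diagonal.

    Returns ``(subject ordinal, diagonal offset)`` pairs where the diagonal is
    the modal value of ``q_pos - s_pos`` over the shared seed matches (ties
    break toward the smaller diagonal).  The query's self-match is always a
    candidate.  Also records the diagonal spread per subject for band sizing
    (see :func:`candidate_details`).
    """
    return [(o, d) for o, d, _ in candidate_details(query, index, min_shared_seeds)]


def candidate_details(
    query: SequenceRecord,
    index: KmerIndex,
    min_shared_seeds: int = 2,
) -> List[Tuple[int, int, int]]:
    """As :func:`find_candidates` but with the diagonal spread as third element."""
    diag_counts: Dict[int, Counter] = defaultdict(Counter)
    for si, key, q_pos in iter_index_kmers(
        query.residues, index.seeds, index.alphabet
    ):
        for ordinal, s_pos in index.postings.get((si, key), ()):
            diag_counts[ordinal][q_pos - s_pos] += 1

    self_ordinal = None
    for ordinal, rec in enumerate(index.records):
        if rec.taxon == query.taxon and rec.gene_id == query.gene_id:
            self_ordinal = ordinal
            break

    out: List[Tuple[int, int, int]] = []
    for ordinal in sorted(diag_counts):
        counts = diag_counts[ordinal]
        total = sum(counts.values())
        if total < min_shared_seeds and ordinal != self_ordinal:
            continue
        # modal diagonal, smallest wins on ties
        modal = min(counts, key=lambda d: (-counts[d], d))
        spread = max(counts) - min(counts)
        out.append((ordinal, modal, spread))
    if self_ordinal is not None and self_ordinal not in diag_counts:
        # shorter than the seed: still report the self alignment
        out.append((self_ordinal, 0, 0))
        out.sort()
    return out


def kbanded_smith_waterman(
    q: str,
    s: str,
    params: AlignmentParams,
    center_diagonal: int = 0,
    half_width: Optional[int] = None,
) -> Tuple[int, int, int, int, int, int, int, int, int]:
    """Local alignment restricted to a band around ``center_diagonal``.

    Returns ``(raw_score, q_start, q_end, s_start, s_end, aln_length,
    identities, mismatches, gap_opens)``; coordinates are 1-based inclusive
    and all-zero when nothing scores above 0.  The band half-width defaults to
    ``params.band_k`` (the maximum number of gaps the alignment may use).
    """
    if not q or not s:
        raise ValueError("sequences must be non-empty")
    w = params.band_k if half_width is None else half_width
    return tuple(
        int(v)
        for v in banded_sw(
            params.encode(q),
            params.encode(s),
            params.matrix,
            params.gap_open,
            params.gap_extend,
            center_diagonal,
            w,
        )
    )


def score_statistics(
    raw_score: int,
    query_len: int,
    db_residues: int,
    params: AlignmentParams,
) -> Tuple[float, float]:
    """Karlin-Altschul bit score and E-value for a raw alignment score.

    ``bit = (lambda*S - ln K) / ln 2`` and ``E = m*n*2**(-bit)``, kept in
    double precision so values down to ~1e-308 survive (no rounding to zero).
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    bit = (params.lambda_ * raw_score - math.log(params.K)) / math.log(2.0)
    evalue = float(query_len) * float(db_residues) * math.pow(2.0, -bit)
    return bit, evalue


def compute_coverage(
    hit: HomologyHit, qlen: int, slen: int
) -> Tuple[float, float]:
    """Fractions of query and subject spanned by the aligned region."""
    if not (1 <= hit.q_start <= hit.q_end <= qlen):
        raise ValueError(f"bad query coordinates in hit {hit.query_id}-{hit.subject_id}")
    if not (1 <= hit.s_start <= hit.s_end <= slen):
        raise ValueError(f"bad subject coordinates in hit {hit.query_id}-{hit.subject_id}")
    return (
        (hit.q_end - hit.q_start + 1) / qlen,
        (hit.s_end - hit.s_start + 1) / slen,
    )


#: cap on the extra band width granted for observed seed-diagonal drift
_MAX_DRIFT_ALLOWANCE = 16


def search_all_vs_all(
    db: Sequence[SequenceRecord],
    params: Optional[AlignmentParams] = None,
    seeds: Optional[Sequence[SpacedSeed]] = None,
    alphabet: Optional[ReducedAlphabet] = None,
    evalue_max: float = 1e-5,
    min_shared_seeds: int = 2,
    id_delimiter: str = "|",
) -> Iterator[HomologyHit]:
    """Stream m8-style hits for every query against the whole database.

    Hits are emitted query-major in database order, then by descending bit
    score, then by subject id, so output bytes are reproducible.  Every
    sequence reports a self-hit (it always passes the default threshold).
    """
    params = params or AlignmentParams()
    index = build_index(db, seeds=seeds, alphabet=alphabet)
    yield from search_against_index(
        index, params, evalue_max=evalue_max,
        min_shared_seeds=min_shared_seeds, id_delimiter=id_delimiter,
    )


def search_against_index(
    index: KmerIndex,
    params: Optional[AlignmentParams] = None,
    evalue_max: float = 1e-5,
    min_shared_seeds: int = 2,
    id_delimiter: str = "|",
    query_ordinals: Optional[Iterable[int]] = None,
) -> Iterator[HomologyHit]:
    """Search a subset (or all) of the indexed sequences against the index.

    ``query_ordinals`` lets callers shard the query set; concatenating the
    shard outputs in ordinal order reproduces the serial result exactly.
    """
    params = params or AlignmentParams()
    db = index.records
    ordinals = range(len(db)) if query_ordinals is None else query_ordinals
    for q_ord in ordinals:
        query = db[q_ord]
        q_codes_len = query.length
        hits: List[HomologyHit] = []
        for s_ord, diag, spread in candidate_details(
            query, index, min_shared_seeds
        ):
            subject = db[s_ord]
            half_width = params.band_k + min(spread, _MAX_DRIFT_ALLOWANCE)
            (
                raw,
                q_start,
                q_end,
                s_start,
                s_end,
                aln_len,
                identities,
                mismatches,
                gap_opens,
            ) = kbanded_smith_waterman(
                query.residues, subject.residues, params, diag, half_width
            )
            if raw <= 0:
                continue
            bit, evalue = score_statistics(
                raw, q_codes_len, index.total_residues, params
            )
            if evalue > evalue_max:
                continue
            hits.append(
                HomologyHit(
                    query_id=query.full_id(id_delimiter),
                    subject_id=subject.full_id(id_delimiter),
                    pct_identity=100.0 * identities / aln_len,
                    aln_length=aln_len,
                    mismatches=mismatches,
                    gap_opens=gap_opens,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    evalue=evalue,
                    bit_score=bit,
                )
            )
        hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
        yield from hits
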
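"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written the slow, obvious way — full-matrix
dynamic programming, exhaustive double loops, dense message passing — and
shares no code with the library paths it checks.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from orthoswift.search import AlignmentParams, HomologyHit


# ---------------------------------------------------------------------------
# full (unbanded) Smith-Waterman with affine gaps — alignment oracle
# ---------------------------------------------------------------------------

def full_smith_waterman(q: str, s: str, params: AlignmentParams) -> int:
    """Best local alignment score over the entire DP matrix (Gotoh)."""
    qc = params.encode(q)
    sc = params.encode(s)
    n, m = len(qc), len(sc)
    NEG = -(10 ** 9)
    open_cost = params.gap_open + params.gap_extend
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    mat = params.matrix
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - params.gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - params.gap_extend)
            h = max(
                0,
                H[i - 1][j - 1] + int(mat[qc[i - 1], sc[j - 1]]),
                E[i][j],
                F[i][j],
            )
            H[i][j] = h
            if h > best:
                best = h
    return best


# ---------------------------------------------------------------------------
# exhaustive orthology-rule oracles over an explicit score table
# ---------------------------------------------------------------------------

ScoreTable = Dict[Tuple[str, str], float]  # symmetric pair -> bit score


def _taxon(gene: str) -> str:
    return gene.split("|", 1)[0]


def _pair_score(table: ScoreTable, a: str, b: str) -> Optional[float]:
    vals = [table[k] for k in ((a, b), (b, a)) if k in table]
    return max(vals) if vals else None


def brute_orthologs(table: ScoreTable) -> Set[Tuple[str, str]]:
    """RBH by exhaustive double loop; ties (relative 1e-6) admit multiples."""
    genes = sorted({g for pair in table for g in pair})

    def best_set(a: str, tax: str) -> Set[str]:
        scored = [
            (b, table[(a, b)])
            for b in genes
            if b != a and _taxon(b) == tax and (a, b) in table
        ]
        if not scored:
            return set()
        top = max(v for _, v in scored)
        return {b for b, v in scored if v >= top - abs(top) * 1e-6}

    out: Set[Tuple[str, str]] = set()
    for a, b in itertools.combinations(genes, 2):
        if _taxon(a) == _taxon(b):
            continue
        if b in best_set(a, _taxon(b)) and a in best_set(b, _taxon(a)):
            out.add((a, b) if a < b else (b, a))
    return out


def brute_inparalogs(
    table: ScoreTable, orthologs: Set[Tuple[str, str]]
) -> Set[Tuple[str, str]]:
    genes = sorted({g for pair in table for g in pair})
    orth_scores: Dict[str, List[float]] = defaultdict(list)
    for a, b in orthologs:
        score = _pair_score(table, a, b)
        orth_scores[a].append(score)
        orth_scores[b].append(score)

    out: Set[Tuple[str, str]] = set()
    for a, b in itertools.combinations(genes, 2):
        if _taxon(a) != _taxon(b):
            continue
        score = _pair_score(table, a, b)
        if score is None:
            continue
        if a not in orth_scores and b not in orth_scores:
            continue
        if all(
            score > max(orth_scores[g])
            for g in (a, b)
            if g in orth_scores
        ):
            out.add((a, b))
    return out


def brute_coorthologs(
    table: ScoreTable,
    orthologs: Set[Tuple[str, str]],
    inparalogs: Set[Tuple[str, str]],
) -> Set[Tuple[str, str]]:
    partners: Dict[str, Set[str]] = defaultdict(set)
    for a, b in inparalogs:
        partners[a].add(b)
        partners[b].add(a)
    out: Set[Tuple[str, str]] = set()
    for a, b in orthologs:
        candidates = (
            [(a2, b) for a2 in partners[a]]
            + [(a, b2) for b2 in partners[b]]
            + [(a2, b2) for a2 in partners[a] for b2 in partners[b]]
        )
        for x, y in candidates:
            pair = (x, y) if x < y else (y, x)
            if pair in orthologs or _taxon(x) == _taxon(y):
                continue
            if _pair_score(table, x, y) is not None:
                out.add(pair)
    return out


def random_score_table(
    rng: np.random.Generator, max_taxa: int = 4, max_genes: int = 6
) -> ScoreTable:
    """A random symmetric sparse score table over a few small taxa."""
    n_taxa = int(rng.integers(2, max_taxa + 1))
    genes: List[str] = []
    for t in range(n_taxa):
        for g in range(int(rng.integers(1, max_genes + 1))):
            genes.append(f"t{t}|g{g}")
    table: ScoreTable = {}
    for a, b in itertools.combinations(genes, 2):
        if rng.random() < 0.6:
            score = float(np.round(rng.uniform(20.0, 300.0), 3))
            table[(a, b)] = score
            table[(b, a)] = score
    return table


def table_to_hits(table: ScoreTable, length: int = 100) -> List[HomologyHit]:
    """Render a score table as full-coverage m8 hits (both directions)."""
    hits = []
    for (a, b), score in sorted(table.items()):
        hits.append(
            HomologyHit(
                query_id=a, subject_id=b, pct_identity=90.0, aln_length=length,
                mismatches=10, gap_opens=0, q_start=1, q_end=length,
                s_start=1, s_end=length, evalue=1e-30, bit_score=score,
            )
        )
    # self hits fix the inferred sequence lengths
    for g in sorted({g for pair in table for g in pair}):
        hits.append(
            HomologyHit(
                query_id=g, subject_id=g, pct_identity=100.0, aln_length=length,
                mismatches=0, gap_opens=0, q_start=1, q_end=length,
                s_start=1, s_end=length, evalue=1e-60, bit_score=2 * max(table.values(), default=100.0),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# dense affinity propagation — clustering oracle
# ---------------------------------------------------------------------------

def dense_affinity_propagation(
    S: np.ndarray, damping: float = 0.5, max_iter: int = 500,
    convergence_window: int = 15,
) -> np.ndarray:
    """Reference matrix-form affinity propagation; returns exemplar indices.

    ``S`` is a full similarity matrix with preferences on the diagonal;
    missing similarities should be a very large negative number.
    """
    n = S.shape[0]
    R = np.zeros_like(S)
    A = np.zeros_like(S)
    prev = None
    stable = 0
    for _ in range(max_iter):
        AS = A + S
        idx = np.argmax(AS, axis=1)
        max1 = AS[np.arange(n), idx]
        AS_masked = AS.copy()
        AS_masked[np.arange(n), idx] = -np.inf
        max2 = AS_masked.max(axis=1)
        newR = S - max1[:, None]
        newR[np.arange(n), idx] = S[np.arange(n), idx] - max2
        R = (1 - damping) * newR + damping * R

        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, 0.0)
        col = Rp.sum(axis=0)
        newA = np.minimum(0.0, np.diag(R)[None, :] + col[None, :] - Rp)
        newA[np.arange(n), np.arange(n)] = col
        A = (1 - damping) * newA + damping * A

        ex = np.argmax(A + R, axis=1)
        if prev is not None and np.array_equal(ex, prev):
            stable += 1
            if stable >= convergence_window:
                break
        else:
            stable = 0
        prev = ex
    return np.argmax(A + R, axis=1)
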
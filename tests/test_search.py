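"""Index construction, candidate pairing, banded alignment, and statistics."""

import math
from collections import defaultdict

import numpy as np
import pytest

from helpers import full_smith_waterman
from orthoswift.search import (
    SequenceRecord,
    build_index,
    compute_coverage,
    find_candidates,
    kbanded_smith_waterman,
    score_statistics,
    search_all_vs_all,
)
from orthoswift.seeds import parse_spaced_seed
from orthoswift.simulate import SimConfig, simulate

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, lo, hi):
    return "".join(rng.choice(list(AA), size=rng.integers(lo, hi + 1)))


class TestKmerIndex:
    def test_single_sequence_postings(self):
        rec = SequenceRecord(gene_id="g", taxon="t", residues="AAAA")
        index = build_index([rec], seeds=[parse_spaced_seed("11")])
        assert index.postings[(0, "AA")] == [(0, 0), (0, 1), (0, 2)]
        assert index.total_residues == 4

    def test_identical_sequences_share_postings(self):
        recs = [
            SequenceRecord(gene_id="g1", taxon="A", residues="MKVLATGW"),
            SequenceRecord(gene_id="g1", taxon="B", residues="MKVLATGW"),
        ]
        index = build_index(recs, seeds=[parse_spaced_seed("111")])
        assert all(len(v) >= 2 for v in index.postings.values())

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            build_index([])

    def test_duplicate_ids_rejected(self):
        rec = SequenceRecord(gene_id="g", taxon="t", residues="MKVL")
        with pytest.raises(ValueError, match="duplicate"):
            build_index([rec, rec])

    def test_matches_brute_force_substring_index(self):
        rng = np.random.default_rng(11)
        recs = [
            SequenceRecord(gene_id=f"g{i}", taxon="t", residues=random_protein(rng, 10, 30))
            for i in range(5)
        ]
        index = build_index(recs, seeds=[parse_spaced_seed("111")])
        brute = defaultdict(list)
        for ordinal, rec in enumerate(recs):
            for pos in range(len(rec.residues) - 2):
                brute[(0, rec.residues[pos : pos + 3])].append((ordinal, pos))
        assert index.postings == dict(brute)


class TestCandidates:
    def test_identical_query_found_on_diagonal_zero(self):
        recs = [
            SequenceRecord(gene_id="g1", taxon="A", residues="MKVLATGWERT"),
            SequenceRecord(gene_id="g2", taxon="A", residues="PPPPPPPPPPP"),
        ]
        index = build_index(recs, seeds=[parse_spaced_seed("111")])
        cands = find_candidates(recs[0], index, min_shared_seeds=2)
        assert (0, 0) in cands

    def test_disjoint_query_yields_no_cross_candidates(self):
        recs = [
            SequenceRecord(gene_id="g1", taxon="A", residues="MKVLATGWERT"),
            SequenceRecord(gene_id="g2", taxon="A", residues="PPPPPPPPPPP"),
        ]
        index = build_index(recs, seeds=[parse_spaced_seed("111")])
        cands = find_candidates(recs[1], index, min_shared_seeds=1)
        assert [c for c, _ in cands] == [1]

    def test_matches_brute_force_kmer_intersection(self):
        rng = np.random.default_rng(5)
        recs = [
            SequenceRecord(gene_id=f"g{i}", taxon="t", residues=random_protein(rng, 15, 25))
            for i in range(3)
        ]
        index = build_index(recs, seeds=[parse_spaced_seed("111")])
        for q_ord, query in enumerate(recs):
            got = {c for c, _ in find_candidates(query, index, min_shared_seeds=1)}
            expected = set()
            q_kmers = {
                query.residues[i : i + 3] for i in range(len(query.residues) - 2)
            }
            for s_ord, subject in enumerate(recs):
                s_kmers = {
                    subject.residues[i : i + 3]
                    for i in range(len(subject.residues) - 2)
                }
                if q_kmers & s_kmers:
                    expected.add(s_ord)
            expected.add(q_ord)  # self-match is always reported
            assert got == expected

    def test_short_sequence_still_reports_self(self):
        recs = [SequenceRecord(gene_id="tiny", taxon="A", residues="MK")]
        index = build_index(recs)  # default seeds are longer than the sequence
        assert find_candidates(recs[0], index) == [(0, 0)]


class TestBandedSmithWaterman:
    def test_identity_alignment(self, params):
        q = "MKVLATGWERTY"
        raw, qs, qe, ss, se, alen, ident, mism, gaps = kbanded_smith_waterman(
            q, q, params, 0
        )
        expected = sum(
            int(params.matrix[params.encode(c)[0], params.encode(c)[0]])
            for c in q
        )
        assert raw == expected
        assert (qs, qe, ss, se) == (1, len(q), 1, len(q))
        assert ident == len(q) and mism == 0 and gaps == 0

    def test_no_positive_scoring_pair(self, params):
        raw, *rest = kbanded_smith_waterman("GGGG", "PPPP", params, 0)
        assert raw == 0
        assert rest == [0, 0, 0, 0, 0, 0, 0, 0]

    def test_empty_sequence_rejected(self, params):
        with pytest.raises(ValueError):
            kbanded_smith_waterman("", "MKVL", params, 0)

    def test_full_band_equals_unrestricted_oracle(self, params):
        rng = np.random.default_rng(42)
        for _ in range(25):
            q = random_protein(rng, 30, 60)
            s = random_protein(rng, 30, 60)
            full = len(q) + len(s)
            raw, *_ = kbanded_smith_waterman(q, s, params, 0, half_width=full)
            assert raw == full_smith_waterman(q, s, params)

    def test_band_monotonicity(self, params):
        rng = np.random.default_rng(7)
        q = random_protein(rng, 40, 60)
        s = random_protein(rng, 40, 60)
        widths = [1, 2, 4, 8, 16, 32, 64, len(q) + len(s)]
        scores = [
            kbanded_smith_waterman(q, s, params, 0, half_width=w)[0]
            for w in widths
        ]
        assert scores == sorted(scores)

    def test_symmetry(self, params):
        rng = np.random.default_rng(3)
        for _ in range(10):
            q = random_protein(rng, 30, 50)
            s = random_protein(rng, 30, 50)
            w = len(q) + len(s)
            assert (
                kbanded_smith_waterman(q, s, params, 0, half_width=w)[0]
                == kbanded_smith_waterman(s, q, params, 0, half_width=w)[0]
            )

    def test_statistics_consistent_with_alignment(self, params):
        rng = np.random.default_rng(9)
        base = random_protein(rng, 50, 60)
        mutated = list(base)
        for i in range(0, len(mutated), 7):
            mutated[i] = "A" if mutated[i] != "A" else "G"
        raw, qs, qe, ss, se, alen, ident, mism, gaps = kbanded_smith_waterman(
            base, "".join(mutated), params, 0
        )
        assert ident + mism <= alen
        assert qe - qs + 1 <= alen and se - ss + 1 <= alen
        assert raw > 0


class TestScoreStatistics:
    def test_closed_form_at_zero_score(self, params):
        bit, evalue = score_statistics(0, 200, 5000, params)
        assert bit == pytest.approx(-math.log(params.K) / math.log(2))
        assert evalue == pytest.approx(200 * 5000 * params.K)

    def test_doubling_bit_score_squares_evalue_over_search_space(self, params):
        m, n = 300, 10**5
        bit1, e1 = score_statistics(100, m, n, params)
        # a raw score chosen so the bit score doubles exactly
        raw2 = (2 * bit1 * math.log(2) + math.log(params.K)) / params.lambda_
        bit2 = (params.lambda_ * raw2 - math.log(params.K)) / math.log(2)
        e2 = m * n * 2.0 ** (-bit2)
        assert e2 == pytest.approx(e1**2 / (m * n), rel=1e-9)

    def test_hand_evaluated_example(self, params):
        bit, evalue = score_statistics(100, 300, 10**5, params)
        # (0.267*100 - ln 0.041)/ln 2 and 300*1e5*2^-bit by calculator
        assert bit == pytest.approx(43.128189, abs=1e-5)
        assert evalue == pytest.approx(3.12063e-06, rel=1e-5)

    def test_deep_evalues_survive_double_precision(self, params):
        bit, evalue = score_statistics(2600, 300, 10**7, params)
        assert 0.0 < evalue < 1e-180

    def test_negative_raw_score_rejected(self, params):
        with pytest.raises(ValueError):
            score_statistics(-1, 10, 10, params)


class TestCoverage:
    def make_hit(self, qs, qe, ss, se):
        from orthoswift.search import HomologyHit

        return HomologyHit(
            query_id="A|q", subject_id="B|s", pct_identity=90.0,
            aln_length=qe - qs + 1, mismatches=0, gap_opens=0,
            q_start=qs, q_end=qe, s_start=ss, s_end=se,
            evalue=1e-10, bit_score=50.0,
        )

    def test_full_length_hit(self):
        assert compute_coverage(self.make_hit(1, 100, 1, 100), 100, 100) == (1.0, 1.0)

    def test_half_query(self):
        q_cov, _ = compute_coverage(self.make_hit(1, 50, 1, 50), 100, 50)
        assert q_cov == 0.5

    def test_matches_direct_arithmetic(self):
        hit = self.make_hit(11, 73, 5, 66)
        q_cov, s_cov = compute_coverage(hit, 90, 80)
        assert q_cov == pytest.approx((73 - 11 + 1) / 90)
        assert s_cov == pytest.approx((66 - 5 + 1) / 80)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            compute_coverage(self.make_hit(1, 120, 1, 50), 100, 50)


class TestAllVsAll:
    def test_identical_cross_taxon_pair(self, params):
        seq = "MKVLATGWERTYHHKNALSDFGIPQRVVM"
        recs = [
            SequenceRecord(gene_id="g1", taxon="A", residues=seq),
            SequenceRecord(gene_id="g1", taxon="B", residues=seq),
        ]
        hits = list(search_all_vs_all(recs, params=params))
        assert len(hits) == 4
        by_pair = {(h.query_id, h.subject_id): h for h in hits}
        assert by_pair[("A|g1", "B|g1")].bit_score == by_pair[("A|g1", "A|g1")].bit_score

    def test_unrelated_sequences_only_self_hits(self, params):
        rng = np.random.default_rng(21)
        recs = [
            SequenceRecord(gene_id="g1", taxon="A", residues=random_protein(rng, 60, 80)),
            SequenceRecord(gene_id="g2", taxon="B", residues=random_protein(rng, 60, 80)),
        ]
        hits = list(search_all_vs_all(recs, params=params, evalue_max=1e-20))
        assert {(h.query_id, h.subject_id) for h in hits} == {
            ("A|g1", "A|g1"),
            ("B|g2", "B|g2"),
        }

    def test_threshold_soundness_and_self_hit_dominance(self, params):
        cfg = SimConfig(n_taxa=2, n_families=6, seed=3)
        recs, _ = simulate(cfg)
        hits = list(search_all_vs_all(recs, params=params, evalue_max=1e-5))
        assert all(h.evalue <= 1e-5 for h in hits)
        self_score = {
            h.query_id: h.bit_score for h in hits if h.query_id == h.subject_id
        }
        for h in hits:
            assert h.bit_score <= self_score[h.subject_id] + 1e-9

    def test_planted_homologs_recovered(self, params):
        # speciation siblings at ~72% identity must be found by default seeds
        cfg = SimConfig(n_taxa=3, n_families=15, duplication_rate=0.0, seed=17)
        recs, truth = simulate(cfg)
        hits = {(h.query_id, h.subject_id) for h in search_all_vs_all(recs, params=params)}
        found = sum(
            1 for a, b in truth.ortholog_pairs if (a, b) in hits or (b, a) in hits
        )
        assert found / len(truth.ortholog_pairs) >= 0.95

    def test_sharded_queries_concatenate_to_serial_result(self, params):
        from orthoswift.search import build_index, search_against_index

        cfg = SimConfig(n_taxa=2, n_families=4, seed=8)
        recs, _ = simulate(cfg)
        index = build_index(recs)
        serial = [
            h.to_m8_line()
            for h in search_against_index(index, params=params)
        ]
        mid = len(recs) // 2
        sharded = [
            h.to_m8_line()
            for shard in (range(0, mid), range(mid, len(recs)))
            for h in search_against_index(index, params=params, query_ordinals=shard)
        ]
        assert sharded == serial

    def test_output_order_is_deterministic(self, params):
        cfg = SimConfig(n_taxa=2, n_families=3, seed=2)
        recs, _ = simulate(cfg)
        first = [h.to_m8_line() for h in search_all_vs_all(recs, params=params)]
        second = [h.to_m8_line() for h in search_all_vs_all(recs, params=params)]
        assert first == second
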
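import itertools
import math
import warnings
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cismotif.enrichment import (
    build_background,
    code_to_kmer,
    count_occurrences,
    enrich_group,
    enumerate_kmers,
    hypergeom_upper_tail,
    kmer_to_code,
    number_enrichment,
    presence_enrichment,
    window_codes,
    encode_sequence,
)
from conftest import make_promoter_set


def exact_upper_tail(x: int, n: int, M: int, N: int) -> Fraction:
    """Independent oracle: direct summation with exact binomials."""
    total = Fraction(0)
    for i in range(x, min(n, M) + 1):
        total += Fraction(math.comb(M, i) * math.comb(N - M, n - i), math.comb(N, n))
    return total


class TestEnumeration:
    @pytest.mark.parametrize("kmin,kmax,count", [(4, 8, 87296), (1, 1, 4), (2, 2, 16)])
    def test_kmer_counts(self, kmin, kmax, count):
        kmers = enumerate_kmers(kmin, kmax)
        assert len(kmers) == count
        assert len(set(kmers)) == count

    def test_lexicographic_within_length(self):
        kmers = enumerate_kmers(2, 2)
        assert kmers[:4] == ["AA", "AC", "AG", "AT"]

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            enumerate_kmers(5, 4)

    def test_code_round_trip(self):
        for kmer in ["GAATATTC", "ACGT", "TTTT"]:
            assert code_to_kmer(kmer_to_code(kmer), len(kmer)) == kmer


class TestCounting:
    @pytest.mark.parametrize(
        "seq,motif,n",
        [
            ("GAAGAA", "GAA", 2),
            ("AAAA", "AA", 3),  # overlaps counted
            ("ACG", "ACGT", 0),  # motif longer than sequence
            ("GAATATTC", "GAATATTC", 1),
        ],
    )
    def test_overlapping_counts(self, seq, motif, n):
        assert count_occurrences(seq, motif) == n

    def test_window_codes_match_string_scan(self):
        seq = "GAAGAATTC"
        codes = window_codes(encode_sequence(seq), 3)
        decoded = [code_to_kmer(int(c), 3) for c in codes]
        assert decoded == [seq[i : i + 3] for i in range(len(seq) - 2)]


class TestBackground:
    def test_single_promoter_counts(self):
        ps = make_promoter_set({"g1": ["GAAGAA"]})
        bg = build_background(ps, 3, 3)
        assert bg.m_presence("GAA") == 1
        assert bg.m_number("GAA") == 2
        assert bg.position_totals[3] == 4
        assert bg.m_presence("CCC") == 0 and bg.m_number("CCC") == 0

    def test_gene_with_two_promoters_counts_presence_once(self):
        ps = make_promoter_set({"g1": ["GAATTTT", "CCCGAAC"]})
        bg = build_background(ps, 3, 3)
        assert bg.m_presence("GAA") == 1
        assert bg.m_number("GAA") == 2

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            build_background(make_promoter_set({}), 4, 8)

    def test_serialization_round_trip(self, tmp_path):
        ps = make_promoter_set({"g1": ["GAAGAATTC"], "g2": ["TTTTCCCC"]})
        bg = build_background(ps, 4, 5)
        bg.save(tmp_path / "bg.json")
        back = bg.load(tmp_path / "bg.json")
        assert back.n_genes == bg.n_genes
        assert back.position_totals == bg.position_totals
        for k in (4, 5):
            np.testing.assert_array_equal(back.presence[k], bg.presence[k])
            np.testing.assert_array_equal(back.number[k], bg.number[k])


class TestHypergeometric:
    @pytest.mark.parametrize(
        "x,n,M,N,expected",
        [
            (0, 5, 4, 10, 1.0),
            (3, 5, 4, 10, 66 / 252),
            (4, 8, 5, 20, 7280 / 125970),
        ],
    )
    def test_known_tails(self, x, n, M, N, expected):
        assert hypergeom_upper_tail(x, n, M, N) == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_subset_enumeration(self):
        # brute force: count subsets of size n with >= x marked elements
        N, M, n = 9, 4, 5
        marked = set(range(M))
        for x in range(min(n, M) + 1):
            hits = sum(
                1
                for s in itertools.combinations(range(N), n)
                if len(marked & set(s)) >= x
            )
            expected = hits / math.comb(N, n)
            assert hypergeom_upper_tail(x, n, M, N) == pytest.approx(expected, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 4, 10, 20)  # x > n
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 5, 25, 20)  # M > N

    @settings(deadline=None, max_examples=60)
    @given(st.integers(1, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_monotone_in_x_and_sum_rule(self, N, M, n, x):
        M, n = min(M, N), min(n, N)
        x = min(x, n, M)
        p = hypergeom_upper_tail(x, n, M, N)
        assert 0.0 <= p <= 1.0
        if x > 0:
            assert hypergeom_upper_tail(x - 1, n, M, N) >= p - 1e-12
            # upper_tail(x) + lower_tail(x-1) = 1
            lower = float(sum(
                Fraction(math.comb(M, i) * math.comb(N - M, n - i), math.comb(N, n))
                for i in range(0, x)
            ))
            assert p + lower == pytest.approx(1.0, abs=1e-12)


class TestGroupEnrichment:
    def toy(self):
        # background of 10 genes, 4 contain GAATATTC; group of 5 with 3
        seqs = {}
        for i in range(10):
            base = "ACACACACACAC"
            if i < 4:
                base = "GAATATTCACAC"
            seqs[f"g{i}"] = [base]
        ps = make_promoter_set(seqs)
        return ps, build_background(ps, 3, 8)

    def test_presence_toy_matches_exact_tail(self):
        ps, bg = self.toy()
        group = ["g0", "g1", "g2", "g8", "g9"]  # 3 of 5 contain the motif
        p = presence_enrichment("GAATATTC", group, ps, bg)
        assert p == pytest.approx(66 / 252, abs=1e-12)

    def test_motif_absent_from_group_gives_p_one(self):
        ps, bg = self.toy()
        assert presence_enrichment("GAATATTC", ["g8", "g9"], ps, bg) == 1.0

    def test_saturated_background_gives_p_one(self):
        seqs = {f"g{i}": ["GAAACCC"] for i in range(6)}
        ps = make_promoter_set(seqs)
        bg = build_background(ps, 3, 3)
        p = presence_enrichment("GAA", ["g0", "g1"], ps, bg)
        assert p == pytest.approx(1.0)

    def test_number_enrichment_degenerate_identity(self):
        # group == entire background: x = M, n = N -> point mass, p = 1
        ps, bg = self.toy()
        p = number_enrichment("GAATATTC", ps, bg)
        assert p == pytest.approx(1.0)

    def test_enrich_group_quadrants_and_oracle_agreement(self):
        ps, bg = self.toy()
        group = ["g0", "g1", "g2", "g8", "g9"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = enrich_group(group, ps, bg, alpha=0.3, k=8)
        by_motif = {r.motif: r for r in results}
        r = by_motif["GAATATTC"]
        assert r.x_presence == 3
        assert r.p_presence == pytest.approx(
            float(exact_upper_tail(3, 5, 4, 10)), abs=1e-12
        )
        # independent number-mode oracle
        assert r.p_number == pytest.approx(
            float(exact_upper_tail(r.x_number, 5 * 5, bg.m_number("GAATATTC"), 50)),
            abs=1e-12,
        )
        assert r.quadrant in (1, 2, 3, 4)
        assert all(
            (res.quadrant == 1) == res.enriched for res in results
        )
        # motifs absent from the group are omitted
        assert all(res.x_number > 0 for res in results)
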
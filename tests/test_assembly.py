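import itertools

import numpy as np
import pytest
from scipy import stats

from cismotif.assembly import (
    build_pssm,
    classify_palindrome,
    map_and_merge,
    rank_core_kmers,
    select_step1_motifs,
    tss_distance_profile,
    write_meme_motif,
)
from cismotif.promoters import reverse_complement
from conftest import make_promoter_set


class TestCoreRanking:
    def test_window_counting_hand_example(self):
        # GAATATTC windows: GAA AAT ATA TAT ATT TTC; AGAACTTC: AGA GAA AAC ACT CTT TTC
        ranking = rank_core_kmers(["GAATATTC", "AGAACTTC"], 3)
        counts = dict(ranking.entries)
        assert counts["GAA"] == 2
        assert counts["TTC"] == 2
        assert counts["TAT"] == 1

    def test_repeated_windows_count_separately(self):
        ranking = rank_core_kmers(["AAAAAAAA"], 3)
        assert ranking.entries == [("AAA", 6)]

    def test_counts_non_increasing_and_ties_lexicographic(self):
        ranking = rank_core_kmers(["GAATATTC", "AGAACTTC", "CGAAGAAT"], 3, top=5)
        counts = [n for _, n in ranking.entries]
        assert counts == sorted(counts, reverse=True)
        for (c1, n1), (c2, n2) in zip(ranking.entries, ranking.entries[1:]):
            if n1 == n2:
                assert c1 < c2

    def test_empty_enriched_set(self):
        assert rank_core_kmers([], 3).entries == []


class TestStep1Selection:
    def test_union_reading(self):
        r3 = rank_core_kmers(["GAAGAAGA"], 3)  # top cores from GAA repeats
        r4 = rank_core_kmers(["CCCCCCCC"], 4)
        motifs = ["GAATTTTT", "CCCCAAAA", "TGTGTGTG"]
        out = select_step1_motifs(motifs, r3, r4)
        assert "GAATTTTT" in out  # carries top 3-mer only
        assert "CCCCAAAA" in out  # carries top 4-mer only
        assert "TGTGTGTG" not in out

    def test_intersection_flag(self):
        r3 = rank_core_kmers(["GAAGAAGA"], 3)
        r4 = rank_core_kmers(["CCCCCCCC"], 4)
        out = select_step1_motifs(["GAATTTTT"], r3, r4, require_both=True)
        assert out == []


class TestMapAndMerge:
    def test_overlapping_occurrences_merge_into_one_region(self):
        ps = make_promoter_set({"g1": ["CCGAATATTCTCC"]})
        regions = map_and_merge(["GAATATTC", "AATATTCT"], ps)
        assert len(regions) == 1
        assert regions[0].sequence == "GAATATTCT"
        assert regions[0].length == 9
        assert len(regions[0].contributing_motifs) == 2

    def test_singleton_occurrence_is_motif_length(self):
        ps = make_promoter_set({"g1": ["CCCGAATATTCCCC"]})
        regions = map_and_merge(["GAATATTC"], ps)
        assert len(regions) == 1
        assert regions[0].sequence == "GAATATTC"

    def test_occurrences_on_different_promoters_never_merge(self):
        ps = make_promoter_set({"g1": ["AAGAATATTCAA"], "g2": ["AAGAATATTCAA"]})
        regions = map_and_merge(["GAATATTC"], ps)
        assert len(regions) == 2

    def test_regions_disjoint_and_cover_every_occurrence(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        ps = make_promoter_set({"g1": [seq]})
        motifs = [seq[i : i + 8] for i in (3, 7, 100, 104, 250)]
        regions = map_and_merge(motifs, ps)
        spans = sorted((r.start_offset, r.end_offset) for r in regions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # disjoint
        for m in set(motifs):
            start = seq.find(m)
            while start != -1:
                assert sum(
                    1
                    for r in regions
                    if r.start_offset <= start and start + 8 <= r.end_offset
                ) == 1
                start = seq.find(m, start + 1)


class TestPSSM:
    def region(self, seq):
        ps = make_promoter_set({"g": [seq]})
        (r,) = map_and_merge([seq], ps)
        return r

    def test_single_region_gives_one_hot_columns(self):
        pssm = build_pssm([self.region("GAAT")])
        assert pssm.frequencies.shape == (4, 4)
        np.testing.assert_allclose(pssm.frequencies.sum(axis=1), 1.0)
        np.testing.assert_allclose(pssm.information_content, 2.0)
        assert pssm.consensus == "GAAT"

    def test_half_split_column(self):
        pssm = build_pssm([self.region("GAAT"), self.region("GAAA")])
        col = pssm.frequencies[3]
        assert col[0] == pytest.approx(0.5)  # A
        assert col[3] == pytest.approx(0.5)  # T
        np.testing.assert_allclose(pssm.frequencies.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pssm.information_content >= 0) and np.all(
            pssm.information_content <= 2
        )

    def test_core_anchoring_aligns_shifted_regions(self):
        # same motif at different offsets within merged regions
        regions = [self.region("TTGAACCC"), self.region("GAACCCTT")]
        pssm = build_pssm(regions, anchor_core="GAA")
        # anchored columns share GAACCC -> consensus contains it contiguously
        assert "GAACCC" in pssm.consensus

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            build_pssm([])

    def test_meme_output_format(self, tmp_path):
        pssm = build_pssm([self.region("GAAT")])
        out = tmp_path / "m.meme"
        write_meme_motif(pssm, "test_motif", out)
        text = out.read_text()
        assert "MEME version 4" in text
        assert "letter-probability matrix: alength= 4 w= 4" in text


class TestPalindromes:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("GAATATTC", "full"),
            ("GAACCTTC", "flank_3"),
            ("AAAAAAAA", "none"),
            ("GATTTTTC", "flank_2"),
            ("GTTTTTTC", "flank_1"),
        ],
    )
    def test_classification(self, motif, expected):
        assert classify_palindrome(motif) == expected

    def test_non_8mer_rejected(self):
        with pytest.raises(ValueError):
            classify_palindrome("GAAT")

    def test_exactly_256_full_palindromes(self):
        full = [
            "".join(m)
            for m in itertools.product("ACGT", repeat=8)
            if classify_palindrome("".join(m)) == "full"
        ]
        assert len(full) == 256
        assert all(reverse_complement(m) == m for m in full)

    def test_gaannttc_family_is_full_or_flank3(self):
        family = ["GAA" + a + b + "TTC" for a in "ACGT" for b in "ACGT"]
        assert len(family) == 16
        classes = {m: classify_palindrome(m) for m in family}
        assert set(classes.values()) <= {"full", "flank_3"}
        assert sum(c == "full" for c in classes.values()) == 4


class TestTSSProfile:
    def test_regions_near_tss_fall_in_first_bin(self):
        seq = "A" * 1000
        ps = make_promoter_set({"g": [seq]})
        regions = map_and_merge(["AAAAAAAA"], ps)  # whole promoter merges
        # construct explicit regions at offsets 950..999
        from cismotif.assembly import MergedRegion

        regs = [
            MergedRegion("g.p1", off, off + 8, seq[off : off + 8], [("AAAAAAAA", off)])
            for off in range(950, 992)
        ]
        hist = tss_distance_profile(regs, ps, bin_size=100, promoter_length=1000)
        assert hist[0] == len(regs)
        assert hist[1:].sum() == 0

    def test_empty_region_list_gives_zero_histogram(self):
        ps = make_promoter_set({"g": ["A" * 1000]})
        hist = tss_distance_profile([], ps)
        assert hist.sum() == 0

    def test_uniform_placement_is_flat(self):
        rng = np.random.default_rng(7)
        seq = "A" * 1000
        ps = make_promoter_set({"g": [seq]})
        from cismotif.assembly import MergedRegion

        offs = rng.integers(0, 992, 1000)
        regs = [
            MergedRegion("g.p1", int(o), int(o) + 8, seq[o : o + 8], []) for o in offs
        ]
        hist = tss_distance_profile(regs, ps)
        chi2, p = stats.chisquare(hist)
        assert p > 0.01
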
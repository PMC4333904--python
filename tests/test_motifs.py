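"""IUPAC scanning, strand symmetry, and Fisher enrichment against an exact oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cobind.io import Genome
from cobind.model import GenomicInterval, ValidationError
from cobind.motifs import (
    PATTERNS,
    MotifPattern,
    enrichment_test,
    mean_hits_per_region,
    occurrence_fraction,
    region_counts,
    reverse_complement,
    scan,
)

from conftest import brute_fisher_two_sided, brute_revcomp, brute_scan_count


class TestScan:
    def test_forward_hit(self):
        hits = scan("TGACAGT", PATTERNS["TGACAG"])
        assert [(h.position, h.strand) for h in hits] == [(0, "+")]

    def test_reverse_complement_hit(self):
        hits = scan("CTGTCA", PATTERNS["TGACAG"])
        assert [(h.position, h.strand) for h in hits] == [(0, "-")]

    def test_n_wildcards(self):
        hits = scan("GATCCATTT", PATTERNS["GATNNAT"], both_strands=False)
        assert [(h.position, h.strand) for h in hits] == [(0, "+")]

    def test_overlapping_hits_counted(self):
        hits = scan("TAATAAT", PATTERNS["TAAT"], both_strands=False)
        assert [h.position for h in hits] == [0, 3]

    def test_genome_n_matches_only_pattern_n(self):
        assert scan("TGNCAG", PATTERNS["TGACAG"]) == []
        assert len(scan("NNNN", MotifPattern("anyN", "NNNN"), both_strands=False)) == 1

    def test_palindromic_double_count_and_dedup(self):
        pal = MotifPattern("pal", "TGCA")  # revcomp(TGCA) = TGCA
        assert reverse_complement("TGCA") == "TGCA"
        assert len(scan("TGCA", pal)) == 2
        assert len(scan("TGCA", pal, dedup_palindromic=True)) == 1

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValidationError):
            MotifPattern("bad", "TGAX")

    @settings(max_examples=150, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=0, max_size=60),
        name=st.sampled_from(sorted(PATTERNS)),
    )
    def test_strand_symmetry(self, seq, name):
        """A pattern's two-strand hit count is the same on either strand's
        reading of the sequence."""
        pattern = PATTERNS[name]
        assert len(scan(seq, pattern)) == len(scan(reverse_complement(seq), pattern))

    @settings(max_examples=150, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=0, max_size=50))
    def test_all_n_pattern_matches_every_window(self, seq):
        pattern = MotifPattern("n4", "NNNN")
        expected = max(0, len(seq) - 3)
        hits = scan(seq, pattern, both_strands=False)
        assert len(hits) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=0, max_size=40),
        name=st.sampled_from(sorted(PATTERNS)),
    )
    def test_matches_sliding_window_oracle(self, seq, name):
        pattern = PATTERNS[name]
        assert len(scan(seq, pattern)) == brute_scan_count(seq, pattern.iupac)


class TestRegionStats:
    @pytest.fixture()
    def genome(self):
        # 21 concatenated 200-nt regions; the first 16 carry one GATNNAT
        seqs = []
        for i in range(21):
            body = "C" * 200
            if i < 16:
                body = "C" * 50 + "GATGGAT" + "C" * 143
            seqs.append(body)
        return Genome.from_dict({"chr1": "".join(seqs)})

    @pytest.fixture()
    def regions(self):
        return [GenomicInterval("chr1", i * 200, (i + 1) * 200) for i in range(21)]

    def test_occurrence_fraction_sixteen_of_twentyone(self, genome, regions):
        occ = occurrence_fraction(regions, genome, PATTERNS["GATNNAT"])
        assert (occ.k, occ.n) == (16, 21)
        assert occ.fraction == pytest.approx(16 / 21)
        assert round(occ.fraction, 3) == 0.762

    def test_all_c_region_has_zero_counts(self, genome):
        counts = region_counts(
            [GenomicInterval("chr1", 16 * 200, 17 * 200)], genome, PATTERNS["TAAT"]
        )
        assert counts.tolist() == [0]

    def test_planted_taat_counts_and_mean(self):
        # regions with 3, 3 and 3 TAAT -> mean 3.0; {0, 6} -> mean 3.0
        def with_taat(n):
            return ("TAAT" + "C" * 16) * n + "C" * (200 - 20 * n)

        genome = Genome.from_dict(
            {"chr1": with_taat(3) * 3 + with_taat(0) + with_taat(6)}
        )
        regions = [GenomicInterval("chr1", i * 200, (i + 1) * 200) for i in range(5)]
        counts = region_counts(regions, genome, PATTERNS["TAAT"])
        assert counts.tolist() == [3, 3, 3, 0, 6]
        assert mean_hits_per_region(regions[:3], genome, PATTERNS["TAAT"]) == 3.0
        assert mean_hits_per_region(regions[3:], genome, PATTERNS["TAAT"]) == 3.0

    def test_empty_region_list_rejected(self, genome):
        with pytest.raises(ValidationError):
            occurrence_fraction([], genome, PATTERNS["TAAT"])


class TestEnrichmentTest:
    def test_matches_exact_enumeration(self):
        res = enrichment_test(16, 21, 2457, 5115)
        assert res.p_value == pytest.approx(
            brute_fisher_two_sided(((16, 5), (2457, 2658))), rel=1e-9
        )

    def test_identical_proportions(self):
        res = enrichment_test(10, 20, 10, 20)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_contrast_is_tiny(self):
        res = enrichment_test(21, 21, 0, 100)
        assert res.p_value < 1e-10
        assert res.p_value == pytest.approx(
            brute_fisher_two_sided(((21, 0), (0, 100))), rel=1e-9
        )

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = enrichment_test(0, 10, 0, 10)
        assert res.p_value == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_test(5, 3, 1, 10)

    @settings(max_examples=120, derandomize=True)
    @given(data=st.data())
    def test_agrees_with_oracle_on_small_tables(self, data):
        n_fg = data.draw(st.integers(1, 50))
        n_bg = data.draw(st.integers(1, 50))
        k_fg = data.draw(st.integers(0, n_fg))
        k_bg = data.draw(st.integers(0, n_bg))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = enrichment_test(k_fg, n_fg, k_bg, n_bg)
        table = ((k_fg, n_fg - k_fg), (k_bg, n_bg - k_bg))
        rows = (n_fg, n_bg)
        cols = (k_fg + k_bg, n_fg + n_bg - k_fg - k_bg)
        if 0 in rows or 0 in cols:
            assert res.p_value == 1.0
        else:
            assert res.p_value == pytest.approx(
                brute_fisher_two_sided(table), rel=1e-8, abs=1e-12
            )
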
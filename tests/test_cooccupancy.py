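"""Distance/FE co-occupancy tables and proximity enrichment statistics."""

import math

import numpy as np
import pytest

from cobind.cooccupancy import (
    distance_fe_histogram,
    fe_stratified_proximity_test,
    high_peak_proximity_fraction,
    multiway_overlap,
    proximity_enrichment_test,
)
from cobind.model import PeakSet, ValidationError

from conftest import (
    brute_distance_fe_counts,
    brute_fisher_two_sided,
    make_peak,
    make_set,
    random_peakset,
)


class TestDistanceFeHistogram:
    def test_known_distance_binning(self):
        # peaks at distances {0, 150, 900, 5000} from the single reference summit
        ref = make_set([(10_000, 1)])
        peaks = make_set([(10_000, 5), (10_150, 5), (10_900, 5), (15_000, 5)])
        table = distance_fe_histogram(
            peaks, ref, distance_edges=(0, 200, 1000, math.inf), fe_edges=(0, math.inf)
        )
        assert table.distance_totals.tolist() == [2, 1, 1]

    def test_coincident_peak_lands_in_first_bin_own_fe_stratum(self):
        ref = make_set([(500, 1)])
        peaks = make_set([(500, 45)])
        table = distance_fe_histogram(peaks, ref)
        assert table.counts[0, 2] == 1  # [0,200) x FE [40,60)
        assert table.n_peaks == 1

    def test_empty_reference_fills_last_distance_bin(self):
        peaks = make_set([(500, 5), (900, 5)])
        table = distance_fe_histogram(peaks, peaks.subset([]))
        assert table.distance_totals.tolist() == [0, 0, 0, 2]

    def test_marginals_reproduce_unstratified_histograms(self):
        rng = np.random.default_rng(8)
        peaks = random_peakset(rng, 150)
        ref = random_peakset(rng, 40)
        table = distance_fe_histogram(peaks, ref)
        assert table.n_peaks == len(peaks)
        assert table.distance_totals.sum() == len(peaks)
        assert table.fe_totals.sum() == len(peaks)

    def test_matches_brute_force_binning(self):
        rng = np.random.default_rng(21)
        peaks = random_peakset(rng, 120)
        ref = random_peakset(rng, 30)
        d_edges = (0, 200, 1000, 10_000, math.inf)
        f_edges = (0, 20, 40, 60, math.inf)
        table = distance_fe_histogram(peaks, ref, d_edges, f_edges)
        assert np.array_equal(
            table.counts, brute_distance_fe_counts(peaks, ref, d_edges, f_edges)
        )

    def test_bad_edges_rejected(self):
        peaks = make_set([(500, 5)])
        with pytest.raises(ValidationError):
            distance_fe_histogram(peaks, peaks, distance_edges=(100, 200, math.inf))


class TestHighPeakProximityFraction:
    def test_fraction_among_high_peaks(self):
        ref = make_set([(10_000, 1)])
        near = [(10_000 + i * 10, 50) for i in range(7)]
        far = [(50_000 + i * 1000, 50) for i in range(3)]
        low = [(80_000 + i * 1000, 5) for i in range(5)]
        peaks = make_set(near + far + low)
        assert high_peak_proximity_fraction(peaks, ref, 40, 200) == 0.7

    def test_threshold_above_all_fe_rejected(self):
        peaks = make_set([(500, 5)])
        with pytest.raises(ValidationError):
            high_peak_proximity_fraction(peaks, peaks, 40, 200)

    def test_all_coincident_gives_one(self):
        ref = make_set([(500, 1), (900, 1)])
        peaks = make_set([(500, 50), (900, 50)])
        assert high_peak_proximity_fraction(peaks, ref, 40, 200) == 1.0

    def test_invariant_under_uniform_translation(self):
        rng = np.random.default_rng(4)
        peaks = random_peakset(rng, 60, chroms=("chr1",))
        ref = random_peakset(rng, 20, chroms=("chr1",))
        base = high_peak_proximity_fraction(peaks, ref, 10, 500)
        shift = 7777
        peaks2 = PeakSet([make_shifted(p, shift) for p in peaks])
        ref2 = PeakSet([make_shifted(p, shift) for p in ref])
        assert high_peak_proximity_fraction(peaks2, ref2, 10, 500) == base


def make_shifted(p, shift):
    from cobind.model import GenomicInterval, Peak

    return Peak(
        interval=GenomicInterval(p.chrom, p.start + shift, p.end + shift),
        summit=p.summit + shift,
        fold_enrichment=p.fold_enrichment,
        name=p.name,
    )


class TestProximityEnrichmentTest:
    def test_p_value_matches_exact_enumeration(self):
        ref = make_set([(10_000, 1)])

        def group(n_near, n_far):
            near = [(10_000 + i * 2, 50) for i in range(n_near)]
            far = [(200_000 + i * 5000, 50) for i in range(n_far)]
            return make_set(near + far)

        res = proximity_enrichment_test(group(70, 30), group(40, 60), ref, 40, 200)
        assert res.table == ((70, 30), (40, 60))
        assert res.p_value == pytest.approx(
            brute_fisher_two_sided(((70, 30), (40, 60))), rel=1e-9
        )

    def test_identical_proportions_give_unit_odds(self):
        ref = make_set([(10_000, 1)])
        near = [(10_000 + i * 7, 50) for i in range(5)]
        far = [(200_000 + i * 5000, 50) for i in range(5)]
        g = make_set(near + far)
        res = proximity_enrichment_test(g, g, ref, 40, 200)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_table_warns_p_one(self):
        ref = make_set([(10_000, 1)])
        far = make_set([(200_000 + i * 5000, 50) for i in range(10)])
        with pytest.warns(UserWarning, match="degenerate"):
            res = proximity_enrichment_test(far, far, ref, 40, 200)
        assert res.p_value == 1.0


class TestStratifiedProximity:
    def test_enhanced_top_stratum_detected(self):
        ref = make_set([(10_000, 1), (20_000, 1)])
        top = [(10_000 + i, 90 + i) for i in range(5)]
        low = [(300_000 + 5000 * i, 5 + 0.01 * i) for i in range(60)]
        mid = [(400_000 + 5000 * i, 40) for i in range(30)]
        res = fe_stratified_proximity_test(
            make_set(top + low + mid), ref, high_quantile=0.9
        )
        assert res.high_fraction == 1.0
        assert res.low_fraction == 0.0
        assert res.p_value < 0.01


class TestMultiwayOverlap:
    def test_hand_enumerated_combinations(self):
        anchor = make_set([(1000, 1), (5000, 1), (9000, 1), (13_000, 1), (17_000, 1)],
                          factor="Hoxa2")
        meis = make_set([(1050, 1), (5100, 1), (13_050, 1)], factor="Meis")
        pbx = make_set([(1100, 1), (9050, 1), (13_100, 1)], factor="Pbx")
        counts = multiway_overlap([anchor, meis, pbx])
        assert counts == {
            frozenset({"Meis", "Pbx"}): 2,  # anchors at 1000 and 13000
            frozenset({"Meis"}): 1,  # 5000
            frozenset({"Pbx"}): 1,  # 9000
            frozenset(): 1,  # 17000
        }

    def test_requires_two_sets(self):
        with pytest.raises(ValidationError):
            multiway_overlap([make_set([(1000, 1)])])
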
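"""Basal-plus-extension domains and region-to-gene association."""

import math

import numpy as np
import pytest

from cobind.genes import (
    associate,
    build_domains,
    distance_to_gene_distribution,
    regulated_fraction,
)
from cobind.model import GeneAnnotation, GenomicInterval, ValidationError


def gene(name, tss, strand="+", chrom="chr1"):
    return GeneAnnotation(name, chrom, tss, strand)


class TestBuildDomains:
    def test_isolated_gene_capped_extension(self):
        [dom] = build_domains([gene("g", 10_000)], chrom_sizes={"chr1": 2_000_000})
        assert dom.basal == GenomicInterval("chr1", 5000, 11_000)
        assert dom.extended == GenomicInterval("chr1", 0, 1_011_000)

    def test_minus_strand_mirrors_basal(self):
        [dom] = build_domains([gene("g", 10_000, strand="-")])
        assert dom.basal == GenomicInterval("chr1", 9000, 15_000)

    def test_extensions_meet_at_neighbor_basal_edges(self):
        # basal domains: [5000,11000) and [14000,20000): 3 kb apart
        doms = build_domains([gene("a", 10_000), gene("b", 19_000)],
                             chrom_sizes={"chr1": 100_000})
        da = next(d for d in doms if d.gene.gene == "a")
        db = next(d for d in doms if d.gene.gene == "b")
        assert da.extended.end == db.basal.start == 14_000
        assert db.extended.start == da.basal.end == 11_000

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_domains([gene("g", 1000), gene("g", 9000)])

    def test_extension_never_overlaps_foreign_basal(self):
        rng = np.random.default_rng(9)
        genes = [
            gene(f"g{i}", int(t), "+-"[i % 2])
            for i, t in enumerate(np.sort(rng.integers(0, 500_000, size=30)))
        ]
        doms = build_domains(genes, chrom_sizes={"chr1": 500_000})
        for d in doms:
            for other in doms:
                if other.gene.gene == d.gene.gene:
                    continue
                # direct check: extension area outside own basal must not
                # intersect the other gene's basal domain
                lo = max(d.extended.start, other.basal.start)
                hi = min(d.extended.end, other.basal.end)
                inter = max(0, hi - lo)
                own = max(
                    0,
                    min(d.basal.end, other.basal.end) - max(d.basal.start, other.basal.start),
                )
                assert inter == own  # any intersection is basal-basal only


class TestAssociate:
    def _setup(self):
        genes = [gene("a", 50_000), gene("b", 200_000), gene("far", 3_500_000)]
        doms = build_domains(genes, chrom_sizes={"chr1": 5_000_000})
        return doms

    def test_region_in_basal_domain_single_gene(self):
        doms = self._setup()
        assign = associate([GenomicInterval("chr1", 49_000, 49_200)], doms)
        assert assign.genes_for(0) == {"a"}
        # + strand, midpoint 49100 upstream of TSS 50000 -> negative distance
        assert assign.assignments[0][0].distance == -900

    def test_region_between_genes_hits_both_extensions(self):
        doms = self._setup()
        assign = associate([GenomicInterval("chr1", 120_000, 120_200)], doms)
        assert assign.genes_for(0) == {"a", "b"}

    def test_region_beyond_cap_has_no_genes(self):
        doms = self._setup()
        # beyond a's and b's caps, short of far's leftward extension
        assign = associate([GenomicInterval("chr1", 1_800_000, 1_800_200)], doms)
        assert assign.genes_for(0) == set()

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(13)
        genes = [
            gene(f"g{i}", int(t), "+-"[i % 2])
            for i, t in enumerate(np.sort(rng.integers(10_000, 800_000, size=15)))
        ]
        doms = build_domains(genes, max_ext=100_000, chrom_sizes={"chr1": 900_000})
        regions = []
        for _ in range(100):
            s = int(rng.integers(0, 899_000))
            regions.append(GenomicInterval("chr1", s, s + int(rng.integers(50, 400))))
        assign = associate(regions, doms)
        for i, r in enumerate(regions):
            brute = {
                d.gene.gene
                for d in doms
                if min(r.end, d.extended.end) - max(r.start, d.extended.start) >= 1
            }
            assert assign.genes_for(i) == brute

    def test_monotone_in_extension_cap(self):
        rng = np.random.default_rng(17)
        genes = [gene(f"g{i}", 40_000 * (i + 1)) for i in range(8)]
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 350_000, size=40)
        ]
        small = associate(regions, build_domains(genes, max_ext=10_000))
        big = associate(regions, build_domains(genes, max_ext=500_000))
        for i in range(len(regions)):
            assert small.genes_for(i) <= big.genes_for(i)


class TestRegulatedFraction:
    def _assign(self):
        genes = [gene(f"g{i}", 20_000 * (i + 1)) for i in range(10)]
        doms = build_domains(genes, max_ext=5_000)
        regions = [
            GenomicInterval("chr1", 20_000 * (i + 1) - 100, 20_000 * (i + 1) + 100)
            for i in range(10)
        ]
        return associate(regions, doms)

    def test_counts_regions_hitting_regulated_genes(self):
        k, n, frac = regulated_fraction(self._assign(), {"g0", "g2", "g4", "g6"})
        assert (k, n, frac) == (4, 10, 0.4)

    def test_all_genes_regulated_equals_any_association(self):
        assign = self._assign()
        k, n, frac = regulated_fraction(assign, {f"g{i}" for i in range(10)})
        any_assoc = sum(1 for i in range(n) if assign.genes_for(i))
        assert k == any_assoc

    def test_contrast_between_subset_and_whole(self):
        # mimics a strong regulated-gene contrast: a focused subset of
        # regions hits regulated genes at ~50%, the whole set at ~10%
        genes = [gene(f"g{i}", 20_000 * (i + 1)) for i in range(25)]
        doms = build_domains(genes, max_ext=5_000)
        regions = [
            GenomicInterval("chr1", 20_000 * (i + 1) - 100, 20_000 * (i + 1) + 100)
            for i in range(25)
        ]
        assign_all = associate(regions, doms)
        regulated = {"g0", "g1", "g2"}
        k_all, n_all, f_all = regulated_fraction(assign_all, regulated)
        assign_sub = associate(regions[:6], doms)
        k_sub, n_sub, f_sub = regulated_fraction(assign_sub, regulated)
        assert (k_all, n_all) == (3, 25) and (k_sub, n_sub) == (3, 6)
        assert f_sub > f_all
        assert k_sub <= k_all

    def test_empty_regulated_set_warns(self):
        with pytest.warns(UserWarning, match="empty regulated"):
            k, n, frac = regulated_fraction(self._assign(), set())
        assert frac == 0.0

    def test_empty_region_list_rejected(self):
        from cobind.genes import RegionGeneAssignment

        with pytest.raises(ValidationError):
            regulated_fraction(RegionGeneAssignment([], []), {"g"})


class TestDistanceDistribution:
    def test_far_and_near_binning(self):
        genes = [gene("g", 100_000)]
        doms = build_domains(genes)
        regions = [
            GenomicInterval("chr1", 99_900, 100_100),  # on the TSS
            GenomicInterval("chr1", 160_000, 160_200),  # 60 kb away
        ]
        hist = distance_to_gene_distribution(associate(regions, doms), (0, 50_000))
        assert hist.counts.tolist() == [1, 1]

    def test_region_with_no_gene_in_farthest_bin(self):
        genes = [gene("g", 100_000)]
        doms = build_domains(genes, max_ext=10_000)
        regions = [GenomicInterval("chr1", 3_000_000, 3_000_200)]
        hist = distance_to_gene_distribution(associate(regions, doms), (0, 50_000))
        assert hist.counts.tolist() == [0, 1]

    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(23)
        genes = [gene(f"g{i}", int(t)) for i, t in
                 enumerate(np.sort(rng.integers(10_000, 400_000, size=10)))]
        doms = build_domains(genes, chrom_sizes={"chr1": 500_000})
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 499_000, size=50)
        ]
        assign = associate(regions, doms)
        edges = (0.0, 5000.0, 50_000.0, math.inf)
        hist = distance_to_gene_distribution(assign, edges)
        brute = [0] * 3
        for i, r in enumerate(regions):
            ds = [abs(a.distance) for a in assign.assignments[i]]
            d = min(ds) if ds else math.inf
            k = 2 if d >= 50_000 else (1 if d >= 5000 else 0)
            brute[k] += 1
        assert hist.counts.tolist() == brute
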
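"""Enhancer calling, Venn classes, genomic-location annotation, SNP
proximity and cell-type gene change fractions."""

import numpy as np
import pytest

from chipscape.enhancers import (
    annotate_locations,
    call_enhancers,
    coverage_fraction,
    gene_change_fraction,
    snp_fraction,
)
from chipscape.intervals import overlaps_any
from chipscape.peaks import ConsensusSet
from chipscape.types import Genome, GenomicInterval, Peak, SnpRecord, TssRecord

from conftest import random_intervals


def consensus(peaks, ct="BC", cond="NC"):
    return ConsensusSet(
        group_key=(ct, cond, "H3K27ac"),
        peaks=peaks,
        support=[2] * len(peaks),
        n_replicates=3,
    )


def peak_at(summit, half=700, chrom="chr1"):
    return Peak(GenomicInterval(chrom, summit - half, summit + half), half)


@pytest.fixture
def genome():
    return Genome(chrom_sizes={"chr1": 1_000_000})


class TestCallEnhancers:
    def test_far_summit_kept(self, genome):
        tss = [TssRecord("g1", "chr1", 10_000)]
        es = call_enhancers({"NC": consensus([peak_at(12_000)])}, tss, genome, "BC")
        assert len(es.enhancers) == 1
        assert es.enhancers[0].interval.width == 1000

    def test_summit_exactly_1000bp_from_tss_kept(self, genome):
        # enhancer [tss+500, tss+1500) abuts promoter [tss-500, tss+500): half-open
        tss = [TssRecord("g1", "chr1", 10_000)]
        es = call_enhancers({"NC": consensus([peak_at(11_000)])}, tss, genome, "BC")
        assert len(es.enhancers) == 1

    def test_summit_999bp_from_tss_removed(self, genome):
        tss = [TssRecord("g1", "chr1", 10_000)]
        es = call_enhancers({"NC": consensus([peak_at(10_999)])}, tss, genome, "BC")
        assert len(es.enhancers) == 0

    def test_no_enhancer_overlaps_any_promoter(self, genome, rng):
        tss = [
            TssRecord(f"g{i}", "chr1", int(p))
            for i, p in enumerate(rng.integers(5_000, 995_000, 40))
        ]
        peaks = [peak_at(int(s)) for s in rng.integers(5_000, 995_000, 120)]
        es = call_enhancers(
            {"NC": consensus(peaks), "MUT": consensus(peaks[1:], cond="MUT")},
            tss, genome, "BC",
        )
        promoters = [t.promoter(500) for t in tss]
        if es.enhancers:
            assert not overlaps_any([e.interval for e in es.enhancers], promoters).any()

    def test_venn_classes_partition(self, genome):
        nc = [peak_at(100_000), peak_at(200_000)]
        mut = [peak_at(100_200), peak_at(300_000)]
        es = call_enhancers(
            {"NC": consensus(nc), "MUT": consensus(mut, cond="MUT")},
            [], genome, "BC",
        )
        v = es.venn
        assert v == {"NC_only": 1, "shared": 1, "MUT_only": 1}
        assert v["NC_only"] + v["shared"] + v["MUT_only"] == len(es.enhancers)


class TestCoverageFraction:
    def test_identical_sets(self):
        r = [GenomicInterval("chr1", 0, 1000)]
        assert coverage_fraction(r, list(r))["nc_covered_by_mut"] == 1.0

    def test_disjoint_sets(self):
        nc = [GenomicInterval("chr1", 0, 1000)]
        mut = [GenomicInterval("chr1", 5000, 6000)]
        out = coverage_fraction(nc, mut)
        assert out["nc_covered_by_mut"] == 0.0
        assert out["mut_unique_fraction"] == 1.0

    def test_empty_nc_errors(self):
        with pytest.raises(ValueError):
            coverage_fraction([], [GenomicInterval("chr1", 0, 10)])

    def test_matches_brute_force(self, rng):
        nc = random_intervals(rng, 60, chroms=("chr1",), max_pos=30_000, max_len=1000)
        mut = random_intervals(rng, 60, chroms=("chr1",), max_pos=30_000, max_len=1000)
        out = coverage_fraction(nc, mut)
        want = sum(
            1 for a in nc if any(a.start < b.end and b.start < a.end for b in mut)
        ) / len(nc)
        assert out["nc_covered_by_mut"] == pytest.approx(want)


class TestAnnotateLocations:
    tss = [TssRecord("g1", "chr1", 100_000)]
    spans = [GenomicInterval("chr1", 100_000, 150_000)]

    def _cat(self, iv):
        cats, _ = annotate_locations([iv], self.tss, self.spans)
        return cats[0]

    def test_just_under_2kb_is_promoter_vicinity(self):
        # promoter window [99500,100500); enhancer edge at 102499 -> gap 1999
        assert self._cat(GenomicInterval("chr1", 102_499, 103_499)) == "promoter_vicinity"

    def test_exactly_2kb_is_not_vicinity(self):
        assert self._cat(GenomicInterval("chr1", 102_500, 103_500)) == "genic"

    def test_inside_gene_far_from_promoter_is_genic(self):
        assert self._cat(GenomicInterval("chr1", 140_000, 141_000)) == "genic"

    def test_far_from_everything_is_distal(self):
        assert self._cat(GenomicInterval("chr1", 800_000, 801_000)) == "distal_intergenic"

    def test_distribution_sums_to_one_and_order_stable(self, rng):
        ivs = random_intervals(rng, 50, chroms=("chr1",), max_pos=900_000, max_len=1000)
        cats1, dist = annotate_locations(ivs, self.tss, self.spans)
        assert sum(dist.values()) == pytest.approx(1.0)
        perm = [ivs[i] for i in rng.permutation(len(ivs))]
        cats2, dist2 = annotate_locations(perm, self.tss, self.spans)
        assert dist == dist2


class TestSnpFraction:
    enh = [GenomicInterval("chr1", 500_000, 501_000)]

    def test_snp_inside_is_associated(self):
        frac, flags = snp_fraction(self.enh, [SnpRecord("rs1", "chr1", 500_500)])
        assert flags == [True]

    def test_boundary_exclusive_at_window(self):
        # end + 150000 = 651000 is outside the half-open window
        frac, flags = snp_fraction(self.enh, [SnpRecord("rs1", "chr1", 651_000)])
        assert flags == [False]
        frac, flags = snp_fraction(self.enh, [SnpRecord("rs1", "chr1", 650_999)])
        assert flags == [True]

    def test_left_edge_inclusive(self):
        frac, flags = snp_fraction(self.enh, [SnpRecord("rs1", "chr1", 350_000)])
        assert flags == [True]
        frac, flags = snp_fraction(self.enh, [SnpRecord("rs1", "chr1", 349_999)])
        assert flags == [False]

    def test_monotone_in_window(self, rng):
        enh = random_intervals(rng, 40, chroms=("chr1",), max_pos=900_000, max_len=1000)
        snps = [SnpRecord(f"rs{i}", "chr1", int(p)) for i, p in enumerate(rng.integers(0, 900_000, 15))]
        fracs = [snp_fraction(enh, snps, window=w)[0] for w in (1000, 10_000, 50_000, 150_000)]
        assert fracs == sorted(fracs)

    def test_empty_snps_error(self):
        with pytest.raises(ValueError):
            snp_fraction(self.enh, [])


class TestGeneChangeFraction:
    def _tss(self, n, spacing=10_000):
        return [TssRecord(f"g{i:03d}", "chr1", 5000 + i * spacing) for i in range(n)]

    def test_no_regions_zero_fraction(self):
        out = gene_change_fraction([], [], ["g000"], self._tss(3))
        assert out["fraction"] == 0.0

    def test_constructed_41_of_712_ratio(self):
        tss = self._tss(712)
        genes = [t.gene_id for t in tss]
        # one down-regulated region next to each of the first 41 genes
        regions = [
            GenomicInterval("chr1", t.tss + 1000, t.tss + 2000) for t in tss[:41]
        ]
        out = gene_change_fraction([], regions, genes, tss)
        assert out["n_changed"] == 41 and out["n_total"] == 712
        assert out["fraction"] == pytest.approx(41 / 712)
        assert out["fraction_down"] == 1.0

    def test_majority_down_rule_with_tie(self):
        tss = self._tss(2)
        up = [GenomicInterval("chr1", tss[0].tss + 100, tss[0].tss + 600)]
        down = [GenomicInterval("chr1", tss[0].tss - 600, tss[0].tss - 100)]
        out = gene_change_fraction(up, down, [t.gene_id for t in tss], tss)
        assert out["n_changed"] == 1
        assert out["fraction_down"] == 1.0  # tie counts as down

    def test_matches_brute_force(self, rng):
        tss = self._tss(50)
        genes = [t.gene_id for t in tss if rng.random() < 0.5]
        ups = random_intervals(rng, 20, chroms=("chr1",), max_pos=500_000, max_len=2000)
        downs = random_intervals(rng, 20, chroms=("chr1",), max_pos=500_000, max_len=2000)
        out = gene_change_fraction(ups, downs, genes, tss)
        from chipscape.intervals import nearest_feature

        per_gene = {}
        for regions, lab in ((ups, "up"), (downs, "down")):
            for r in regions:
                g, _ = nearest_feature(r, tss)
                per_gene.setdefault(g, []).append(lab)
        want = sorted(g for g in per_gene if g in set(genes))
        assert out["changed_genes"] == want

    def test_empty_gene_list_errors(self):
        with pytest.raises(ValueError):
            gene_change_fraction([], [], [], self._tss(2))
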
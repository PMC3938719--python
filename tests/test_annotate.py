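"""Location classification against an exhaustive oracle, plus interval
arithmetic on the printed FRA2/ChIP-seq coordinates."""

import numpy as np
import pytest

from gaschip.annotate import (
    annotate_cohort,
    interval_gap,
    locate_site,
)
from gaschip.genomic import ClonedSite, GeneModel


def _site(mid, length=100, site_id="s", chrom="chr1"):
    start = mid - length // 2
    return ClonedSite(site_id, chrom, start, start + length)


class TestLocateSite:
    def test_midpoint_in_only_intron_is_intron1(self):
        gene = GeneModel("g", "chr1", "+", 1000, 5000, ((1000, 1500), (3000, 5000)))
        ann = locate_site(_site(2000), [gene])
        assert ann.category == "intron1"
        assert ann.intron_ordinal == 1
        assert ann.genes == ("g",)

    def test_upstream_within_window_strand_aware(self):
        gene = GeneModel("g", "chr1", "+", 50_000, 60_000, ((50_000, 60_000),))
        ann = locate_site(_site(45_000), [gene])
        assert ann.category == "upstream_lt10kb"
        assert ann.dist_to_nearest_tss == 5_000
        # same position relative to a minus-strand gene is downstream
        gene_minus = GeneModel("g", "chr1", "-", 50_000, 60_000, ((50_000, 60_000),))
        assert locate_site(_site(45_000), [gene_minus]).category == "intergenic"
        assert locate_site(_site(65_000), [gene_minus]).category == "upstream_lt10kb"

    def test_intergenic_lists_both_flanking_genes(self):
        genes = [
            GeneModel("gA", "chr1", "+", 10_000, 15_000, ((10_000, 15_000),)),
            GeneModel("gB", "chr1", "+", 55_000, 60_000, ((55_000, 60_000),)),
        ]
        ann = locate_site(_site(30_000), genes)
        assert ann.category == "intergenic"
        assert ann.genes == ("gA", "gB")
        assert ann.dist_to_nearest_tss == 20_000

    def test_chromosome_end_intergenic_has_single_flank(self):
        genes = [GeneModel("gA", "chr1", "+", 10_000, 15_000, ((10_000, 15_000),))]
        ann = locate_site(_site(40_000), genes)
        assert ann.category == "intergenic"
        assert ann.genes == ("gA",)

    def test_exonic_midpoint_flagged_as_other(self):
        gene = GeneModel("g", "chr1", "+", 1000, 5000, ((1000, 1500), (3000, 5000)))
        ann = locate_site(_site(1200), [gene])
        assert ann.category == "other"

    def test_no_genes_on_chromosome_warns(self, caplog):
        with caplog.at_level("WARNING"):
            ann = locate_site(_site(1000), [])
        assert ann.category == "intergenic"
        assert ann.genes == ()
        assert ann.dist_to_nearest_tss is None

    def test_intron_precedence_over_upstream(self):
        # site inside gA's intron and within 10 kb upstream of gB -> intronic
        gA = GeneModel("gA", "chr1", "+", 1000, 20_000, ((1000, 1500), (19_000, 20_000)))
        gB = GeneModel("gB", "chr1", "+", 12_000, 14_000, ((12_000, 14_000),))
        ann = locate_site(_site(5_000), [gA, gB])
        assert ann.category == "intron1"
        assert ann.genes == ("gA",)

    def test_fra2_gas1_maps_to_internal_intron_3(self):
        # toy FRA2 model on chr2, + strand: TSS placed so that the cloned
        # GAS1 interval chr2:28,487,132-28,487,836 sits at +17,850..+18,554
        # relative to the TSS, inside intron 3
        tss = 28_487_132 - 17_850
        exons = (
            (tss, tss + 300),
            (tss + 2_000, tss + 2_200),
            (tss + 9_000, tss + 9_400),
            (tss + 20_000, tss + 20_500),
        )
        fra2 = GeneModel("FRA2", "chr2", "+", tss, tss + 20_500, exons)
        gas1 = ClonedSite("GAS1", "chr2", 28_487_132, 28_487_836)
        ann = locate_site(gas1, [fra2])
        assert ann.category == "internal_intron"
        assert ann.intron_ordinal == 3
        assert ann.genes == ("FRA2",)


class TestIntervalGap:
    def test_printed_chipseq_peak_to_gas1_distance(self):
        peak = ("chr2", 28_485_399, 28_485_970)
        gas1 = ("chr2", 28_487_132, 28_487_836)
        assert interval_gap(peak, gas1) == 1_162

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 0, 10), ("chr1", 5, 20), 0),
            (("chr1", 0, 10), ("chr1", 10, 20), 0),
            (("chr1", 30, 40), ("chr1", 0, 10), 20),
        ],
    )
    def test_overlap_adjacency_and_order(self, a, b, expected):
        assert interval_gap(a, b) == expected

    def test_different_chromosomes_error(self):
        with pytest.raises(ValueError, match="chromosome"):
            interval_gap(("chr1", 0, 10), ("chr2", 20, 30))


def _random_instance(rng):
    """Random gene layout plus random sites on one chromosome."""
    genes = []
    pos = int(rng.integers(0, 5_000))
    for i in range(int(rng.integers(1, 5))):
        n_exons = int(rng.integers(1, 5))
        exons = []
        p = pos
        for j in range(n_exons):
            e = p + int(rng.integers(50, 400))
            exons.append((p, e))
            p = e + int(rng.integers(500, 4_000))
        tx_end = exons[-1][1]
        genes.append(
            GeneModel(
                f"g{i}",
                "chr1",
                "+" if rng.random() < 0.5 else "-",
                exons[0][0],
                tx_end,
                tuple(exons),
            )
        )
        pos = tx_end + int(rng.integers(1_000, 40_000))
    sites = [
        _site(int(rng.integers(0, pos + 20_000)), length=200, site_id=f"s{k}")
        for k in range(10)
    ]
    return genes, sites


def _oracle_locate(site, genes, window):
    """Straight-line reimplementation of the classification rules, testing
    every gene and intron directly (no shared code with locate_site)."""
    mid = (site.start + site.end) // 2
    best = None  # (category_rank, tiebreak, result)
    for g in genes:
        introns = [
            (g.exons[i][1], g.exons[i + 1][0]) for i in range(len(g.exons) - 1)
        ]
        if g.strand == "-":
            ordinals = list(range(len(introns), 0, -1))
        else:
            ordinals = list(range(1, len(introns) + 1))
        for (s, e), o in zip(introns, ordinals):
            if s <= mid < e:
                cand = (0, g.gene_id, ("intron1" if o == 1 else "internal_intron", o))
                if best is None or cand < best:
                    best = cand
    if best is not None:
        return best[2][0]
    ups = []
    for g in genes:
        tss = g.tx_start if g.strand == "+" else g.tx_end - 1
        d = (tss - mid) if g.strand == "+" else (mid - tss)
        if 0 < d <= window:
            ups.append((d, g.gene_id))
    if ups:
        return "upstream_lt10kb"
    if any(g.tx_start <= mid < g.tx_end for g in genes):
        return "other"
    return "intergenic"


class TestCohortAnnotation:
    def test_empty_cohort(self):
        assert annotate_cohort([], []) == []

    def test_lone_far_site_is_intergenic(self):
        genes = [GeneModel("g", "chr1", "+", 0, 1_000, ((0, 1_000),))]
        [ann] = annotate_cohort([_site(500_000)], genes)
        assert ann.category == "intergenic"

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            genes, sites = _random_instance(rng)
            annotations = annotate_cohort(sites, genes)
            by_id = {a.site_id: a for a in annotations}
            for site in sites:
                assert by_id[site.site_id].category == _oracle_locate(
                    site, genes, 10_000
                )

    def test_every_site_gets_exactly_one_category(self):
        rng = np.random.default_rng(77)
        genes, sites = _random_instance(rng)
        annotations = annotate_cohort(sites, genes)
        assert len(annotations) == len(sites)
        assert sorted(a.site_id for a in annotations) == sorted(
            s.site_id for s in sites
        )

    def test_enlarging_window_only_moves_intergenic_to_upstream(
        self, paper_scale_cohort
    ):
        _, _, genes, sites, _ = paper_scale_cohort
        small = {a.site_id: a.category for a in annotate_cohort(sites, genes, 5_000)}
        large = {a.site_id: a.category for a in annotate_cohort(sites, genes, 10_000)}
        for site_id, cat_small in small.items():
            if cat_small != large[site_id]:
                assert cat_small == "intergenic"
                assert large[site_id] == "upstream_lt10kb"

    def test_any_overlap_mode_runs_and_partitions(self, paper_scale_cohort):
        _, _, genes, sites, _ = paper_scale_cohort
        annotations = annotate_cohort(sites, genes, mode="any_overlap")
        assert len(annotations) == len(sites)
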
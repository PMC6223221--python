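"""Transcript selection, 12-region partition and promoter-bin geometry."""

import numpy as np
import pytest

from methregions.annotation import (
    REGION_LABELS,
    GeneModel,
    make_bins,
    partition_regions,
    read_refflat,
    select_transcripts,
)

from conftest import make_gene


class TestSelectTranscripts:
    def test_tie_break_smallest_accession(self):
        a = make_gene("geneA", "NM_002", tx_start=100, tx_end=5000)
        b = make_gene("geneA", "NM_001", tx_start=100, tx_end=6000)
        out = select_transcripts([a, b])
        assert [g.transcript_id for g in out] == ["NM_001"]

    def test_non_mature_transcripts_excluded(self):
        nr = make_gene("geneB", "NR_100", tx_start=50, tx_end=4000)
        assert select_transcripts([nr]) == []

    def test_distinct_genes_at_same_tss_both_kept(self):
        c = make_gene("geneC", "NM_7", tx_start=10_000, tx_end=14_000)
        d = make_gene("geneD", "NM_8", tx_start=10_000, tx_end=15_000)
        out = select_transcripts([c, d])
        assert sorted(g.gene_id for g in out) == ["geneC", "geneD"]

    def test_same_gene_different_tss_kept_separately(self):
        a = make_gene("geneE", "NM_1", tx_start=1000, tx_end=9000)
        b = make_gene("geneE", "NM_2", tx_start=3000, tx_end=9000)
        assert len(select_transcripts([a, b])) == 2

    def test_empty_table_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert select_transcripts([]) == []
        assert "empty" in caplog.text

    def test_prefix_configurable(self):
        xm = make_gene("g", "XM_5", tx_start=100, tx_end=4000)
        assert select_transcripts([xm], mature_mrna_prefix="XM_")

    def test_minus_strand_tss_is_tx_end(self):
        a = make_gene("g", "NM_1", strand="-", tx_start=100, tx_end=5000)
        b = make_gene("g", "NM_2", strand="-", tx_start=900, tx_end=5000)
        # same TSS (tx_end) on the minus strand: tie-break applies
        out = select_transcripts([a, b])
        assert [g.transcript_id for g in out] == ["NM_1"]


class TestPartitionRegions:
    def _by_label(self, g, **kw):
        return {r.region_label: r.intervals for r in partition_regions(g, **kw)}

    def test_plus_strand_flanks(self):
        g = make_gene(tx_start=100_000, tx_end=105_000)
        regions = self._by_label(g)
        assert regions["up2"] == (("chr1", 98_000, 100_000),)
        assert regions["up5"] == (("chr1", 95_000, 98_000),)
        assert regions["up10"] == (("chr1", 90_000, 95_000),)
        assert regions["up20"] == (("chr1", 80_000, 90_000),)
        assert regions["down2"] == (("chr1", 105_000, 107_000),)
        assert regions["down20"] == (("chr1", 115_000, 125_000),)

    def test_minus_strand_flanks_mirrored(self):
        g = make_gene(strand="-", tx_start=95_000, tx_end=100_000)
        regions = self._by_label(g)
        assert regions["up2"] == (("chr1", 100_000, 102_000),)
        assert regions["down2"] == (("chr1", 93_000, 95_000),)

    def test_single_exon_coding_gene_body(self):
        g = GeneModel("g", "NM_1", "chr1", "+", 0, 1000, 200, 800,
                      exons=((0, 1000),))
        regions = self._by_label(g)
        assert regions["5UTR"] == (("chr1", 0, 200),)
        assert regions["exon"] == (("chr1", 200, 800),)
        assert regions["3UTR"] == (("chr1", 800, 1000),)
        assert regions["intron"] == ()

    def test_minus_strand_utrs_swap_sides(self):
        g = GeneModel("g", "NM_1", "chr1", "-", 0, 1000, 200, 800,
                      exons=((0, 1000),))
        regions = self._by_label(g)
        assert regions["5UTR"] == (("chr1", 800, 1000),)
        assert regions["3UTR"] == (("chr1", 0, 200),)

    def test_all_twelve_labels_always_emitted(self):
        g = make_gene()
        labels = [r.region_label for r in partition_regions(g)]
        assert labels == list(REGION_LABELS)

    def test_noncoding_gene_body(self, caplog):
        g = GeneModel("g", "NR_1", "chr1", "+", 1000, 5000, 1000, 1000,
                      exons=((1000, 2000), (3000, 5000)))
        regions = self._by_label(g)
        assert regions["5UTR"] == () and regions["3UTR"] == () and regions["exon"] == ()
        assert regions["intron"] == (("chr1", 2000, 3000),)

    def test_clipping_at_chromosome_start(self):
        g = make_gene(tx_start=5000, tx_end=9000)
        regions = self._by_label(g)
        assert regions["up5"] == (("chr1", 0, 3000),)
        assert regions["up10"] == ()  # entirely off-chromosome

    def test_gene_body_partition(self):
        """The four body regions tile [tx_start, tx_end) without overlap."""
        g = make_gene(
            tx_start=10_000, tx_end=20_000, cds_start=10_400, cds_end=19_300,
            exons=((10_000, 11_000), (13_000, 14_500), (18_000, 20_000)))
        regions = self._by_label(g)
        covered = np.zeros(10_000, dtype=int)
        for label in ("5UTR", "exon", "intron", "3UTR"):
            for _, s, e in regions[label]:
                covered[s - 10_000:e - 10_000] += 1
        assert (covered == 1).all()


class TestMakeBins:
    def test_plus_strand_bin1_abuts_tss(self):
        bins = {b.bin_index: b.interval for b in make_bins(make_gene(tx_start=10_000, tx_end=16_000))}
        assert bins[1] == ("chr1", 10_000, 10_200)

    def test_core_bins_span_minus800_to_1200(self):
        bins = {b.bin_index: b.interval for b in make_bins(make_gene(tx_start=10_000, tx_end=16_000))}
        assert bins[-4][1] == 9200
        assert bins[6][2] == 11_200

    def test_minus_strand_bin1_upstream_in_genome(self):
        g = make_gene(strand="-", tx_start=5000, tx_end=10_000)
        bins = {b.bin_index: b.interval for b in make_bins(g)}
        assert bins[1] == ("chr1", 9800, 10_000)

    def test_no_bin_zero_and_twenty_bins(self):
        bins = make_bins(make_gene())
        idx = [b.bin_index for b in bins]
        assert len(idx) == 20 and 0 not in idx
        assert sorted(idx) == list(range(-10, 0)) + list(range(1, 11))

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_bins_tile_promoter_disjointly(self, strand):
        g = make_gene(strand=strand, tx_start=50_000, tx_end=55_000)
        bins = make_bins(g)
        ivs = sorted((b.interval[1], b.interval[2]) for b in bins)
        assert ivs[0][0] == g.tss - 2000 and ivs[-1][1] == g.tss + 2000
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 == s2  # consecutive, non-overlapping

    def test_strand_reversal_reflects_bins_about_tss(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tss = int(rng.integers(30_000, 200_000))
            fwd = make_gene(strand="+", tx_start=tss, tx_end=tss + 5000)
            rev = make_gene(strand="-", tx_start=tss - 5000, tx_end=tss)
            fb = {b.bin_index: b.interval for b in make_bins(fwd)}
            rb = {b.bin_index: b.interval for b in make_bins(rev)}
            for k, (_, s, e) in fb.items():
                assert rb[k][1:] == (2 * tss - e, 2 * tss - s)

    def test_edge_clip_flags_partial(self):
        g = make_gene(tx_start=500, tx_end=5000)
        bins = make_bins(g)
        partial = [b for b in bins if b.partial]
        assert partial and all(b.interval[1] >= 0 for b in bins)

    def test_indivisible_half_width_rejected(self):
        with pytest.raises(ValueError):
            make_bins(make_gene(), half_width=2000, bin_size=300)


def test_refflat_parser_skips_malformed_rows(tmp_path, caplog):
    path = tmp_path / "genes.refflat"
    good = "\t".join(["gA", "NM_1", "chr1", "+", "100", "9000", "300", "8000",
                      "1", "100,", "9000,"])
    bad = "gB\tNM_2\tchr1\t+\tnot_a_number"
    path.write_text(good + "\n" + bad + "\n")
    with caplog.at_level("WARNING"):
        models = read_refflat(path)
    assert [g.transcript_id for g in models] == ["NM_1"]
    assert "malformed" in caplog.text
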
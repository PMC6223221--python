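"""Region/bin aggregation, stage averaging and methylated-bin counts."""

import numpy as np
import pandas as pd
import pytest

from methregions import aggregate, annotation
from methregions.methio import Sample, SampleManifest

from conftest import make_gene


def calls_frame(positions, levels, chrom="chr1"):
    return pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "meth_level": levels, "coverage": 10,
    })


def simple_anno(intervals, gene="g1", label="r1"):
    return pd.DataFrame(
        [(gene, label, c, s, e, "+") for c, s, e in intervals],
        columns=["gene_id", "label", "chrom", "start", "end", "strand"])


class TestRegionMethylation:
    def test_unweighted_mean_of_levels(self):
        calls = {"s1": calls_frame([10, 20, 30], [0.2, 0.4, 0.6])}
        m = aggregate.region_methylation(calls, simple_anno([("chr1", 0, 100)]))
        cell = m.data.iloc[0]
        assert cell["meth"] == pytest.approx(0.4)
        assert cell["n_cpg"] == 3

    def test_empty_region_is_missing_not_zero(self):
        calls = {"s1": calls_frame([500], [0.2])}
        m = aggregate.region_methylation(calls, simple_anno([("chr1", 0, 100)]))
        cell = m.data.iloc[0]
        assert np.isnan(cell["meth"]) and cell["n_cpg"] == 0

    def test_half_open_boundaries(self):
        # CpG exactly at the end boundary excluded; at the start included
        calls = {"s1": calls_frame([0, 100], [1.0, 0.0])}
        m = aggregate.region_methylation(calls, simple_anno([("chr1", 0, 100)]))
        cell = m.data.iloc[0]
        assert cell["n_cpg"] == 1 and cell["meth"] == pytest.approx(1.0)

    def test_multi_interval_region_pools_cpgs(self):
        anno = simple_anno([("chr1", 0, 10), ("chr1", 50, 60)])
        calls = {"s1": calls_frame([5, 55], [0.0, 1.0])}
        m = aggregate.region_methylation(calls, anno)
        assert m.data.iloc[0]["meth"] == pytest.approx(0.5)

    def test_value_bounded_by_call_levels(self):
        rng = np.random.default_rng(0)
        lev = rng.random(50)
        calls = {"s1": calls_frame(np.arange(50) * 3, lev)}
        m = aggregate.region_methylation(calls, simple_anno([("chr1", 0, 150)]))
        v = m.data.iloc[0]["meth"]
        assert lev.min() <= v <= lev.max()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        pos = rng.choice(10_000, 200, replace=False)
        lev = rng.random(200)
        anno = simple_anno([("chr1", 1000, 9000)])
        m1 = aggregate.region_methylation({"s": calls_frame(pos, lev)}, anno)
        perm = rng.permutation(200)
        m2 = aggregate.region_methylation({"s": calls_frame(pos[perm], lev[perm])}, anno)
        assert m1.data.iloc[0]["meth"] == pytest.approx(m2.data.iloc[0]["meth"], abs=1e-15)

    def test_matches_brute_force_oracle(self):
        """Fast prefix-sum aggregation equals a direct interval scan."""
        rng = np.random.default_rng(42)
        models = [make_gene(f"g{i}", f"NM_{i}", tx_start=30_000 + i * 50_000,
                            tx_end=30_000 + i * 50_000 + 4000,
                            strand="+" if i % 2 else "-")
                  for i in range(20)]
        annos = [r for g in models for r in annotation.partition_regions(g)]
        frame = annotation.regions_frame(annos)
        pos = np.sort(rng.choice(1_200_000, 4000, replace=False))
        lev = rng.random(4000)
        calls = {"s": calls_frame(pos, lev)}
        m = aggregate.region_methylation(calls, frame)
        for a in rng.choice(annos, 60, replace=False):
            mask = np.zeros(len(pos), dtype=bool)
            for _, s, e in a.intervals:
                mask |= (pos >= s) & (pos < e)
            rows = m.data[(m.data.gene_id == a.gene_id)
                          & (m.data.label == a.region_label)]
            if not a.intervals:
                # regions with no genomic extent never enter the matrix
                assert rows.empty
                continue
            row = rows.iloc[0]
            if mask.sum() == 0:
                assert np.isnan(row["meth"])
            else:
                assert row["meth"] == pytest.approx(lev[mask].mean(), abs=1e-12)
            assert row["n_cpg"] == mask.sum()


class TestStageAverage:
    def _matrix(self, values_by_sample):
        frames = []
        for sid, vals in values_by_sample.items():
            for gene, v in vals.items():
                frames.append((gene, "r1", sid, v, 0 if np.isnan(v) else 5))
        data = pd.DataFrame(frames, columns=["gene_id", "label", "sample_id",
                                             "meth", "n_cpg"])
        return aggregate.MethylationMatrix(
            data=data, labels=["r1"], sample_ids=list(values_by_sample))

    def test_replicate_mean(self):
        m = self._matrix({"a": {"g": 0.2}, "b": {"g": 0.4}})
        man = SampleManifest([Sample("a", "st", 1), Sample("b", "st", 2)])
        out = aggregate.stage_average(m, man)
        assert out["st"].gene_region.loc["g", "r1"] == pytest.approx(0.3)

    def test_missing_replicate_ignored(self):
        m = self._matrix({"a": {"g": 0.2}, "b": {"g": np.nan}})
        man = SampleManifest([Sample("a", "st", 1), Sample("b", "st", 2)])
        out = aggregate.stage_average(m, man)
        assert out["st"].gene_region.loc["g", "r1"] == pytest.approx(0.2)

    def test_global_mean_over_genes(self):
        m = self._matrix({"a": {"g1": 0.1, "g2": 0.2, "g3": 0.6}})
        man = SampleManifest([Sample("a", "st", 1)])
        out = aggregate.stage_average(m, man)
        assert out["st"].global_means["r1"] == pytest.approx(0.3)

    def test_chromosome_means(self):
        m = self._matrix({"a": {"g1": 0.1, "g2": 0.5}})
        man = SampleManifest([Sample("a", "st", 1)])
        out = aggregate.stage_average(m, man, gene_chrom={"g1": "chr1", "g2": "chr2"})
        assert out["st"].chrom_means.loc["chr2", "r1"] == pytest.approx(0.5)

    def test_stage_without_samples_is_rejected_by_manifest(self):
        with pytest.raises(ValueError):
            SampleManifest([Sample("a", "st", 1)], stages=["st", "ghost"])


class TestGeneLevel:
    def test_pooled_cpg_weighted_mean(self):
        data = pd.DataFrame([
            ("g", "up2", "s", 0.2, 1),
            ("g", "exon", "s", 0.8, 3),
            ("g", "3UTR", "s", np.nan, 0),
        ], columns=["gene_id", "label", "sample_id", "meth", "n_cpg"])
        m = aggregate.MethylationMatrix(data, ["up2", "exon", "3UTR"], ["s"])
        values, n = aggregate.gene_level(m)
        assert values.loc["g", "s"] == pytest.approx((0.2 + 3 * 0.8) / 4)
        assert n.loc["g", "s"] == 4


class TestMethylatedBinCounts:
    def test_counts_genes_with_methylated_bins(self):
        values = pd.DataFrame({1: [0.0, 0.5, np.nan]}, index=["g1", "g2", "g3"])
        out = aggregate.methylated_bin_counts(values)
        assert out.loc[1, "n_methylated"] == 1
        assert out.loc[1, "mean_meth"] == pytest.approx(0.5)

    def test_all_missing_counts_zero(self):
        values = pd.DataFrame({1: [np.nan, np.nan]}, index=["g1", "g2"])
        out = aggregate.methylated_bin_counts(values)
        assert out.loc[1, "n_methylated"] == 0

    def test_fully_methylated(self):
        values = pd.DataFrame({1: [1.0, 1.0, 1.0]}, index=list("abc"))
        out = aggregate.methylated_bin_counts(values)
        assert out.loc[1, "n_methylated"] == 3
        assert out.loc[1, "mean_meth"] == pytest.approx(1.0)

    def test_eps_threshold(self):
        values = pd.DataFrame({1: [0.05, 0.5]}, index=["g1", "g2"])
        out = aggregate.methylated_bin_counts(values, eps=0.1)
        assert out.loc[1, "n_methylated"] == 1
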
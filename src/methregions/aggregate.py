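"""Aggregate per-CpG calls to region/bin, replicate and stage level.

A region's methylation level is the unweighted arithmetic mean of the
methylation levels of all covered CpGs whose (+ strand) position falls in
any of the region's half-open intervals.  A region with no covered CpG is
missing, never zero.  Stage values average the available replicates; the
genome-level value of a sample or stage is the unweighted mean over genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .methio import SampleManifest


@dataclass
class MethylationMatrix:
    """Genes x regions (or bins) x samples methylation with missingness.

    ``data`` is long-form with columns gene_id, label, sample_id, meth
    (NaN = missing) and n_cpg; a cell is missing iff its n_cpg is 0.
    """

    data: pd.DataFrame
    labels: list
    sample_ids: list

    @property
    def gene_ids(self) -> list:
        return sorted(self.data["gene_id"].unique())

    def matrix(self, sample_id: str) -> pd.DataFrame:
        """Genes x labels value matrix for one sample."""
        sub = self.data[self.data["sample_id"] == sample_id]
        m = sub.pivot(index="gene_id", columns="label", values="meth")
        return m.reindex(columns=self.labels)

    def ncpg_matrix(self, sample_id: str) -> pd.DataFrame:
        sub = self.data[self.data["sample_id"] == sample_id]
        m = sub.pivot(index="gene_id", columns="label", values="n_cpg")
        return m.reindex(columns=self.labels).fillna(0).astype(int)


@dataclass
class StageSummary:
    """Replicate-averaged methylation for one developmental stage."""

    stage: str
    gene_region: pd.DataFrame       # genes x labels, mean over replicates
    n_cpg: pd.DataFrame             # genes x labels, summed over replicates
    global_means: pd.Series         # per label, unweighted mean over genes
    chrom_means: Optional[pd.DataFrame] = None  # chrom x labels


def _interval_means(
    calls: pd.DataFrame, anno: pd.DataFrame
) -> pd.DataFrame:
    """Per (gene, label) sums/counts of call levels over annotation intervals.

    Uses binary search on the position-sorted calls of each chromosome with
    a prefix-sum of levels, so each interval costs O(log n).
    """
    pieces = []
    for chrom, grp in anno.groupby("chrom", sort=False):
        sub = calls[calls["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        lev = sub["meth_level"].to_numpy()[order]
        cum = np.concatenate([[0.0], np.cumsum(lev)])
        i = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        j = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
        pieces.append(pd.DataFrame({
            "gene_id": grp["gene_id"].to_numpy(),
            "label": grp["label"].to_numpy(),
            "sum": cum[j] - cum[i],
            "n": j - i,
        }))
    if not pieces:
        return pd.DataFrame(columns=["gene_id", "label", "sum", "n"])
    merged = pd.concat(pieces, ignore_index=True)
    return merged.groupby(["gene_id", "label"], sort=False, as_index=False).agg(
        sum=("sum", "sum"), n=("n", "sum"))


def region_methylation(
    calls: Mapping[str, pd.DataFrame],
    anno: pd.DataFrame,
) -> MethylationMatrix:
    """Mean methylation per (gene, region-or-bin, sample).

    ``calls`` maps sample_id -> coverage-filtered call frame (chrom, pos,
    meth_level, coverage); ``anno`` is a long interval table from
    :func:`methregions.annotation.regions_frame` or ``bins_frame``.  Every
    (gene, label) pair of the annotation appears for every sample; cells
    with no covered CpG are NaN with n_cpg 0.
    """
    pairs = anno[["gene_id", "label"]].drop_duplicates()
    # labels in first-seen annotation order (region order / bin order)
    labels = list(dict.fromkeys(anno["label"]))
    grid = pd.MultiIndex.from_frame(pairs)
    frames = []
    for sample_id, df in calls.items():
        stats = _interval_means(df, anno)
        stats = stats.set_index(["gene_id", "label"]).reindex(grid, fill_value=0)
        n = stats["n"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            meth = np.where(n > 0, stats["sum"].to_numpy() / np.where(n > 0, n, 1), np.nan)
        frames.append(pd.DataFrame({
            "gene_id": pairs["gene_id"].to_numpy(),
            "label": pairs["label"].to_numpy(),
            "sample_id": sample_id,
            "meth": meth,
            "n_cpg": n.astype(int),
        }))
    data = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["gene_id", "label", "sample_id", "meth", "n_cpg"]))
    return MethylationMatrix(data=data, labels=labels, sample_ids=list(calls.keys()))


def stage_average(
    m: MethylationMatrix,
    manifest: SampleManifest,
    gene_chrom: Optional[Mapping[str, str]] = None,
) -> dict[str, StageSummary]:
    """Replicate-averaged stage summaries, one per manifest stage.

    A stage value for a (gene, label) cell is the arithmetic mean over the
    replicates with a non-missing value there; the genome-level value is
    the unweighted mean over genes.  Per-chromosome means are added when a
    gene -> chromosome mapping is supplied.
    """
    out: dict[str, StageSummary] = {}
    for stage in manifest.stages:
        ids = [s.sample_id for s in manifest.samples_of(stage)]
        if not ids:
            raise ValueError(f"stage {stage!r} has no samples")
        mats = [m.matrix(i) for i in ids]
        ncs = [m.ncpg_matrix(i) for i in ids]
        stacked = pd.concat(mats, keys=ids)
        gene_region = stacked.groupby(level=1, sort=True).mean()
        n_cpg = pd.concat(ncs, keys=ids).groupby(level=1, sort=True).sum()
        global_means = gene_region.mean(axis=0)
        chrom_means = None
        if gene_chrom is not None:
            chroms = pd.Series({g: gene_chrom.get(g) for g in gene_region.index})
            chrom_means = gene_region.groupby(chroms).mean()
        out[stage] = StageSummary(
            stage=stage, gene_region=gene_region, n_cpg=n_cpg,
            global_means=global_means, chrom_means=chrom_means,
        )
    return out


def gene_level(m: MethylationMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Whole-gene methylation per sample: CpG-pooled mean over all labels.

    Pools every CpG contributing to any of the gene's regions (CpG-weighted
    across labels), which equals the mean over the gene's covered CpGs when
    the labels partition the neighbourhood.  Returns (values, n_cpg) frames
    of shape genes x samples.
    """
    d = m.data.copy()
    d["wsum"] = d["meth"].fillna(0.0) * d["n_cpg"]
    g = d.groupby(["gene_id", "sample_id"], sort=True).agg(
        wsum=("wsum", "sum"), n=("n_cpg", "sum"))
    with np.errstate(invalid="ignore"):
        g["meth"] = np.where(g["n"] > 0, g["wsum"] / g["n"].where(g["n"] > 0, 1), np.nan)
    values = g["meth"].unstack("sample_id").reindex(columns=m.sample_ids)
    n = g["n"].unstack("sample_id").reindex(columns=m.sample_ids).fillna(0).astype(int)
    return values, n


def stage_mean_frame(
    values: pd.DataFrame, manifest: SampleManifest
) -> pd.DataFrame:
    """Average genes x samples values into genes x stages (ignoring NaN)."""
    stage_of = {s.sample_id: s.stage for s in manifest.samples}
    grouped = values.T.groupby(values.columns.map(stage_of)).mean().T
    return grouped.reindex(columns=manifest.stages)


def methylated_bin_counts(
    values: pd.DataFrame,
    n_cpg: Optional[pd.DataFrame] = None,
    eps: float = 0.0,
) -> pd.DataFrame:
    """Per-bin count of genes with a methylated bin, plus their mean level.

    A gene's bin is methylated when it has at least one covered CpG and a
    methylation level above ``eps`` (default 0).  ``values`` is a genes x
    bins frame (NaN = no covered CpG); the mean is taken over the counted
    (methylated) bins only.
    """
    methylated = values.notna() & (values > eps)
    counts = methylated.sum(axis=0)
    means = values.where(methylated).mean(axis=0)
    return pd.DataFrame({"n_methylated": counts.astype(int), "mean_meth": means})
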
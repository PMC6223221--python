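"""CpG counts per promoter bin and HCG/ICG/LCG density classes.

A 200 bp window is high-CpG (HCG) with more than 8 CpGs, low-CpG (LCG)
with fewer than 4, and intermediate (ICG) with 4-8 inclusive.  Counts are
of CpG dyads whose + strand C lies in the half-open window.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import PromoterBin

DENSITY_CLASSES = ("HCG", "ICG", "LCG")

#: Class boundaries: LCG for counts 0-3, ICG for 4-8, HCG for >= 9.
LCG_BELOW = 4
HCG_ABOVE = 8


def classify_density(cpg_count) -> str | np.ndarray:
    """HCG/ICG/LCG class of a 200 bp window from its CpG count.

    Accepts a scalar (returns a string) or an array (returns an array).
    """
    counts = np.asarray(cpg_count)
    if (counts < 0).any():
        raise ValueError("CpG count cannot be negative")
    classes = np.select(
        [counts > HCG_ABOVE, counts < LCG_BELOW], ["HCG", "LCG"], default="ICG"
    )
    if np.isscalar(cpg_count) or np.ndim(cpg_count) == 0:
        return str(classes[()])
    return classes


def count_bin_cpgs(
    bins: Iterable[PromoterBin],
    cpg_index: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """CpG count and density class for every promoter bin.

    ``cpg_index`` maps chromosome -> sorted array of CpG C positions (from
    :func:`methregions.methio.cpg_positions`).  Returns a frame with
    gene_id, bin_index, cpg_count, density_class.
    """
    rows = []
    sorted_cache: dict[str, np.ndarray] = {}
    for b in bins:
        chrom, start, end = b.interval
        pos = sorted_cache.get(chrom)
        if pos is None:
            pos = np.asarray(cpg_index.get(chrom, np.empty(0, dtype=np.int64)))
            sorted_cache[chrom] = pos
        n = int(np.searchsorted(pos, end, side="left")
                - np.searchsorted(pos, start, side="left"))
        rows.append((b.gene_id, b.bin_index, n))
    df = pd.DataFrame(rows, columns=["gene_id", "bin_index", "cpg_count"])
    df["density_class"] = classify_density(df["cpg_count"].to_numpy()) if len(df) else []
    return df


def bin_profile(density: pd.DataFrame) -> pd.DataFrame:
    """Mean CpG count per bin index across genes (metagene density profile)."""
    prof = density.groupby("bin_index")["cpg_count"].agg(["mean", "sum", "count"])
    return prof.rename(columns={"mean": "mean_cpg", "sum": "total_cpg", "count": "n_genes"})


def promoter_class(
    density: pd.DataFrame, rule: str = "max"
) -> pd.Series:
    """Roll a gene's 20 per-bin classes up to one promoter-level class.

    ``rule='max'`` classifies the per-gene maximum bin count (a promoter is
    as CpG-rich as its densest window); ``rule='mean'`` classifies the mean
    count per bin.
    """
    if rule == "max":
        stat = density.groupby("gene_id")["cpg_count"].max()
    elif rule == "mean":
        stat = density.groupby("gene_id")["cpg_count"].mean()
    else:
        raise ValueError(f"unknown promoter roll-up rule {rule!r}")
    return pd.Series(classify_density(stat.to_numpy()), index=stat.index, name="density_class")
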
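"""Methylation-expression integration: log2 RPKM, Pearson r, bin PCA.

Expression is log2-transformed after the zero-reset rule: RPKM values of
exactly 0 are replaced by the minimum non-zero RPKM (per sample by
default) so the logarithm is defined.  For every developmental stage and
every region or promoter bin, the Pearson correlation between stage-level
methylation and stage-level log2 expression is computed over the genes
with both values present.  A PCA over the bins x stages matrix of r values
summarises which promoter bins share a correlation profile.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

MIN_GENES_FOR_R = 3


def log_expression(rpkm: pd.DataFrame, zero_reset: str = "sample") -> pd.DataFrame:
    """log2 of a genes x samples RPKM table with zero-reset.

    ``zero_reset='sample'`` replaces zeros with each sample's minimum
    non-zero RPKM; ``'global'`` uses the table-wide minimum.  Negative
    RPKM, or a sample with no non-zero value, is an error.
    """
    if (rpkm < 0).any().any():
        raise ValueError("RPKM values must be non-negative")
    out = rpkm.astype(float).copy()
    if zero_reset == "sample":
        for col in out.columns:
            nonzero = out[col][out[col] > 0]
            if nonzero.empty:
                raise ValueError(f"sample {col!r} has no non-zero RPKM")
            out.loc[out[col] == 0, col] = nonzero.min()
    elif zero_reset == "global":
        nonzero = out.to_numpy()[out.to_numpy() > 0]
        if nonzero.size == 0:
            raise ValueError("expression table has no non-zero RPKM")
        out = out.mask(out == 0, nonzero.min())
    else:
        raise ValueError(f"unknown zero_reset mode {zero_reset!r}")
    return np.log2(out)


def stage_correlation(
    meth: pd.DataFrame, expr: pd.Series, stage: str = ""
) -> pd.DataFrame:
    """Pearson r between methylation and expression for each label.

    ``meth`` is a genes x labels stage-level matrix and ``expr`` a
    per-gene stage-level log2 expression series.  For each label, r is
    computed over pairwise-complete genes; it is missing when fewer than
    three genes remain or either vector is constant, and results with
    n < 3 are flagged unreliable.
    """
    expr = expr.reindex(meth.index)
    rows = []
    for label in meth.columns:
        x = meth[label]
        mask = x.notna() & expr.notna()
        n = int(mask.sum())
        r = np.nan
        if n >= MIN_GENES_FOR_R:
            xv = x[mask].to_numpy(dtype=float)
            yv = expr[mask].to_numpy(dtype=float)
            if np.ptp(xv) > 0 and np.ptp(yv) > 0:
                r = float(stats.pearsonr(xv, yv).statistic)
        rows.append((stage, label, r, n, n >= MIN_GENES_FOR_R))
    return pd.DataFrame(rows, columns=["stage", "label", "r", "n", "reliable"])


def correlation_table(
    stage_meth: Mapping[str, pd.DataFrame],
    stage_expr: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(stage, label) correlations for every stage in ``stage_meth``.

    ``stage_expr`` is a genes x stages log2 expression frame.
    """
    parts = [
        stage_correlation(meth, stage_expr[stage], stage=stage)
        for stage, meth in stage_meth.items()
    ]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["stage", "label", "r", "n", "reliable"])


def bin_pca(r_matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal components of the bins x stages r matrix.

    Rows are promoter bins (observations), columns are stages (features);
    features are centred, not scaled, since r values are already
    commensurate.  The sign of each component is fixed by making its
    largest-magnitude loading positive, so results are deterministic.
    Missing cells are an error: impute or drop bins first.
    """
    if r_matrix.isna().any().any():
        raise ValueError(
            "r matrix has missing cells; impute (e.g. stage mean) or drop "
            "incomplete bins before PCA"
        )
    from sklearn.decomposition import PCA

    n_comp = min(2, min(r_matrix.shape))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(r_matrix.to_numpy(dtype=float))
    for k in range(n_comp):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, k] *= -1
            pca.components_[k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_comp)]
    return (
        pd.DataFrame(scores, index=r_matrix.index, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )
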
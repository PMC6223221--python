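"""Differential-gene selection at promoter bin 1 between two stages.

A gene is selected when all four filters pass:

(i)   its bin-1 methylation decreased more than ``fold_change_min``-fold
      from stage A to stage B (replicate means; direction configurable);
(ii)  a Welch two-sample t-test over the replicate values gives
      p < ``p_max``;
(iii) its stage-A bin-1 level exceeds the cohort mean at stage A;
(iv)  its expression increased from stage A to stage B.

The default ``p_max`` of 0.5 is deliberately permissive (the fold-change
criterion dominates selection); pass 0.05 for a conventional test.  The
selected identifiers can be written one per line for external
GO-enrichment tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DiffFilterConfig:
    fold_change_min: Optional[float] = 2.0   # None disables the fold filter
    p_max: float = 0.5
    require_above_mean: bool = True
    require_expression_increase: bool = True
    direction: str = "decrease"              # methylation A -> B
    untestable_policy: str = "fail"          # t-test impossible: "pass"/"fail"

    def __post_init__(self) -> None:
        if self.fold_change_min is not None and not self.fold_change_min > 1:
            raise ValueError("fold_change_min must exceed 1 (or be None)")
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must lie in (0, 1]")
        if self.direction not in ("decrease", "increase"):
            raise ValueError("direction must be 'decrease' or 'increase'")
        if self.untestable_policy not in ("pass", "fail"):
            raise ValueError("untestable_policy must be 'pass' or 'fail'")


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def select_diff_genes(
    meth_a: pd.DataFrame,
    meth_b: pd.DataFrame,
    expr_a: pd.Series,
    expr_b: pd.Series,
    cfg: DiffFilterConfig = DiffFilterConfig(),
) -> pd.DataFrame:
    """Apply the four bin-1 filters gene by gene.

    ``meth_a``/``meth_b`` are genes x replicates bin-1 methylation at the
    two stages (NaN = replicate missing); ``expr_a``/``expr_b`` are
    stage-level expression values.  Returns one row per gene with the
    replicate means, fold change, p-value, four boolean filter flags, an
    ``untestable`` flag (fewer than 2 replicates in either stage) and the
    overall ``selected`` verdict.
    """
    genes = meth_a.index.union(meth_b.index).union(expr_a.index).union(expr_b.index)
    meth_a = meth_a.reindex(genes)
    meth_b = meth_b.reindex(genes)
    expr_a = expr_a.reindex(genes)
    expr_b = expr_b.reindex(genes)

    mean_a = meth_a.mean(axis=1)
    mean_b = meth_b.mean(axis=1)
    cohort_mean_a = mean_a.mean()

    rows = []
    for gene in genes:
        ma, mb = mean_a[gene], mean_b[gene]
        a = meth_a.loc[gene].dropna().to_numpy(dtype=float)
        b = meth_b.loc[gene].dropna().to_numpy(dtype=float)
        complete = (len(a) >= 1 and len(b) >= 1
                    and pd.notna(expr_a[gene]) and pd.notna(expr_b[gene]))

        if cfg.direction == "decrease":
            hi, lo = ma, mb
        else:
            hi, lo = mb, ma
        if cfg.fold_change_min is None:
            fold_ok = complete
            fold = np.nan
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                fold = hi / lo if lo > 0 else (np.inf if hi > 0 else np.nan)
            fold_ok = bool(complete and pd.notna(fold) and fold > cfg.fold_change_min and hi > lo)

        untestable = len(a) < 2 or len(b) < 2
        if untestable:
            p = np.nan
            p_ok = complete and cfg.untestable_policy == "pass"
        else:
            p = _welch_p(a, b)
            p_ok = bool(p < cfg.p_max)

        above_mean = bool(complete and pd.notna(ma) and ma > cohort_mean_a) \
            if cfg.require_above_mean else complete
        expr_up = bool(complete and expr_b[gene] > expr_a[gene]) \
            if cfg.require_expression_increase else complete

        rows.append({
            "gene_id": gene,
            "mean_a": ma, "mean_b": mb,
            "fold_change": fold, "p_value": p,
            "pass_fold": fold_ok, "pass_ttest": p_ok,
            "pass_above_mean": above_mean, "pass_expression": expr_up,
            "untestable": untestable,
            "selected": bool(fold_ok and p_ok and above_mean and expr_up),
        })
    return pd.DataFrame(rows).set_index("gene_id")


def write_gene_list(result: pd.DataFrame, path: str | Path) -> int:
    """Write selected gene ids one per line (for external GO tools)."""
    selected = result.index[result["selected"]].tolist()
    with open(path, "w") as fh:
        for gene in selected:
            fh.write(f"{gene}\n")
    return len(selected)
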
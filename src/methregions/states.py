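"""Hypo/moderate/hyper methylation states and stage-to-stage transitions.

A gene (or one of its regions) is hypo-methylated when its mean methylation
fraction is at or below ``hypo_max``, hyper-methylated at or above
``hyper_min``, and moderately methylated in between.  Both boundaries are
inclusive.  No consensus thresholds exist for whole-gene WGBS levels; the
defaults (0.3, 0.7) are conventional cut-offs and are always echoed into
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATES = ("hypo", "moderate", "hyper")


@dataclass(frozen=True)
class StateThresholds:
    hypo_max: float = 0.3
    hyper_min: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 <= self.hypo_max < self.hyper_min <= 1.0):
            raise ValueError(
                f"need 0 <= hypo_max < hyper_min <= 1, got "
                f"({self.hypo_max}, {self.hyper_min})"
            )


def classify_states(
    values: pd.Series, thresholds: StateThresholds = StateThresholds()
) -> pd.Series:
    """Discretise per-gene methylation fractions into the three states.

    Missing values stay missing (unclassified).  Values outside [0, 1]
    raise, since they cannot be methylation fractions.
    """
    v = values.astype(float)
    finite = v.dropna()
    if ((finite < 0) | (finite > 1)).any():
        raise ValueError("methylation values must lie in [0, 1]")
    out = pd.Series(
        np.select(
            [v <= thresholds.hypo_max, v >= thresholds.hyper_min],
            ["hypo", "hyper"],
            default="moderate",
        ),
        index=values.index,
        dtype="object",
    )
    out[v.isna()] = np.nan
    return out


@dataclass
class TransitionCounts:
    """3x3 gene counts over state pairs between two stages."""

    stage_from: str
    stage_to: str
    counts: pd.DataFrame  # index = state at stage_from, columns = state at stage_to
    n_excluded: int       # genes unclassified in either stage

    @property
    def hypo_to_hyper(self) -> int:
        return int(self.counts.loc["hypo", "hyper"])

    @property
    def hyper_to_hypo(self) -> int:
        return int(self.counts.loc["hyper", "hypo"])

    @property
    def maintained_hypo(self) -> int:
        return int(self.counts.loc["hypo", "hypo"])

    @property
    def n_classified(self) -> int:
        return int(self.counts.to_numpy().sum())


def transitions(
    states_a: pd.Series,
    states_b: pd.Series,
    stage_from: str = "A",
    stage_to: str = "B",
) -> TransitionCounts:
    """Count state transitions over the genes classified at both stages.

    Genes unclassified (missing) in either stage are excluded and reported
    in ``n_excluded``.  The two inputs must share at least one gene.
    """
    common = states_a.index.intersection(states_b.index)
    if len(common) == 0:
        raise ValueError("state series share no genes")
    a = states_a.loc[common]
    b = states_b.loc[common]
    both = a.notna() & b.notna()
    n_excluded = int((~both).sum())
    tab = pd.crosstab(a[both], b[both])
    counts = tab.reindex(index=STATES, columns=STATES, fill_value=0).astype(int)
    counts.index.name = stage_from
    counts.columns.name = stage_to
    return TransitionCounts(
        stage_from=stage_from, stage_to=stage_to,
        counts=counts, n_excluded=n_excluded,
    )
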
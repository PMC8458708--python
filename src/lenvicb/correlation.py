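"""Gene-gene correlation between the ICB and lenvatinib target arms.

Pearson correlations are computed on log2(x+1) expression over tumor
samples only, giving an 11 x 4 matrix (lenvatinib targets x ICB targets)
per cancer.  A cancer's co-expression evidence is summarised as the number
of pairs with r >= 0.1 (inclusive; at most 44); pairs with r >= 0.15 are
additionally recorded as "strong".  Ranking cancers by that count and
splitting at the upper half yields the high/low correlation groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .panel import TargetPanel

POSITIVE_R = 0.1
STRONG_R = 0.15


@dataclass
class CorrelationMatrix:
    """Pearson r for every (lenvatinib gene, ICB gene) pair in one cancer."""

    cancer_type: str
    rows: list[str]  # lenvatinib targets
    cols: list[str]  # icb targets
    r: np.ndarray  # shape (len(rows), len(cols)), NaN where a gene is constant
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.rows, columns=self.cols)


@dataclass(frozen=True)
class CorrelationSummary:
    """Counting summary of one cancer's correlation matrix."""

    cancer_type: str
    positive_pair_count: int  # pairs with r >= POSITIVE_R
    strong_pairs: tuple[tuple[str, str], ...] = ()
    group: str = ""  # 'high' | 'low', set by rank_cancers_by_correlation


def pairwise_correlation(matrix: ExpressionMatrix, panel: TargetPanel) -> CorrelationMatrix:
    """Pearson r on log2(x+1) tumor-sample expression for all cross-arm pairs.

    Requires >= 3 tumor samples.  Constant genes produce NaN cells (with a
    warning); NaN cells are excluded from all downstream counting.
    """
    tmask = matrix.tumor_mask()
    if int(tmask.sum()) < 3:
        raise ValueError(f"{matrix.cancer_type}: need >=3 tumor samples, have {int(tmask.sum())}")
    logv = matrix.log_values()[:, tmask]
    idx = {g: i for i, g in enumerate(matrix.genes)}
    rows = sorted(g for g in panel.lenvatinib_targets if g in idx)
    cols = sorted(g for g in panel.icb_targets if g in idx)
    if not rows or not cols:
        raise ValueError(f"{matrix.cancer_type}: both gene arms must be present")
    r = np.full((len(rows), len(cols)), np.nan)
    constant = {g for g in rows + cols if np.std(logv[idx[g]]) == 0.0}
    if constant:
        warnings.warn(
            f"{matrix.cancer_type}: constant gene(s) {sorted(constant)}, r set to NaN",
            stacklevel=2,
        )
    for i, g1 in enumerate(rows):
        for j, g2 in enumerate(cols):
            if g1 in constant or g2 in constant:
                continue
            r[i, j] = stats.pearsonr(logv[idx[g1]], logv[idx[g2]]).statistic
    return CorrelationMatrix(matrix.cancer_type, rows, cols, r, int(tmask.sum()))


def count_positive_pairs(cm: CorrelationMatrix, threshold: float = POSITIVE_R) -> int:
    """Number of non-NaN pairs with r >= threshold (inclusive boundary)."""
    with np.errstate(invalid="ignore"):
        return int(np.nansum(cm.r >= threshold))


def summarize_correlation(
    cm: CorrelationMatrix,
    positive_threshold: float = POSITIVE_R,
    strong_threshold: float = STRONG_R,
) -> CorrelationSummary:
    strong = tuple(
        (cm.rows[i], cm.cols[j])
        for i in range(len(cm.rows))
        for j in range(len(cm.cols))
        if not math.isnan(cm.r[i, j]) and cm.r[i, j] >= strong_threshold
    )
    return CorrelationSummary(
        cancer_type=cm.cancer_type,
        positive_pair_count=count_positive_pairs(cm, positive_threshold),
        strong_pairs=strong,
    )


def rank_cancers_by_correlation(summaries: list[CorrelationSummary]) -> list[CorrelationSummary]:
    """Sort by positive-pair count (desc, code-alphabetical tie-break); top half is 'high'.

    The high group holds ceil(k/2) cancers.
    """
    if not summaries:
        raise ValueError("no correlation summaries to rank")
    ordered = sorted(summaries, key=lambda s: (-s.positive_pair_count, s.cancer_type))
    n_high = math.ceil(len(ordered) / 2)
    return [
        CorrelationSummary(s.cancer_type, s.positive_pair_count, s.strong_pairs,
                           "high" if i < n_high else "low")
        for i, s in enumerate(ordered)
    ]


def pan_cancer_correlation(
    matrices: list[ExpressionMatrix], panel: TargetPanel, mode: str = "pooled"
) -> CorrelationMatrix:
    """Pan-cancer 11 x 4 matrix: 'pooled' concatenates tumor samples across
    cancers before correlating; 'mean_r' averages per-cancer r cell-wise."""
    if not matrices:
        raise ValueError("no expression matrices supplied")
    if mode == "pooled":
        genes = matrices[0].genes
        for m in matrices[1:]:
            if m.genes != genes:
                raise ValueError("pooled mode requires identical gene ordering")
        values = np.concatenate([m.values for m in matrices], axis=1)
        merged = ExpressionMatrix(
            cancer_type="PANCAN",
            genes=list(genes),
            samples=[f"{m.cancer_type}:{s}" for m in matrices for s in m.samples],
            values=values,
            condition=[c for m in matrices for c in m.condition],
        )
        return pairwise_correlation(merged, panel)
    if mode == "mean_r":
        cms = [pairwise_correlation(m, panel) for m in matrices]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.nanmean(np.stack([cm.r for cm in cms]), axis=0)
        return CorrelationMatrix("PANCAN", cms[0].rows, cms[0].cols, r,
                                 sum(cm.n_samples for cm in cms))
    raise ValueError(f"unknown pan-cancer mode {mode!r}")
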
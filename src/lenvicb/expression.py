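"""Tumor-vs-normal differential expression of the target genes, per cancer.

A cancer is called *high* when at least 4 lenvatinib targets and at least
2 ICB targets are significantly up-regulated in tumor relative to normal
tissue; *moderate* when exactly one of those two conditions holds; *low*
when no target of either arm is up; anything else is *unclassified* (the
three named categories do not partition all outcomes).

The per-gene test is a two-sided Welch t-test on log2(x+1) expression
(portal-style tumor/normal comparisons); "up" requires tumor mean > normal
mean on the log scale, and "significantly up" additionally p < alpha.
No multiple-testing correction is applied across the 15 genes — the
counting rules are defined on per-gene nominal p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import TargetPanel

LENV_UP_MIN = 4  # lenvatinib targets up-regulated for a "high" call
ICB_UP_MIN = 2  # ICB targets up-regulated for a "high" call


@dataclass
class ExpressionMatrix:
    """Genes x samples expression for one cancer with tumor/normal labels.

    ``values`` are non-negative TPM-like units (pre-normalised); tests run
    on log2(x+1).
    """

    cancer_type: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (genes, samples)
    condition: list[str]  # per-sample, 'tumor' | 'normal'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != ({len(self.genes)}, {len(self.samples)})"
            )
        if len(self.condition) != len(self.samples):
            raise ValueError("condition must label every sample")
        bad = set(self.condition) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("expression values must be finite and >= 0")

    def tumor_mask(self) -> np.ndarray:
        return np.array([c == "tumor" for c in self.condition])

    def log_values(self) -> np.ndarray:
        return np.log2(self.values + 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass(frozen=True)
class DEResult:
    """One gene's tumor-vs-normal comparison."""

    gene: str
    mean_log_tumor: float
    mean_log_normal: float
    p_value: float
    up: bool
    significant_up: bool
    testable: bool = True


@dataclass(frozen=True)
class ExpressionCategory:
    """Per-cancer counts of up-regulated targets and the derived category."""

    cancer_type: str
    lenv_up_count: int
    icb_up_count: int
    category: str  # high | moderate | low | unclassified


def differential_expression(matrix: ExpressionMatrix, alpha: float = 0.05) -> list[DEResult]:
    """Welch t-test per gene on log2(x+1), tumor vs normal.

    Genes with fewer than two samples in either condition are flagged
    untestable and excluded from downstream counts.  Zero-variance ties in
    both arms yield p = 1 by convention (never significant).
    """
    logv = matrix.log_values()
    tmask = matrix.tumor_mask()
    n_t, n_n = int(tmask.sum()), int((~tmask).sum())
    results: list[DEResult] = []
    for i, gene in enumerate(matrix.genes):
        tum, nor = logv[i, tmask], logv[i, ~tmask]
        if n_t < 2 or n_n < 2:
            warnings.warn(
                f"{matrix.cancer_type}/{gene}: <2 samples in a condition, untestable",
                stacklevel=2,
            )
            results.append(DEResult(gene, float("nan"), float("nan"), 1.0, False, False, False))
            continue
        mt, mn = float(tum.mean()), float(nor.mean())
        if tum.std() == 0.0 and nor.std() == 0.0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(tum, nor, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        up = mt > mn
        results.append(DEResult(gene, mt, mn, p, up, up and p < alpha))
    return results


def classify_expression(
    results: list[DEResult], panel: TargetPanel, cancer_type: str | None = None
) -> ExpressionCategory:
    """Count significantly up-regulated targets per arm and apply the category rule.

    high: lenv_up >= 4 and icb_up >= 2; moderate: exactly one of the two;
    low: no up-regulated target in either arm; otherwise unclassified.
    """
    lenv_up = sum(
        1
        for r in results
        if r.testable and r.significant_up and r.gene in panel.lenvatinib_targets
    )
    icb_up = sum(
        1 for r in results if r.testable and r.significant_up and r.gene in panel.icb_targets
    )
    lenv_hit, icb_hit = lenv_up >= LENV_UP_MIN, icb_up >= ICB_UP_MIN
    if lenv_hit and icb_hit:
        category = "high"
    elif lenv_hit or icb_hit:
        category = "moderate"
    elif lenv_up == 0 and icb_up == 0:
        category = "low"
    else:
        category = "unclassified"
    return ExpressionCategory(cancer_type or "", lenv_up, icb_up, category)


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """DE results as a tidy DataFrame (one row per gene)."""
    return pd.DataFrame([r.__dict__ for r in results])
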
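"""Target-gene vs immune-infiltration correlations and survival risk calls.

Two box rules flag a cancer's immune microenvironment with respect to the
11 lenvatinib targets:

- CD8 depletion: >= 8 of the 11 gene-vs-CD8_T correlations are negative
  AND >= 5 of them are <= -0.15;
- suppressive-cell enrichment (Treg / M2 macrophage / MDSC): >= 8 positive
  AND >= 5 with r >= 0.15.

Correlations are Spearman (immune-deconvolution-portal convention); when
per-sample tumor purity is available a partial Spearman is used: both
variables are rank-transformed, regressed on purity ranks, and the
residuals are Pearson-correlated.

Prognostic calls classify an infiltrate (or gene) as a risk or protective
factor from a univariate Cox proportional-hazards fit (Efron ties, via
lifelines) on the standardized covariate: risk iff p < 0.05 and z > 0,
protective iff p < 0.05 and z < 0, else neutral.  A Kaplan-Meier log-rank
comparison at the covariate median is provided alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .expression import ExpressionMatrix
from .panel import TargetPanel

NEG_COUNT_MIN = 8  # negative (or positive) correlations required
STRONG_COUNT_MIN = 5  # of which beyond +/-0.15 ("more than four")
STRONG_R = 0.15
SUPPRESSIVE_CELLS = ("Treg", "M2_macrophage", "MDSC")


@dataclass
class InfiltrationTable:
    """Per-sample immune-cell fractions (scores >= 0) with optional tumor purity."""

    cancer_type: str
    samples: list[str]
    cell_types: list[str]
    values: np.ndarray  # shape (samples, cell_types)
    purity: np.ndarray | None = None  # per-sample, in [0,1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.cell_types)):
            raise ValueError("infiltration values shape mismatch")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("cell fractions must be finite and >= 0")
        if self.purity is not None:
            self.purity = np.asarray(self.purity, dtype=float)
            if self.purity.shape != (len(self.samples),):
                raise ValueError("purity must be per-sample")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.samples, columns=self.cell_types)
        if self.purity is not None:
            df["purity"] = self.purity
        return df


@dataclass(frozen=True)
class GeneCellCorrelation:
    gene: str
    cell_type: str
    r: float
    n: int


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time, event indicator (1 death / 0 censored), covariate."""

    sample_id: str
    time: float
    event: int
    covariate: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.sample_id}: negative time")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0 or 1")


@dataclass(frozen=True)
class PrognosticCall:
    cancer_type: str
    cell_type: str
    z: float
    p: float
    call: str  # risk | protective | neutral


def _partial_spearman(x: np.ndarray, y: np.ndarray, purity: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rp = stats.rankdata(purity)
    def resid(v):
        A = np.column_stack([np.ones_like(rp), rp])
        beta, *_ = np.linalg.lstsq(A, v, rcond=None)
        return v - A @ beta
    ex, ey = resid(rx), resid(ry)
    if np.std(ex) == 0.0 or np.std(ey) == 0.0:
        return float("nan")
    return float(stats.pearsonr(ex, ey).statistic)


def gene_infiltration_correlation(
    expr: ExpressionMatrix,
    infil: InfiltrationTable,
    panel: TargetPanel,
    method: str = "spearman",
) -> list[GeneCellCorrelation]:
    """Correlate each lenvatinib-target gene with each cell type over shared tumor samples.

    Spearman by default (``method='pearson'`` available); partial Spearman
    adjusting for purity when the infiltration table carries it.  Requires
    >= 3 shared tumor samples; constant vectors yield NaN with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    tmask = expr.tumor_mask()
    tumor_samples = [s for s, m in zip(expr.samples, tmask) if m]
    shared = [s for s in tumor_samples if s in infil.samples]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared tumor samples, have {len(shared)}")
    ei = {s: i for i, s in enumerate(expr.samples)}
    ii = {s: i for i, s in enumerate(infil.samples)}
    logv = expr.log_values()
    gidx = {g: k for k, g in enumerate(expr.genes)}
    purity = (
        np.array([infil.purity[ii[s]] for s in shared]) if infil.purity is not None else None
    )
    out: list[GeneCellCorrelation] = []
    for gene in sorted(g for g in panel.lenvatinib_targets if g in gidx):
        x = np.array([logv[gidx[gene], ei[s]] for s in shared])
        for j, cell in enumerate(infil.cell_types):
            y = np.array([infil.values[ii[s], j] for s in shared])
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                warnings.warn(f"constant vector for ({gene}, {cell}), r=NaN", stacklevel=2)
                r = float("nan")
            elif purity is not None and method == "spearman":
                r = _partial_spearman(x, y, purity)
            elif method == "spearman":
                r = float(stats.spearmanr(x, y).statistic)
            else:
                r = float(stats.pearsonr(x, y).statistic)
            out.append(GeneCellCorrelation(gene, cell, r, len(shared)))
    return out


def _box_flag(corrs: list[float], direction: int) -> bool:
    rs = [r for r in corrs if not np.isnan(r)]
    if direction < 0:
        n_signed = sum(1 for r in rs if r < 0)
        n_strong = sum(1 for r in rs if r <= -STRONG_R)
    else:
        n_signed = sum(1 for r in rs if r > 0)
        n_strong = sum(1 for r in rs if r >= STRONG_R)
    return n_signed >= NEG_COUNT_MIN and n_strong >= STRONG_COUNT_MIN


def cd8_box_flag(corrs: list[float]) -> bool:
    """CD8+ T-cell depletion rule: >=8 negative correlations, >=5 of them <= -0.15."""
    return _box_flag(corrs, direction=-1)


def suppressive_box_flag(corrs: list[float]) -> bool:
    """Suppressive-cell enrichment rule: >=8 positive correlations, >=5 of them >= 0.15."""
    return _box_flag(corrs, direction=+1)


def cox_classify(
    records: list[SurvivalRecord], cancer_type: str = "", cell_type: str = ""
) -> PrognosticCall:
    """Univariate Cox PH fit on the standardized covariate; risk/protective/neutral call.

    Requires >= 10 subjects and >= 1 event; degenerate inputs or
    non-convergence yield a neutral call with a warning.
    """
    if len(records) < 10:
        raise ValueError(f"need >=10 survival records, have {len(records)}")
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "covariate": [r.covariate for r in records],
        }
    )
    sd = df["covariate"].std()
    if df["event"].sum() == 0 or sd == 0.0 or not np.isfinite(sd):
        warnings.warn(f"{cancer_type}/{cell_type}: no events or constant covariate", stacklevel=2)
        return PrognosticCall(cancer_type, cell_type, 0.0, 1.0, "neutral")
    df["covariate"] = (df["covariate"] - df["covariate"].mean()) / sd
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        z = float(cph.summary.loc["covariate", "z"])
        p = float(cph.summary.loc["covariate", "p"])
    except Exception as exc:  # non-convergence
        warnings.warn(f"{cancer_type}/{cell_type}: Cox fit failed ({exc})", stacklevel=2)
        return PrognosticCall(cancer_type, cell_type, 0.0, 1.0, "neutral")
    if p < 0.05 and z > 0:
        call = "risk"
    elif p < 0.05 and z < 0:
        call = "protective"
    else:
        call = "neutral"
    return PrognosticCall(cancer_type, cell_type, z, p, call)


def km_logrank(
    records: list[SurvivalRecord], split_quantile: float = 0.5
) -> tuple[float, float, dict[str, float]]:
    """Two-group log-rank test after a covariate quantile split (default median).

    Ties at the split go to the high group.  Returns (chi-square, p,
    per-group median survival).  All-equal covariates are a degenerate
    split and an error.
    """
    cov = np.array([r.covariate for r in records], dtype=float)
    cut = float(np.quantile(cov, split_quantile))
    high = cov >= cut
    if high.all() or (~high).all():
        raise ValueError("degenerate split: all subjects on one side of the cut")
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records])
    res = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
    medians: dict[str, float] = {}
    for name, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(t[mask], e[mask])
        medians[name] = float(km.median_survival_time_)
    return float(res.test_statistic), float(res.p_value), medians
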
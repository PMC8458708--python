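"""Meta-analysis of response proportions across trial cohorts.

Pools objective response rate (ORR) or disease control rate (DCR) over
single-arm cohorts of combination-therapy trials.  Published cohort tables
print percentages rather than event counts, so events are first
reconstructed by nearest-integer rounding of ``pct/100 * n``.

The pooling pipeline is the conventional one for meta-analysis of
proportions (the Stata ``metaprop`` default):

1. Freeman-Tukey double-arcsine variance-stabilising transform
   ``t = asin(sqrt(x/(n+1))) + asin(sqrt((x+1)/(n+1)))`` with within-study
   variance ``1/(n + 0.5)``;
2. inverse-variance fixed-effect pooling, Cochran's Q, I-squared, and the
   DerSimonian-Laird moment estimate of the between-study variance tau^2;
3. random-effects pooling with weights ``1/(v_i + tau^2)`` when I^2 > 50%
   (fixed-effect weights otherwise);
4. a 95% CI on the transformed scale (normal quantile 1.96) and the Miller
   inverse transform, evaluated at the harmonic mean of the study sizes,
   back to the proportion scale.

A logit transform is available as an alternative (``transform='logit'``).

The public surface is modelled on statsmodels: build a
:class:`ProportionMetaAnalysis` from records or a DataFrame, call
:meth:`~ProportionMetaAnalysis.fit`, and read estimates, heterogeneity
statistics, weights and forest-plot rows off the returned
:class:`MetaAnalysisResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "StudyRecord",
    "ArmOutcome",
    "TransformedEffect",
    "HeterogeneityStats",
    "MetaAnalysisResults",
    "ProportionMetaAnalysis",
    "reconstruct_events",
    "ft_transform",
    "ft_backtransform",
    "pool_fixed",
    "pool_random",
    "heterogeneity",
    "study_ci",
]


@dataclass(frozen=True)
class StudyRecord:
    """One trial cohort: the pooling unit (basket trials contribute one row per tumor type)."""

    study_id: str
    tumor_type: str
    n: int
    orr_pct: float | None
    dcr_pct: float | None = None
    phase: str | None = None
    line: str | None = None
    intervention: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.study_id}: n must be >= 1, got {self.n}")
        for name, pct in (("orr_pct", self.orr_pct), ("dcr_pct", self.dcr_pct)):
            if pct is not None and not 0.0 <= pct <= 100.0:
                raise ValueError(f"{self.study_id}: {name}={pct} outside [0, 100]")


@dataclass(frozen=True)
class ArmOutcome:
    """Reconstructed event count for one cohort."""

    events: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.events <= self.n:
            raise ValueError(f"events={self.events} outside [0, n={self.n}]")

    @property
    def proportion(self) -> float:
        return self.events / self.n


@dataclass(frozen=True)
class TransformedEffect:
    """A proportion on the transformed scale with its within-study variance."""

    t: float
    var: float


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q, its degrees of freedom, I-squared (%) and DerSimonian-Laird tau^2."""

    Q: float
    df: int
    I2: float
    tau2: float


def reconstruct_events(pct: float, n: int) -> ArmOutcome:
    """Reconstruct the event count from a printed percentage.

    Nearest integer, ties rounded half up (71.0% of 355 -> 252, not 253 by
    bankers' rounding of 252.05; 50% of 5 -> 2.5 -> 3).
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage {pct} outside [0, 100]")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    events = int(math.floor(pct / 100.0 * n + 0.5))
    return ArmOutcome(events=min(events, n), n=n)


def ft_transform(outcome: ArmOutcome) -> TransformedEffect:
    """Freeman-Tukey double-arcsine transform of an event proportion."""
    x, n = outcome.events, outcome.n
    t = math.asin(math.sqrt(x / (n + 1.0))) + math.asin(math.sqrt((x + 1.0) / (n + 1.0)))
    return TransformedEffect(t=t, var=1.0 / (n + 0.5))


def ft_backtransform(t_bar: float, n_bar: float) -> float:
    """Miller inverse of the double-arcsine transform at harmonic-mean size ``n_bar``.

    Clamped to [0, 1]; degenerate pooled values at or beyond the transform's
    range map to the boundary proportions.
    """
    if n_bar <= 0:
        raise ValueError(f"n_bar must be positive, got {n_bar}")
    if t_bar <= 0.0:
        return 0.0
    if t_bar >= math.pi:
        return 1.0
    s = math.sin(t_bar)
    inner = 1.0 - (s + (s - 1.0 / s) / n_bar) ** 2
    inner = max(inner, 0.0)
    p = 0.5 * (1.0 - math.copysign(1.0, math.cos(t_bar)) * math.sqrt(inner))
    return min(max(p, 0.0), 1.0)


def _logit_transform(outcome: ArmOutcome) -> TransformedEffect:
    # 0.5 continuity correction at the boundaries, the usual Wald-logit recipe
    x, n = outcome.events, outcome.n
    if x == 0 or x == n:
        x_, n_ = x + 0.5, n + 1.0
    else:
        x_, n_ = float(x), float(n)
    return TransformedEffect(t=math.log(x_ / (n_ - x_)), var=1.0 / x_ + 1.0 / (n_ - x_))


def pool_fixed(effects: list[TransformedEffect]) -> tuple[float, float]:
    """Inverse-variance fixed-effect pool; returns (pooled value, its variance)."""
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    w = np.array([1.0 / e.var for e in effects])
    t = np.array([e.t for e in effects])
    return float(np.sum(w * t) / np.sum(w)), float(1.0 / np.sum(w))


def pool_random(effects: list[TransformedEffect], tau2: float) -> tuple[float, float]:
    """Random-effects pool with weights 1/(v_i + tau^2)."""
    if tau2 < 0:
        raise ValueError(f"tau2 must be >= 0, got {tau2}")
    return pool_fixed([TransformedEffect(e.t, e.var + tau2) for e in effects])


def heterogeneity(effects: list[TransformedEffect]) -> HeterogeneityStats:
    """Cochran's Q, I^2 and the DerSimonian-Laird tau^2 (all truncated at zero)."""
    k = len(effects)
    if k < 2:
        return HeterogeneityStats(Q=0.0, df=0, I2=0.0, tau2=0.0)
    w = np.array([1.0 / e.var for e in effects])
    t = np.array([e.t for e in effects])
    t_bar = np.sum(w * t) / np.sum(w)
    Q = float(np.sum(w * (t - t_bar) ** 2))
    df = k - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityStats(Q=Q, df=df, I2=I2, tau2=tau2)


def study_ci(outcome: ArmOutcome, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval for one cohort (forest whiskers)."""
    alpha = 1.0 - level
    x, n = outcome.events, outcome.n
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


@dataclass(frozen=True)
class MetaAnalysisResults:
    """Pooled proportion with CI, model choice, heterogeneity and per-study weights."""

    endpoint: str
    k: int
    estimate: float
    ci_low: float
    ci_high: float
    model: str  # 'fixed' | 'random'
    het: HeterogeneityStats
    weights: np.ndarray  # normalized, sum to 1, input order
    study_ids: list[str] = field(default_factory=list)
    transform: str = "double_arcsine"
    t_bar: float = 0.0
    var_t_bar: float = 0.0
    outcomes: list[ArmOutcome] = field(default_factory=list)

    def summary(self) -> str:
        """A plain-text summary table in the style of a fitted-model report."""
        h = self.het
        lines = [
            f"Meta-analysis of proportions ({self.endpoint})",
            "=" * 46,
            f"cohorts (k)           {self.k:>10d}",
            f"model                 {self.model:>10s}",
            f"transform       {self.transform:>16s}",
            f"pooled proportion     {self.estimate:>10.3f}",
            f"95% CI           [{self.ci_low:.3f}, {self.ci_high:.3f}]",
            f"Q (df={h.df})             {h.Q:>10.2f}",
            f"I^2 (%)               {h.I2:>10.1f}",
            f"tau^2                 {h.tau2:>10.4f}",
        ]
        return "\n".join(lines)

    def forest_data(self) -> pd.DataFrame:
        """Per-study rows (proportion, exact CI, weight) plus a flagged pooled row."""
        rows = []
        for sid, out, w in zip(self.study_ids, self.outcomes, self.weights):
            lo, hi = study_ci(out)
            rows.append(
                {
                    "study_id": sid,
                    "proportion": out.proportion,
                    "ci_low": lo,
                    "ci_high": hi,
                    "weight": float(w),
                    "pooled": False,
                }
            )
        rows.append(
            {
                "study_id": f"pooled ({self.model})",
                "proportion": self.estimate,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "weight": 1.0,
                "pooled": True,
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        h = self.het
        return {
            "endpoint": self.endpoint,
            "k": self.k,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "model": self.model,
            "transform": self.transform,
            "heterogeneity": {"Q": h.Q, "df": h.df, "I2": h.I2, "tau2": h.tau2},
            "weights": {s: float(w) for s, w in zip(self.study_ids, self.weights)},
        }


class ProportionMetaAnalysis:
    """Meta-analysis model over trial cohorts for one endpoint (ORR or DCR).

    Parameters
    ----------
    studies
        Cohort records; rows missing the endpoint percentage are dropped
        with a warning (never imputed).
    endpoint
        ``'ORR'`` or ``'DCR'``.
    transform
        ``'double_arcsine'`` (default) or ``'logit'``.
    i2_threshold
        Random effects are selected iff I^2 strictly exceeds this (default 50).

    Examples
    --------
    >>> model = ProportionMetaAnalysis.from_bundled_trials(endpoint="ORR")
    >>> res = model.fit()
    >>> round(res.estimate, 2)
    0.38
    """

    def __init__(
        self,
        studies: list[StudyRecord],
        endpoint: str = "ORR",
        transform: str = "double_arcsine",
        i2_threshold: float = 50.0,
        ci_level: float = 0.95,
    ):
        endpoint = endpoint.upper()
        if endpoint not in ("ORR", "DCR"):
            raise ValueError(f"endpoint must be ORR or DCR, got {endpoint!r}")
        if transform not in ("double_arcsine", "logit"):
            raise ValueError(f"unknown transform {transform!r}")
        kept, dropped = [], []
        for s in studies:
            pct = s.orr_pct if endpoint == "ORR" else s.dcr_pct
            (dropped if pct is None else kept).append(s)
        if dropped:
            warnings.warn(
                f"{len(dropped)} cohort(s) missing {endpoint} dropped: "
                f"{[s.study_id for s in dropped]}",
                stacklevel=2,
            )
        if not kept:
            raise ValueError(f"no cohorts carry endpoint {endpoint}")
        self.studies = kept
        self.endpoint = endpoint
        self.transform = transform
        self.i2_threshold = i2_threshold
        self.ci_level = ci_level

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, endpoint: str = "ORR", **kwargs):
        """Build from a DataFrame with columns study_id, tumor_type, n, orr_pct[, dcr_pct]."""
        records = []
        for _, row in df.iterrows():
            def _pct(col):
                v = row.get(col)
                return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    tumor_type=str(row["tumor_type"]),
                    n=int(row["n"]),
                    orr_pct=_pct("orr_pct"),
                    dcr_pct=_pct("dcr_pct"),
                )
            )
        return cls(records, endpoint=endpoint, **kwargs)

    @classmethod
    def from_bundled_trials(cls, endpoint: str = "ORR", **kwargs):
        """Build from the bundled 20-cohort combination-therapy trial table."""
        from .io import load_bundled_study_table

        return cls(load_bundled_study_table(), endpoint=endpoint, **kwargs)

    def _outcomes(self) -> list[ArmOutcome]:
        col = "orr_pct" if self.endpoint == "ORR" else "dcr_pct"
        return [reconstruct_events(getattr(s, col), s.n) for s in self.studies]

    def fit(self) -> MetaAnalysisResults:
        """Transform, estimate heterogeneity, select the model by I^2, pool, back-transform."""
        outcomes = self._outcomes()
        fwd = ft_transform if self.transform == "double_arcsine" else _logit_transform
        effects = [fwd(o) for o in outcomes]
        het = heterogeneity(effects)
        if het.I2 > self.i2_threshold:
            model = "random"
            t_bar, var_bar = pool_random(effects, het.tau2)
            w = np.array([1.0 / (e.var + het.tau2) for e in effects])
        else:
            model = "fixed"
            t_bar, var_bar = pool_fixed(effects)
            w = np.array([1.0 / e.var for e in effects])
        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        lo_t, hi_t = t_bar - z * math.sqrt(var_bar), t_bar + z * math.sqrt(var_bar)
        if self.transform == "double_arcsine":
            ns = np.array([o.n for o in outcomes], dtype=float)
            n_bar = len(ns) / np.sum(1.0 / ns)  # harmonic mean
            est = ft_backtransform(t_bar, n_bar)
            lo, hi = ft_backtransform(lo_t, n_bar), ft_backtransform(hi_t, n_bar)
        else:
            est, lo, hi = (float(special.expit(v)) for v in (t_bar, lo_t, hi_t))
        return MetaAnalysisResults(
            endpoint=self.endpoint,
            k=len(outcomes),
            estimate=est,
            ci_low=min(lo, hi),
            ci_high=max(lo, hi),
            model=model,
            het=het,
            weights=w / w.sum(),
            study_ids=[s.study_id for s in self.studies],
            transform=self.transform,
            t_bar=t_bar,
            var_t_bar=var_bar,
            outcomes=outcomes,
        )


def meta_analyze(studies: list[StudyRecord], endpoint: str = "ORR", **kwargs) -> MetaAnalysisResults:
    """Functional convenience wrapper: build the model and fit in one call."""
    return ProportionMetaAnalysis(studies, endpoint=endpoint, **kwargs).fit()
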
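"""Meta-analysis of proportions: transform, pooling, heterogeneity, model objects."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lenvicb.meta import (
    ArmOutcome,
    ProportionMetaAnalysis,
    StudyRecord,
    TransformedEffect,
    ft_backtransform,
    ft_transform,
    heterogeneity,
    meta_analyze,
    pool_fixed,
    pool_random,
    reconstruct_events,
    study_ci,
)


def brute_force_pool(xs, ns):
    """Independent oracle: direct arithmetic, no shared code with the implementation."""
    ts, vs = [], []
    for x, n in zip(xs, ns):
        ts.append(math.asin((x / (n + 1)) ** 0.5) + math.asin(((x + 1) / (n + 1)) ** 0.5))
        vs.append(1.0 / (n + 0.5))
    w = [1.0 / v for v in vs]
    sw = sum(w)
    tbar = sum(wi * ti for wi, ti in zip(w, ts)) / sw
    Q = sum(wi * (ti - tbar) ** 2 for wi, ti in zip(w, ts))
    df = len(ts) - 1
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (Q - df) / denom) if df > 0 else 0.0
    I2 = max(0.0, (Q - df) / Q) * 100 if Q > 0 and df > 0 else 0.0
    if I2 > 50:
        wr = [1.0 / (v + tau2) for v in vs]
        tbar = sum(wi * ti for wi, ti in zip(wr, ts)) / sum(wr)
        var = 1.0 / sum(wr)
    else:
        var = 1.0 / sw
    return tbar, var, tau2, I2


@pytest.mark.parametrize(
    "pct, n, expected",
    [
        (71.0, 355, 252),  # 252.05 rounds down
        (100.0, 29, 29),
        (16.1, 31, 5),  # 4.991 rounds up
        (38.3, 94, 36),  # 36.002
        (50.0, 5, 3),  # 2.5 ties rounded half up
        (0.0, 10, 0),
    ],
)
def test_reconstruct_events(pct, n, expected):
    assert reconstruct_events(pct, n).events == expected


@pytest.mark.parametrize("pct, n", [(-1.0, 10), (101.0, 10), (50.0, 0)])
def test_reconstruct_events_validation(pct, n):
    with pytest.raises(ValueError):
        reconstruct_events(pct, n)


def test_ft_transform_known_value():
    eff = ft_transform(ArmOutcome(0, 10))
    assert eff.t == pytest.approx(0.30627, abs=1e-5)
    assert eff.var == pytest.approx(1 / 10.5)
    assert ft_transform(ArmOutcome(10, 10)).t == pytest.approx(math.pi - 0.30627, abs=1e-5)


@given(st.integers(0, 200).flatmap(lambda n: st.tuples(st.integers(0, n), st.just(n))))
def test_ft_symmetry(xn):
    """t(x,n) + t(n-x,n) = pi, an identity of the double-arcsine transform."""
    x, n = xn
    t1 = ft_transform(ArmOutcome(x, n)).t
    t2 = ft_transform(ArmOutcome(n - x, n)).t
    assert abs(t1 + t2 - math.pi) < 1e-12


def test_backtransform_boundaries():
    assert ft_backtransform(0.0, 50) == 0.0
    assert ft_backtransform(-0.5, 50) == 0.0
    assert ft_backtransform(math.pi, 50) == 1.0
    assert ft_backtransform(4.0, 50) == 1.0


def test_backtransform_roundtrip_n20():
    n = 20
    for x in range(n + 1):
        t = ft_transform(ArmOutcome(x, n)).t
        assert ft_backtransform(t, n) == pytest.approx(x / n, abs=1.0 / n)


def test_pool_fixed_identities():
    e = TransformedEffect(1.1, 0.04)
    assert pool_fixed([e]) == (pytest.approx(1.1), pytest.approx(0.04))
    t, v = pool_fixed([e, e])
    assert t == pytest.approx(1.1)
    assert v == pytest.approx(0.02)
    with pytest.raises(ValueError):
        pool_fixed([])


def test_pool_fixed_hand_worked():
    effects = [TransformedEffect(0.5, 0.1), TransformedEffect(0.8, 0.05), TransformedEffect(0.6, 0.2)]
    w = [10.0, 20.0, 5.0]
    expect_t = (10 * 0.5 + 20 * 0.8 + 5 * 0.6) / 35
    t, v = pool_fixed(effects)
    assert t == pytest.approx(expect_t)
    assert v == pytest.approx(1 / 35)
    assert sum(w) == 35  # the spreadsheet arithmetic above


def test_heterogeneity_no_dispersion():
    effects = [TransformedEffect(0.7, v) for v in (0.1, 0.05, 0.2)]
    het = heterogeneity(effects)
    assert het.Q == pytest.approx(0.0)
    assert het.I2 == 0.0
    assert het.tau2 == 0.0


def test_heterogeneity_truncation_makes_random_equal_fixed():
    # tiny dispersion relative to within-study variance: Q <= df, tau2 truncates to 0
    effects = [TransformedEffect(0.70, 0.1), TransformedEffect(0.71, 0.1), TransformedEffect(0.705, 0.1)]
    het = heterogeneity(effects)
    assert het.Q <= het.df
    assert het.tau2 == 0.0
    assert pool_random(effects, het.tau2) == pool_fixed(effects)


def test_heterogeneity_single_study():
    het = heterogeneity([TransformedEffect(0.5, 0.1)])
    assert (het.Q, het.df, het.I2, het.tau2) == (0.0, 0, 0.0, 0.0)


def test_dl_tau2_recovery(rng):
    """DL moment estimator recovers a planted between-study variance on average."""
    true_tau2, k = 0.04, 40
    estimates = []
    for _ in range(200):
        vs = rng.uniform(0.004, 0.02, size=k)
        ts = rng.normal(1.0, np.sqrt(true_tau2 + vs))
        estimates.append(heterogeneity([TransformedEffect(t, v) for t, v in zip(ts, vs)]).tau2)
    assert abs(np.mean(estimates) - true_tau2) < 0.5 * true_tau2


def test_pool_random_limits():
    effects = [TransformedEffect(0.4, 0.1), TransformedEffect(0.9, 0.02)]
    assert pool_random(effects, 0.0) == pool_fixed(effects)
    t_inf, _ = pool_random(effects, 1e9)
    assert t_inf == pytest.approx(np.mean([0.4, 0.9]), abs=1e-6)
    with pytest.raises(ValueError):
        pool_random(effects, -0.1)


def test_study_ci():
    assert study_ci(ArmOutcome(0, 10))[0] == 0.0
    assert study_ci(ArmOutcome(10, 10))[1] == 1.0
    lo, hi = study_ci(ArmOutcome(5, 10))
    assert lo == pytest.approx(0.187, abs=0.001)
    assert hi == pytest.approx(0.813, abs=0.001)


def _studies(rows):
    return [
        StudyRecord(f"S{i}", "SIM", n, orr, dcr)
        for i, (n, orr, dcr) in enumerate(rows)
    ]


def test_meta_analyze_single_study():
    res = meta_analyze(_studies([(10, 50.0, None)]), "ORR")
    assert res.model == "fixed"
    assert res.k == 1
    assert res.estimate == pytest.approx(0.5, abs=0.05)


def test_meta_analyze_identical_studies_any_k():
    for k in (2, 5, 9):
        res = meta_analyze(_studies([(40, 30.0, None)] * k), "ORR")
        assert res.het.I2 == 0.0
        assert res.estimate == pytest.approx(12 / 40, abs=0.01)


def test_pooled_estimate_within_study_range(rng):
    for _ in range(20):
        k = int(rng.integers(3, 10))
        rows = [(int(rng.integers(10, 120)), float(rng.uniform(5, 95)), None) for _ in range(k)]
        res = meta_analyze(_studies(rows), "ORR")
        ps = [o.proportion for o in res.outcomes]
        assert min(ps) - 1e-9 <= res.estimate <= max(ps) + 1e-9


def test_equivalence_with_brute_force_oracle(rng):
    """Pooling on the transformed scale matches independent direct arithmetic."""
    for _ in range(50):
        k = int(rng.integers(2, 12))
        ns = rng.integers(5, 200, size=k)
        xs = [int(rng.integers(0, n + 1)) for n in ns]
        rows = [(int(n), 100.0 * x / n, None) for x, n in zip(xs, ns)]
        studies = _studies(rows)
        # reconstruct_events(100*x/n, n) round-trips exactly to x
        res = meta_analyze(studies, "ORR")
        tbar, var, tau2, _ = brute_force_pool([o.events for o in res.outcomes], ns)
        assert res.t_bar == pytest.approx(tbar, abs=1e-10)
        assert res.var_t_bar == pytest.approx(var, abs=1e-10)
        assert res.het.tau2 == pytest.approx(tau2, abs=1e-10)


def test_against_statsmodels_dl():
    """Cross-check DL tau2 and the random-effects pool against statsmodels."""
    sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
    model = ProportionMetaAnalysis.from_bundled_trials(endpoint="ORR")
    effects = [ft_transform(o) for o in model._outcomes()]
    res = model.fit()
    cmb = sm_meta.combine_effects(
        np.array([e.t for e in effects]), np.array([e.var for e in effects]), method_re="dl"
    )
    frame = cmb.summary_frame()
    assert res.het.tau2 == pytest.approx(float(cmb.tau2), rel=1e-8)
    assert res.t_bar == pytest.approx(float(frame.loc["random effect", "eff"]), rel=1e-8)


def test_missing_endpoint_dropped_with_warning():
    studies = _studies([(30, 40.0, 80.0), (30, 50.0, None)])
    with pytest.warns(UserWarning, match="missing DCR"):
        res = meta_analyze(studies, "DCR")
    assert res.k == 1


def test_weights_sum_to_one_and_ci_order():
    res = ProportionMetaAnalysis.from_bundled_trials(endpoint="ORR").fit()
    assert res.weights.sum() == pytest.approx(1.0)
    assert res.ci_low <= res.estimate <= res.ci_high


def test_forest_data_row_counts():
    res = ProportionMetaAnalysis.from_bundled_trials(endpoint="ORR").fit()
    df = res.forest_data()
    assert len(df) == 21
    assert df["pooled"].sum() == 1
    single = meta_analyze(_studies([(10, 50.0, None)]), "ORR").forest_data()
    assert len(single) == 2
    assert single.loc[0, "weight"] == pytest.approx(1.0)


def test_logit_transform_alternative():
    res = ProportionMetaAnalysis.from_bundled_trials(endpoint="ORR", transform="logit").fit()
    assert 0.2 < res.estimate < 0.6
    assert res.transform == "logit"


def test_summary_mentions_key_quantities():
    res = ProportionMetaAnalysis.from_bundled_trials(endpoint="ORR").fit()
    text = res.summary()
    assert "random" in text and "I^2" in text and f"{res.estimate:.3f}" in text
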
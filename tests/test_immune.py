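"""Infiltration correlations, box rules, Cox risk calls and the log-rank test."""

import numpy as np
import pytest

from lenvicb.expression import ExpressionMatrix
from lenvicb.immune import (
    InfiltrationTable,
    SurvivalRecord,
    cd8_box_flag,
    cox_classify,
    gene_infiltration_correlation,
    km_logrank,
    suppressive_box_flag,
)


def _expr(panel, gene_values: dict, n, cancer="SYN"):
    genes = sorted(panel.all_targets)
    vals = np.ones((len(genes), n))
    for i, g in enumerate(genes):
        if g in gene_values:
            vals[i] = np.exp2(np.asarray(gene_values[g])) - 1.0
    return ExpressionMatrix(cancer, genes, [f"s{i}" for i in range(n)], vals, ["tumor"] * n)


def _infil(cells: dict, n, purity=None, cancer="SYN"):
    names = sorted(cells)
    values = np.column_stack([np.asarray(cells[c], dtype=float) for c in names])
    return InfiltrationTable(cancer, [f"s{i}" for i in range(n)], names, values, purity)


def test_monotone_link_gives_r_one(panel, rng):
    x = rng.uniform(1, 6, 30)
    em = _expr(panel, {"KDR": x}, 30)
    it = _infil({"CD8_T": np.exp(x)}, 30)  # strictly monotone transform
    corrs = gene_infiltration_correlation(em, it, panel)
    kdr = next(c for c in corrs if c.gene == "KDR" and c.cell_type == "CD8_T")
    assert kdr.r == pytest.approx(1.0)


def test_spearman_invariant_under_monotone_transform(panel, rng):
    x = rng.uniform(1, 6, 50)
    y = x + rng.normal(0, 1, 50)
    em = _expr(panel, {"RET": x}, 50)
    r1 = next(
        c.r
        for c in gene_infiltration_correlation(em, _infil({"CD8_T": y - y.min() + 0.1}, 50), panel)
        if c.gene == "RET"
    )
    r2 = next(
        c.r
        for c in gene_infiltration_correlation(
            em, _infil({"CD8_T": np.exp(y)}, 50), panel
        )
        if c.gene == "RET"
    )
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_planted_negative_link_recovered(panel, rng):
    n = 300
    x = rng.normal(4, 1, n)
    em = _expr(panel, {"FGFR2": x}, n)
    it = _infil({"CD8_T": np.maximum(0.0, 5.0 - 0.8 * x + rng.normal(0, 0.3, n))}, n)
    r = next(c.r for c in gene_infiltration_correlation(em, it, panel) if c.gene == "FGFR2")
    assert r <= -0.5


def test_purity_adjustment_removes_confounding(panel, rng):
    # gene and cell both driven by purity only: partial Spearman ~ 0, raw strongly > 0
    n = 200
    purity = rng.uniform(0.2, 0.9, n)
    x = 3 + 2 * purity + rng.normal(0, 0.1, n)
    cell = 0.1 + purity + rng.normal(0, 0.05, n)
    em = _expr(panel, {"KIT": x}, n)
    raw = next(
        c.r
        for c in gene_infiltration_correlation(em, _infil({"CD8_T": cell}, n), panel)
        if c.gene == "KIT"
    )
    adj = next(
        c.r
        for c in gene_infiltration_correlation(
            em, _infil({"CD8_T": cell}, n, purity=purity), panel
        )
        if c.gene == "KIT"
    )
    assert raw > 0.8
    assert abs(adj) < 0.25


def test_shared_sample_requirement(panel):
    em = _expr(panel, {}, 5)
    it = InfiltrationTable("SYN", ["x1", "x2", "x3"], ["CD8_T"], np.ones((3, 1)))
    with pytest.raises(ValueError, match="shared tumor samples"):
        gene_infiltration_correlation(em, it, panel)


@pytest.mark.parametrize(
    "rs, expected",
    [
        ([-0.2] * 5 + [-0.1] * 4 + [0.05, 0.1], True),  # 9 negative, 5 <= -0.15
        ([-0.2] * 4 + [-0.1] * 4 + [0.05, 0.1, 0.2], False),  # only 4 strong
        ([0.0] * 11, False),
        ([-0.16] * 11, True),
    ],
)
def test_cd8_box_flag(rs, expected):
    assert cd8_box_flag(rs) is expected


@pytest.mark.parametrize(
    "rs, expected",
    [
        ([0.2] * 6 + [0.05] * 4 + [-0.1], True),  # 10 positive, 6 >= 0.15
        ([0.2] * 4 + [0.05] * 7, False),  # 11 positive but 4 strong
        ([0.2] * 5 + [-0.1] * 6, False),  # only 5 positive
    ],
)
def test_suppressive_box_flag(rs, expected):
    assert suppressive_box_flag(rs) is expected


def test_box_flag_monotone(rng):
    rs = list(rng.uniform(-0.3, 0.1, 11))
    if cd8_box_flag(rs):
        more = [r - 0.2 for r in rs]
        assert cd8_box_flag(more)
    rs_true = [-0.2] * 11
    assert cd8_box_flag(rs_true) and cd8_box_flag([r - 1.0 + 1e-9 for r in rs_true])


def _surv(rng, n, coef, baseline=0.05, censor=0.02):
    cov = rng.normal(0, 1, n)
    t_event = rng.exponential(1.0 / (baseline * np.exp(coef * cov)))
    t_cens = rng.exponential(1.0 / censor, n) if censor > 0 else np.full(n, np.inf)
    return [
        SurvivalRecord(f"s{i}", float(min(te, tc)), int(te <= tc), float(c))
        for i, (te, tc, c) in enumerate(zip(t_event, t_cens, cov))
    ]


def test_cox_planted_risk(rng):
    call = cox_classify(_surv(rng, 500, 0.7))
    assert call.call == "risk"
    assert call.z > 0 and call.p < 0.05


def test_cox_sign_symmetry(rng):
    recs = _surv(rng, 200, 0.5)
    flipped = [SurvivalRecord(r.sample_id, r.time, r.event, -r.covariate) for r in recs]
    z1 = cox_classify(recs).z
    z2 = cox_classify(flipped).z
    assert z1 == pytest.approx(-z2, rel=1e-6)


def test_cox_degenerate_inputs(rng):
    with pytest.raises(ValueError, match=">=10"):
        cox_classify(_surv(rng, 5, 0.0))
    no_events = [SurvivalRecord(f"s{i}", 1.0 + i, 0, float(i)) for i in range(12)]
    with pytest.warns(UserWarning, match="no events"):
        assert cox_classify(no_events).call == "neutral"


def test_logrank_identical_groups():
    # covariate splits into two groups with identical time/event profiles
    times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    recs = [
        SurvivalRecord(f"a{i}", t, 1, 0.0) for i, t in enumerate(times)
    ] + [SurvivalRecord(f"b{i}", t, 1, 1.0) for i, t in enumerate(times)]
    chi2, p, medians = km_logrank(recs)
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-6)
    assert medians["high"] == medians["low"]


def test_logrank_separated_groups(rng):
    n = 100
    cov = np.concatenate([np.zeros(n), np.ones(n)])
    t = np.concatenate([rng.exponential(1.0, n), rng.exponential(3.0, n)])
    recs = [
        SurvivalRecord(f"s{i}", float(ti), 1, float(c)) for i, (ti, c) in enumerate(zip(t, cov))
    ]
    chi2, p, medians = km_logrank(recs)
    assert p < 0.05
    assert medians["high"] > medians["low"]


def test_logrank_degenerate_split():
    recs = [SurvivalRecord(f"s{i}", float(i + 1), 1, 5.0) for i in range(10)]
    with pytest.raises(ValueError, match="degenerate split"):
        km_logrank(recs)


def test_logrank_matches_brute_force_risk_sets():
    """Six-subject worked example against direct risk-set arithmetic."""
    # group A (low, cov 0): times 1, 3, 5 all events; group B (high, cov 1): 2, 4, 6 all events
    recs = [
        SurvivalRecord("a1", 1, 1, 0.0),
        SurvivalRecord("a2", 3, 1, 0.0),
        SurvivalRecord("a3", 5, 1, 0.0),
        SurvivalRecord("b1", 2, 1, 1.0),
        SurvivalRecord("b2", 4, 1, 1.0),
        SurvivalRecord("b3", 6, 1, 1.0),
    ]
    chi2, _, _ = km_logrank(recs)
    # brute force: O-E and hypergeometric variance per distinct death time (high group)
    data = [(1, 0), (2, 1), (3, 0), (4, 1), (5, 0), (6, 1)]  # (time, in_high)
    at_risk_high, at_risk_low = 3, 3
    o_minus_e, var = 0.0, 0.0
    for _, is_high in data:
        n_tot = at_risk_high + at_risk_low
        e = at_risk_high / n_tot
        o_minus_e += is_high - e
        var += e * (1 - e)  # one death per time, no ties
        if is_high:
            at_risk_high -= 1
        else:
            at_risk_low -= 1
    assert chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-6)
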
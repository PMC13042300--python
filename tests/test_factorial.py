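"""Factorial ANOVA, summary bridge, Šidák / Dunnett post hocs, reporting policy."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from hypothesis import given, settings, strategies as st

from foragestat import (
    AdjustMethod,
    AnovaTable,
    BootstrapConfig,
    FactorialDesign,
    SummaryCell,
    anova_from_summary,
    anova_raw,
    bootstrap_difference,
    bootstrap_effect_anova,
    posthoc_dunnett,
    posthoc_sidak,
    report_hierarchy,
    sidak_adjust,
    two_sample_t,
)


def summarize(design: FactorialDesign) -> FactorialDesign:
    cells = {
        k: SummaryCell(float(np.mean(v)), float(np.std(v, ddof=1)), len(v))
        for k, v in design.cells.items()
    }
    return FactorialDesign(factors=design.factors, cells=cells)


@pytest.fixture
def worked_design():
    return FactorialDesign.from_samples(
        {"A": ["a1", "a2"], "B": ["b1", "b2"]},
        {
            ("a1", "b1"): [10.0, 20.0],
            ("a1", "b2"): [30.0, 40.0],
            ("a2", "b1"): [50.0, 60.0],
            ("a2", "b2"): [70.0, 80.0],
        },
    )


def random_design(rng, n_factors=2, balanced=False):
    names = ["A", "B", "C"][:n_factors]
    factors = {n: [f"{n.lower()}1", f"{n.lower()}2"] for n in names}
    cells = {}
    for key in itertools.product(*factors.values()):
        n = 5 if balanced else int(rng.integers(3, 9))
        cells[key] = rng.normal(rng.normal(0, 5), rng.uniform(0.5, 8), n)
    return FactorialDesign.from_samples(factors, cells)


def test_worked_2x2_sums_of_squares(worked_design):
    t = anova_raw(worked_design).table
    assert t.loc["A", "sum_sq"] == pytest.approx(3200.0)
    assert t.loc["B", "sum_sq"] == pytest.approx(800.0)
    assert t.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
    assert t.loc["Residual", "sum_sq"] == pytest.approx(200.0)
    assert t.loc["Residual", "df"] == 4
    assert t.loc["A", "F"] == pytest.approx(64.0)


def test_no_variance_means_zero_effect_ss():
    d = FactorialDesign.from_samples(
        {"A": ["a1", "a2"], "B": ["b1", "b2"]},
        {k: [7.0, 7.0, 7.0] for k in itertools.product(["a1", "a2"], ["b1", "b2"])},
    )
    with pytest.warns(RuntimeWarning, match="zero within-cell"):
        table = anova_raw(d)
    assert table.degenerate
    assert np.allclose(table.table.loc[["A", "B", "A:B"], "sum_sq"], 0.0, atol=1e-9)


def test_balanced_type3_equals_sequential():
    rng = np.random.default_rng(3)
    d = random_design(rng, n_factors=2, balanced=True)
    mine = anova_raw(d).table
    rows = [
        dict(A=k[0], B=k[1], y=v)
        for k, vals in d.cells.items()
        for v in vals
    ]
    data = pd.DataFrame(rows)
    seq = sm.stats.anova_lm(
        smf.ols("y ~ C(A, Sum) * C(B, Sum)", data=data).fit(), typ=1
    )
    for term, pretty in [("C(A, Sum)", "A"), ("C(B, Sum)", "B"),
                         ("C(A, Sum):C(B, Sum)", "A:B")]:
        assert mine.loc[pretty, "sum_sq"] == pytest.approx(
            seq.loc[term, "sum_sq"], rel=1e-8
        )


@pytest.mark.parametrize("n_factors", [2, 3])
def test_summary_bridge_exact(n_factors):
    rng = np.random.default_rng(17 + n_factors)
    for _ in range(10):
        d = random_design(rng, n_factors=n_factors)
        raw = anova_raw(d).table
        summ = anova_from_summary(summarize(d)).table.loc[raw.index]
        assert np.allclose(
            raw[["sum_sq", "df", "F", "p"]].values,
            summ[["sum_sq", "df", "F", "p"]].values,
            rtol=1e-8, atol=1e-8, equal_nan=True,
        )


def test_summary_scaling_identity(worked_design):
    base = summarize(worked_design)
    doubled = FactorialDesign(
        factors=base.factors,
        cells={k: SummaryCell(c.mean, 2 * c.sd, c.n) for k, c in base.cells.items()},
    )
    t1, t2 = anova_from_summary(base).table, anova_from_summary(doubled).table
    assert t2.loc["Residual", "sum_sq"] == pytest.approx(
        4 * t1.loc["Residual", "sum_sq"]
    )
    assert t2.loc["A", "sum_sq"] == pytest.approx(t1.loc["A", "sum_sq"])


def test_df_bookkeeping():
    rng = np.random.default_rng(5)
    d = random_design(rng, n_factors=3)
    t = anova_raw(d).table
    n_total = sum(len(v) for v in d.cells.values())
    assert t["df"].sum() == pytest.approx(n_total - 1)


@pytest.mark.parametrize(
    "p,m,expected", [(0.05, 1, 0.05), (0.0, 7, 0.0), (0.01, 3, 0.029701)]
)
def test_sidak_closed_form(p, m, expected):
    assert sidak_adjust(p, m) == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.floats(0, 1), st.integers(1, 20), st.integers(1, 20))
def test_sidak_monotone(p, m1, m2):
    lo, hi = min(m1, m2), max(m1, m2)
    assert sidak_adjust(p, lo) <= sidak_adjust(p, hi) + 1e-15
    assert sidak_adjust(p, lo) >= p - 1e-15


def test_posthoc_sidak_identity_and_null(worked_design):
    plan = [("a1 vs a2 at b1", ("a1", "b1"), ("a2", "b1"))]
    (res,) = posthoc_sidak(worked_design, plan)
    assert res.adjusted_p == pytest.approx(res.raw_p)  # m = 1
    same = FactorialDesign.from_samples(
        {"A": ["a1", "a2"], "B": ["b1", "b2"]},
        {k: [10.0, 20.0, 30.0] for k in itertools.product(["a1", "a2"], ["b1", "b2"])},
    )
    (res2,) = posthoc_sidak(same, plan)
    assert res2.estimate == 0.0
    assert res2.raw_p == pytest.approx(1.0)


def test_posthoc_sidak_familywise_error_null():
    """4-comparison family on null data keeps familywise error near 0.05."""
    rng = np.random.default_rng(8)
    n_sims, rejections = 600, 0
    factors = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
    plan = [
        ("c1", ("a1", "b1"), ("a2", "b1")),
        ("c2", ("a1", "b2"), ("a2", "b2")),
        ("c3", ("a1", "b1"), ("a1", "b2")),
        ("c4", ("a2", "b1"), ("a2", "b2")),
    ]
    for _ in range(n_sims):
        cells = {
            k: rng.normal(0, 1, 8) for k in itertools.product(["a1", "a2"], ["b1", "b2"])
        }
        d = FactorialDesign.from_samples(factors, cells)
        comps = posthoc_sidak(d, plan)
        rejections += any(c.adjusted_p < 0.05 for c in comps)
    rate = rejections / n_sims
    se = np.sqrt(0.05 * 0.95 / n_sims)
    assert rate <= 0.05 + 3 * se


def test_dunnett_k1_reduces_to_pooled_t():
    rng = np.random.default_rng(0)
    a, ctrl = rng.normal(0.4, 1, 9), rng.normal(0, 1, 11)
    (res,) = posthoc_dunnett({"trt": a}, ctrl)
    _, p = sps.ttest_ind(a, ctrl, equal_var=True)
    assert res.adjusted_p == pytest.approx(p, abs=1e-6)


def test_dunnett_identical_groups_p_near_one():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = posthoc_dunnett({"trt": x, "trt2": x + 0.0}, x)
    assert all(r.adjusted_p > 0.95 for r in res)


def test_dunnett_matches_scipy_oracle():
    """Independent cross-check of the multivariate-t box probabilities."""
    rng = np.random.default_rng(4)
    groups = [rng.normal(0.5, 1, 8), rng.normal(0, 1, 10), rng.normal(1.0, 1, 6)]
    ctrl = rng.normal(0, 1, 12)
    mine = posthoc_dunnett({f"g{i}": g for i, g in enumerate(groups)}, ctrl)
    ref = sps.dunnett(*groups, control=ctrl, random_state=1)
    for r, p_ref in zip(mine, ref.pvalue):
        assert r.adjusted_p == pytest.approx(p_ref, abs=1e-3)
        assert r.adjusted_p >= r.raw_p - 1e-12  # adjustment never helps


def test_two_sample_t_identical_and_summary_bridge():
    x = np.array([10.0, 20.0, 30.0, 40.0])
    res = two_sample_t(x, x.copy())
    assert res.statistic == 0.0
    assert res.raw_p == pytest.approx(1.0)
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 2, 7), rng.normal(1, 2, 9)
    raw = two_sample_t(a, b)
    summ = two_sample_t(
        SummaryCell(float(a.mean()), float(a.std(ddof=1)), 7),
        SummaryCell(float(b.mean()), float(b.std(ddof=1)), 9),
    )
    assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
    assert raw.raw_p == pytest.approx(summ.raw_p, abs=1e-10)


def _fake_table(term_ps: dict[str, float]) -> AnovaTable:
    idx = list(term_ps) + ["Residual"]
    df = pd.DataFrame(
        {
            "sum_sq": 1.0,
            "df": 1.0,
            "mean_sq": 1.0,
            "F": 1.0,
            "p": [term_ps[t] for t in term_ps] + [np.nan],
        },
        index=idx,
    )
    return AnovaTable(table=df)


def test_report_hierarchy_policy():
    # significant 3-way: only that term
    t = _fake_table({"A": 0.01, "B": 0.2, "C": 0.6, "A:B": 0.01, "A:B:C": 0.001})
    assert report_hierarchy(t) == [("A:B:C", 0.001)]
    # 3-way ns, two significant 2-ways: both reported
    t = _fake_table({"A": 0.001, "A:B": 0.01, "B:C": 0.04, "A:C": 0.9, "A:B:C": 0.3})
    assert set(x[0] for x in report_hierarchy(t)) == {"A:B", "B:C"}
    # no interaction significant, one main effect significant
    t = _fake_table({"A": 0.02, "B": 0.8, "A:B": 0.4})
    assert report_hierarchy(t) == [("A", 0.02)]
    # nothing significant
    t = _fake_table({"A": 0.5, "A:B": 0.4, "B": 0.9})
    assert report_hierarchy(t) == []


def test_bootstrap_effect_anova_identical_results():
    fed, fd = [20.0, 30.0, 10.0, 20.0], [60.0, 70.0, 50.0, 80.0]
    res = bootstrap_difference(fed, fd, BootstrapConfig(n_reps=2000, seed=2))
    table, comps = bootstrap_effect_anova(
        {("s1",): res, ("s2",): res}, {"strain": ["s1", "s2"]},
        posthoc=AdjustMethod.SIDAK, plan=[("s2 vs s1", ("s2",), ("s1",))],
    )
    assert table.table.loc["strain", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
    assert comps[0].estimate == 0.0


def test_bootstrap_effect_anova_degenerate_variance():
    constant = bootstrap_difference(
        [50.0, 50.0], [80.0, 80.0], BootstrapConfig(n_reps=500, seed=0)
    )
    shifted = bootstrap_difference(
        [50.0, 50.0], [90.0, 90.0], BootstrapConfig(n_reps=500, seed=0)
    )
    with pytest.warns(RuntimeWarning, match="zero within-cell"):
        table, _ = bootstrap_effect_anova(
            {("s1",): constant, ("s2",): shifted}, {"strain": ["s1", "s2"]}
        )
    assert table.degenerate
    assert np.isnan(table.table.loc["strain", "F"])
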
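"""Design construction, ANOVA decomposition, one-way collapses, contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import massanova as ma
from massanova.design import BLOCK, ModelSpec, decompose, f_test, term_label

from conftest import ls_sequential_ss, residual_noise


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def test_build_design_sizes(design_4x3):
    assert design_4x3.N == 48
    assert design_4x3.residual_df == 36
    d3 = ma.build_design([("A", 3), ("B", 2), ("C", 4)], replication=3)
    assert d3.N == 72
    assert d3.n_cells == 24


@pytest.mark.parametrize(
    "factors, rep, err",
    [
        ([("A", 2), ("B", 2)], 1, "replication"),
        ([("A", 1), ("B", 2)], 3, "levels"),
        ([("A", 2), ("B", 2), ("C", 2), ("D", 2)], 2, "factors"),
    ],
)
def test_build_design_rejects_degenerate(factors, rep, err):
    with pytest.raises(ValueError, match=err):
        ma.build_design(factors, replication=rep)


def test_unbalanced_design_rejected():
    codes = {"A": np.array([0, 0, 0, 1, 1]), "B": np.array([0, 1, 1, 0, 1])}
    with pytest.raises(ValueError, match="not balanced"):
        ma.Design.from_codes(["A", "B"], {"A": ["a1", "a2"], "B": ["b1", "b2"]}, codes)


def test_enumerate_terms_order(design_4x3, design_3f, design_blocked):
    assert ma.enumerate_terms(design_4x3) == [("Genotype",), ("Salt",), ("Genotype", "Salt")]
    terms3 = ma.enumerate_terms(design_3f)
    assert len(terms3) == 7
    assert [len(t) for t in terms3] == [1, 1, 1, 2, 2, 2, 3]
    assert ma.enumerate_terms(design_blocked)[0] == BLOCK
    assert len(ma.enumerate_terms(design_blocked)) == 4


# ---------------------------------------------------------------------------
# fit_anova
# ---------------------------------------------------------------------------


def test_fit_anova_df_column(design_4x3, rng):
    table = ma.fit_anova(rng.standard_normal(48), design_4x3).table
    assert list(table["df"]) == [3, 2, 6, 36]
    assert list(table.index) == ["Genotype", "Salt", "Genotype:Salt", "Residual"]


def test_fit_anova_constant_response(design_4x3):
    t = ma.fit_anova(np.full(48, 3.7), design_4x3)
    assert t.table["sum_sq"].abs().max() == pytest.approx(0.0, abs=1e-20)
    assert (t.table.loc[list(t.treatment_labels), "p"] == 1).all()
    assert t.table.loc[list(t.treatment_labels), "F"].isna().all()


def test_fit_anova_rejects_bad_input(design_4x3, rng):
    with pytest.raises(ValueError, match="length"):
        ma.fit_anova(rng.standard_normal(47), design_4x3)
    y = rng.standard_normal(48)
    y[0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        ma.fit_anova(y, design_4x3)


@pytest.mark.parametrize("fixture", ["design_4x3", "design_3f", "design_blocked"])
def test_ss_matches_least_squares_oracle(fixture, rng, request):
    """Term SS from marginal means equals sequential projection SS, any order."""
    design = request.getfixturevalue(fixture)
    y = rng.standard_normal(design.N) + design.codes[design.factor_names[0]] * 0.5
    table = ma.fit_anova(y, design)
    terms = ma.treatment_terms(design)
    for order in (terms, terms[::-1]):
        oracle = ls_sequential_ss(y, design, list(order))
        for t in terms:
            assert table.table.loc[term_label(t), "sum_sq"] == pytest.approx(oracle[t], rel=1e-10)
        assert table.ss_res == pytest.approx(oracle["__residual__"], rel=1e-10)
        if design.block_name:
            assert table.table.loc["Block", "sum_sq"] == pytest.approx(oracle[BLOCK], rel=1e-10)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    ta=st.integers(2, 4),
    tb=st.integers(2, 3),
    rep=st.integers(2, 4),
)
def test_ss_conservation_property(seed, ta, tb, rep):
    """Treatment SS plus residual SS reproduce the total corrected SS."""
    design = ma.build_design([("A", ta), ("B", tb)], replication=rep)
    r = np.random.default_rng(seed)
    y = r.standard_normal(design.N) * r.uniform(0.5, 3) + r.standard_normal()
    t = ma.fit_anova(y, design)
    total = float(((y - y.mean()) ** 2).sum())
    assert float(t.table["sum_sq"].drop("Residual").sum() + t.ss_res) == pytest.approx(total, rel=1e-10)


# ---------------------------------------------------------------------------
# One-way collapses and pooling
# ---------------------------------------------------------------------------


def test_pool_from_printed_table():
    """Pooling published two-way rows reproduces the published one-way test."""
    tab = ma.AnovaTable.from_components(
        {"Genotype": (3, 27.503), "Salt": (2, 11.852), "Genotype:Salt": (6, 2.328)},
        residual=(36, 8.633),
    )
    ow = ma.pool_from_table(tab)
    assert (ow.df1, ow.df2) == (11, 36)
    assert ow.F == pytest.approx(15.802, abs=2e-3)


def test_pool_single_term_table():
    tab = ma.AnovaTable.from_components({"A": (2, 6.0)}, residual=(9, 4.5))
    ow = ma.pool_from_table(tab)
    assert ow.F == pytest.approx(tab.table.loc["A", "F"])
    assert ow.p == pytest.approx(tab.table.loc["A", "p"])


def test_pool_requires_residual_row(design_4x3, rng):
    tab = ma.fit_anova(rng.standard_normal(48), design_4x3)
    broken = ma.AnovaTable(tab.table.drop("Residual"), tab.treatment_labels, tab.N)
    with pytest.raises(ValueError, match="residual"):
        ma.pool_from_table(broken)


def test_pooled_equals_direct_oneway(design_4x3, rng):
    """pool_from_table(fit_anova(y)) is the one-way ANOVA on crossed labels."""
    y = rng.standard_normal(48)
    ow = ma.pool_from_table(ma.fit_anova(y, design_4x3))
    code, ncell = design_4x3.cell_codes()
    groups = [y[code == k] for k in range(ncell)]
    F_direct, p_direct = stats.f_oneway(*groups)
    assert ow.F == pytest.approx(F_direct, rel=1e-10)
    assert ow.p == pytest.approx(p_direct, rel=1e-8)


def test_collapse_saturated_identity(design_4x3, rng):
    y = rng.standard_normal(48)
    ow1 = ma.collapse_oneway(y, design_4x3, ModelSpec.saturated(design_4x3))
    ow2 = ma.pool_from_table(ma.fit_anova(y, design_4x3))
    assert ow1.F == pytest.approx(ow2.F, rel=1e-12)
    assert ow1.p == pytest.approx(ow2.p, rel=1e-12)
    assert (ow1.df1, ow1.df2) == (11, 36)


def test_collapse_df_conventions(design_4x3_rep3, rng):
    """Additive-model df: standard (5, 30) vs as-printed (6, 29) at N=36."""
    y = rng.standard_normal(36)
    additive = ModelSpec(frozenset({("Genotype",), ("Salt",)}))
    std = ma.collapse_oneway(y, design_4x3_rep3, additive, convention="standard")
    printed = ma.collapse_oneway(y, design_4x3_rep3, additive, convention="as-printed")
    assert (std.df1, std.df2) == (5, 30)
    assert (printed.df1, printed.df2) == (6, 29)
    # same SS ratio, different normalisation
    assert printed.F * printed.df1 / printed.df2 == pytest.approx(std.F * std.df1 / std.df2, rel=1e-12)


def test_collapse_rejects_open_model(design_4x3, rng):
    open_model = ModelSpec(frozenset({("Genotype", "Salt")}))
    with pytest.raises(ValueError, match="marginality"):
        ma.collapse_oneway(rng.standard_normal(48), design_4x3, open_model)


def test_collapse_null_model(design_4x3, rng):
    ow = ma.collapse_oneway(rng.standard_normal(48), design_4x3, ModelSpec())
    assert np.isnan(ow.F) and ow.p == 1.0


# ---------------------------------------------------------------------------
# f_tail
# ---------------------------------------------------------------------------


def test_f_tail_anchors():
    assert ma.f_tail(2, 11, 24) == pytest.approx(0.075, abs=5e-4)
    assert ma.f_tail(1.618, 6, 36) == pytest.approx(0.171, abs=5e-4)
    assert ma.f_tail(0.0, 3, 10) == 1.0
    assert ma.f_tail(1e9, 3, 10) < 1e-12


def test_f_tail_monotone_and_validated():
    grid = np.linspace(0.01, 10, 50)
    p = ma.f_tail(grid, 4, 20)
    assert (np.diff(p) < 0).all()
    with pytest.raises(ValueError):
        ma.f_tail(1.0, 0, 5)
    with pytest.raises(ValueError):
        ma.f_tail(-0.5, 3, 5)


@pytest.mark.parametrize("F,df1,df2", [(0.5, 1, 8), (2.0, 11, 24), (3.3, 6, 36), (1.0, 2, 2)])
def test_f_tail_against_numerical_integration(F, df1, df2):
    """Upper tail agrees with direct quadrature of the F density."""
    val, _ = integrate.quad(lambda x: stats.f.pdf(x, df1, df2), F, np.inf, limit=200)
    assert ma.f_tail(F, df1, df2) == pytest.approx(val, abs=1e-8)


# ---------------------------------------------------------------------------
# Lack of fit
# ---------------------------------------------------------------------------


def test_lack_of_fit_preserves_residual_df(design_4x3_rep3, rng):
    y = rng.standard_normal(36)
    additive = ModelSpec(frozenset({("Genotype",), ("Salt",)}))
    lof = ma.lack_of_fit_test(y, design_4x3_rep3, additive)
    assert lof.df2 == 24  # the designed residual df, unchanged
    # conservation: retained + lack-of-fit = pooled one-way treatment SS
    sat = ma.fit_anova(y, design_4x3_rep3)
    pooled_ss = float(sat.table.loc[list(sat.treatment_labels), "sum_sq"].sum())
    retained_ss = lof.F * lof.df1 * sat.ms_res
    assert retained_ss + lof.lack_of_fit[1] == pytest.approx(pooled_ss, rel=1e-10)


def test_lack_of_fit_zero_for_additive_means(design_4x3_rep3):
    d = design_4x3_rep3
    y = 0.8 * d.codes["Genotype"] - 0.3 * d.codes["Salt"] + 1.0
    lof = ma.lack_of_fit_test(y, d, ModelSpec(frozenset({("Genotype",), ("Salt",)})))
    assert lof.lack_of_fit[1] == pytest.approx(0.0, abs=1e-12)


def test_lack_of_fit_rejects_saturated(design_4x3, rng):
    with pytest.raises(ValueError, match="saturated"):
        ma.lack_of_fit_test(rng.standard_normal(48), design_4x3, ModelSpec.saturated(design_4x3))


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


def test_contrast_components_sum_to_factor_ss(design_4x3, rng):
    y = rng.standard_normal(48)
    cs = ma.ContrastSet.build("Salt", {"linear": [-1, 0, 1], "quadratic": [1, -2, 1]})
    tab = ma.contrast_anova(y, design_4x3, {"Salt": cs})
    sat = ma.fit_anova(y, design_4x3)
    comp_sum = tab.table.loc["Salt:linear", "sum_sq"] + tab.table.loc["Salt:quadratic", "sum_sq"]
    assert comp_sum == pytest.approx(sat.table.loc["Salt", "sum_sq"], rel=1e-10)
    assert tab.table.loc["Salt:linear", "df"] == 1


def test_ecotype_contrast_dfs(design_4x3, rng):
    """1-df ecotype split plus a 2-df within-ecotype component spans the factor."""
    y = rng.standard_normal(48)
    cs = ma.ContrastSet.build(
        "Genotype",
        {
            "ecotype": [-1, -1, -1, 3],  # Eutrema vs the three Arabidopsis lines
            "within": [[1, -1, 0, 0], [1, 1, -2, 0]],
        },
    )
    tab = ma.contrast_anova(y, design_4x3, {"Genotype": cs})
    assert tab.table.loc["Genotype:ecotype", "df"] == 1
    assert tab.table.loc["Genotype:within", "df"] == 2
    total = tab.table.loc["Genotype:ecotype", "sum_sq"] + tab.table.loc["Genotype:within", "sum_sq"]
    sat = ma.fit_anova(y, design_4x3)
    assert total == pytest.approx(sat.table.loc["Genotype", "sum_sq"], rel=1e-10)


def test_pure_linear_trend_has_no_deviation(design_4x3, rng):
    d = design_4x3
    y = 2.0 * d.codes["Salt"].astype(float) + residual_noise(d, rng) * 0.1
    cs = ma.ContrastSet.build("Salt", {"linear": [-1, 0, 1]})
    tab = ma.contrast_anova(y, d, {"Salt": cs})
    assert tab.table.loc["Salt:deviations", "sum_sq"] == pytest.approx(0.0, abs=1e-12)


def test_contrast_validation():
    with pytest.raises(ValueError, match="sum to 0"):
        ma.ContrastSet.build("Salt", {"bad": [1, 0, 1]})
    with pytest.raises(ValueError, match="orthogonal"):
        ma.ContrastSet.build("Salt", {"c1": [-1, 0, 1], "c2": [-1, 1, 0]})
    with pytest.raises(ValueError, match="zero row"):
        ma.ContrastSet.build("A", {"c": [0, 0, 0]})


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------


def test_predict_saturated_equals_cell_means(design_4x3, rng):
    y = rng.standard_normal(48)
    preds = ma.predict_cells(y, design_4x3, ModelSpec.saturated(design_4x3))
    code, ncell = design_4x3.cell_codes()
    means = np.array([y[code == k].mean() for k in range(ncell)])
    np.testing.assert_allclose(preds["prediction"].to_numpy(), means, rtol=1e-12)


def test_predict_null_is_grand_mean(design_4x3, rng):
    y = rng.standard_normal(48)
    preds = ma.predict_cells(y, design_4x3, ModelSpec())
    np.testing.assert_allclose(preds["prediction"].to_numpy(), y.mean(), rtol=1e-12)


def test_predict_additive_closed_form(design_4x3, rng):
    """Balanced additive fit: row mean + column mean - grand mean."""
    d = design_4x3
    y = rng.standard_normal(48)
    preds = ma.predict_cells(y, d, ModelSpec(frozenset({("Genotype",), ("Salt",)})))
    gm = y.mean()
    for _, row in preds.iterrows():
        a = y[d.codes["Genotype"] == d.levels["Genotype"].index(row["Genotype"])].mean()
        b = y[d.codes["Salt"] == d.levels["Salt"].index(row["Salt"])].mean()
        assert row["prediction"] == pytest.approx(a + b - gm, rel=1e-10)


def test_null_pvalues_uniform(design_2x2):
    """Saturated one-way p-values under pure noise are uniform (KS check)."""
    r = np.random.default_rng(7)
    Y = r.standard_normal((design_2x2.N, 10_000))
    dec = decompose(Y, design_2x2)
    ss1 = dec.ss_matrix().sum(axis=1)
    _, p = f_test(ss1, dec.df_vector().sum(), dec.ss_res, dec.df_res)
    ks = stats.kstest(p, "uniform").statistic
    assert ks < 0.05
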
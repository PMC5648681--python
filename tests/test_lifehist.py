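import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qstfst.lifehist import (brood_growth, filter_growth_broods, fit_trait_glm,
                             habitat_contrast, lsmeans, size_corrected,
                             trait_correlation, trait_pca, tukey_hsd)


def one_way_data(means, n_per, sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in enumerate(means):
        for _ in range(n_per):
            rows.append({"population": f"G{g}", "y": mu + rng.normal(0, sd)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLM / sequential ANOVA

def test_one_way_anova_matches_hand_computation():
    df = one_way_data([1.0, 2.0, 4.0], n_per=4, sd=1.0, seed=1)
    fit = fit_trait_glm(df, "y")
    # independent oracle: textbook group/residual sums of squares
    grand = df["y"].mean()
    groups = [g["y"].to_numpy() for _, g in df.groupby("population")]
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_oracle = (ss_b / 2) / (ss_w / (len(df) - 3))
    row = fit.anova.set_index("term").loc["C(population)"]
    assert row["F"] == pytest.approx(f_oracle, abs=1e-8)
    assert row["df_num"] == 2 and row["df_den"] == len(df) - 3


def test_sequential_ss_sum_to_total():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "population": np.repeat(["A", "B", "C"], 10),
        "x": rng.normal(size=30),
    })
    df["y"] = 0.5 * df["x"] + df["population"].map(
        {"A": 0, "B": 1, "C": 2}) + rng.normal(size=30)
    fit = fit_trait_glm(df, "y", covariate="x", include_interaction=True)
    total_ss = float(((df["y"] - df["y"].mean()) ** 2).sum())
    assert fit.anova["ss"].sum() == pytest.approx(total_ss, rel=1e-8)


def test_no_population_effect_when_response_is_covariate():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({
        "population": np.repeat(["A", "B", "C", "D"], 12),
        "x": rng.normal(size=48),
    })
    df["y"] = df["x"] + rng.normal(0, 1e-6, size=48)
    fit = fit_trait_glm(df, "y", covariate="x")
    row = fit.anova.set_index("term").loc["C(population)"]
    assert row["F"] < 3.0 and row["p"] > 0.01


def test_interaction_detection_power():
    """A real slope-by-population interaction is found at alpha=0.05."""
    hits = 0
    for s in range(40):
        rng = np.random.default_rng(s)
        pop = np.repeat(["A", "B"], 30)
        x = rng.normal(size=60)
        slope = np.where(pop == "A", 1.0, 2.0)  # strong interaction
        y = slope * x + rng.normal(0, 0.5, size=60)
        df = pd.DataFrame({"population": pop, "x": x, "y": y})
        fit = fit_trait_glm(df, "y", covariate="x", include_interaction=True)
        p = fit.anova.set_index("term").iloc[2]["p"]
        hits += p < 0.05
    assert hits / 40 > 0.8


def test_interaction_rank_deficiency_names_population():
    df = one_way_data([1, 2], n_per=3, sd=1, seed=0)
    df = pd.concat([df, pd.DataFrame([{"population": "G9", "y": 5.0}])],
                   ignore_index=True)
    df["x"] = np.arange(len(df), dtype=float)
    with pytest.raises(ValueError, match="G9"):
        fit_trait_glm(df, "y", covariate="x", include_interaction=True)


# ---------------------------------------------------------------------------
# Tukey-Kramer

def test_tukey_identical_groups_p_one():
    vals = [1.0, 2.0, 3.0, 4.0]
    df = pd.DataFrame({
        "population": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
        "y": vals + vals + [10.0, 11.0, 12.0, 13.0],
    })
    tk = tukey_hsd(fit_trait_glm(df, "y"))
    assert tk.p_matrix.loc["A", "B"] == pytest.approx(1.0, abs=1e-9)
    assert tk.p_matrix.loc["A", "C"] < 0.01


def test_tukey_matches_studentized_range_oracle():
    """Balanced 3-group toy versus a direct q-distribution computation."""
    df = one_way_data([0.0, 1.0, 3.0], n_per=5, sd=1.0, seed=7)
    fit = fit_trait_glm(df, "y")
    tk = tukey_hsd(fit)
    groups = {g: d["y"].to_numpy() for g, d in df.groupby("population")}
    k, n = 3, 5
    dfe = k * (n - 1)
    mse = np.mean([np.var(v, ddof=1) for v in groups.values()])
    for g1, g2 in [("G0", "G1"), ("G0", "G2"), ("G1", "G2")]:
        q = abs(groups[g1].mean() - groups[g2].mean()) / np.sqrt(mse / n)
        p_oracle = stats.studentized_range.sf(q, k, dfe)
        assert tk.p_matrix.loc[g1, g2] == pytest.approx(p_oracle, abs=1e-6)


def test_tukey_adjusted_p_at_least_unadjusted():
    rng = np.random.default_rng(5)
    df = one_way_data([0, 0.5, 1.0, 1.5], n_per=8, sd=1.0, seed=5)
    fit = fit_trait_glm(df, "y")
    tk = tukey_hsd(fit)
    mse = fit.result.scale
    dfe = fit.df_resid
    for _, row in tk.table.iterrows():
        t = abs(row["diff"]) / row["se"]
        p_unadj = 2 * stats.t.sf(t, dfe)
        assert row["p_adj"] >= p_unadj - 1e-12


def test_tukey_degenerate_zero_residual_variance():
    df = pd.DataFrame({"population": ["A"] * 3 + ["B"] * 3,
                       "y": [1.0] * 3 + [2.0] * 3})
    tk = tukey_hsd(fit_trait_glm(df, "y"))
    assert tk.degenerate


# ---------------------------------------------------------------------------
# LS-means

def test_lsmeans_equal_raw_means_without_covariate():
    df = one_way_data([1.0, 3.0], n_per=6, sd=1.0, seed=8)
    lsm = lsmeans(fit_trait_glm(df, "y")).set_index("population")
    raw = df.groupby("population")["y"].mean()
    for g in raw.index:
        assert lsm.loc[g, "lsmean"] == pytest.approx(raw[g], abs=1e-10)


def test_lsmeans_two_group_ancova_hand_oracle():
    """Adjusted means mu_g + beta*(xbar - xbar_g) from pooled within-group
    regression, computed independently."""
    rng = np.random.default_rng(9)
    df = pd.DataFrame({
        "population": np.repeat(["A", "B"], 10),
        "x": np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)]),
    })
    df["y"] = 2.0 + 1.5 * df["x"] + (df["population"] == "B") * 1.0 \
        + rng.normal(0, 0.3, 20)
    fit = fit_trait_glm(df, "y", covariate="x")
    lsm = lsmeans(fit).set_index("population")
    # oracle: pooled within-group slope
    sxx = sxy = 0.0
    for _, g in df.groupby("population"):
        xc = g["x"] - g["x"].mean()
        sxx += (xc**2).sum()
        sxy += (xc * (g["y"] - g["y"].mean())).sum()
    beta = sxy / sxx
    xbar = df["x"].mean()
    for g, sub in df.groupby("population"):
        adj = sub["y"].mean() + beta * (xbar - sub["x"].mean())
        assert lsm.loc[g, "lsmean"] == pytest.approx(adj, abs=1e-8)


def test_lsmeans_extrapolation_flag():
    df = pd.DataFrame({
        "population": ["A"] * 5 + ["B"] * 5,
        "x": list(np.linspace(0, 1, 5)) + list(np.linspace(10, 11, 5)),
    })
    df["y"] = df["x"] * 1.0
    lsm = lsmeans(fit_trait_glm(df, "y", covariate="x"))
    assert lsm["extrapolated"].all()  # grand mean ~5.5 outside both ranges


# ---------------------------------------------------------------------------
# residuals, correlations, filters, growth

def test_size_corrected_moments():
    rng = np.random.default_rng(11)
    df = pd.DataFrame({"x": rng.normal(size=50)})
    df["t"] = 2 * df["x"] + rng.normal(size=50)
    sc = size_corrected(df, "t", "x")
    assert abs(sc.mean()) < 1e-10
    assert abs(sc.std(ddof=0) - 1) < 1e-10
    assert not sc.attrs["degenerate"]


def test_size_corrected_degenerate_and_errors():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    df["t"] = 2 * df["x"]
    sc = size_corrected(df, "t", "x")
    assert sc.attrs["degenerate"] and np.allclose(sc, 0.0)
    df["c"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        size_corrected(df, "t", "c")


def test_trait_correlation_extremes():
    x = np.arange(10.0)
    assert trait_correlation(x, -x).r == pytest.approx(-1.0)
    rng = np.random.default_rng(0)
    r = trait_correlation(x, rng.permutation(x)).n
    assert r == 10
    with pytest.raises(ValueError, match="zero variance"):
        trait_correlation(x, np.ones(10))


def test_trait_correlation_null_p_uniform():
    rng = np.random.default_rng(1)
    pvals = [trait_correlation(rng.normal(size=20), rng.normal(size=20)).p
             for _ in range(500)]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_filter_growth_broods_boundaries():
    df = pd.DataFrame({"n_reared": [4, 5, 19, 20]})
    kept, counts = filter_growth_broods(df)
    assert sorted(kept["n_reared"]) == [5, 19]
    assert counts == {"retained": 2, "excluded": 2}
    empty, counts0 = filter_growth_broods(df.iloc[:0])
    assert len(empty) == 0 and counts0 == {"retained": 0, "excluded": 0}


def test_brood_growth():
    row = pd.Series({"fry_tl_day0_mm": 10.0, "fry_tl_day35_mm": 14.5})
    assert brood_growth(row, 0, 35) == pytest.approx(4.5)
    with pytest.raises(KeyError, match="70"):
        brood_growth(row, 0, 70)
    df = pd.DataFrame([row, row])
    assert np.allclose(brood_growth(df, 0, 35), 4.5)


# ---------------------------------------------------------------------------
# trait PCA

def test_trait_pca_perfectly_correlated_pair():
    rng = np.random.default_rng(12)
    x = rng.normal(size=30)
    df = pd.DataFrame({"a": x, "b": 2 * x + 1})
    res = trait_pca(df)
    assert res.explained[0] == pytest.approx(1.0, abs=1e-10)


def test_trait_pca_eigen_oracle_and_orthonormality():
    rng = np.random.default_rng(13)
    df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
    df["d"] = df["a"] * 0.5 + df["d"]
    res = trait_pca(df)
    corr = np.corrcoef((df - df.mean()).div(df.std(ddof=1)).T)
    evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    assert np.allclose(res.explained * evals.sum(), evals, atol=1e-10)
    L = res.loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(4), atol=1e-10)
    assert res.explained.sum() == pytest.approx(1.0, abs=1e-12)


def test_trait_pca_constant_column_error():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 1, 1, 1]})
    with pytest.raises(ValueError, match="b"):
        trait_pca(df)


# ---------------------------------------------------------------------------
# habitat contrast

def test_habitat_contrast_identical_means():
    out = habitat_contrast([1, 1, 1, 1, 1, 1, 1, 1],
                           ["lake"] * 4 + ["per"] * 4)
    assert out["F"] == pytest.approx(0.0, abs=1e-12)
    assert (out["df_num"], out["df_den"]) == (1, 6)


def test_habitat_contrast_matches_hand_anova():
    means = np.array([1.0, 1.2, 0.9, 1.1, 2.0, 2.3, 1.9, 2.1])
    labels = ["lake"] * 4 + ["per"] * 4
    out = habitat_contrast(means, labels)
    g1, g2 = means[:4], means[4:]
    grand = means.mean()
    ssb = 4 * (g1.mean() - grand) ** 2 + 4 * (g2.mean() - grand) ** 2
    ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
    f_hand = ssb / (ssw / 6)
    assert out["F"] == pytest.approx(f_hand, rel=1e-10)
    with pytest.raises(ValueError, match=">= 2"):
        habitat_contrast(means[:5], ["lake"] * 4 + ["per"])
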
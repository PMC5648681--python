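"""Common-garden life-history trait statistics.

ANCOVA-style general linear models with sequential F-tests, Tukey-Kramer
post-hoc comparisons on covariate-adjusted means, least-square means,
size-corrected trade-off residuals, correlation-matrix trait PCA, the
growth-brood density filter, and the lake-versus-peripheral habitat
contrast on population-level adjusted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitGlm",
    "fit_trait_glm",
    "TukeyResult",
    "tukey_hsd",
    "lsmeans",
    "size_corrected",
    "CorrelationResult",
    "trait_correlation",
    "filter_growth_broods",
    "brood_growth",
    "CorrPca",
    "trait_pca",
    "habitat_contrast",
]


# ---------------------------------------------------------------------------
# general linear models

@dataclass
class TraitGlm:
    """Fitted trait model plus its entry-order ANOVA table."""

    response: str
    covariate: str | None
    population: str
    anova: pd.DataFrame = field(repr=False)
    result: object = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def df_resid(self) -> float:
        return float(self.result.df_resid)


def fit_trait_glm(
    records: pd.DataFrame,
    response: str,
    covariate: str | None = None,
    include_interaction: bool = False,
    population: str = "population",
    tests: str = "sequential",
) -> TraitGlm:
    """OLS fit of ``response ~ covariate + population (+ interaction)``.

    F-tests are sequential (entry order: covariate, population,
    interaction), matching the conventional ANCOVA table layout;
    ``tests='marginal'`` switches to partial (type III) tests.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    cols = [population, response] + ([covariate] if covariate else [])
    data = records[cols].dropna().copy()
    if data[population].nunique() < 2:
        raise ValueError("at least 2 populations required")
    if include_interaction and covariate:
        sizes = data.groupby(population).size()
        thin = sizes[sizes < 2]
        if len(thin):
            raise ValueError(
                f"interaction model is rank deficient: population(s) with a "
                f"single record: {list(thin.index)}"
            )
    terms = []
    if covariate:
        terms.append(covariate)
    terms.append(f"C({population})")
    if include_interaction and covariate:
        terms.append(f"{covariate}:C({population})")
    formula = f"{response} ~ " + " + ".join(terms)
    res = smf.ols(formula, data=data).fit()
    if res.df_resid <= 0:
        raise ValueError("model saturated: no residual degrees of freedom")
    df_resid = float(res.df_resid)
    ms_resid = float(res.ssr / res.df_resid)

    if tests == "sequential":
        # entry-order (type I) tests from nested fits: patsy reorders terms
        # in the design matrix, so the increments are computed explicitly
        rows = []
        prev = smf.ols(f"{response} ~ 1", data=data).fit()
        for i, term in enumerate(terms):
            cur = smf.ols(f"{response} ~ " + " + ".join(terms[: i + 1]),
                          data=data).fit()
            d_ss = float(prev.ssr - cur.ssr)
            d_df = float(prev.df_resid - cur.df_resid)
            fval = (d_ss / d_df) / ms_resid if d_df > 0 and ms_resid > 0 else np.nan
            rows.append({
                "term": term, "df_num": d_df, "df_den": df_resid, "ss": d_ss,
                "F": fval,
                "p": float(stats.f.sf(fval, d_df, df_resid))
                if np.isfinite(fval) else np.nan,
            })
            prev = cur
    else:
        table = sm.stats.anova_lm(res, typ=3)
        rows = [{
            "term": term,
            "df_num": float(table.loc[term, "df"]),
            "df_den": df_resid,
            "ss": float(table.loc[term, "sum_sq"]),
            "F": float(table.loc[term, "F"]),
            "p": float(table.loc[term, "PR(>F)"]),
        } for term in table.index if term not in ("Residual", "Intercept")]
    rows.append({
        "term": "Residual", "df_num": df_resid, "df_den": np.nan,
        "ss": float(res.ssr), "F": np.nan, "p": np.nan,
    })
    return TraitGlm(response, covariate, population,
                    pd.DataFrame(rows), res, data)


def _adjusted_means(fit: TraitGlm) -> tuple[list, np.ndarray, np.ndarray]:
    """Population means at the grand covariate mean, with their covariance."""
    from patsy import build_design_matrices

    levels = sorted(fit.data[fit.population].unique())
    new = pd.DataFrame({fit.population: levels})
    if fit.covariate:
        new[fit.covariate] = fit.data[fit.covariate].mean()
    design_info = fit.result.model.data.design_info
    (L,) = build_design_matrices([design_info], new)
    L = np.asarray(L)
    means = L @ fit.result.params.to_numpy()
    cov = L @ fit.result.cov_params().to_numpy() @ L.T
    return levels, means, cov


@dataclass
class TukeyResult:
    levels: list
    p_matrix: pd.DataFrame = field(repr=False)
    table: pd.DataFrame = field(repr=False)
    degenerate: bool = False


def tukey_hsd(fit: TraitGlm) -> TukeyResult:
    """Tukey-Kramer studentized-range comparisons of adjusted means.

    The Kramer form (pair-specific standard errors from the model
    covariance) keeps the test valid for unbalanced group sizes; p-values
    come from the studentized range distribution with the model's residual
    degrees of freedom.
    """
    levels, means, cov = _adjusted_means(fit)
    k = len(levels)
    df_resid = fit.df_resid
    scale = float(fit.result.scale)
    pmat = np.ones((k, k))
    rows = []
    y_var = float(np.var(fit.data[fit.response].to_numpy(dtype=float)))
    degenerate = (not np.isfinite(scale)) or scale <= 1e-12 * max(y_var, 1e-300)
    for i in range(k):
        for j in range(i):
            diff = means[i] - means[j]
            if degenerate:
                p = 1.0 if diff == 0 else 0.0
                se = 0.0
            else:
                se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
                if se == 0:
                    p = 1.0
                else:
                    q = abs(diff) / (se / np.sqrt(2.0))
                    p = float(stats.studentized_range.sf(q, k, df_resid))
            p = min(max(p, 0.0), 1.0)
            pmat[i, j] = pmat[j, i] = p
            rows.append((levels[i], levels[j], float(diff), se, p))
    return TukeyResult(
        levels,
        pd.DataFrame(pmat, index=levels, columns=levels),
        pd.DataFrame(rows, columns=["pop1", "pop2", "diff", "se", "p_adj"]),
        degenerate=degenerate,
    )


def lsmeans(fit: TraitGlm, alpha: float = 0.05) -> pd.DataFrame:
    """Least-square (covariate-adjusted) population means with 95% CIs.

    Means are evaluated at the grand mean of the covariate; the
    ``extrapolated`` column flags populations whose own covariate range
    does not contain that value.
    """
    levels, means, cov = _adjusted_means(fit)
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    tcrit = stats.t.ppf(1 - alpha / 2, fit.df_resid)
    extrapolated = []
    if fit.covariate:
        grand = fit.data[fit.covariate].mean()
        for lev in levels:
            x = fit.data.loc[fit.data[fit.population] == lev, fit.covariate]
            extrapolated.append(not (x.min() <= grand <= x.max()))
    else:
        extrapolated = [False] * len(levels)
    return pd.DataFrame({
        "population": levels,
        "lsmean": means,
        "se": ses,
        "ci_low": means - tcrit * ses,
        "ci_high": means + tcrit * ses,
        "extrapolated": extrapolated,
    })


# ---------------------------------------------------------------------------
# trade-offs and correlations

def size_corrected(records: pd.DataFrame, trait: str, covariate: str) -> pd.Series:
    """Standardized residuals of ``trait`` regressed on ``covariate``.

    Residuals are divided by their (population, ddof=0) standard deviation
    so the output has mean 0 and SD 1 exactly.  A zero residual SD (trait
    fully explained) yields all-zero output with ``attrs['degenerate']``.
    """
    data = records[[trait, covariate]].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 records")
    x = data[covariate].to_numpy(dtype=float)
    y = data[trait].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError(f"covariate '{covariate}' is constant")
    xc = x - x.mean()
    beta = float(np.sum(xc * y) / np.sum(xc**2))
    resid = y - y.mean() - beta * xc
    sd = float(resid.std(ddof=0))
    out = pd.Series(np.zeros_like(resid) if sd == 0 else resid / sd,
                    index=data.index, name=f"{trait}_sizecorr")
    out.attrs["degenerate"] = sd == 0
    return out


class CorrelationResult(NamedTuple):
    r: float
    n: int
    p: float


def trait_correlation(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), len(x), float(p))


# ---------------------------------------------------------------------------
# brood filters and growth

def filter_growth_broods(
    broods: pd.DataFrame,
    count_col: str = "n_reared",
    min_n: int = 5,
    max_n: int = 19,
) -> tuple[pd.DataFrame, dict]:
    """Retain broods whose reared offspring count is in [min_n, max_n].

    Restricting growth comparisons to mid-sized broods limits the bias
    that extreme rearing densities would otherwise introduce.  Returns the
    retained subset and {'retained': r, 'excluded': e}.
    """
    if len(broods) == 0:
        return broods.copy(), {"retained": 0, "excluded": 0}
    keep = broods[count_col].between(min_n, max_n, inclusive="both")
    return broods[keep].copy(), {
        "retained": int(keep.sum()),
        "excluded": int((~keep).sum()),
    }


def brood_growth(brood, t1: int, t2: int):
    """Mean fry total-length gain (mm) between measurement days t1 and t2."""
    c1, c2 = f"fry_tl_day{t1}_mm", f"fry_tl_day{t2}_mm"
    if isinstance(brood, pd.DataFrame):
        for c in (c1, c2):
            if c not in brood.columns:
                raise KeyError(f"missing time point column '{c}'")
        return brood[c2] - brood[c1]
    if c1 not in brood or c2 not in brood or pd.isna(brood[c1]) or pd.isna(brood[c2]):
        raise KeyError(f"missing time point for growth {t1}->{t2}")
    return float(brood[c2] - brood[c1])


# ---------------------------------------------------------------------------
# correlation-matrix PCA

@dataclass
class CorrPca:
    columns: list
    loadings: pd.DataFrame = field(repr=False)
    scores: np.ndarray = field(repr=False)
    explained: np.ndarray = field(repr=False)
    flagged: pd.DataFrame = field(repr=False, default=None)


def trait_pca(table: pd.DataFrame, loading_flag: float = 0.4) -> CorrPca:
    """PCA of a trait (or site-feature) table on its correlation matrix.

    Columns are standardized, the correlation matrix eigendecomposed, and
    components ordered by eigenvalue.  Sign convention: the largest-
    magnitude loading on each axis is positive.  Loadings with magnitude
    above ``loading_flag`` are flagged as the axis's defining variables.
    """
    num = table.select_dtypes(include=[np.number]).dropna()
    if num.shape[0] < 3 or num.shape[1] < 2:
        raise ValueError("need >= 3 rows and >= 2 numeric columns")
    sds = num.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    Z = (num - num.mean()) / sds
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    for c in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, c])), c] < 0:
            evecs[:, c] *= -1
    explained = evals / evals.sum()
    pcs = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=num.columns, columns=pcs)
    scores = Z.to_numpy() @ evecs
    flagged = (loadings.abs() > loading_flag)
    return CorrPca(list(num.columns), loadings, scores, explained, flagged)


# ---------------------------------------------------------------------------
# habitat contrast

def habitat_contrast(population_lsmeans, habitat_labels) -> dict:
    """One-way contrast of population-level adjusted means between habitats.

    Operates on the population means (one value per population), so the
    denominator degrees of freedom are n_populations - 2.
    """
    y = np.asarray(population_lsmeans, dtype=float)
    labels = np.asarray(habitat_labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two habitat classes required")
    groups = [y[labels == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each habitat class needs >= 2 populations")
    df1, df2 = 1, len(y) - 2
    grand = y.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if ss_w == 0:
        f = 0.0 if ss_b <= 1e-24 else np.inf  # identical data in both classes
    else:
        f = (ss_b / df1) / (ss_w / df2)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return {"F": float(f), "df_num": df1, "df_den": df2, "p": p}
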
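"""Nested half-sib variance components and Q_ST.

The breeding design is two-level: populations, sires nested within
population, one brood (record) per dam.  The model

    y = mu (+ beta * covariate) + u_pop + u_sire(pop) + e

yields V_b (between populations), V_male (between sires within
population) and V_res.  Dams are unreplicated within sires, so dam and
residual variance are confounded by design; the within-population
variance is V_w = V_male + V_res, and

    Q_ST = V_b / (2 * V_w + V_b).

REML estimation goes through a profiled mixed-model fit; a
method-of-moments nested ANOVA (Henderson I with unbalanced expected
mean-square coefficients) is the flagged fallback when REML fails to
converge and the cross-check on balanced designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .matrices import DistanceMatrix

__all__ = [
    "VarianceComponents",
    "fit_nested_ranef",
    "mom_nested_anova",
    "qst",
    "pairwise_qst",
]


@dataclass
class VarianceComponents:
    v_between: float
    v_male: float
    v_res: float
    method: str = "reml"
    converged: bool = True
    boundary: bool = False
    degenerate: bool = False
    n_obs: int = 0
    n_populations: int = 0

    @property
    def v_within(self) -> float:
        return self.v_male + self.v_res

    def as_dict(self) -> dict:
        return {
            "v_between": self.v_between,
            "v_male": self.v_male,
            "v_res": self.v_res,
            "v_within": self.v_within,
            "method": self.method,
            "converged": self.converged,
            "boundary": self.boundary,
            "degenerate": self.degenerate,
            "n_obs": self.n_obs,
            "n_populations": self.n_populations,
        }


def _validate(df: pd.DataFrame, response: str, population: str, sire: str) -> None:
    if df[population].nunique() < 2:
        raise ValueError("at least 2 populations required")
    sires_per_pop = df.groupby(population)[sire].nunique()
    if (sires_per_pop < 2).all():
        raise ValueError("at least one population needs >= 2 sires")


def mom_nested_anova(
    df: pd.DataFrame,
    response: str = "y",
    population: str = "population",
    sire: str = "sire",
    covariate: str | None = None,
) -> VarianceComponents:
    """Method-of-moments components from the unbalanced nested ANOVA.

    Uses Henderson-style expected mean squares: with n_ij observations for
    sire j in population i, n_i per population and N total,

        E[MS_res]       = V_res
        E[MS_sire(pop)] = V_res + c1 * V_male
        E[MS_pop]       = V_res + c2 * V_male + c3 * V_b

    with the standard unbalanced coefficients.  A covariate, when given,
    is removed first by ordinary regression (flagged approximation).
    """
    df = df[[population, sire, response] + ([covariate] if covariate else [])].dropna()
    _validate(df, response, population, sire)
    y = df[response].to_numpy(dtype=float)
    if covariate is not None:
        x = df[covariate].to_numpy(dtype=float)
        xc = x - x.mean()
        denom = float(np.sum(xc**2))
        if denom > 0:
            y = y - xc * float(np.sum(xc * (y - y.mean()))) / denom
    pops = df[population].to_numpy()
    sires = (df[population].astype(str) + "//" + df[sire].astype(str)).to_numpy()

    grand = y.mean()
    n_tot = len(y)
    pop_levels = pd.unique(pops)
    sire_levels = pd.unique(sires)
    P, S = len(pop_levels), len(sire_levels)
    if np.allclose(y, y[0]):
        return VarianceComponents(0.0, 0.0, 0.0, method="mom", degenerate=True,
                                  n_obs=n_tot, n_populations=P)

    ss_pop = ss_sire = ss_res = 0.0
    sum_nij2_over_ni = 0.0
    sum_nij2 = 0.0
    sum_ni2 = 0.0
    for p in pop_levels:
        sel = pops == p
        yp = y[sel]
        n_i = len(yp)
        sum_ni2 += n_i**2
        ss_pop += n_i * (yp.mean() - grand) ** 2
        for s in pd.unique(sires[sel]):
            ys = y[sires == s]
            n_ij = len(ys)
            sum_nij2 += n_ij**2
            sum_nij2_over_ni += n_ij**2 / n_i
            ss_sire += n_ij * (ys.mean() - yp.mean()) ** 2
            ss_res += float(np.sum((ys - ys.mean()) ** 2))

    df_pop = P - 1
    df_sire = S - P
    df_res = n_tot - S
    if df_sire <= 0 or df_res <= 0:
        raise ValueError("design leaves no degrees of freedom for sires/residual")
    ms_pop = ss_pop / df_pop
    ms_sire = ss_sire / df_sire
    ms_res = ss_res / df_res
    c1 = (n_tot - sum_nij2_over_ni) / df_sire
    c2 = (sum_nij2_over_ni - sum_nij2 / n_tot) / df_pop
    c3 = (n_tot - sum_ni2 / n_tot) / df_pop

    v_res = ms_res
    v_male = (ms_sire - ms_res) / c1
    boundary = False
    if v_male < 0:
        v_male, boundary = 0.0, True
    v_b = (ms_pop - ms_res - c2 * v_male) / c3
    if v_b < 0:
        v_b, boundary = 0.0, True
    return VarianceComponents(
        float(v_b), float(v_male), float(v_res), method="mom",
        boundary=boundary, n_obs=n_tot, n_populations=P,
    )


def fit_nested_ranef(
    df: pd.DataFrame,
    response: str = "y",
    population: str = "population",
    sire: str = "sire",
    covariate: str | None = None,
    method: str = "reml",
) -> VarianceComponents:
    """REML variance components for the nested random-intercept model.

    Fits ``response ~ 1 (+ covariate)`` with a random population intercept
    and a sire-within-population variance component; non-negativity holds by
    the profiled parameterisation, and components estimated at the boundary
    are reported as 0 with a boundary flag.  Falls back to
    :func:`mom_nested_anova` (flagged) on non-convergence.
    """
    import statsmodels.formula.api as smf

    cols = [population, sire, response] + ([covariate] if covariate else [])
    data = df[cols].dropna().copy()
    _validate(data, response, population, sire)
    data["_sire"] = data[population].astype(str) + "//" + data[sire].astype(str)
    n_obs, n_pops = len(data), data[population].nunique()
    y = data[response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return VarianceComponents(0.0, 0.0, 0.0, degenerate=True,
                                  n_obs=n_obs, n_populations=n_pops)
    if method == "mom":
        return mom_nested_anova(df, response, population, sire, covariate)

    fixed = f"{response} ~ 1" + (f" + {covariate}" if covariate else "")
    ok = False
    y_var = float(np.var(y))
    for optimizer in ("bfgs", "lbfgs", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    fixed, data, groups=data[population], re_formula="1",
                    vc_formula={"male": "0 + C(_sire)"},
                )
                res = model.fit(reml=True, method=optimizer, maxiter=500)
            v_b = float(res.cov_re.iloc[0, 0])
            v_male = float(res.vcomp[0])
            v_res = float(res.scale)
            # a collapsed residual variance means the profiled likelihood is
            # degenerate (e.g. noise-free data); moments handle it exactly
            ok = (bool(res.converged)
                  and np.isfinite([v_b, v_male, v_res]).all()
                  and v_res > 1e-10 * y_var)
        except Exception:
            ok = False
        if ok:
            break
    if not ok:
        vc = mom_nested_anova(df, response, population, sire, covariate)
        vc.converged = False
        return vc
    tol = 1e-8 * (v_b + v_male + v_res)
    boundary = v_b <= tol or v_male <= tol
    return VarianceComponents(
        max(v_b, 0.0) if v_b > tol else 0.0,
        max(v_male, 0.0) if v_male > tol else 0.0,
        v_res,
        method="reml", boundary=boundary, n_obs=n_obs, n_populations=n_pops,
    )


def qst(vc: VarianceComponents) -> float:
    """Q_ST = V_b / (2 * V_w + V_b) from fitted components."""
    if vc.v_between < 0 or vc.v_male < 0 or vc.v_res < 0:
        raise ValueError("variance components must be non-negative")
    denom = 2.0 * vc.v_within + vc.v_between
    if denom == 0:
        raise ValueError("all variance components are zero; Q_ST undefined")
    return float(vc.v_between / denom)


def pairwise_qst(
    df: pd.DataFrame,
    response: str = "y",
    population: str = "population",
    sire: str = "sire",
    covariate: str | None = None,
    mode: str = "subset",
    method: str = "reml",
) -> tuple[DistanceMatrix, dict]:
    """Q_ST for every unordered population pair.

    ``mode='subset'`` (default) refits the nested model on each pair's
    records.  ``mode='global'`` is the sensitivity alternative: the
    within-population components come from one fit on all populations,
    and only the pair's between-population variance is re-estimated (by
    moments on the pair subset), so pairs share a common V_w.  Degenerate
    pairs are NaN in the matrix and logged.
    """
    pops = list(pd.unique(df[population]))
    k = len(pops)
    vals = np.full((k, k), 0.0)
    log: dict[str, dict] = {}
    if mode == "global":
        vc_all = fit_nested_ranef(df, response, population, sire, covariate,
                                  method=method)
    for i, j in combinations(range(k), 2):
        pair = df[df[population].isin([pops[i], pops[j]])]
        key = f"{pops[i]}|{pops[j]}"
        try:
            if mode == "global":
                vb_pair = mom_nested_anova(pair, response, population, sire,
                                           covariate).v_between
                vc = VarianceComponents(
                    vb_pair, vc_all.v_male, vc_all.v_res, method="global",
                    degenerate=vc_all.degenerate,
                    n_obs=len(pair), n_populations=2,
                )
            else:
                vc = fit_nested_ranef(pair, response, population, sire,
                                      covariate, method=method)
            value = np.nan if vc.degenerate else qst(vc)
            log[key] = vc.as_dict()
        except ValueError as exc:
            value, vc = np.nan, None
            log[key] = {"error": str(exc)}
        vals[i, j] = vals[j, i] = value
    return DistanceMatrix(pops, vals), log
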
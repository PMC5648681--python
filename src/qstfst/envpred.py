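"""Colwell environmental predictability statistics and site ordination.

Colwell's information-theoretic decomposition treats a monthly series as
a months-of-year x state contingency table: constancy C measures how
uniform the variable is across the whole year, contingency M how
repeatable the seasonal pattern is, and predictability P = C + M.  A
habitat can be predictable because it never changes (high C) or because
it changes the same way every year (high M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifehist import CorrPca, trait_pca

__all__ = ["ColwellStats", "colwell_stats", "summarize_site", "env_pca"]


@dataclass
class ColwellStats:
    predictability: float
    constancy: float
    contingency: float
    n_bins: int
    degenerate: bool = False


def _entropy(counts: np.ndarray) -> float:
    z = counts.sum()
    p = counts[counts > 0] / z
    return float(-np.sum(p * np.log(p)))


def colwell_stats(
    values,
    months=None,
    n_bins: int = 10,
    binning: str = "width",
) -> ColwellStats:
    """Colwell's P, C and M for one monthly series.

    Values are binned into ``n_bins`` states — equal-width intervals over
    the observed range by default (the hydrological convention; the top
    interval is right-closed), or equal-frequency quantile bins with
    ``binning='frequency'``.  With months-of-year i (rows), state bins j
    (columns), counts N_ij and entropies H(X), H(Y), H(XY):

        C = 1 - H(Y)/log(s),  M = (H(X) + H(Y) - H(XY))/log(s),  P = C + M

    The normalisation by log(n_bins) makes the result independent of the
    logarithm base.  A constant series occupies a single state and returns
    (P, C, M) = (1, 1, 0) with a degenerate-range flag.
    """
    x = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(x) < 12:
        raise ValueError("need at least one full year of monthly data")
    if months is None:
        months = np.arange(len(x)) % 12
    months = np.asarray(months, dtype=int) % 12

    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return ColwellStats(1.0, 1.0, 0.0, n_bins, degenerate=True)
    if binning == "width":
        states = np.clip(
            np.floor((x - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1
        )
    elif binning == "frequency":
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
        states = np.searchsorted(edges, x, side="left")
    else:
        raise ValueError("binning must be 'width' or 'frequency'")

    table = np.zeros((12, n_bins))
    np.add.at(table, (months, states), 1.0)
    hx = _entropy(table.sum(axis=1))
    hy = _entropy(table.sum(axis=0))
    hxy = _entropy(table.ravel())
    logs = np.log(n_bins)
    c = 1.0 - hy / logs
    m = (hx + hy - hxy) / logs
    return ColwellStats(c + m, c, m, n_bins)


def summarize_site(
    series: pd.DataFrame,
    flow: bool,
    deep_water_close: bool,
    altitude: float,
    variables: tuple[str, ...] = ("temperature_c", "precipitation_mm"),
    n_bins: int = 10,
) -> pd.Series:
    """Site feature vector: per-variable max/min/mean and C, M, P, plus
    0/1-coded flow and deep-water flags and altitude.

    These are the descriptors used to ordinate environmental similarity of
    sampling sites (lake versus peripheral habitats).
    """
    feats: dict[str, float] = {}
    months = series["month"].to_numpy() - 1 if "month" in series else None
    for var in variables:
        if var not in series:
            raise KeyError(f"missing variable '{var}'")
        vals = series[var].to_numpy(dtype=float)
        short = var.split("_")[0]
        feats[f"{short}_max"] = float(vals.max())
        feats[f"{short}_min"] = float(vals.min())
        feats[f"{short}_mean"] = float(vals.mean())
        cw = colwell_stats(vals, months=months, n_bins=n_bins)
        feats[f"{short}_C"] = cw.constancy
        feats[f"{short}_M"] = cw.contingency
        feats[f"{short}_P"] = cw.predictability
    feats["flow"] = float(bool(flow))
    feats["deep_water_close"] = float(bool(deep_water_close))
    feats["altitude_m"] = float(altitude)
    return pd.Series(feats)


def env_pca(site_features: pd.DataFrame) -> CorrPca:
    """Correlation-matrix PCA of the site x feature table.

    Constant feature columns (e.g. all sites flowing) carry no ordination
    information and are dropped with a warning before the shared
    correlation-PCA engine runs.
    """
    import warnings

    num = site_features.select_dtypes(include=[np.number])
    sds = num.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant feature column(s): {constant}")
        num = num.drop(columns=constant)
    return trait_pca(num)
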
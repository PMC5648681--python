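"""Q_ST versus F_ST matrix comparison and selection-regime classification.

If trait divergence tracked neutral drift, pairwise Q_ST would rank the
same way as pairwise F_ST.  The association is tested with Spearman's
rank correlation over the population pairs, with significance from a
Mantel-style permutation of one matrix's population labels (cells of a
distance matrix are not independent, so a naive pair-level permutation
is anti-conservative and is provided only as a flagged alternative).
Pairs where trait divergence exceeds the neutral level suggest
directional selection (Q_ST > F_ST); the converse suggests stabilizing
selection (F_ST > Q_ST).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import DistanceMatrix

__all__ = ["MatrixComparison", "spearman_permutation", "classify_selection"]


@dataclass
class MatrixComparison:
    trait: str
    rho: float
    p_value: float
    n_perm: int
    method: str
    pairs: pd.DataFrame = field(repr=False)


def classify_selection(qst_value, fst_value, tolerance: float = 0.0) -> str:
    """Label a population pair by the sign of Q_ST - F_ST.

    Q_ST above F_ST by more than ``tolerance`` suggests directional
    selection on the trait; the converse, stabilizing selection; within
    the tolerance band the regimes are indistinguishable.
    """
    if qst_value is None or fst_value is None or \
            not (np.isfinite(qst_value) and np.isfinite(fst_value)):
        return "missing"
    if qst_value > fst_value + tolerance:
        return "directional"
    if fst_value > qst_value + tolerance:
        return "stabilizing"
    return "indistinguishable"


def _tri_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(k, k=-1)


def spearman_permutation(
    qst: DistanceMatrix,
    fst: DistanceMatrix,
    n_perm: int = 9_999,
    seed: int | None = 0,
    method: str = "mantel",
    trait: str = "",
    tolerance: float = 0.0,
) -> MatrixComparison:
    """Spearman rank association between two distance matrices.

    rho is computed over the lower-triangle pairs with mid-ranked ties.
    ``method='mantel'`` (default) permutes one matrix's population labels
    jointly over rows and columns; ``method='exhaustive'`` enumerates all
    label permutations (feasible for small panels); ``method='pairs'``
    permutes the pair vector directly (anti-conservative, for comparison
    only).  Two-sided p with +1 smoothing: (1 + #{|rho*| >= |rho|}) /
    (n_perm + 1).  Pairs missing in either matrix are excluded listwise.
    """
    common = [l for l in qst.labels if l in set(fst.labels)]
    if len(common) < 4:
        raise ValueError("need at least 4 common populations (>= 6 pairs)")
    q = qst.reindex(common)
    f = fst.reindex(common)
    k = len(common)
    rows, cols = _tri_indices(k)
    qv = q.values[rows, cols]
    fv = f.values[rows, cols]
    valid = np.isfinite(qv) & np.isfinite(fv)
    if valid.sum() < 3:
        raise ValueError("fewer than 3 complete pairs after listwise exclusion")

    qr = stats.rankdata(qv)  # ranks of all cells; missing handled via mask below
    fr = stats.rankdata(fv)

    def rho_of(mask_q, mask_f, m) -> float:
        a = stats.rankdata(mask_q[m])
        b = stats.rankdata(mask_f[m])
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    rho_obs = rho_of(qv, fv, valid)

    # pair index map for a label permutation sigma: cell (i,j) -> (sigma i, sigma j)
    cell_index = np.full((k, k), -1, dtype=int)
    for idx, (i, j) in enumerate(zip(rows, cols)):
        cell_index[i, j] = cell_index[j, i] = idx

    def permuted_rho(sigma: np.ndarray) -> float:
        perm_idx = cell_index[sigma[rows], sigma[cols]]
        return rho_of(qv[perm_idx], fv, np.isfinite(qv[perm_idx]) & np.isfinite(fv))

    rng = np.random.default_rng(seed)
    if method == "mantel":
        count = 0
        for _ in range(n_perm):
            sigma = rng.permutation(k)
            if abs(permuted_rho(sigma)) >= abs(rho_obs) - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        used = n_perm
    elif method == "exhaustive":
        rhos = [permuted_rho(np.asarray(sig)) for sig in permutations(range(k))]
        rhos = np.asarray(rhos)
        p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        used = len(rhos)
    elif method == "pairs":
        idx = np.flatnonzero(valid)
        count = 0
        for _ in range(n_perm):
            shuf = rng.permutation(idx)
            r = rho_of(qv[shuf], fv[idx], np.ones(len(idx), dtype=bool))
            if abs(r) >= abs(rho_obs) - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        used = n_perm
    else:
        raise ValueError("method must be 'mantel', 'exhaustive' or 'pairs'")

    pairs = pd.DataFrame({
        "pop1": [common[i] for i in rows],
        "pop2": [common[j] for j in cols],
        "qst": qv,
        "fst": fv,
    })
    pairs["classification"] = [
        classify_selection(a, b, tolerance) for a, b in zip(qv, fv)
    ]
    return MatrixComparison(trait, rho_obs, float(p), used, method, pairs)
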
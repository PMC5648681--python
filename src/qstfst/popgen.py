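"""Microsatellite population-genetic statistics.

Covers the wild-genotype side of the divergence analysis: observed and
unbiased expected heterozygosity, exact Hardy-Weinberg tests (Markov
chain and full enumeration), genotypic linkage-disequilibrium permutation
tests with Fisher combination across populations, Weir-Cockerham (1984)
theta for multiallelic loci, and individual-level genotype ordination.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import hwe_switch_chain, ld_permutation_counts
from .genepop import GenotypeTable
from .matrices import DistanceMatrix

__all__ = [
    "heterozygosity",
    "HweResult",
    "hwe_exact_test",
    "hwe_exact_enumeration",
    "hwe_table",
    "LdResult",
    "ld_test",
    "weir_cockerham_components",
    "global_fst",
    "pairwise_fst",
    "PcaResult",
    "genotype_pca",
]

_TIE_TOL = 1e-9  # tables with probability equal to observed count as extreme


# ---------------------------------------------------------------------------
# heterozygosity

def heterozygosity(gt: GenotypeTable) -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per population x locus.

    H_O is the fraction of genotyped individuals carrying two different
    alleles; H_E is Nei's unbiased estimator (2n/(2n-1)) * (1 - sum p_k^2)
    with allele frequencies taken over genotyped individuals only.  Cells
    with no genotyped individuals are reported with NaN, not zero.
    """
    rows = []
    for pop in gt.pop_names:
        pmask = gt.pop_mask(pop)
        for li, locus in enumerate(gt.loci):
            mask = pmask & gt.genotyped_mask(li)
            n = int(mask.sum())
            if n == 0:
                rows.append((pop, locus, 0, np.nan, np.nan))
                continue
            pairs = gt.calls[mask, li, :]
            h_obs = float((pairs[:, 0] != pairs[:, 1]).mean())
            _, counts = np.unique(pairs.ravel(), return_counts=True)
            freqs = counts / (2 * n)
            h_exp = 0.0
            if 2 * n > 1:
                h_exp = (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(freqs**2)))
            rows.append((pop, locus, n, h_obs, h_exp))
    return pd.DataFrame(rows, columns=["population", "locus", "n", "h_obs", "h_exp"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact tests

@dataclass
class HweResult:
    p_value: float
    se: float
    n_steps: int
    degenerate: bool = False


def _counts_to_genos(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    k = counts.shape[0]
    genos = []
    for i in range(k):
        for j in range(k):
            c = counts[i, j] if j >= i else 0
            genos.extend([(i, j)] * int(c))
    return np.asarray(genos, dtype=np.int64).reshape(-1, 2)


def _present_alleles(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.int64)
    tri = np.triu(counts)
    m = tri.sum(axis=0) + tri.sum(axis=1)  # allele copies per code
    return m


def hwe_exact_test(
    genotype_counts,
    chain_steps: int = 1_000_000,
    dememorization: int = 100_000,
    seed: int | None = None,
    n_batches: int = 100,
) -> HweResult:
    """Exact Hardy-Weinberg test by Markov chain over genotype tables.

    The chain switches allele copies between individuals, which leaves the
    allele counts fixed and samples genotype tables from their conditional
    distribution under Hardy-Weinberg proportions.  The p-value is the
    proportion of post-dememorisation states whose conditional probability
    is less than or equal to that of the observed table; the Monte-Carlo
    standard error comes from batch proportions.
    """
    counts = np.asarray(genotype_counts, dtype=np.int64)
    m = _present_alleles(counts)
    if (m > 0).sum() < 2:
        return HweResult(1.0, 0.0, 0, degenerate=True)
    genos = _counts_to_genos(counts)
    if seed is None:
        seed = 0
    n_batches = max(1, min(n_batches, chain_steps))
    batch_hits, per_batch = hwe_switch_chain(
        genos, int(chain_steps), int(dememorization), int(n_batches),
        int(seed) % (2**31 - 1), _TIE_TOL,
    )
    total = per_batch * n_batches
    p = float(batch_hits.sum()) / total
    props = batch_hits / per_batch
    se = float(props.std(ddof=1) / math.sqrt(n_batches)) if n_batches > 1 else 0.0
    return HweResult(p, se, total)


def _log_table_prob(cells: dict[tuple[int, int], int]) -> float:
    """Unnormalised log conditional probability: H*ln2 - sum ln(n_ij!)."""
    logp = 0.0
    for (i, j), c in cells.items():
        logp -= math.lgamma(c + 1)
        if i != j:
            logp += c * math.log(2.0)
    return logp


def hwe_exact_enumeration(genotype_counts) -> float:
    """Exact Hardy-Weinberg p-value by full enumeration of genotype tables.

    Enumerates every genotype table with the observed allele counts and
    sums the conditional probabilities of tables no more probable than the
    observed one.  Practical for 2-allele tables at any modest n and for
    3-4 allele tables at small n; the Markov-chain test covers the rest.
    """
    counts = np.asarray(genotype_counts, dtype=np.int64)
    m = _present_alleles(counts)
    keep = np.flatnonzero(m > 0)
    if len(keep) < 2:
        return 1.0
    m = m[keep]
    k = len(keep)
    remap = {a: i for i, a in enumerate(keep)}
    obs_cells: dict[tuple[int, int], int] = {}
    for i in range(counts.shape[0]):
        for j in range(i, counts.shape[1]):
            if counts[i, j] > 0:
                obs_cells[(remap[i], remap[j])] = int(counts[i, j])
    logp_obs = _log_table_prob(obs_cells)

    cell_order = [(i, j) for i in range(k) for j in range(i, k)]
    logps: list[float] = []

    def recurse(idx: int, rem: np.ndarray, cells: dict) -> None:
        if idx == len(cell_order):
            if (rem == 0).all():
                logps.append(_log_table_prob(cells))
            return
        i, j = cell_order[idx]
        if i == j:
            hi = rem[i] // 2
        else:
            hi = min(rem[i], rem[j])
        for c in range(int(hi) + 1):
            rem2 = rem.copy()
            rem2[i] -= c * (2 if i == j else 1)
            if i != j:
                rem2[j] -= c
            # prune: allele i can no longer be placed once all its cells done
            if j == k - 1 and rem2[i] != 0:
                continue
            if c > 0:
                cells[(i, j)] = c
            recurse(idx + 1, rem2, cells)
            cells.pop((i, j), None)

    recurse(0, m.copy(), {})
    logps_arr = np.asarray(logps)
    # normalise within the enumerated set and sum the "as or more extreme" mass
    lmax = logps_arr.max()
    w = np.exp(logps_arr - lmax)
    total = w.sum()
    extreme = w[logps_arr <= logp_obs + _TIE_TOL].sum()
    return float(extreme / total)


def hwe_table(
    gt: GenotypeTable,
    chain_steps: int = 1_000_000,
    dememorization: int = 100_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per population x locus summary: n, H_O, H_E and exact-test p-value."""
    het = heterozygosity(gt)
    pvals, ses = [], []
    rng = np.random.default_rng(seed)
    for _, row in het.iterrows():
        if row["n"] == 0:
            pvals.append(np.nan)
            ses.append(np.nan)
            continue
        li = gt.loci.index(row["locus"])
        counts = gt.genotype_counts(li, pop=row["population"])
        res = hwe_exact_test(
            counts, chain_steps, dememorization,
            seed=int(rng.integers(2**31 - 1)),
        )
        pvals.append(res.p_value)
        ses.append(res.se)
    het = het.copy()
    het["p_hwe"] = pvals
    het["p_hwe_se"] = ses
    return het


# ---------------------------------------------------------------------------
# linkage disequilibrium

@dataclass
class LdResult:
    locus_pair: tuple[str, str]
    per_population: pd.DataFrame = field(repr=False)
    chi2: float = np.nan
    df: int = 0
    p_combined: float = np.nan


def _genotype_codes(gt: GenotypeTable, locus: int, mask: np.ndarray):
    pairs = np.sort(gt.calls[mask, locus, :], axis=1)
    keys = pairs[:, 0].astype(np.int64) * 10_000 + pairs[:, 1]
    _, codes = np.unique(keys, return_inverse=True)
    return codes.astype(np.int64)


def _s_obs(codes_a, codes_b, kb) -> float:
    joint = codes_a * kb + codes_b
    counts = np.bincount(joint)
    counts = counts[counts > 0]
    return float(np.sum(counts * np.log(counts)))


def _g_statistic(codes_a, codes_b, ka, kb) -> float:
    n = len(codes_a)
    joint = np.bincount(codes_a * kb + codes_b, minlength=ka * kb)
    rows = np.bincount(codes_a, minlength=ka).astype(float)
    cols = np.bincount(codes_b, minlength=kb).astype(float)
    o = joint[joint > 0].astype(float)
    s = float(np.sum(o * np.log(o)))
    s -= float(np.sum(rows[rows > 0] * np.log(rows[rows > 0])))
    s -= float(np.sum(cols[cols > 0] * np.log(cols[cols > 0])))
    s += n * math.log(n)
    return 2.0 * s


def ld_test(
    gt: GenotypeTable,
    locus_pair: tuple[str, str],
    batches: int = 100,
    iterations_per_batch: int = 1_000,
    dememorization: int = 1_000,
    seed: int | None = 0,
) -> LdResult:
    """Genotypic linkage-disequilibrium test for one locus pair.

    Within each population the null distribution of the two-locus genotypic
    log-likelihood-ratio statistic is generated by permuting one locus's
    genotypes among individuals; the batch structure yields a Monte-Carlo
    standard error.  Population p-values are combined with Fisher's method
    (chi-square with 2k degrees of freedom over the k testable populations).
    """
    la, lb = (gt.loci.index(locus_pair[0]), gt.loci.index(locus_pair[1]))
    rng = np.random.default_rng(seed)
    rows = []
    for pop in gt.pop_names:
        mask = gt.pop_mask(pop) & gt.genotyped_mask(la) & gt.genotyped_mask(lb)
        n = int(mask.sum())
        if n < 2:
            rows.append((pop, n, np.nan, np.nan, np.nan, "too few genotypes"))
            continue
        ca = _genotype_codes(gt, la, mask)
        cb = _genotype_codes(gt, lb, mask)
        ka, kb = int(ca.max()) + 1, int(cb.max()) + 1
        if ka < 2 or kb < 2:
            rows.append((pop, n, np.nan, np.nan, np.nan, "monomorphic locus"))
            continue
        g_obs = _g_statistic(ca, cb, ka, kb)
        s_obs = _s_obs(ca, cb, kb)
        batch_hits = ld_permutation_counts(
            ca, cb, kb, int(batches), int(iterations_per_batch),
            int(dememorization), int(rng.integers(2**31 - 1)), s_obs, _TIE_TOL,
        )
        n_perm = batches * iterations_per_batch
        p = (1.0 + float(batch_hits.sum())) / (n_perm + 1.0)
        props = batch_hits / iterations_per_batch
        se = float(props.std(ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
        rows.append((pop, n, g_obs, p, se, ""))
    per_pop = pd.DataFrame(
        rows, columns=["population", "n", "g_stat", "p_value", "se", "note"]
    )
    tested = per_pop.dropna(subset=["p_value"])
    result = LdResult((gt.loci[la], gt.loci[lb]), per_pop)
    if len(tested):
        chi2 = float(-2.0 * np.sum(np.log(tested["p_value"])))
        df = 2 * len(tested)
        result.chi2, result.df = chi2, df
        result.p_combined = float(stats.chi2.sf(chi2, df))
    return result


# ---------------------------------------------------------------------------
# Weir-Cockerham theta

def weir_cockerham_components(
    gt: GenotypeTable, pops: list[str] | None = None
) -> pd.DataFrame:
    """Per-locus Weir-Cockerham (1984) variance components a, b, c.

    a: among populations; b: among individuals within populations;
    c: within individuals.  Components are summed over alleles at each
    locus; missing genotypes are excluded per locus; populations with no
    genotyped individuals at a locus drop out of that locus.
    """
    if pops is None:
        pops = gt.pop_names
    if len(pops) < 2:
        raise ValueError("theta requires at least two populations")
    empty = [
        p for p in pops
        if not any((gt.pop_mask(p) & gt.genotyped_mask(li)).any()
                   for li in range(gt.n_loci))
    ]
    if empty:
        warnings.warn(f"populations with no genotyped individuals excluded: {empty}")
        pops = [p for p in pops if p not in empty]
        if len(pops) < 2:
            raise ValueError("fewer than two populations with data")

    rows = []
    for li, locus in enumerate(gt.loci):
        ns, pfreq, hfreq = [], [], []
        for pop in pops:
            mask = gt.pop_mask(pop) & gt.genotyped_mask(li)
            n_i = int(mask.sum())
            if n_i == 0:
                continue
            pairs = gt.calls[mask, li, :]
            ns.append(n_i)
            pfreq.append(pairs)
        r = len(ns)
        if r < 2:
            rows.append((locus, np.nan, np.nan, np.nan))
            continue
        ns_arr = np.asarray(ns, dtype=float)
        nbar = ns_arr.mean()
        if nbar <= 1:
            rows.append((locus, np.nan, np.nan, np.nan))
            continue
        ntot = ns_arr.sum()
        nc = (ntot - float(np.sum(ns_arr**2)) / ntot) / (r - 1)
        alleles = np.unique(np.concatenate([p.ravel() for p in pfreq]))
        a_sum = b_sum = c_sum = 0.0
        for allele in alleles:
            p_i = np.asarray(
                [np.mean(pairs == allele) for pairs in pfreq]
            )
            h_i = np.asarray([
                np.mean((pairs[:, 0] != pairs[:, 1])
                        & ((pairs[:, 0] == allele) | (pairs[:, 1] == allele)))
                for pairs in pfreq
            ])
            pbar = float(np.sum(ns_arr * p_i) / ntot)
            s2 = float(np.sum(ns_arr * (p_i - pbar) ** 2) / ((r - 1) * nbar))
            hbar = float(np.sum(ns_arr * h_i) / ntot)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2.0
            a_sum += a
            b_sum += b
            c_sum += c
        rows.append((locus, a_sum, b_sum, c_sum))
    return pd.DataFrame(rows, columns=["locus", "a", "b", "c"])


def global_fst(gt: GenotypeTable, pops: list[str] | None = None) -> float:
    """Multilocus Weir-Cockerham theta: ratio of summed components.

    Sum(a) / Sum(a+b+c) across loci (never the mean of per-locus ratios).
    The unbiased estimator can be slightly negative; values are reported
    unclipped.
    """
    comp = weir_cockerham_components(gt, pops).dropna()
    denom = float((comp["a"] + comp["b"] + comp["c"]).sum())
    if denom == 0:
        return np.nan
    return float(comp["a"].sum() / denom)


def pairwise_fst(gt: GenotypeTable) -> DistanceMatrix:
    """Pairwise multilocus theta between every population pair."""
    pops = gt.pop_names
    k = len(pops)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i):
            theta = global_fst(gt, pops=[pops[i], pops[j]])
            vals[i, j] = vals[j, i] = theta
    return DistanceMatrix(pops, vals)


# ---------------------------------------------------------------------------
# genotype ordination

@dataclass
class PcaResult:
    scores: pd.DataFrame = field(repr=False)
    loadings: np.ndarray = field(repr=False)
    explained: np.ndarray = field(repr=False)
    columns: list = field(default_factory=list)


def genotype_pca(gt: GenotypeTable) -> PcaResult:
    """PCA of individuals on the (locus, allele) dosage matrix.

    Builds the 0/1/2 allele-count matrix per individual, imputes missing
    entries with column means, column-centres, and eigendecomposes.
    Scores carry the population label for plotting.
    """
    if gt.n_individuals < 3:
        raise ValueError("genotype PCA needs at least 3 individuals")
    cols, mats = [], []
    for li, locus in enumerate(gt.loci):
        mask = gt.genotyped_mask(li)
        alleles = np.unique(gt.calls[mask, li, :])
        for allele in alleles:
            dose = (gt.calls[:, li, :] == allele).sum(axis=1).astype(float)
            dose[~mask] = np.nan
            cols.append((locus, int(allele)))
            mats.append(dose)
    X = np.column_stack(mats) if mats else np.zeros((gt.n_individuals, 0))
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing columns")
        X = X[:, ~all_missing]
        cols = [c for c, drop in zip(cols, all_missing) if not drop]
    col_means = np.nanmean(X, axis=0) if X.shape[1] else np.zeros(0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_means, inds[1])
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    score_df = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    score_df.insert(0, "population", gt.populations)
    score_df.insert(0, "id", gt.ids)
    return PcaResult(score_df, vt, explained, cols)
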
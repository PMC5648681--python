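"""Numba kernels for the two Monte-Carlo loops of the genetic analysis.

Both loops are trivially expressed but run for 1e5-1e6 iterations per
locus/population cell at the study's published settings, so the inner
loops are compiled.  The surrounding statistics, p-values and standard
errors stay in plain NumPy in :mod:`qstfst.popgen`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LN2 = float(np.log(2.0))


@njit(cache=True)
def hwe_switch_chain(genos, n_steps, demem, n_batches, seed, tol):
    """Allele-switch Markov chain over genotype tables with fixed allele counts.

    ``genos`` is an (n, 2) array of allele indices, one row per individual.
    A step picks two individuals and one allele copy from each and swaps
    them.  The chain is uniform over allele pairings, whose induced
    distribution on genotype tables is exactly the Hardy-Weinberg
    conditional distribution given allele counts, so every switch is
    accepted.  Returns per-batch counts of post-dememorisation states whose
    conditional probability is <= that of the starting (observed) table.
    """
    np.random.seed(seed)
    n = genos.shape[0]
    g = genos.copy()
    k = 0
    for i in range(n):
        for s in range(2):
            if g[i, s] + 1 > k:
                k = g[i, s] + 1
    counts = np.zeros((k, k), dtype=np.int64)
    for i in range(n):
        a, b = g[i, 0], g[i, 1]
        if a > b:
            a, b = b, a
        counts[a, b] += 1
    # log-probability up to an additive constant: H*ln2 - sum lgamma(n_ij+1)
    logp = 0.0
    for i in range(k):
        for j in range(i, k):
            if counts[i, j] > 0:
                logp -= np.sum(np.log(np.arange(1, counts[i, j] + 1)))
            if i != j:
                logp += LN2 * counts[i, j]
    logp_obs = logp

    batch_hits = np.zeros(n_batches, dtype=np.int64)
    per_batch = n_steps // n_batches
    total = demem + n_batches * per_batch
    for step in range(total):
        ia = np.random.randint(0, n)
        ib = np.random.randint(0, n)
        if ia != ib:
            sa = np.random.randint(0, 2)
            sb = np.random.randint(0, 2)
            x = g[ia, sa]
            y = g[ib, sb]
            if x != y:
                # remove both current genotypes from the table
                for (p, q) in ((g[ia, 0], g[ia, 1]), (g[ib, 0], g[ib, 1])):
                    i0, j0 = (p, q) if p <= q else (q, p)
                    logp += np.log(counts[i0, j0])
                    counts[i0, j0] -= 1
                    if i0 != j0:
                        logp -= LN2
                g[ia, sa] = y
                g[ib, sb] = x
                for (p, q) in ((g[ia, 0], g[ia, 1]), (g[ib, 0], g[ib, 1])):
                    i0, j0 = (p, q) if p <= q else (q, p)
                    counts[i0, j0] += 1
                    logp -= np.log(counts[i0, j0])
                    if i0 != j0:
                        logp += LN2
        if step >= demem:
            if logp <= logp_obs + tol:
                batch_hits[(step - demem) // per_batch] += 1
    return batch_hits, per_batch


@njit(cache=True)
def ld_permutation_counts(codes_a, codes_b, kb, n_batches, per_batch,
                          demem, seed, s_obs, tol):
    """Permutation null for the genotypic two-locus association statistic.

    ``codes_a``/``codes_b`` are per-individual genotype category indices at
    the two loci.  The log-likelihood-ratio statistic G of the joint
    genotype contingency table is monotone in S = sum O*ln(O) because the
    margins are fixed under permutation; the kernel therefore counts
    permutations with S >= s_obs - tol, in batches.
    """
    np.random.seed(seed)
    n = codes_a.shape[0]
    b = codes_b.copy()
    ncells = 0
    for i in range(n):
        idx = codes_a[i] * kb  # upper bound helper; real cells tracked below
        if idx >= ncells:
            ncells = idx
    counts = np.zeros(ncells + kb + 1, dtype=np.int64)
    touched = np.zeros(n, dtype=np.int64)
    batch_hits = np.zeros(n_batches, dtype=np.int64)
    for batch in range(-1, n_batches):
        n_iter = demem if batch < 0 else per_batch
        for _ in range(n_iter):
            # Fisher-Yates shuffle of locus-B genotypes among individuals
            for i in range(n - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                tmp = b[i]
                b[i] = b[j]
                b[j] = tmp
            if batch < 0:
                continue
            s = 0.0
            for i in range(n):
                idx = codes_a[i] * kb + b[i]
                counts[idx] += 1
                touched[i] = idx
            for i in range(n):
                c = counts[touched[i]]
                if c > 0:
                    s += c * np.log(c)
                    counts[touched[i]] = 0
            if s >= s_obs - tol:
                batch_hits[batch] += 1
    return batch_hits
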
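import numpy as np
import pandas as pd
import pytest

from qstfst import (GenotypeSimSpec, GenotypeTable, genotype_pca, global_fst,
                    heterozygosity, pairwise_fst, simulate_genotypes,
                    weir_cockerham_components)


def table_from_pairs(pairs_by_pop: dict[str, list[tuple[int, int]]]):
    ids, pops, calls = [], [], []
    for pop, pairs in pairs_by_pop.items():
        for i, pr in enumerate(pairs):
            ids.append(f"{pop}{i}")
            pops.append(pop)
            calls.append([list(pr)])
    return GenotypeTable(ids, pops, ["L1"], np.asarray(calls))


# ---------------------------------------------------------------------------
# heterozygosity

@pytest.mark.parametrize(
    "pairs, h_obs, h_exp",
    [
        ([(1, 1), (2, 2)], 0.0, 4 / 3 * 0.5),      # {AA, BB}
        ([(1, 2), (1, 2)], 1.0, 4 / 3 * 0.5),      # both AB
        ([(1, 1), (1, 1)], 0.0, 0.0),              # monomorphic
    ],
)
def test_heterozygosity_closed_form(pairs, h_obs, h_exp):
    gt = table_from_pairs({"P": pairs})
    row = heterozygosity(gt).iloc[0]
    assert row["h_obs"] == pytest.approx(h_obs)
    assert row["h_exp"] == pytest.approx(h_exp)


def test_heterozygosity_empty_cell_is_missing():
    gt = table_from_pairs({"P": [(0, 0), (0, 0)]})
    row = heterozygosity(gt).iloc[0]
    assert row["n"] == 0
    assert np.isnan(row["h_obs"]) and np.isnan(row["h_exp"])


def test_h_exp_unbiased_over_replicates():
    """Mean sample H_E from known allele frequencies matches truth +-0.01."""
    rng = np.random.default_rng(0)
    freqs = np.array([0.5, 0.3, 0.2])
    truth = 1 - np.sum(freqs**2)
    n = 15
    est = []
    for _ in range(400):
        draws = rng.choice([1, 2, 3], size=(n, 1, 2), p=freqs)
        gt = GenotypeTable([f"i{k}" for k in range(n)], ["P"] * n, ["L1"], draws)
        est.append(heterozygosity(gt)["h_exp"].iloc[0])
    assert abs(np.mean(est) - truth) < 0.01


# ---------------------------------------------------------------------------
# Weir-Cockerham theta

def test_wc_components_hand_case(tiny_table):
    """{AA, AB} vs {AB, BB}: a=0.125, b=0, c=0.5 per the 1984 formulas."""
    comp = weir_cockerham_components(tiny_table).iloc[0]
    assert comp["a"] == pytest.approx(0.125, abs=1e-10)
    assert comp["b"] == pytest.approx(0.0, abs=1e-10)
    assert comp["c"] == pytest.approx(0.5, abs=1e-10)
    assert global_fst(tiny_table) == pytest.approx(0.2, abs=1e-10)


def test_theta_one_for_fixed_differences():
    gt = table_from_pairs({"P1": [(1, 1)] * 5, "P2": [(2, 2)] * 5})
    assert global_fst(gt) == pytest.approx(1.0, abs=1e-12)


def test_theta_near_zero_for_duplicated_population():
    base = simulate_genotypes(GenotypeSimSpec(
        n_populations=1, n_per_pop=200, n_loci=5, alleles_per_locus=8,
        divergence_f=0.0, missing_rate=0.0, seed=3))
    dup = GenotypeTable(
        base.ids + [f"d_{i}" for i in base.ids],
        ["A"] * base.n_individuals + ["B"] * base.n_individuals,
        base.loci,
        np.concatenate([base.calls, base.calls]),
    )
    assert abs(global_fst(dup)) <= 0.005


def test_theta_invariant_to_relabeling(diverged_genotypes):
    gt = diverged_genotypes
    theta = global_fst(gt)
    # permute allele codes with an order-scrambling map
    remap = {0: 0}
    remap.update({a: 1000 - 7 * a for a in range(1, 20)})
    recoded = GenotypeTable(
        gt.ids, gt.populations, gt.loci,
        np.vectorize(remap.get)(gt.calls),
    )
    assert global_fst(recoded) == pytest.approx(theta, abs=1e-12)
    # permute population order
    order = np.argsort([p for p in gt.populations])[::-1]
    shuffled = GenotypeTable(
        [gt.ids[i] for i in order], [gt.populations[i] for i in order],
        gt.loci, gt.calls[order])
    assert global_fst(shuffled) == pytest.approx(theta, abs=1e-12)


def test_multilocus_theta_is_ratio_of_sums():
    """Constructed case where ratio-of-sums and mean-of-ratios differ."""
    gt = GenotypeTable(
        [f"i{k}" for k in range(8)],
        ["P1"] * 4 + ["P2"] * 4,
        ["L1", "L2"],
        np.array([
            [[1, 1], [1, 2]], [[1, 1], [1, 1]], [[1, 2], [2, 2]], [[1, 1], [1, 2]],
            [[2, 2], [1, 2]], [[2, 2], [1, 1]], [[1, 2], [1, 2]], [[2, 2], [2, 2]],
        ]),
    )
    comp = weir_cockerham_components(gt)
    tot = comp["a"] + comp["b"] + comp["c"]
    per_locus = comp["a"] / tot
    ratio_of_sums = comp["a"].sum() / tot.sum()
    assert abs(ratio_of_sums - per_locus.mean()) > 1e-3  # they differ here
    assert global_fst(gt) == pytest.approx(ratio_of_sums, abs=1e-12)


def test_pairwise_fst_matrix(diverged_genotypes):
    dm = pairwise_fst(diverged_genotypes)
    assert dm.labels == ["Pop1", "Pop2"]
    assert dm.values[0, 0] == 0.0
    assert dm.values[0, 1] == dm.values[1, 0]
    assert dm.values[0, 1] == pytest.approx(global_fst(diverged_genotypes), abs=1e-12)


# ---------------------------------------------------------------------------
# genotype PCA

def test_genotype_pca_separates_diverged_populations(diverged_genotypes):
    from sklearn.metrics import silhouette_score
    res = genotype_pca(diverged_genotypes)
    pc1 = res.scores[["PC1"]].to_numpy()
    labels = res.scores["population"].to_numpy()
    assert silhouette_score(pc1, labels) > 0.5


def test_genotype_pca_identical_individuals():
    calls = np.tile(np.array([[[1, 2], [3, 3]]]), (5, 1, 1))
    gt = GenotypeTable([f"i{k}" for k in range(5)], ["P"] * 5,
                       ["L1", "L2"], calls)
    res = genotype_pca(gt)
    assert np.allclose(res.scores.filter(like="PC").to_numpy(), 0.0)


def test_genotype_pca_variance_fractions_sum_to_one(diverged_genotypes):
    res = genotype_pca(diverged_genotypes)
    assert res.explained.sum() == pytest.approx(1.0, abs=1e-10)
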
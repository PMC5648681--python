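import numpy as np
import pandas as pd
import pytest

from qstfst import (ClimateSimSpec, ExperimentSimSpec, GenotypeSimSpec,
                    TraitSpec, global_fst, simulate_climate,
                    simulate_experiment, simulate_genotypes,
                    simulate_nested_trait)
from qstfst.lifehist import size_corrected, trait_correlation
from qstfst.simulate import write_spec_sidecar


# ---------------------------------------------------------------------------
# determinism

def test_fixed_seed_reproducibility(tmp_path):
    a = simulate_genotypes(GenotypeSimSpec(seed=5))
    b = simulate_genotypes(GenotypeSimSpec(seed=5))
    np.testing.assert_array_equal(a.calls, b.calls)
    ca, ba = simulate_experiment(ExperimentSimSpec(seed=5))
    cb, bb = simulate_experiment(ExperimentSimSpec(seed=5))
    pd.testing.assert_frame_equal(ca, cb)
    pd.testing.assert_frame_equal(ba, bb)
    pd.testing.assert_frame_equal(
        simulate_climate(ClimateSimSpec(seed=5)),
        simulate_climate(ClimateSimSpec(seed=5)))
    write_spec_sidecar(ExperimentSimSpec(seed=5), tmp_path / "spec.json")
    assert (tmp_path / "spec.json").read_text().startswith("{")


# ---------------------------------------------------------------------------
# genotypes

def test_genotype_spec_validation():
    with pytest.raises(ValueError):
        GenotypeSimSpec(divergence_f=1.0)
    with pytest.raises(ValueError):
        GenotypeSimSpec(alleles_per_locus=1)
    with pytest.raises(ValueError):
        GenotypeSimSpec(missing_rate=1.0)


def test_zero_divergence_theta_near_zero():
    thetas = []
    for s in range(50):
        gt = simulate_genotypes(GenotypeSimSpec(
            n_populations=2, n_per_pop=200, n_loci=5, alleles_per_locus=8,
            divergence_f=0.0, missing_rate=0.0, seed=s))
        thetas.append(global_fst(gt))
    assert abs(np.mean(thetas)) < 0.01


def test_missing_rate_applied():
    gt = simulate_genotypes(GenotypeSimSpec(missing_rate=0.2, seed=1))
    frac = (gt.calls == 0).all(axis=2).mean()
    assert 0.15 < frac < 0.25


def test_hwe_holds_within_population():
    """Generator draws random unions of gametes, so within-population exact
    HWE p-values are approximately uniform across loci/populations."""
    from qstfst import hwe_table
    gt = simulate_genotypes(GenotypeSimSpec(
        n_populations=3, n_per_pop=50, n_loci=5, alleles_per_locus=4,
        divergence_f=0.1, missing_rate=0.0, seed=2))
    tab = hwe_table(gt, chain_steps=20_000, dememorization=2_000, seed=0)
    assert (tab["p_hwe"] < 0.01).mean() <= 0.10


# ---------------------------------------------------------------------------
# experiment

def test_default_design_counts(default_experiment):
    clutches, broods = default_experiment
    assert len(broods) == 128  # 8 pops x 4 sires x 4 dams
    assert broods["sire_id"].nunique() == 32
    assert broods["population"].nunique() == 8
    assert (broods["n_reared"] <= 32).all()
    # clutch bookkeeping invariant
    np.testing.assert_allclose(
        clutches["total_egg_mass_g"],
        clutches["clutch_size"] * clutches["mean_egg_mass_g"], rtol=1e-12)


def test_experiment_spec_validation():
    with pytest.raises(ValueError):
        ExperimentSimSpec(tradeoff_rho=-1.5)
    with pytest.raises(ValueError):
        ExperimentSimSpec(brood_cap=0)
    with pytest.raises(ValueError):
        TraitSpec(1.0, v_pop=-1.0, v_male=0.0, v_res=1.0)


def test_noise_free_traits_equal_population_means():
    traits = {
        "brood_size": TraitSpec(12.0, 0, 0, 0),
        "incubation_days": TraitSpec(18.0, 0, 0, 0),
        "fry_tl_day0_mm": TraitSpec(10.0, 0, 0, 0),
        "growth_0_35_mm": TraitSpec(4.0, 0, 0, 0),
        "growth_35_70_mm": TraitSpec(4.0, 0, 0, 0),
    }
    spec = ExperimentSimSpec(brood_traits=traits, seed=0, density_slope=0.0)
    _, broods = simulate_experiment(spec)
    for col, expect in [("brood_size", 12), ("incubation_days", 18.0),
                        ("fry_tl_day0_mm", 10.0)]:
        assert broods.groupby("population")[col].nunique().max() == 1
        assert broods[col].iloc[0] == pytest.approx(expect)


def test_tradeoff_rho_recovery():
    spec = ExperimentSimSpec(seed=0, tradeoff_rho=-0.9, clutches_per_pop=63)
    clutches, _ = simulate_experiment(spec)
    assert len(clutches) >= 500
    sc = size_corrected(clutches, "clutch_size", "female_tl_mm")
    r = trait_correlation(sc, clutches.loc[sc.index, "mean_egg_mass_g"]).r
    assert -0.95 <= r <= -0.80


def test_density_dependent_growth():
    """Stronger negative density slope depresses growth in big broods."""
    spec = ExperimentSimSpec(seed=1, density_slope=-6.0)
    _, broods = simulate_experiment(spec)
    g35 = broods["fry_tl_day35_mm"] - broods["fry_tl_day0_mm"]
    r = trait_correlation(np.log10(broods["n_reared"]), g35).r
    assert r < -0.3


def test_fry_lengths_non_decreasing(default_experiment):
    _, broods = default_experiment
    assert (broods["fry_tl_day35_mm"] >= broods["fry_tl_day0_mm"]).all()
    assert (broods["fry_tl_day70_mm"] >= broods["fry_tl_day35_mm"]).all()


def test_nested_trait_moment_recovery():
    """Empirical variance components converge to the configured values."""
    frames = [simulate_nested_trait(v_pop=1.0, v_male=0.25, v_res=0.75, seed=s)
              for s in range(200)]
    from qstfst import mom_nested_anova
    ests = np.array([
        [vc.v_between, vc.v_male, vc.v_res]
        for vc in (mom_nested_anova(f) for f in frames)
    ])
    assert ests.mean(axis=0) == pytest.approx([1.0, 0.25, 0.75], rel=0.10)


# ---------------------------------------------------------------------------
# climate

def test_climate_validation_and_periodicity():
    with pytest.raises(ValueError):
        ClimateSimSpec(n_years=0)
    with pytest.raises(ValueError):
        ClimateSimSpec(monthly_profile={"temperature_c": [1.0] * 11})
    spec = ClimateSimSpec(n_years=3, noise_sd={"temperature_c": 0.0,
                                               "precipitation_mm": 0.0})
    out = simulate_climate(spec)
    assert len(out) == 36
    x = out["temperature_c"].to_numpy()
    np.testing.assert_allclose(x[:12], x[12:24])
    np.testing.assert_allclose(x[:12], x[24:])


def test_constant_profile_is_fully_constant():
    from qstfst import colwell_stats
    spec = ClimateSimSpec(
        n_years=5,
        monthly_profile={"temperature_c": [20.0] * 12},
        noise_sd={"temperature_c": 0.0})
    out = simulate_climate(spec)
    cw = colwell_stats(out["temperature_c"].to_numpy())
    assert (cw.constancy, cw.contingency) == (1.0, 0.0)
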
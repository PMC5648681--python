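"""End-to-end orchestration: simulate (optional) -> population genetics ->
variance components / Q_ST -> life-history statistics -> environmental
predictability -> Q_ST-F_ST comparison.

Every stage writes plain CSV/TSV/JSON files so each one can be re-run
independently; the machine-readable ``summary.json`` is byte-identical
under an identical config and seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import spearman_permutation
from .envpred import env_pca, summarize_site
from .genepop import read_genepop, write_genepop
from .lifehist import (filter_growth_broods, fit_trait_glm, habitat_contrast,
                       lsmeans, size_corrected, trait_correlation, trait_pca,
                       tukey_hsd)
from .popgen import genotype_pca, global_fst, hwe_table, ld_test, pairwise_fst
from .quantgen import pairwise_qst
from .simulate import (ClimateSimSpec, ExperimentSimSpec, GenotypeSimSpec,
                       simulate_climate, simulate_experiment,
                       simulate_genotypes, write_spec_sidecar)

__all__ = ["PipelineConfig", "default_config", "run_pipeline"]

log = logging.getLogger("qstfst")


@dataclass
class PipelineConfig:
    """Inputs (paths or simulation specs) plus per-stage parameters.

    Exactly one of (``genepop_path``, ``genotype_spec``) must be set, and
    likewise for the experiment tables and the climate series.  All
    stochastic stages draw their seeds deterministically from ``seed``.
    """

    seed: int = 0
    genotype_spec: GenotypeSimSpec | None = None
    genepop_path: str | None = None
    experiment_spec: ExperimentSimSpec | None = None
    clutch_path: str | None = None
    brood_path: str | None = None
    climate_specs: dict | None = None     # site -> ClimateSimSpec
    climate_path: str | None = None       # tidy CSV: site, year, month, vars
    site_descriptors: dict = field(default_factory=dict)
    habitat_labels: dict = field(default_factory=dict)  # population -> habitat
    hwe_chain_steps: int = 1_000_000
    hwe_dememorization: int = 100_000
    ld_batches: int = 100
    ld_iterations_per_batch: int = 1_000
    ld_dememorization: int = 1_000
    n_perm: int = 9_999
    colwell_bins: int = 10
    growth_min_n: int = 5
    growth_max_n: int = 19
    qst_mode: str = "subset"


def default_config(seed: int = 0) -> PipelineConfig:
    """Fully synthetic configuration emulating the study design.

    Eight experimental populations (four lake, four peripheral), seven of
    them genotyped at seven microsatellite loci; one climate site per
    population with lake sites low, warm and wet-stable and peripheral
    sites high, cool and seasonal.
    """
    pops = [f"Pop{i + 1}" for i in range(8)]
    habitats = {p: ("lake" if i < 4 else "peripheral")
                for i, p in enumerate(pops)}
    climate_specs = {}
    descriptors = {}
    base_temp = np.asarray([25.0, 25.0, 24.5, 23.0, 21.0, 19.0,
                            18.5, 20.0, 22.5, 24.5, 25.5, 25.5])
    base_prec = np.asarray([220.0, 200.0, 150.0, 60.0, 10.0, 2.0,
                            1.0, 1.0, 5.0, 20.0, 80.0, 180.0])
    for i, pop in enumerate(pops):
        lake = habitats[pop] == "lake"
        altitude = 480.0 + 15 * i if lake else 700.0 + 220 * (i - 4)
        temp = base_temp - 0.005 * (altitude - 480.0) + (0.3 if lake else -0.5)
        prec_scale = 1.0 if lake else 0.75 + 0.1 * (i - 4)
        climate_specs[pop] = ClimateSimSpec(
            n_years=15,
            monthly_profile={
                "temperature_c": list(np.round(temp, 3)),
                "precipitation_mm": list(np.round(base_prec * prec_scale, 3)),
            },
            noise_sd={"temperature_c": 0.8 if lake else 1.3,
                      "precipitation_mm": 18.0 if lake else 35.0},
            seed=seed * 101 + i,
        )
        descriptors[pop] = {
            "flow": not lake,
            "deep_water_close": lake,
            "altitude": altitude,
        }
    return PipelineConfig(
        seed=seed,
        genotype_spec=GenotypeSimSpec(n_populations=7, seed=seed * 7 + 1),
        experiment_spec=ExperimentSimSpec(seed=seed * 13 + 2),
        climate_specs=climate_specs,
        site_descriptors=descriptors,
        habitat_labels=habitats,
    )


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        if not np.isfinite(obj):
            return None
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _glm_summary(fit) -> list[dict]:
    return fit.anova.to_dict(orient="records")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full analysis and write the report bundle to ``outdir``.

    Returns the summary dict (also written as ``summary.json``).  Stage
    failures raise with the stage name; previously written stage outputs
    are left in place next to a ``FAILED_<stage>`` marker.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed}
    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        stage = "simulate"
        if config.genotype_spec is not None:
            gt = simulate_genotypes(config.genotype_spec)
            write_genepop(gt, out / "genotypes.gen")
            write_spec_sidecar(config.genotype_spec, out / "genotypes.spec.json")
        elif config.genepop_path:
            gt = read_genepop(config.genepop_path)
        else:
            raise ValueError("no genotype input: set genotype_spec or genepop_path")

        if config.experiment_spec is not None:
            clutches, broods = simulate_experiment(config.experiment_spec)
            clutches.to_csv(out / "clutches.csv", index=False)
            broods.to_csv(out / "broods.csv", index=False)
            write_spec_sidecar(config.experiment_spec, out / "experiment.spec.json")
        elif config.clutch_path and config.brood_path:
            clutches = pd.read_csv(config.clutch_path)
            broods = pd.read_csv(config.brood_path)
        else:
            raise ValueError("no experiment input: set experiment_spec or "
                             "clutch_path + brood_path")

        if config.climate_specs is not None:
            climate = pd.concat(
                [simulate_climate(spec, site=site)
                 for site, spec in config.climate_specs.items()],
                ignore_index=True,
            )
            climate.to_csv(out / "climate.csv", index=False)
        elif config.climate_path:
            climate = pd.read_csv(config.climate_path)
        else:
            raise ValueError("no climate input: set climate_specs or climate_path")

        # ---- popgen -----------------------------------------------------
        stage = "popgen"
        log.info("popgen: heterozygosity + HWE exact tests")
        het = hwe_table(gt, config.hwe_chain_steps, config.hwe_dememorization,
                        seed=config.seed * 1_000 + 11)
        het.to_csv(out / "heterozygosity.csv", index=False)
        log.info("popgen: linkage disequilibrium")
        ld_rows = []
        rng = np.random.default_rng(config.seed * 1_000 + 13)
        for i in range(gt.n_loci):
            for j in range(i + 1, gt.n_loci):
                res = ld_test(gt, (gt.loci[i], gt.loci[j]),
                              config.ld_batches, config.ld_iterations_per_batch,
                              config.ld_dememorization,
                              seed=int(rng.integers(2**31 - 1)))
                ld_rows.append({"locus1": gt.loci[i], "locus2": gt.loci[j],
                                "chi2": res.chi2, "df": res.df,
                                "p_combined": res.p_combined})
        ld_df = pd.DataFrame(ld_rows)
        ld_df.to_csv(out / "linkage_disequilibrium.csv", index=False)
        log.info("popgen: Weir-Cockerham theta")
        fst_global = global_fst(gt)
        fst_mat = pairwise_fst(gt)
        fst_mat.to_tsv(out / "fst_pairwise.tsv")
        gpca = genotype_pca(gt)
        gpca.scores.to_csv(out / "genotype_pca_scores.csv", index=False)
        summary["popgen"] = {
            "global_fst": fst_global,
            "pairwise_fst": fst_mat.to_frame().round(10).to_dict(),
            "n_hwe_significant_005":
                int((het["p_hwe"].dropna() < 0.05).sum()),
            "min_ld_p_combined": float(ld_df["p_combined"].min()),
            "genotype_pca_explained": gpca.explained[:5].tolist(),
        }

        # ---- life-history statistics ------------------------------------
        stage = "lifehist"
        log.info("lifehist: GLMs, Tukey, LS-means, trade-offs")
        broods = broods.copy()
        broods["growth_0_35_mm"] = broods["fry_tl_day35_mm"] - broods["fry_tl_day0_mm"]
        broods["growth_0_70_mm"] = broods["fry_tl_day70_mm"] - broods["fry_tl_day0_mm"]
        broods["log10_density_0_35"] = np.log10(broods["density_0_35"])
        broods["log10_density_0_70"] = np.log10(
            (broods["density_0_35"] + broods["density_35_70"]) / 2.0
        )
        growth_broods, growth_counts = filter_growth_broods(
            broods, min_n=config.growth_min_n, max_n=config.growth_max_n)

        analyses = [
            ("clutch_size", clutches, "female_tl_mm", True),
            ("mean_egg_mass_g", clutches, "female_tl_mm", True),
            ("total_egg_mass_g", clutches, "female_tl_mm", True),
            ("brood_size", broods, "female_tl_mm", True),
            ("incubation_days", broods, "female_tl_mm", True),
            ("fry_tl_day0_mm", broods, "female_tl_mm", True),
            ("growth_0_35_mm", growth_broods, "log10_density_0_35", False),
            ("growth_0_70_mm", growth_broods, "log10_density_0_70", False),
        ]
        lh_summary: dict = {"growth_filter": growth_counts}
        habitat = config.habitat_labels
        for trait, data, cov, interact in analyses:
            fit = fit_trait_glm(data, trait, covariate=cov,
                                include_interaction=interact)
            fit.anova.to_csv(out / f"anova_{trait}.csv", index=False)
            tk = tukey_hsd(fit)
            tk.p_matrix.to_csv(out / f"tukey_{trait}.csv")
            lsm = lsmeans(fit)
            lsm.to_csv(out / f"lsmeans_{trait}.csv", index=False)
            entry = {"anova": _glm_summary(fit)}
            if habitat:
                labels = [habitat.get(p, "lake") for p in lsm["population"]]
                if len(set(labels)) == 2:
                    entry["lake_vs_peripheral"] = habitat_contrast(
                        lsm["lsmean"], labels)
            lh_summary[trait] = entry

        tradeoffs = {}
        cs_resid = size_corrected(clutches, "clutch_size", "female_tl_mm")
        em = clutches.loc[cs_resid.index, "mean_egg_mass_g"]
        tradeoffs["clutch_size_vs_egg_mass"] = trait_correlation(
            cs_resid, em)._asdict()
        bs_resid = size_corrected(broods, "brood_size", "female_tl_mm")
        tradeoffs["brood_size_vs_incubation"] = trait_correlation(
            bs_resid, broods.loc[bs_resid.index, "incubation_days"])._asdict()
        tradeoffs["brood_size_vs_fry_tl"] = trait_correlation(
            bs_resid, broods.loc[bs_resid.index, "fry_tl_day0_mm"])._asdict()
        lh_summary["tradeoffs"] = tradeoffs

        exp1_resid = pd.DataFrame({
            "clutch_size": size_corrected(clutches, "clutch_size", "female_tl_mm"),
            "mean_egg_mass_g": size_corrected(clutches, "mean_egg_mass_g",
                                              "female_tl_mm"),
            "total_egg_mass_g": size_corrected(clutches, "total_egg_mass_g",
                                               "female_tl_mm"),
        })
        pca1 = trait_pca(exp1_resid)
        exp2_resid = pd.DataFrame({
            "incubation_days": growth_broods["incubation_days"],
            "fry_tl_day0_mm": growth_broods["fry_tl_day0_mm"],
            "brood_size": size_corrected(growth_broods, "brood_size",
                                         "female_tl_mm"),
            "growth_0_35_mm": size_corrected(growth_broods, "growth_0_35_mm",
                                             "log10_density_0_35"),
            "growth_0_70_mm": size_corrected(growth_broods, "growth_0_70_mm",
                                             "log10_density_0_70"),
        }).dropna()
        pca2 = trait_pca(exp2_resid)
        pca1.loadings.to_csv(out / "trait_pca_exp1_loadings.csv")
        pca2.loadings.to_csv(out / "trait_pca_exp2_loadings.csv")
        lh_summary["trait_pca_explained"] = {
            "experiment1": pca1.explained.tolist(),
            "experiment2": pca2.explained.tolist(),
        }
        summary["lifehist"] = lh_summary

        # ---- quantgen: Q_ST matrices ------------------------------------
        stage = "quantgen"
        log.info("quantgen: pairwise Q_ST per trait")
        qst_specs = [
            ("brood_size", broods, "female_tl_mm"),
            ("incubation_days", broods, None),
            ("fry_tl_day0_mm", broods, None),
            ("growth_0_35_mm", growth_broods, "log10_density_0_35"),
            ("growth_0_70_mm", growth_broods, "log10_density_0_70"),
        ]
        qst_matrices = {}
        components_log = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for trait, data, cov in qst_specs:
                dm, logd = pairwise_qst(data, response=trait, sire="sire_id",
                                        covariate=cov, mode=config.qst_mode)
                dm.to_tsv(out / f"qst_{trait}.tsv")
                qst_matrices[trait] = dm
                components_log[trait] = logd
        with open(out / "qst_components.json", "w") as fh:
            json.dump(_round_floats(components_log), fh, indent=2, sort_keys=True)
        summary["qst"] = {
            trait: dm.to_frame().round(10).to_dict()
            for trait, dm in qst_matrices.items()
        }

        # ---- envpred ----------------------------------------------------
        stage = "envpred"
        log.info("envpred: Colwell statistics and site ordination")
        feats = {}
        for site, sub in climate.groupby("site"):
            desc = config.site_descriptors.get(
                site, {"flow": False, "deep_water_close": False, "altitude": 0.0})
            feats[site] = summarize_site(
                sub, desc["flow"], desc["deep_water_close"], desc["altitude"],
                n_bins=config.colwell_bins)
        site_features = pd.DataFrame(feats).T.sort_index()
        site_features.to_csv(out / "site_features.csv", index_label="site")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            epca = env_pca(site_features)
        epca.loadings.to_csv(out / "env_pca_loadings.csv")
        summary["envpred"] = {
            "colwell": {
                site: {c: site_features.loc[site, c]
                       for c in site_features.columns if c[-2:] in ("_P", "_C", "_M")}
                for site in site_features.index
            },
            "env_pca_explained": epca.explained[:3].tolist(),
        }

        # ---- comparison -------------------------------------------------
        stage = "comparison"
        log.info("comparison: Q_ST vs F_ST Spearman permutation")
        comp_summary = {}
        pair_tables = []
        for trait, dm in qst_matrices.items():
            mc = spearman_permutation(
                dm, fst_mat, n_perm=config.n_perm,
                seed=config.seed * 1_000 + 17, trait=trait)
            tab = mc.pairs.copy()
            tab.insert(0, "trait", trait)
            pair_tables.append(tab)
            comp_summary[trait] = {
                "rho": mc.rho, "p": mc.p_value, "n_perm": mc.n_perm,
                "n_directional": int((tab["classification"] == "directional").sum()),
                "n_stabilizing": int((tab["classification"] == "stabilizing").sum()),
            }
        pd.concat(pair_tables, ignore_index=True).to_csv(
            out / "qst_fst_pairs.csv", index=False)
        summary["comparison"] = comp_summary

        stage = "summary"
        summary = _round_floats(summary)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        (out / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
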
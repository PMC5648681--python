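"""Synthetic genotype, common-garden and climate data generators.

The generators reproduce the statistical structure the analysis assumes,
so every downstream stage can be exercised and calibrated without the
deposited field data:

* wild microsatellite genotypes under the Balding-Nichols model, whose
  divergence parameter F is also the expected Weir-Cockerham theta;
* the hierarchical half-sib breeding design (populations x sires x dams,
  one brood per dam) with additive population, sire and residual trait
  effects, a maternal-length covariate, the egg size/number trade-off,
  and density-dependent juvenile growth;
* seasonal monthly climate series (temperature, precipitation) as a
  periodic baseline plus i.i.d. noise.

Defaults mirror the study conditions: 8 populations x 4 sires x 4 dams
(128 families), broods capped at 32 reared fry, 15-21 clutches per
population, 7 microsatellite loci, and a 15-year monthly climate record.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genepop import GenotypeTable

__all__ = [
    "GenotypeSimSpec",
    "ExperimentSimSpec",
    "TraitSpec",
    "ClimateSimSpec",
    "simulate_genotypes",
    "simulate_experiment",
    "simulate_nested_trait",
    "simulate_climate",
    "write_spec_sidecar",
]


# ---------------------------------------------------------------------------
# genotypes

@dataclass
class GenotypeSimSpec:
    n_populations: int = 7
    n_per_pop: int = 20
    n_loci: int = 7
    alleles_per_locus: int = 10
    divergence_f: float = 0.10
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        if not 0 <= self.divergence_f < 1:
            raise ValueError("divergence_f must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def simulate_genotypes(spec: GenotypeSimSpec) -> GenotypeTable:
    """Draw diploid genotypes under the Balding-Nichols divergence model.

    Ancestral allele frequencies are symmetric-Dirichlet; each population's
    frequencies are Dirichlet with concentration p * (1 - F) / F around the
    ancestral vector (identical to ancestral when F = 0), which makes F the
    expected value of Weir-Cockerham theta.  Genotypes are random unions of
    gametes within population, so Hardy-Weinberg proportions hold by
    construction; missing genotypes get the GENEPOP zero code.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.alleles_per_locus
    F = spec.divergence_f
    n_ind = spec.n_populations * spec.n_per_pop
    calls = np.zeros((n_ind, spec.n_loci, 2), dtype=np.int32)
    for li in range(spec.n_loci):
        anc = rng.dirichlet(np.ones(k))
        for p in range(spec.n_populations):
            if F > 0:
                freqs = rng.dirichlet(anc * (1 - F) / F)
            else:
                freqs = anc
            sl = slice(p * spec.n_per_pop, (p + 1) * spec.n_per_pop)
            calls[sl, li, :] = rng.choice(
                np.arange(1, k + 1), size=(spec.n_per_pop, 2), p=freqs
            )
    if spec.missing_rate > 0:
        drop = rng.random((n_ind, spec.n_loci)) < spec.missing_rate
        calls[drop] = 0
    pops = [f"Pop{p + 1}" for p in range(spec.n_populations)
            for _ in range(spec.n_per_pop)]
    ids = [f"{pops[i]}_ind{i % spec.n_per_pop + 1}" for i in range(n_ind)]
    loci = [f"Loc{li + 1}" for li in range(spec.n_loci)]
    return GenotypeTable(ids, pops, loci, calls)


# ---------------------------------------------------------------------------
# common-garden experiments

@dataclass
class TraitSpec:
    """One trait's generative parameters (units of the trait itself)."""

    mean: float
    v_pop: float
    v_male: float
    v_res: float
    tl_slope: float = 0.0

    def __post_init__(self) -> None:
        if min(self.v_pop, self.v_male, self.v_res) < 0:
            raise ValueError("variance components must be non-negative")


def _default_brood_traits() -> dict[str, TraitSpec]:
    return {
        # ~12.5 fry/brood so 128 families yield ~1,600 offspring
        "brood_size": TraitSpec(12.5, 4.0, 2.0, 9.0, tl_slope=0.15),
        "incubation_days": TraitSpec(18.0, 2.0, 0.5, 2.0),
        "fry_tl_day0_mm": TraitSpec(10.5, 0.25, 0.10, 0.20),
        "growth_0_35_mm": TraitSpec(4.5, 0.30, 0.10, 0.40),
        "growth_35_70_mm": TraitSpec(4.0, 0.20, 0.05, 0.30),
    }


def _default_clutch_traits() -> dict[str, TraitSpec]:
    return {
        "clutch_size": TraitSpec(40.0, 25.0, 0.0, 49.0, tl_slope=0.5),
        "mean_egg_mass_g": TraitSpec(0.015, 2.5e-6, 0.0, 4.0e-6, tl_slope=2e-5),
    }


@dataclass
class ExperimentSimSpec:
    n_populations: int = 8
    sires_per_pop: int = 4
    dams_per_sire: int = 4
    clutches_per_pop: int = 17
    brood_traits: dict[str, TraitSpec] = field(default_factory=_default_brood_traits)
    clutch_traits: dict[str, TraitSpec] = field(default_factory=_default_clutch_traits)
    population_trait_means: dict[str, list[float]] | None = None
    tradeoff_rho: float = -0.39
    brood_residual_corr: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("brood_size", "incubation_days"): -0.20,
            ("brood_size", "fry_tl_day0_mm"): -0.25,
        }
    )
    density_slope: float = -2.0  # mm per log10(individuals)
    brood_cap: int = 32
    female_tl_mean_mm: float = 85.0
    female_tl_log_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.tradeoff_rho) > 1:
            raise ValueError("|tradeoff_rho| must be <= 1")
        if self.brood_cap < 1:
            raise ValueError("brood_cap must be >= 1")
        for rho in self.brood_residual_corr.values():
            if abs(rho) > 1:
                raise ValueError("|residual correlation| must be <= 1")


def _correlated_effects(rng: np.random.Generator, n: int, sds: np.ndarray,
                        chol: np.ndarray) -> np.ndarray:
    """n draws of a zero-mean effect vector with the configured correlation."""
    return (rng.standard_normal((n, len(sds))) @ chol.T) * sds


def _pop_means(spec: ExperimentSimSpec, traits: dict[str, TraitSpec],
               chol: np.ndarray,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-population trait means: configured values, or draws with variance
    v_pop sharing the same cross-trait correlation as the residuals (so the
    configured trade-offs hold in pooled data, not only within population)."""
    names = list(traits)
    sds = np.asarray([np.sqrt(traits[n].v_pop) for n in names])
    eff = _correlated_effects(rng, spec.n_populations, sds, chol)
    out = {}
    for ti, name in enumerate(names):
        if spec.population_trait_means and name in spec.population_trait_means:
            vals = np.asarray(spec.population_trait_means[name], dtype=float)
            if len(vals) != spec.n_populations:
                raise ValueError(f"need {spec.n_populations} means for '{name}'")
            out[name] = vals
        else:
            out[name] = traits[name].mean + eff[:, ti]
    return out


def _corr_chol(names: list[str],
               corr: dict[tuple[str, str], float]) -> np.ndarray:
    k = len(names)
    R = np.eye(k)
    for (a, b), rho in corr.items():
        if a in names and b in names:
            i, j = names.index(a), names.index(b)
            R[i, j] = R[j, i] = rho
    evals = np.linalg.eigvalsh(R)
    if evals.min() < -1e-10:
        raise ValueError("residual correlation matrix is not positive semidefinite")
    return np.linalg.cholesky(R + 1e-12 * np.eye(k))


def _female_tl(rng: np.random.Generator, spec: ExperimentSimSpec,
               size: int) -> np.ndarray:
    # log-normal keeps lengths positive; slope is applied to centred TL
    return spec.female_tl_mean_mm * np.exp(
        rng.normal(0, spec.female_tl_log_sd, size)
        - spec.female_tl_log_sd**2 / 2
    )


def simulate_experiment(
    spec: ExperimentSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate clutch (experiment 1) and brood (experiment 2) tables.

    Each trait is population effect + sire effect + residual +
    tl_slope * (TL - mean TL); clutch size and mean egg mass share residual
    correlation ``tradeoff_rho``; brood size is negatively tied to
    incubation time and fry release length through the configured residual
    correlations; growth over each interval carries the density slope on
    log10(reared individuals).  Counts are rounded with a floor of 1, and
    reared fry are truncated at ``brood_cap``.
    """
    rng = np.random.default_rng(spec.seed)
    pops = [f"Pop{p + 1}" for p in range(spec.n_populations)]

    # ---- experiment 1: clutches -----------------------------------------
    ctraits = spec.clutch_traits
    cnames = list(ctraits)
    chol = _corr_chol(cnames, {("clutch_size", "mean_egg_mass_g"):
                               spec.tradeoff_rho})
    cmeans = _pop_means(spec, ctraits, chol, rng)
    clutch_rows = []
    for pi, pop in enumerate(pops):
        n = spec.clutches_per_pop
        tl = _female_tl(rng, spec, n)
        z = rng.standard_normal((n, len(cnames))) @ chol.T
        for f in range(n):
            row = {"female_id": f"{pop}_F{f + 1}", "population": pop,
                   "female_tl_mm": tl[f]}
            for ti, name in enumerate(cnames):
                t = ctraits[name]
                val = (cmeans[name][pi]
                       + z[f, ti] * np.sqrt(t.v_res)
                       + t.tl_slope * (tl[f] - spec.female_tl_mean_mm))
                row[name] = val
            row["clutch_size"] = max(1, int(round(row["clutch_size"])))
            row["mean_egg_mass_g"] = max(row["mean_egg_mass_g"], 1e-4)
            row["total_egg_mass_g"] = row["clutch_size"] * row["mean_egg_mass_g"]
            clutch_rows.append(row)
    clutches = pd.DataFrame(clutch_rows)

    # ---- experiment 2: half-sib broods ----------------------------------
    btraits = spec.brood_traits
    bnames = list(btraits)
    chol_b = _corr_chol(bnames, spec.brood_residual_corr)
    bmeans = _pop_means(spec, btraits, chol_b, rng)
    sire_sds = np.asarray([np.sqrt(btraits[n].v_male) for n in bnames])
    log_dens_centre = np.log10(min(btraits["brood_size"].mean, spec.brood_cap))
    brood_rows = []
    for pi, pop in enumerate(pops):
        sire_mat = _correlated_effects(rng, spec.sires_per_pop, sire_sds, chol_b)
        sire_eff = {name: sire_mat[:, ti] for ti, name in enumerate(bnames)}
        for s in range(spec.sires_per_pop):
            tl = _female_tl(rng, spec, spec.dams_per_sire)
            z = rng.standard_normal((spec.dams_per_sire, len(bnames))) @ chol_b.T
            for d in range(spec.dams_per_sire):
                latent = {}
                for ti, name in enumerate(bnames):
                    t = btraits[name]
                    latent[name] = (bmeans[name][pi] + sire_eff[name][s]
                                    + z[d, ti] * np.sqrt(t.v_res)
                                    + t.tl_slope * (tl[d] - spec.female_tl_mean_mm))
                brood_size = max(1, int(round(latent["brood_size"])))
                n_reared = min(brood_size, spec.brood_cap)
                dens_term = spec.density_slope * (np.log10(n_reared)
                                                  - log_dens_centre)
                g35 = max(latent["growth_0_35_mm"] + dens_term, 0.0)
                g70 = g35 + max(latent["growth_35_70_mm"] + dens_term, 0.0)
                tl0 = max(latent["fry_tl_day0_mm"], 1.0)
                brood_rows.append({
                    "brood_id": f"{pop}_S{s + 1}_D{d + 1}",
                    "population": pop,
                    "sire_id": f"{pop}_S{s + 1}",
                    "dam_id": f"{pop}_S{s + 1}_D{d + 1}",
                    "female_tl_mm": tl[d],
                    "brood_size": brood_size,
                    "n_reared": n_reared,
                    "incubation_days": max(latent["incubation_days"], 1.0),
                    "fry_tl_day0_mm": tl0,
                    "fry_tl_day35_mm": tl0 + g35,
                    "fry_tl_day70_mm": tl0 + g70,
                    "density_0_35": n_reared,
                    "density_35_70": n_reared,
                })
    broods = pd.DataFrame(brood_rows)
    return clutches, broods


def simulate_nested_trait(
    n_populations: int = 8,
    sires_per_pop: int = 4,
    dams_per_sire: int = 4,
    v_pop: float = 1.0,
    v_male: float = 0.25,
    v_res: float = 0.75,
    mean: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """One continuous trait on the bare half-sib design (for calibration).

    Returns a tidy frame (population, sire, dam, y) with y = mean +
    population effect + sire effect + residual, the exact generative model
    the nested variance-component fit assumes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_populations):
        pe = rng.normal(0, np.sqrt(v_pop))
        for s in range(sires_per_pop):
            se = rng.normal(0, np.sqrt(v_male))
            for d in range(dams_per_sire):
                rows.append({
                    "population": f"Pop{p + 1}",
                    "sire": f"S{s + 1}",
                    "dam": f"D{d + 1}",
                    "y": mean + pe + se + rng.normal(0, np.sqrt(v_res)),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# climate

def _default_profiles() -> dict[str, list[float]]:
    # southern-hemisphere tropical seasonality: warm wet Nov-Apr, cool dry Jun-Sep
    return {
        "temperature_c": [25.0, 25.0, 24.5, 23.0, 21.0, 19.0,
                          18.5, 20.0, 22.5, 24.5, 25.5, 25.5],
        "precipitation_mm": [220.0, 200.0, 150.0, 60.0, 10.0, 2.0,
                             1.0, 1.0, 5.0, 20.0, 80.0, 180.0],
    }


@dataclass
class ClimateSimSpec:
    n_years: int = 15
    monthly_profile: dict[str, list[float]] = field(default_factory=_default_profiles)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"temperature_c": 0.8, "precipitation_mm": 20.0}
    )
    start_year: int = 2001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        for var, prof in self.monthly_profile.items():
            if len(prof) != 12:
                raise ValueError(f"profile for '{var}' must have 12 values")


def simulate_climate(spec: ClimateSimSpec, site: str = "site1") -> pd.DataFrame:
    """Monthly series = seasonal baseline + i.i.d. Gaussian noise.

    Precipitation is floored at zero (dry-season months sit near it).
    Returns a tidy frame (site, year, month, <variables...>).
    """
    rng = np.random.default_rng(spec.seed)
    n = 12 * spec.n_years
    years = np.repeat(np.arange(spec.start_year, spec.start_year + spec.n_years), 12)
    months = np.tile(np.arange(1, 13), spec.n_years)
    out = pd.DataFrame({"site": site, "year": years, "month": months})
    for var, prof in spec.monthly_profile.items():
        base = np.tile(np.asarray(prof, dtype=float), spec.n_years)
        vals = base + rng.normal(0, spec.noise_sd.get(var, 0.0), n)
        if var == "precipitation_mm":
            vals = np.clip(vals, 0.0, None)
        out[var] = vals
    return out


def _jsonable(o):
    if hasattr(o, "__dataclass_fields__"):
        o = asdict(o)
    if isinstance(o, dict):
        return {("|".join(k) if isinstance(k, tuple) else str(k)): _jsonable(v)
                for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    return o


def write_spec_sidecar(spec, path) -> None:
    """JSON record of the generator spec actually used (reproducibility)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
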
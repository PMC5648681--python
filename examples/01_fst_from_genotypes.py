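"""Microsatellite divergence: simulate wild genotypes, estimate theta.

Generates a 7-population panel under the Balding-Nichols model with
divergence F = 0.10, writes/reads GENEPOP, and prints heterozygosity and
Weir-Cockerham F_ST.  Because F is the expected theta, the global value
should land near 0.10.
"""

from qstfst import (GenotypeSimSpec, global_fst, heterozygosity, pairwise_fst,
                    read_genepop, simulate_genotypes, write_genepop)

spec = GenotypeSimSpec(n_populations=7, n_per_pop=20, n_loci=7,
                       alleles_per_locus=10, divergence_f=0.10, seed=1)
gt = simulate_genotypes(spec)
write_genepop(gt, "scratch_genotypes.gen")
gt = read_genepop("scratch_genotypes.gen")

het = heterozygosity(gt)
print("per-population expected heterozygosity (mean over loci):")
print(het.groupby("population")["h_exp"].mean().round(3))

theta = global_fst(gt)
print(f"\nglobal multilocus Weir-Cockerham theta = {theta:.3f}")
print("(simulated divergence F = 0.10, so theta should be close to 0.10)")

dm = pairwise_fst(gt)
print("\npairwise theta matrix:")
print(dm.to_frame().round(3))
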
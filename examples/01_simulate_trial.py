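"""Generate a synthetic aluminum-tolerance trial and inspect its structure.

Builds a scaled-down version of the study design — partially inbred S0
lines genotyped at biallelic SNPs with slow LD decay, phenotyped for four
traits in two soil conditions (ALU = aluminum-toxic, LIM = limed control)
on a p-rep layout — and prints the structural facts the downstream
analysis relies on.
"""

import numpy as np

from alugs import SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_lines=150, n_snps=1200, n_chromosomes=6,
                       n_blocks=16, plots_per_block=13, n_checks=4,
                       check_reps=5, seed=11)
geno, truth, plots = simulate_dataset(cfg)

print(f"genotypes: {geno.n_lines} lines x {geno.n_snps} SNPs, "
      f"MAF in [{geno.maf().min():.3f}, {geno.maf().max():.3f}]")
adj = [np.corrcoef(geno.dosages[:, j], geno.dosages[:, j + 1])[0, 1]
       for j in range(60)]
print(f"mean adjacent-marker dosage correlation: {np.mean(adj):.2f} "
      f"(ld_rho = {cfg.ld_rho})")

r = np.corrcoef(truth.true_bv[('YLD', 'ALU')], truth.true_bv[('YLD', 'LIM')])[0, 1]
print(f"cross-condition genetic correlation for YLD: {r:.2f} "
      f"(target rho_g = {cfg.rho_g}) — this is the GxE knob")

for cond, sub in plots.groupby("condition"):
    fam = sub[~sub.is_check]["entry_id"].value_counts()
    print(f"{cond}: {len(sub)} plots in {cfg.n_blocks} blocks; "
          f"{(fam == 2).sum()} of {cfg.n_lines} test entries duplicated "
          f"(p-rep), checks fill the rest")
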
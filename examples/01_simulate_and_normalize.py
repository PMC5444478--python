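"""Simulate a two-genotype embryo RNA-seq experiment and normalize it.

Generates negative-binomial counts for WT and mutant embryos at three
developmental stages (four replicates each, with lane effects and
length/GC-dependent capture), then applies the 5-read expression filter,
TMM scaling factors and FPKM.
"""

from seminalseq import normalization as nz
from seminalseq.simulate import SimConfig, simulate_experiment

sim = simulate_experiment(SimConfig(n_genes=500, seed=1))
cm = sim.counts

filtered = nz.expression_filter(cm, min_count=5)
norm = nz.tmm_factors(cm)
fpkm = nz.fpkm(cm, sim.annotation["length_bp"], norm)

print(f"simulated {cm.n_genes} genes x {cm.n_samples} samples")
print(f"{len(filtered)} genes have >= 5 reads in every replicate of some "
      "genotype/stage cell (the expression filter)")
print("TMM factors (geometric mean 1; deviations reflect composition "
      "differences between libraries):")
print(norm.tmm_factor.round(3).to_string())
print("\nFPKM of the first 3 filtered genes in the first 4 samples:")
print(fpkm.loc[filtered[:3]].iloc[:, :4].round(2))
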
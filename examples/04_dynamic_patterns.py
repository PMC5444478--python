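"""Classify expression dynamics across stages within each genotype.

With three stages there are 3^(3-1) - 1 = 8 non-constant patterns of
consecutive-stage transitions (up/down/same). Each transition is labeled
from its moderated contrast (later minus earlier stage): significant and
|log2FC| >= 1 gives UP or DOWN, otherwise SAME; all-SAME genes carry no
pattern. K-means on standardized profiles is shown as a companion view.
"""

import pandas as pd

from seminalseq import de as de_mod
from seminalseq import dynamics as dyn
from seminalseq import normalization as nz
from seminalseq.simulate import SimConfig, simulate_experiment

sim = simulate_experiment(SimConfig(n_genes=800, seed=4))
cm = sim.counts
norm = nz.tmm_factors(cm)
filtered = nz.expression_filter(cm)
logexpr = de_mod.log_expression(
    nz.fpkm(cm, sim.annotation["length_bp"], norm).loc[filtered])

print(f"pattern catalogue for 3 stages: "
      f"{[p.label for p in dyn.enumerate_patterns(3)]}")

assignments = {}
for genotype in ("WT", "MUT"):
    contrasts = {f"{a}-{b}": (f"{genotype}:{b}", f"{genotype}:{a}")
                 for a, b in [(25, 30), (30, 35)]}
    trans, _ = de_mod.de_analysis(logexpr, cm.samples, contrasts=contrasts)
    assignments[genotype] = dyn.assign_patterns_table(
        trans.rename(columns={"contrast": "transition"}))

comp = dyn.compare_genotype_patterns(assignments["WT"], assignments["MUT"])
print(f"\ngenes with a dynamic pattern: WT {comp['n_assigned_a']}, "
      f"MUT {comp['n_assigned_b']}")
print(f"genes with the same pattern in both genotypes: {comp['overlap']}")
print("\nper-pattern tallies (n_same = identical in both genotypes):")
print(comp["per_pattern"].to_string())

profiles = pd.DataFrame({
    s: logexpr[[c for c in logexpr.columns if c.startswith(f"WT_{s}_")]]
    .mean(axis=1) for s in (25, 30, 35)
})
km = dyn.kmeans_profiles(profiles, k=8, seed=4)
print("\nK-means companion view, cluster sizes:",
      km.value_counts().sort_index().tolist())
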
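# seminalseq

A tested, reusable implementation of the transcriptome-analysis workflow for
comparing wild-type and *rtcs* (rootless concerning crown and seminal roots)
maize embryos across three stages of seminal-root primordia formation
(25, 30, 35 days after pollination). The mutant lacks an LBD transcription
factor required for seminal-root initiation; contrasting the two
transcriptomes, stage by stage, nominates the genes and putative direct
targets behind that program. The pipeline starts from a gene x sample
count matrix and provides:

* **Bayesian gene-activity calling** — per gene, a negative-binomial
  generalized linear mixed model with one fixed effect per genotype/stage
  cell, a sequencing-lane random effect, and library-size plus length/GC
  offsets:

  `y_gi ~ NB(mu_gi, phi_g)`, `log mu_gi = beta_{g,ts} + u_lane(i) + o_i + o_g`

  with empirical-Bayes priors `beta_{g,ts} ~ N(m_ts, v_ts)`,
  `log phi_g ~ N(m_phi, v_phi)` estimated across genes, posteriors by
  per-gene Laplace approximation, and the activity rule
  `P_gts(T) = Pr(beta_{g,ts} > T | data) > 0.5`.
* **Differential expression** — the 5-reads-in-all-replicates expression
  filter, TMM normalization, FPKM, then moderated t statistics on
  log2(FPKM + 0.5) with the lane as a random effect (consensus intra-lane
  correlation, GLS), Benjamini–Hochberg FDR, and the call
  `q < 0.05 AND |log2FC| >= 1`.
* **Dynamic patterns** — the `3^(t-1) - 1` catalogue of up/down/same
  transition patterns (8 for three stages), rule-based assignment from
  consecutive-stage contrasts, K-means companion view, genotype overlap.
* **Promoter motifs** — 1-kb upstream (of the ATG) promoter extraction and
  exact scanning for the LBD motif 5'-GCGGCG-3'.
* **Enrichment** — functional-category and syntenic/non-syntenic
  over/under-representation by chi-square with Yates' continuity correction
  (alpha = 0.01), expected counts from the expressed-gene background.
* **Synthetic data with exact truth** — a generator that emulates the
  full design (NB counts, lane effects, length/GC capture, inactive genes,
  DE genes, planted patterns, synteny enrichment, planted motifs) so every
  stage is testable without external data.

`docs/methods.md` describes the models, defaults and limitations in detail.

## Worked example

`examples/` contains one short script per capability. For instance, activity
calling on a simulated 400-gene experiment (`examples/02_activity_calling.py`):

```bash
$ python examples/02_activity_calling.py
activity threshold T = -9.48 (natural-log scale)
genes called active per genotype/stage cell:
WT:25     295
WT:30     295
WT:35     293
MUT:25    294
MUT:30    293
MUT:35    296

active in >= 1 cell: 315
constitutively active (all 6 cells): 265
exclusive to WT: 8, exclusive to MUT: 11
```

`T` is the fixed-effect level at which a gene would yield ~5 expected reads
in a median library; each per-cell count is the number of genes whose
posterior probability of exceeding `T` is above one half; the
"exclusive" sets are genes active in at least one cell of one genotype and
none of the other — the genotype-specific genes this comparison is designed
to surface. The other examples print, analogously, the normalization
factors, the per-stage DE Venn partition, the 8-pattern tallies with the
between-genotype overlap, planted-motif recovery (48 of 131 promoters, 37%),
and the enrichment and QC summaries.

The whole pipeline also runs as one command:

```bash
seminal-seq all --out results/ --seed 1       # simulates, then runs all stages
seminal-seq simulate --out sim/ --seed 1 --n-genes 500
seminal-seq normalize --counts sim/counts.tsv --annotation sim/annotation.tsv --out norm/
```

`results/report.json` collects the headline numbers (per-cell active counts,
DE Venn, pattern tallies, motif fractions, enrichment p-values), each
recomputable from the stage tables written next to it.

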
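"""Synthetic RNA-seq experiment generator with known truth.

Emulates a two-genotype (wild type vs mutant), three-stage embryo RNA-seq
design with four replicates per genotype/stage cell: negative-binomial counts
whose log mean is a per-cell fixed effect plus a sequencing-lane random
effect, a library-size offset and a smooth length/GC capture effect.
Planted structure — inactive genes, differentially expressed genes,
dynamic expression patterns, synteny enrichment among DE genes, and LBD
promoter motifs — is recorded exactly in a :class:`SimTruth` object so every
downstream stage of the pipeline can be scored against ground truth.

The negative binomial is parameterized throughout as Var = mu + phi * mu^2
(phi = dispersion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleMeta

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate_experiment",
           "plant_motifs", "build_genome", "ConfigError"]

LN2 = math.log(2.0)
LBD_MOTIF = "GCGGCG"

TF_FAMILIES = ("ERF", "NAC", "bHLH", "bZIP", "HOMEOBOX", "MYB", "WRKY", "LBD")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Scales are tuned to each other: with the default library size of ~1e6
    fragments, an active-gene fixed effect of -10 corresponds to ~45 expected
    reads, the activity threshold implied by a 5-read scale is
    log(5e-6) ~ -12.2, and the inactive level of -14.2 sits two log units
    below that threshold (~0.7 expected reads).
    """

    n_genes: int = 2000
    genotypes: tuple[str, str] = ("WT", "MUT")
    stages: tuple[int, ...] = (25, 30, 35)
    reps_per_cell: int = 4
    n_lanes: int = 4
    lane_sd: float = 0.1

    # fixed-effect scales (natural-log of per-fragment rate)
    baseline_logmean: tuple[float, float] = (-10.0, 1.5)   # (mu, sd) for active genes
    inactive_level: float = -14.2
    activity_threshold: float = -12.2  # T used to derive truth activity flags
    inactive_fraction: float | Mapping[tuple[str, int], float] = 0.2
    genotype_specific_fraction: float = 0.04

    # differential expression (WT minus MUT, log2 scale)
    de_fraction: float = 0.10
    de_log2fc_min: float = 1.0
    de_log2fc_exp_scale: float = 0.7   # |lfc| = min + Exponential(scale)
    de_stage_mode: str = "subset"      # "subset": random non-empty stage subset; "all"

    # dynamic patterns: per-transition step in log2 units
    pattern_fraction: float = 0.15
    pattern_step_log2: float = 2.0
    pattern_assignments: Mapping[str, int] | None = None  # label -> gene quota

    # dispersion and gene covariates
    dispersion_logmean: float = math.log(0.1)
    dispersion_logsd: float = 0.6
    length_logmean: float = math.log(1500.0)
    length_logsd: float = 0.5
    gc_beta: tuple[float, float] = (17.0, 19.0)
    capture_len_coef: float = 1.0
    capture_gc_coef: float = -2.0      # coefficient of (gc - 0.5)^2

    # library sizes and lanes
    libsize_logmean: float = math.log(1.0e6)
    libsize_logsd: float = 0.15

    # annotation structure
    synteny_base_nonsyntenic: float = 0.51
    synteny_de_enrichment: float = 1.7  # odds multiplier for non-syntenic among DE
    n_categories: int = 32
    tf_fraction: float = 0.08

    # promoters
    promoter_len: int = 1000
    motif_fraction: float = 0.30
    make_promoters: bool = True

    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "genotype_specific_fraction": self.genotype_specific_fraction,
            "de_fraction": self.de_fraction,
            "pattern_fraction": self.pattern_fraction,
            "motif_fraction": self.motif_fraction,
            "tf_fraction": self.tf_fraction,
            "synteny_base_nonsyntenic": self.synteny_base_nonsyntenic,
        }
        if isinstance(self.inactive_fraction, Mapping):
            for k, v in self.inactive_fraction.items():
                fracs[f"inactive_fraction[{k}]"] = v
        else:
            fracs["inactive_fraction"] = self.inactive_fraction
        for name, v in fracs.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.reps_per_cell < 2:
            raise ConfigError("need >= 2 replicates per cell for model fitting")
        if self.de_log2fc_min < 1.0:
            raise ConfigError("de_log2fc_min must be >= 1 (DE definition)")
        if self.pattern_assignments is not None:
            total = sum(self.pattern_assignments.values())
            if total > self.n_genes:
                raise ConfigError(
                    f"pattern_assignments ask for {total} genes, "
                    f"only {self.n_genes} available"
                )

    @property
    def cells(self) -> list[tuple[str, int]]:
        return [(g, s) for g in self.genotypes for s in self.stages]

    def cell_labels(self) -> list[str]:
        return [f"{g}:{s}" for g, s in self.cells]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    beta/active are genes x cell-label frames; ``gene`` holds per-gene scalar
    truth (dispersion, synteny, DE flags and signed WT-minus-MUT log2 fold
    changes per stage, pattern label per genotype, planted-motif count);
    ``motif_positions`` maps gene -> list of planted 0-based offsets.
    """

    beta: pd.DataFrame
    active: pd.DataFrame
    gene: pd.DataFrame
    lane_effects: pd.Series
    library_sizes: pd.Series
    capture_offsets: pd.Series
    motif_positions: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class SimResult:
    counts: CountMatrix
    annotation: pd.DataFrame
    promoters: dict[str, str]
    truth: SimTruth

    def __iter__(self):
        return iter((self.counts, self.annotation, self.promoters, self.truth))


def _transition_label(delta_log2: np.ndarray, threshold: float = 1.0) -> list[str]:
    out = []
    for d in delta_log2:
        if d >= threshold:
            out.append("UP")
        elif d <= -threshold:
            out.append("DOWN")
        else:
            out.append("SAME")
    return out


def pattern_label_from_beta(beta_stages: np.ndarray, threshold: float = 1.0) -> str:
    """Rule-based pattern of a per-stage fixed-effect trajectory (natural log)."""
    deltas = np.diff(beta_stages) / LN2
    labels = _transition_label(deltas, threshold)
    if all(l == "SAME" for l in labels):
        return "NONE"
    return "-".join(labels)


def _inactive_p(config: SimConfig, cell: tuple[str, int]) -> float:
    if isinstance(config.inactive_fraction, Mapping):
        return float(config.inactive_fraction.get(cell, 0.0))
    return float(config.inactive_fraction)


def _draw_clean_promoter(rng: np.random.Generator, length: int) -> str:
    bases = np.array(list("ACGT"))
    for _ in range(200):
        seq = "".join(rng.choice(bases, size=length))
        if LBD_MOTIF not in seq:
            return seq
    raise RuntimeError("failed to draw a motif-free promoter")  # pragma: no cover


def plant_motifs(
    promoters: Mapping[str, str],
    fraction: float,
    seed: int | np.random.Generator,
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Plant the LBD hexamer into round(fraction * n) promoters.

    Promoters must be motif-free beforehand. Returns the edited promoter set
    and a map gene -> planted 0-based offsets (empty list when unplanted).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"motif fraction {fraction} outside [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    names = list(promoters)
    for name in names:
        if LBD_MOTIF in promoters[name]:
            raise ValueError(f"promoter {name!r} already contains {LBD_MOTIF}")
    n_plant = round(fraction * len(names))
    chosen = rng.choice(len(names), size=n_plant, replace=False) if n_plant else []
    out = dict(promoters)
    positions: dict[str, list[int]] = {name: [] for name in names}
    for idx in chosen:
        name = names[idx]
        seq = out[name]
        pos = int(rng.integers(0, len(seq) - len(LBD_MOTIF) + 1))
        out[name] = seq[:pos] + LBD_MOTIF + seq[pos + len(LBD_MOTIF):]
        positions[name] = [pos]
    return out, positions


def build_genome(
    promoters: Mapping[str, str],
    seed: int | np.random.Generator,
    cds_len: int = 60,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Embed each promoter in a one-gene contig, half on each strand.

    Returns (genome, coords) where coords has columns chrom/strand/atg_pos
    (1-based position of the A of the ATG on the contig). Extracting
    ``len(promoter)`` bases upstream of the ATG, strand-aware, recovers each
    promoter exactly.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    comp = str.maketrans("ACGTN", "TGCAN")
    bases = np.array(list("ACGT"))
    genome: dict[str, str] = {}
    rows = []
    for gene, prom in promoters.items():
        cds = "".join(rng.choice(bases, size=cds_len))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"contig_{gene}"
        if strand == "+":
            contig = prom + "ATG" + cds
            atg_pos = len(prom) + 1
        else:
            # minus-strand gene reads right-to-left: revcomp(prom+ATG+cds)
            contig = (prom + "ATG" + cds)[::-1].translate(comp)
            atg_pos = cds_len + 3  # contig position pairing with the A of ATG
        genome[chrom] = contig
        rows.append({"gene_id": gene, "chrom": chrom, "strand": strand,
                     "atg_pos": atg_pos})
    coords = pd.DataFrame(rows).set_index("gene_id")
    return genome, coords


def simulate_experiment(config: SimConfig) -> SimResult:
    """Generate counts, annotation, promoters and exact truth labels.

    Counts are drawn y ~ NB(mean = exp(beta_cell + u_lane + log(libsize) +
    f(length, gc)), dispersion phi_g); deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    cells = config.cells
    cell_labels = config.cell_labels()
    stages = list(config.stages)
    wt, mut = config.genotypes
    genes = [f"g{i + 1:05d}" for i in range(G)]

    # --- gene covariates -------------------------------------------------
    lengths = np.maximum(
        rng.lognormal(config.length_logmean, config.length_logsd, G), 200.0
    ).astype(np.int64)
    gc = rng.beta(*config.gc_beta, G)
    capture = (config.capture_len_coef * np.log(lengths)
               + config.capture_gc_coef * (gc - 0.5) ** 2)
    capture = capture - capture.mean()
    phi = rng.lognormal(config.dispersion_logmean, config.dispersion_logsd, G)

    # --- activity structure (nested thresholds => mostly constitutive) ---
    u_act = rng.random(G)
    inactive = np.zeros((G, len(cells)), dtype=bool)
    for j, cell in enumerate(cells):
        inactive[:, j] = u_act < _inactive_p(config, cell)
    fully_active = ~inactive.any(axis=1)

    order = rng.permutation(np.flatnonzero(fully_active))
    cursor = 0

    n_gs = round(config.genotype_specific_fraction * G)
    n_gs = min(n_gs, len(order))
    gs_idx = order[:n_gs]
    cursor = n_gs
    wt_only = gs_idx[: n_gs // 2]
    mut_only = gs_idx[n_gs // 2:]
    for j, (g, _s) in enumerate(cells):
        if g == mut:
            inactive[wt_only, j] = True
        if g == wt:
            inactive[mut_only, j] = True

    n_de = round(config.de_fraction * G)
    if cursor + n_de > len(order):
        raise ConfigError(
            f"de_fraction={config.de_fraction} needs {n_de} fully active genes; "
            f"only {len(order) - cursor} available"
        )
    de_idx = order[cursor:cursor + n_de]
    cursor += n_de

    if config.pattern_assignments is not None:
        quota = dict(config.pattern_assignments)
    else:
        n_pat = round(config.pattern_fraction * G)
        pats = _all_pattern_labels(len(stages))
        base, extra = divmod(n_pat, len(pats))
        quota = {p: base + (1 if k < extra else 0) for k, p in enumerate(pats)}
    n_pat_total = sum(quota.values())
    if cursor + n_pat_total > len(order):
        raise ConfigError(
            f"pattern quotas need {n_pat_total} genes; "
            f"only {len(order) - cursor} fully active genes remain"
        )
    pattern_of: dict[int, str] = {}
    for label, count in quota.items():
        for idx in order[cursor:cursor + count]:
            pattern_of[int(idx)] = label
        cursor += count

    # --- fixed effects ---------------------------------------------------
    mu0, sd0 = config.baseline_logmean
    baseline = rng.normal(mu0, sd0, G) if sd0 > 0 else np.full(G, mu0)

    # per-gene per-stage trajectory (shared by both genotypes pre-DE);
    # pattern steps are centered on the baseline so the baseline keeps its
    # meaning as the gene's average abundance across stages
    traj = np.tile(baseline[:, None], (1, len(stages)))
    step = config.pattern_step_log2 * LN2
    for idx, label in pattern_of.items():
        dirs = label.split("-")
        path = np.zeros(len(stages))
        for t, d in enumerate(dirs):
            delta = step if d == "UP" else (-step if d == "DOWN" else 0.0)
            path[t + 1:] += delta
        traj[idx] += path - path.mean()

    # DE shifts applied to the mutant genotype (lfc = WT - MUT, log2)
    lfc = np.zeros((G, len(stages)))
    for idx in de_idx:
        mag = config.de_log2fc_min + rng.exponential(config.de_log2fc_exp_scale)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if config.de_stage_mode == "all":
            which = np.ones(len(stages), bool)
        else:
            which = rng.random(len(stages)) < 0.5
            if not which.any():
                which[rng.integers(len(stages))] = True
        lfc[idx, which] = sign * mag

    beta = np.zeros((G, len(cells)))
    for j, (g, s) in enumerate(cells):
        t = stages.index(s)
        beta[:, j] = traj[:, t]
        if g == mut:
            beta[:, j] -= lfc[:, t] * LN2
    beta[inactive] = config.inactive_level

    # --- samples, lanes, library sizes -----------------------------------
    samples: list[SampleMeta] = []
    for g, s in cells:
        for r in range(1, config.reps_per_cell + 1):
            lane = f"L{1 + (r - 1) % config.n_lanes}"
            samples.append(SampleMeta(f"{g}_{s}_r{r}", g, s, r, lane))
    lane_names = [f"L{k + 1}" for k in range(config.n_lanes)]
    u_lane = (rng.normal(0.0, config.lane_sd, config.n_lanes)
              if config.lane_sd > 0 else np.zeros(config.n_lanes))
    libsizes = rng.lognormal(config.libsize_logmean, config.libsize_logsd,
                             len(samples))

    # --- counts -----------------------------------------------------------
    cell_index = {c: j for j, c in enumerate(cells)}
    log_mu = np.empty((G, len(samples)))
    for i, sm in enumerate(samples):
        j = cell_index[sm.cell]
        log_mu[:, i] = (beta[:, j] + u_lane[lane_names.index(sm.lane)]
                        + math.log(libsizes[i]) + capture)
    mu = np.exp(log_mu)
    r_nb = 1.0 / np.maximum(phi, 1e-300)
    counts = np.empty_like(mu, dtype=np.int64)
    poissonish = phi < 1e-8
    if poissonish.any():
        counts[poissonish] = rng.poisson(mu[poissonish])
    if (~poissonish).any():
        rr = r_nb[~poissonish][:, None] * np.ones((1, len(samples)))
        mm = mu[~poissonish]
        # NB as gamma-Poisson keeps the Var = mu + phi mu^2 parameterization
        lam = rng.gamma(shape=rr, scale=mm / rr)
        counts[~poissonish] = rng.poisson(lam)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                     columns=[s.sample_id for s in samples]),
        samples,
    )

    # --- annotation -------------------------------------------------------
    p_base = config.synteny_base_nonsyntenic
    odds = p_base / (1 - p_base) * config.synteny_de_enrichment
    p_de = odds / (1 + odds)
    is_de_gene = np.zeros(G, bool)
    is_de_gene[de_idx] = True
    p_nonsyn = np.where(is_de_gene, p_de, p_base)
    nonsyn = rng.random(G) < p_nonsyn
    synteny = np.where(nonsyn, "NON_SYNTENIC", "SYNTENIC")

    cat_probs = rng.dirichlet(np.full(config.n_categories, 5.0))
    categories = rng.choice(
        [f"C{k + 1:02d}" for k in range(config.n_categories)], size=G, p=cat_probs
    )
    tf_family = np.where(
        rng.random(G) < config.tf_fraction,
        rng.choice(TF_FAMILIES, size=G),
        None,
    )
    annotation = pd.DataFrame(
        {
            "length_bp": lengths,
            "gc": gc,
            "synteny": synteny,
            "category": categories,
            "tf_family": tf_family,
        },
        index=pd.Index(genes, name="gene_id"),
    )

    # --- promoters --------------------------------------------------------
    promoters: dict[str, str] = {}
    motif_positions: dict[str, list[int]] = {g: [] for g in genes}
    if config.make_promoters:
        promoters = {
            g: _draw_clean_promoter(rng, config.promoter_len) for g in genes
        }
        promoters, motif_positions = plant_motifs(
            promoters, config.motif_fraction, rng
        )

    # --- truth ------------------------------------------------------------
    beta_df = pd.DataFrame(beta, index=genes, columns=cell_labels)
    active_df = pd.DataFrame(beta > config.activity_threshold,
                             index=genes, columns=cell_labels)
    stage_cols = {}
    for t, s in enumerate(stages):
        lfc_t = (beta_df[f"{wt}:{s}"] - beta_df[f"{mut}:{s}"]) / LN2
        stage_cols[f"lfc_{s}"] = lfc_t
        stage_cols[f"de_{s}"] = lfc_t.abs() >= config.de_log2fc_min
    gene_truth = pd.DataFrame(
        {
            "dispersion": phi,
            "synteny": synteny,
            "is_de": is_de_gene,
            "motif_planted": [len(motif_positions[g]) for g in genes],
            "pattern_WT": [
                pattern_label_from_beta(
                    beta_df.loc[g, [f"{wt}:{s}" for s in stages]].to_numpy()
                ) for g in genes
            ],
            "pattern_MUT": [
                pattern_label_from_beta(
                    beta_df.loc[g, [f"{mut}:{s}" for s in stages]].to_numpy()
                ) for g in genes
            ],
            **stage_cols,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth = SimTruth(
        beta=beta_df,
        active=active_df,
        gene=gene_truth,
        lane_effects=pd.Series(u_lane, index=lane_names),
        library_sizes=pd.Series(libsizes, index=[s.sample_id for s in samples]),
        capture_offsets=pd.Series(capture, index=genes),
        motif_positions=motif_positions,
    )
    return SimResult(cm, annotation, promoters, truth)


def _all_pattern_labels(n_stages: int) -> list[str]:
    from itertools import product

    labels = []
    for combo in product(("DOWN", "SAME", "UP"), repeat=n_stages - 1):
        if all(c == "SAME" for c in combo):
            continue
        labels.append("-".join(combo))
    return labels
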
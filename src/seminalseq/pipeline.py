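"""One-call orchestration of the full analysis with a JSON report.

Stages: (optional) simulate -> filter/normalize -> activity -> differential
expression -> dynamic patterns -> promoter motifs -> enrichment -> sample QC.
Every stage's tabular output is written under the output directory and the
headline numbers are collected in ``report.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import activity as _activity
from . import de as _de
from . import dynamics as _dynamics
from . import enrichment as _enrichment
from . import motifs as _motifs
from . import normalization as _norm
from .io import CountMatrix, read_annotation, read_counts, read_fasta, write_counts
from .simulate import SimConfig, simulate_experiment

log = logging.getLogger("seminalseq")

__all__ = ["PipelineConfig", "run_all"]

_KNOWN_KEYS = {
    "counts", "meta", "annotation", "promoters", "simulate",
    "min_count", "filter_scope", "activity_threshold", "fdr", "lfc",
    "alpha", "promoter_len", "both_strands", "background", "linkage",
    "seed", "eb_max_iter",
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for an end-to-end run."""

    counts: str | None = None
    meta: str | None = None
    annotation: str | None = None
    promoters: str | None = None
    simulate: dict[str, Any] | None = None   # SimConfig overrides, or None

    min_count: int = 5
    filter_scope: str = "cell"
    activity_threshold: float | None = None
    fdr: float = 0.05
    lfc: float = 1.0
    alpha: float = 0.01
    promoter_len: int = 1000
    both_strands: bool = False
    background: str = "active"               # active | filtered
    linkage: str = "average"
    eb_max_iter: int = 25
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if not 0 < self.fdr < 1 or not 0 < self.alpha < 1:
            raise ValueError("fdr and alpha must lie in (0, 1)")
        if self.lfc < 0 or self.min_count < 0 or self.promoter_len < 6:
            raise ValueError("threshold outside documented range")
        if self.filter_scope not in ("cell", "genotype"):
            raise ValueError(f"unknown filter_scope {self.filter_scope!r}")
        if self.background not in ("active", "filtered"):
            raise ValueError(f"unknown background {self.background!r}")


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the whole pipeline and return the report dictionary."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed}

    stage = "input"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim = simulate_experiment(SimConfig(**sim_kwargs))
            cm, annotation, promoters = sim.counts, sim.annotation, sim.promoters
            write_counts(cm, out / "counts.tsv")
            annotation.to_csv(out / "annotation.tsv", sep="\t")
        else:
            if config.counts is None:
                raise ValueError("either 'counts' or 'simulate' must be given")
            cm = read_counts(config.counts, meta_path=config.meta)
            annotation = (read_annotation(config.annotation)
                          if config.annotation else None)
            promoters = (read_fasta(config.promoters)
                         if config.promoters else {})

        stage = "normalize"
        filtered = _norm.expression_filter(cm, config.min_count,
                                           scope=config.filter_scope)
        norm = _norm.tmm_factors(cm)
        offsets = None
        if annotation is not None and len(filtered) >= 50:
            offsets = _norm.fit_length_gc_offset(cm, annotation, norm,
                                                 genes=filtered)
        lengths = (annotation["length_bp"] if annotation is not None
                   else pd.Series(1000, index=cm.genes))
        fpkm = _norm.fpkm(cm, lengths, norm)
        fpkm.to_csv(out / "fpkm.tsv", sep="\t")
        report["n_genes"] = cm.n_genes
        report["n_filtered"] = len(filtered)

        stage = "activity"
        post, hyper = _activity.activity_analysis(
            cm, norm, offsets, threshold=config.activity_threshold,
            max_iter=config.eb_max_iter,
        )
        act_summary = _activity.summarize_activity(post.call)
        _write_activity(post, out / "activity.tsv")
        report["activity"] = {
            "threshold": post.threshold,
            "per_cell": {k: int(v) for k, v in act_summary.per_cell.items()},
            "n_active_any": len(act_summary.active_any),
            "n_constitutive": len(act_summary.constitutive),
            "n_exclusive": {g: len(s) for g, s in act_summary.exclusive.items()},
        }

        stage = "differential_expression"
        filt = [g for g in filtered if g in fpkm.index]
        logexpr = _de.log_expression(fpkm.loc[filt])
        de_table, mod = _de.de_analysis(logexpr, cm.samples,
                                        fdr=config.fdr, lfc=config.lfc)
        de_table.to_csv(out / "de.tsv", sep="\t", index=False)
        venn = _de.venn_counts(de_table)
        de_genes = sorted(set(de_table.loc[de_table["de_call"], "gene"]))
        report["de"] = {
            "rho": mod.rho,
            "d0": mod.d0 if np.isfinite(mod.d0) else "inf",
            "per_contrast": {
                name: int(sub["de_call"].sum())
                for name, sub in de_table.groupby("contrast")
            },
            "venn": venn,
            "n_de_any": len(de_genes),
        }

        stage = "patterns"
        stages_ = sorted({s.stage for s in cm.samples})
        pattern_report = {}
        assignments = {}
        for genotype in ("WT", "MUT"):
            contrasts = {
                f"{a}-{b}": (f"{genotype}:{b}", f"{genotype}:{a}")
                for a, b in zip(stages_[:-1], stages_[1:])
            }
            trans, _ = _de.de_analysis(logexpr, cm.samples, contrasts=contrasts,
                                       fdr=config.fdr, lfc=config.lfc,
                                       rho=mod.rho)
            trans = trans.rename(columns={"contrast": "transition"})
            assignments[genotype] = _dynamics.assign_patterns_table(
                trans, fdr=config.fdr, lfc=config.lfc
            )
        comp = _dynamics.compare_genotype_patterns(assignments["WT"],
                                                   assignments["MUT"])
        pd.DataFrame(assignments).to_csv(out / "patterns.tsv", sep="\t")
        profiles = pd.DataFrame({
            s: logexpr[[c for c in logexpr.columns
                        if c.startswith(f"WT_{s}_")]].mean(axis=1)
            for s in stages_
        })
        km = _dynamics.kmeans_profiles(profiles, k=8, seed=config.seed)
        pattern_report = {
            "n_assigned_WT": comp["n_assigned_a"],
            "n_assigned_MUT": comp["n_assigned_b"],
            "same_pattern_overlap": comp["overlap"],
            "kmeans_sizes": km.value_counts().sort_index().tolist(),
        }
        report["patterns"] = pattern_report

        stage = "motifs"
        if promoters:
            hits = _motifs.scan_promoter_set(
                promoters, both_strands=config.both_strands)
            sets = {"all_genes": list(promoters)}
            if de_genes:
                sets["de_genes"] = [g for g in de_genes if g in hits]
            if annotation is not None and "tf_family" in annotation:
                tf_de = [g for g in de_genes
                         if g in hits and pd.notna(annotation["tf_family"].get(g))]
                if tf_de:
                    sets["de_tf_genes"] = tf_de
            summary = _motifs.motif_set_summary(hits, sets)
            summary.to_csv(out / "motifs.tsv", sep="\t")
            report["motifs"] = {
                name: {"n_with_motif": int(r["n_with_motif"]),
                       "n_total": int(r["n_total"]),
                       "fraction": float(r["fraction"])}
                for name, r in summary.iterrows()
            }

        stage = "enrichment"
        if annotation is not None and de_genes:
            background = (sorted(act_summary.active_any)
                          if config.background == "active" else filt)
            background = sorted(set(background) | set(de_genes))
            cat = _enrichment.category_enrichment(
                de_genes, annotation["category"], background,
                alpha=config.alpha,
            )
            cat.to_csv(out / "enrichment.tsv", sep="\t")
            syn = _enrichment.synteny_enrichment(
                de_genes, annotation, reference="EXPRESSED",
                background=background, alpha=config.alpha,
            )
            report["enrichment"] = {
                "n_significant_categories": int(cat["significant"].sum()),
                "synteny": {
                    "observed_nonsyntenic": syn.observed,
                    "p_value": syn.p_value,
                    "direction": syn.direction,
                },
            }

        stage = "qc"
        from .qc import sample_qc

        qc = sample_qc(logexpr, linkage=config.linkage)
        qc.pc_scores.to_csv(out / "pc_scores.tsv", sep="\t")
        report["qc"] = {
            "pc1_var": float(qc.explained_variance[0]),
            "leaf_order": qc.leaf_order,
        }
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def _write_activity(post, path: Path) -> None:
    rows = []
    for cell in post.mean.columns:
        rows.append(pd.DataFrame({
            "gene": post.mean.index,
            "cell": cell,
            "post_mean": post.mean[cell],
            "post_sd": post.sd[cell],
            "P_gts": post.p_active[cell],
            "call": np.where(post.call[cell], "ACTIVE", "INACTIVE"),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
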
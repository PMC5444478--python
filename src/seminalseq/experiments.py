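"""Self-contained validation experiments with known ground truth.

Each experiment simulates data under stated conditions, runs the relevant
pipeline stage, and scores the result against the simulator's truth labels.
They back both the test suite and the reproducibility script.

Design notes: the pattern-recovery experiment draws baselines from
N(-8.5, 0.5) (natural log of per-fragment rate) so every planted trajectory
stays at roughly 20 or more expected reads — it isolates classifier
correctness from low-abundance detection power, which is reported separately
by the power-limited default conditions. The hyperparameter-recovery score
compares the estimated prior mean against the true mean plus the realized
mean lane effect, because a constant shift between fixed effects and lane
effects is not identifiable (only their sum enters the likelihood).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import activity as act
from . import de as de_mod
from . import dynamics as dyn
from . import normalization as nz
from .enrichment import category_enrichment
from .simulate import SimConfig, simulate_experiment

__all__ = [
    "activity_recovery",
    "global_null_type_i",
    "pattern_recovery",
    "hyperparam_recovery",
    "fdr_calibration",
    "enrichment_null_calibration",
]

DEFAULT_T = -12.2


def _prepare_logexpr(sim):
    cm = sim.counts
    norm = nz.tmm_factors(cm)
    filt = nz.expression_filter(cm)
    fp = nz.fpkm(cm, sim.annotation["length_bp"], norm)
    return cm, norm, filt, de_mod.log_expression(fp.loc[filt])


def activity_recovery(seed: int, n_genes: int = 2000) -> dict[str, float]:
    """Sensitivity/specificity of activity calls, effects +-2 around T.

    Half the genes sit at T+2 (active), half at T-2 (inactive), four
    replicates per cell; the full empirical-Bayes caller is run blind.
    """
    cfg = SimConfig(
        n_genes=n_genes, seed=seed,
        baseline_logmean=(DEFAULT_T + 2.0, 0.0),
        inactive_level=DEFAULT_T - 2.0, activity_threshold=DEFAULT_T,
        inactive_fraction=0.5, genotype_specific_fraction=0.0,
        de_fraction=0.0, pattern_fraction=0.0, make_promoters=False,
    )
    sim = simulate_experiment(cfg)
    norm = nz.tmm_factors(sim.counts)
    offsets = nz.fit_length_gc_offset(sim.counts, sim.annotation, norm)
    post, _ = act.activity_analysis(sim.counts, norm, offsets)
    truth = sim.truth.active
    pred = post.call[truth.columns].to_numpy()
    t = truth.to_numpy()
    tp = int((pred & t).sum())
    fn = int((~pred & t).sum())
    tn = int((~pred & ~t).sum())
    fp = int((pred & ~t).sum())
    return {
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
        "n": int(t.size),
    }


def global_null_type_i(seed: int, n_genes: int = 2000) -> dict[str, float]:
    """Fraction of p < 0.05 under a global null (no genotype differences)."""
    sim = simulate_experiment(SimConfig(
        n_genes=n_genes, seed=seed, de_fraction=0.0,
        genotype_specific_fraction=0.0, pattern_fraction=0.0,
        make_promoters=False,
    ))
    _, _, _, logexpr = _prepare_logexpr(sim)
    table, _ = de_mod.de_analysis(logexpr, sim.counts.samples)
    rate = float((table["p_value"] < 0.05).mean())
    return {"type_i_rate": rate, "n": int(len(table))}


def fdr_calibration(seed: int, n_genes: int = 2000) -> dict[str, float]:
    """Observed FDR among DE calls with 10% true DE genes."""
    sim = simulate_experiment(SimConfig(
        n_genes=n_genes, seed=seed, de_fraction=0.10,
        genotype_specific_fraction=0.0, pattern_fraction=0.0,
        make_promoters=False,
    ))
    _, _, _, logexpr = _prepare_logexpr(sim)
    table, _ = de_mod.de_analysis(logexpr, sim.counts.samples)
    truth = sim.truth.gene
    false = 0
    called = 0
    for s in (25, 30, 35):
        sub = table[table["contrast"] == f"stage_{s}"].set_index("gene")
        calls = sub.index[sub["de_call"]]
        called += len(calls)
        false += int((~truth.loc[calls, f"de_{s}"]).sum())
    return {"observed_fdr": false / max(called, 1), "n": called}


def pattern_recovery(seed: int, n_genes: int = 2000) -> dict[str, float]:
    """Fraction of planted dynamic patterns recovered by the rule classifier."""
    sim = simulate_experiment(SimConfig(
        n_genes=n_genes, seed=seed, de_fraction=0.0,
        pattern_fraction=0.3, baseline_logmean=(-8.5, 0.5),
        make_promoters=False,
    ))
    cm, _, _, logexpr = _prepare_logexpr(sim)
    stages = sorted({s.stage for s in cm.samples})
    contrasts = {
        f"{a}-{b}": (f"WT:{b}", f"WT:{a}")
        for a, b in zip(stages[:-1], stages[1:])
    }
    trans, _ = de_mod.de_analysis(logexpr, cm.samples, contrasts=contrasts)
    assign = dyn.assign_patterns_table(
        trans.rename(columns={"contrast": "transition"}))
    truth = sim.truth.gene["pattern_WT"]
    carriers = truth.index[truth != dyn.NONE_LABEL].intersection(assign.index)
    rate = float((assign.loc[carriers] == truth.loc[carriers]).mean())
    return {"pattern_recovery": rate, "n": int(len(carriers))}


def hyperparam_recovery(seed: int, n_genes: int = 2000) -> dict[str, float]:
    """Recovery of the cross-gene prior (m, v) from beta ~ N(2, 1) per cell."""
    rng = np.random.default_rng(seed)
    C, L, reps = 6, 4, 4
    n = C * reps
    X = np.zeros((n, C))
    Z = np.zeros((n, L))
    for i in range(n):
        X[i, i // reps] = 1.0
        Z[i, i % L] = 1.0
    beta = rng.normal(2.0, 1.0, (n_genes, C))
    u = rng.normal(0.0, 0.1, L)
    phi = rng.lognormal(math.log(0.1), 0.5, n_genes)
    mu = np.exp(beta @ X.T + (Z @ u)[None, :])
    lam = rng.gamma(1.0 / phi[:, None], mu * phi[:, None])
    y = rng.poisson(lam)
    hyper, _ = act.estimate_hyperparams(y, X, Z, np.zeros((n_genes, n)))
    # beta and lane effects are identified only through their sum
    m_err = hyper.m_beta - (2.0 + u.mean())
    v_err = np.sqrt(hyper.v_beta) - 1.0
    return {
        "m_max_abs_error": float(np.abs(m_err).max()),
        "sqrt_v_max_abs_error": float(np.abs(v_err).max()),
        "n": n_genes,
    }


def enrichment_null_calibration(
    seed: int, rounds: int = 200, n_genes: int = 2000, n_categories: int = 32,
    de_size: int = 200, alpha: float = 0.01,
) -> dict[str, float]:
    """Significant categories per round for uniformly drawn DE sets."""
    import warnings

    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    probs = rng.dirichlet(np.full(n_categories, 5.0))
    cats = rng.choice([f"C{k:02d}" for k in range(n_categories)],
                      size=n_genes, p=probs)
    cmap = dict(zip(genes, cats))
    counts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(rounds):
            de = list(rng.choice(genes, size=de_size, replace=False))
            tab = category_enrichment(de, cmap, genes, alpha=alpha)
            counts.append(int(tab["significant"].sum()))
    counts = np.array(counts)
    return {
        "max_significant_per_round": int(counts.max()),
        "mean_significant_per_round": float(counts.mean()),
        "rounds": rounds,
    }
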
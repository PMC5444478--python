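"""Moderated differential expression with lane blocking.

Per-gene linear models on log2(FPKM + 0.5) with a cell-means design
(one coefficient per genotype/stage cell) are fitted by generalized least
squares under a common intra-lane correlation (the lane treated as a random
effect), residual variances are shrunk toward a common prior by
empirical-Bayes moment matching of a scaled F distribution, and pairwise
contrasts (wild type minus mutant within each stage, or later minus earlier
stage within a genotype) are tested with moderated t statistics. Calls
require both q < fdr (Benjamini-Hochberg) and |log2 fold change| >= lfc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CountMatrix, SampleMeta, ValidationError

__all__ = [
    "ModerationParams",
    "log_expression",
    "design_cell_means",
    "contrast_vector",
    "estimate_lane_correlation",
    "fit_contrasts",
    "moderate_variances",
    "bh_adjust",
    "call_de",
    "venn_counts",
    "de_analysis",
]

PSEUDOCOUNT = 0.5


@dataclass
class ModerationParams:
    """Empirical-Bayes variance prior: d0 prior df, s0_sq prior variance."""

    d0: float
    s0_sq: float
    rho: float = 0.0


def log_expression(fpkm: pd.DataFrame, pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """log2(FPKM + pseudocount), the scale used for all linear modelling."""
    return np.log2(fpkm + pseudocount)


def design_cell_means(samples: Sequence[SampleMeta]) -> tuple[np.ndarray, list[str]]:
    """Cell-means design matrix: one indicator column per (genotype, stage)."""
    labels = []
    for s in samples:
        lab = f"{s.genotype}:{s.stage}"
        if lab not in labels:
            labels.append(lab)
    labels = sorted(labels, key=lambda l: (l.split(":")[0] != "WT", int(l.split(":")[1])))
    X = np.zeros((len(samples), len(labels)))
    for i, s in enumerate(samples):
        X[i, labels.index(f"{s.genotype}:{s.stage}")] = 1.0
    if np.linalg.matrix_rank(X) < X.shape[1]:
        empty = [labels[j] for j in range(X.shape[1]) if X[:, j].sum() == 0]
        raise ValidationError(f"rank-deficient design; empty cell(s): {empty}")
    return X, labels


def contrast_vector(cell_labels: Sequence[str], plus: str, minus: str) -> np.ndarray:
    c = np.zeros(len(cell_labels))
    c[list(cell_labels).index(plus)] = 1.0
    c[list(cell_labels).index(minus)] = -1.0
    return c


def _lane_matrix(lanes: Sequence[str]) -> np.ndarray:
    names = sorted(set(lanes))
    Z = np.zeros((len(lanes), len(names)))
    for i, l in enumerate(lanes):
        Z[i, names.index(l)] = 1.0
    return Z


def _block_cov(lanes: Sequence[str], rho: float) -> np.ndarray:
    Z = _lane_matrix(lanes)
    V = rho * (Z @ Z.T)
    np.fill_diagonal(V, 1.0)
    return V


def estimate_lane_correlation(
    logexpr: pd.DataFrame,
    X: np.ndarray,
    lanes: Sequence[str],
    grid: np.ndarray | None = None,
) -> float:
    """Consensus intra-lane correlation under a random-intercept model.

    Per gene, the REML criterion of the model y = X b + e with
    cov(e) = sigma^2 [(1 - rho) I + rho * same-lane] is profiled over a grid
    of rho values; the consensus is tanh(mean(atanh(per-gene argmax))),
    trimming non-finite values. A single lane returns 0 with a warning.
    """
    if len(set(lanes)) < 2:
        warnings.warn("single sequencing lane: lane correlation set to 0")
        return 0.0
    if grid is None:
        # V stays positive definite only for rho > -1/(largest lane - 1)
        block = max(np.bincount(pd.factorize(np.asarray(lanes))[0]))
        lo = max(-0.3, -1.0 / max(block - 1, 1) + 0.05)
        grid = np.linspace(lo, 0.98, 60)
    Y = logexpr.to_numpy(dtype=float)
    n, p = X.shape
    crit = np.empty((len(grid), Y.shape[0]))
    for k, rho in enumerate(grid):
        V = _block_cov(lanes, float(rho))
        if np.linalg.eigvalsh(V).min() < 1e-4:
            crit[k] = np.inf
            continue
        try:
            W = np.linalg.inv(V)
            sign, logdetV = np.linalg.slogdet(V)
            if sign <= 0:
                crit[k] = np.inf
                continue
        except np.linalg.LinAlgError:  # pragma: no cover
            crit[k] = np.inf
            continue
        M = X.T @ W @ X
        signM, logdetM = np.linalg.slogdet(M)
        P = W - W @ X @ np.linalg.solve(M, X.T @ W)
        quad = np.einsum("gi,ij,gj->g", Y, P, Y)
        quad = np.maximum(quad, 1e-300)
        crit[k] = logdetV + logdetM + (n - p) * np.log(quad)
    best = grid[np.argmin(crit, axis=0)]
    z = np.arctanh(np.clip(best, -0.99, 0.99))
    z = z[np.isfinite(z)]
    if z.size == 0:
        warnings.warn("no finite per-gene correlation estimates; using 0")
        return 0.0
    return float(np.clip(math.tanh(z.mean()), -0.99, 0.99))


def fit_contrasts(
    logexpr: pd.DataFrame,
    X: np.ndarray,
    contrasts: Mapping[str, np.ndarray],
    lanes: Sequence[str],
    rho: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Per-gene GLS coefficients and contrast estimates under the lane blocks.

    Returns (long results frame with columns gene/contrast/estimate/
    stderr_unit, per-gene residual variance s2, residual df). ``stderr_unit``
    is the contrast standard error per unit residual sd, so the usable
    standard error is stderr_unit * s_g (or its moderated version).
    """
    Y = logexpr.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValidationError("no residual degrees of freedom")
    V = _block_cov(lanes, rho)
    W = np.linalg.inv(V)
    M = X.T @ W @ X
    Minv = np.linalg.inv(M)
    A = Minv @ X.T @ W                      # p x n
    coef = Y @ A.T                          # G x p
    resid = Y - coef @ X.T
    s2 = np.einsum("gi,ij,gj->g", resid, W, resid) / (n - p)
    s2 = np.maximum(s2, 1e-12)

    rows = []
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        est = coef @ c
        unit = math.sqrt(float(c @ Minv @ c))
        rows.append(pd.DataFrame({
            "gene": logexpr.index,
            "contrast": name,
            "estimate": est,
            "stderr_unit": unit,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out, pd.Series(s2, index=logexpr.index, name="s2"), n - p


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, with safe bracketing)."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if x <= 0:
            x = 1e-8
        if abs(dif) < 1e-10 * x:
            break
    return x


def moderate_variances(
    s2: pd.Series | np.ndarray, df: float
) -> tuple[ModerationParams, pd.Series]:
    """Empirical-Bayes shrinkage of residual variances.

    Matches the moments of log s^2 to a scaled F_{df, d0} distribution
    (digamma/trigamma equations) to estimate the prior (d0, s0_sq), then
    returns posterior variances (d0 s0^2 + df s^2) / (d0 + df). When the
    between-gene spread is no larger than the chi-square sampling noise, d0
    is infinite and every posterior variance equals s0^2.
    """
    s2_arr = np.asarray(s2, dtype=float)
    if s2_arr.size < 2:
        raise ValidationError("need at least 2 genes to moderate variances")
    z = np.log(np.maximum(s2_arr, 1e-300))
    if float(np.var(z)) < 1e-15:
        # degenerate spread: no evidence of sampling noise; the common value
        # is the prior, and every posterior variance equals it
        s0 = float(np.exp(z.mean()))
        post = np.full_like(s2_arr, s0)
        index = s2.index if isinstance(s2, pd.Series) else None
        return ModerationParams(d0=float("inf"), s0_sq=s0), pd.Series(post, index=index)
    e = z - float(special.digamma(df / 2)) + math.log(df / 2)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(float(np.mean(e)) + float(special.digamma(d0 / 2))
                         - math.log(d0 / 2))
    else:
        d0 = float("inf")
        s0_sq = math.exp(float(np.mean(e)))
    if math.isinf(d0):
        post = np.full_like(s2_arr, s0_sq)
    else:
        post = (d0 * s0_sq + df * s2_arr) / (d0 + df)
    index = s2.index if isinstance(s2, pd.Series) else None
    return ModerationParams(d0=d0, s0_sq=s0_sq), pd.Series(post, index=index)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1, order-preserving)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame, fdr: float = 0.05, lfc: float = 1.0
) -> pd.DataFrame:
    """Add q-values (BH within contrast) and the conjunction DE call.

    Expects columns gene/contrast/log2fc/p_value; the call is
    q < fdr AND |log2fc| >= lfc, direction WT_UP for positive fold change.
    """
    out = results.copy()
    out["q_value"] = np.nan
    for name, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "q_value"] = bh_adjust(out.loc[idx, "p_value"].to_numpy())
    out["de_call"] = (out["q_value"] < fdr) & (out["log2fc"].abs() >= lfc)
    out["direction"] = np.where(out["log2fc"] > 0, "WT_UP", "MUT_UP")
    out.loc[~out["de_call"], "direction"] = "NONE"
    return out


def venn_counts(de_table: pd.DataFrame) -> dict[str, int]:
    """Seven-region Venn partition of DE gene sets across three contrasts."""
    sets = {
        name: set(sub.loc[sub["de_call"], "gene"])
        for name, sub in de_table.groupby("contrast")
    }
    names = sorted(sets)
    if len(names) != 3:
        raise ValidationError(f"Venn partition needs 3 contrasts, got {len(names)}")
    a, b, c = (sets[n] for n in names)
    return {
        f"{names[0]}_only": len(a - b - c),
        f"{names[1]}_only": len(b - a - c),
        f"{names[2]}_only": len(c - a - b),
        f"{names[0]}&{names[1]}": len((a & b) - c),
        f"{names[0]}&{names[2]}": len((a & c) - b),
        f"{names[1]}&{names[2]}": len((b & c) - a),
        "all_three": len(a & b & c),
        "union": len(a | b | c),
    }


def de_analysis(
    logexpr: pd.DataFrame,
    samples: Sequence[SampleMeta],
    contrasts: Mapping[str, tuple[str, str]] | None = None,
    fdr: float = 0.05,
    lfc: float = 1.0,
    rho: float | None = None,
) -> tuple[pd.DataFrame, ModerationParams]:
    """End-to-end moderated contrasts on a log-expression matrix.

    ``contrasts`` maps a name to (plus_cell, minus_cell) labels like
    ("WT:25", "MUT:25"); the default is wild type minus mutant at every
    stage. The intra-lane correlation is estimated by REML unless supplied.
    """
    X, labels = design_cell_means(samples)
    lanes = [s.lane for s in samples]
    if contrasts is None:
        stages = sorted({s.stage for s in samples})
        contrasts = {f"stage_{t}": (f"WT:{t}", f"MUT:{t}") for t in stages}
    cvecs = {
        name: contrast_vector(labels, plus, minus)
        for name, (plus, minus) in contrasts.items()
    }
    if rho is None:
        rho = estimate_lane_correlation(logexpr, X, lanes)
    fitted, s2, df_resid = fit_contrasts(logexpr, X, cvecs, lanes, rho)
    params, s2_post = moderate_variances(s2, df_resid)
    params.rho = rho

    s2_map = s2_post.loc[fitted["gene"]].to_numpy()
    t_stat = fitted["estimate"].to_numpy() / (
        fitted["stderr_unit"].to_numpy() * np.sqrt(s2_map)
    )
    df_total = (df_resid + params.d0) if math.isfinite(params.d0) else np.inf
    p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    table = fitted.rename(columns={"estimate": "log2fc"})
    table["moderated_t"] = t_stat
    table["p_value"] = p
    table = call_de(table, fdr=fdr, lfc=lfc)
    return table, params
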
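"""Expression filtering, TMM scaling factors, FPKM, and length/GC offsets.

TMM (trimmed mean of M-values) is computed exactly as published for the
cited method: per-sample log2 ratios (M) against a reference column are
doubly trimmed — 30% from each tail of M and 5% from each tail of the
average log abundance A — and averaged with inverse asymptotic-variance
weights; factors are then rescaled to geometric mean one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError

__all__ = [
    "NormFactors",
    "OffsetModel",
    "expression_filter",
    "tmm_factors",
    "fpkm",
    "fit_length_gc_offset",
]


@dataclass
class NormFactors:
    """Per-sample scaling: TMM factor, raw library size, effective size."""

    tmm_factor: pd.Series
    library_size: pd.Series

    @property
    def effective_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor

    def sample_offsets(self, use_tmm: bool = True) -> pd.Series:
        """Natural-log offsets log(effective library size) per sample."""
        size = self.effective_size if use_tmm else self.library_size
        return np.log(size.astype(float))


@dataclass
class OffsetModel:
    """Fitted smooth capture effect f(length, gc): centered per-gene log offsets."""

    offsets: pd.Series
    df_model: int
    residual_sd: float


def expression_filter(
    cm: CountMatrix, min_count: int = 5, scope: str = "cell"
) -> list[str]:
    """Genes with at least ``min_count`` reads in every replicate of some group.

    ``scope="cell"`` requires one (genotype, stage) cell whose replicates all
    reach the threshold; ``scope="genotype"`` pools a genotype's samples
    across stages and requires all of them to reach it.
    """
    counts = cm.counts.to_numpy()
    if scope == "cell":
        groups = cm.cell_columns().values()
    elif scope == "genotype":
        meta = cm.meta
        groups = [
            [j for j, s in enumerate(cm.samples) if s.genotype == g]
            for g in sorted(meta["genotype"].unique())
        ]
    else:
        raise ValueError(f"unknown filter scope {scope!r}")
    passing = np.zeros(cm.n_genes, dtype=bool)
    for cols in groups:
        if cols:
            passing |= (counts[:, cols] >= min_count).all(axis=1)
    return [g for g, ok in zip(cm.genes, passing) if ok]


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """log2 TMM factor of one column against the reference column."""
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    if np.allclose(M, M[0], atol=1e-10):
        return 0.0  # degenerate: identical proportional columns

    n = M.size
    loM = np.floor(n * logratio_trim) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * sum_trim) + 1
    hiA = n + 1 - loA
    rM = pd.Series(M).rank(method="average").to_numpy()
    rA = pd.Series(A).rank(method="average").to_numpy()
    keep2 = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep2.any():
        return 0.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None) -> NormFactors:
    """TMM scaling factors for every sample, rescaled to geometric mean 1.

    The reference (when not given) is the sample whose upper-quartile of
    library-size-scaled counts is closest to the mean upper-quartile.
    """
    counts = cm.counts.to_numpy().astype(float)
    lib = counts.sum(axis=0)
    zero = lib == 0
    if zero.any():
        bad = cm.counts.columns[zero][0]
        raise ValidationError(f"sample {bad!r} has all-zero counts")
    if cm.n_samples < 2:
        raise ValidationError("TMM needs at least 2 samples")

    if ref_sample is None:
        f75 = np.array([
            np.quantile(counts[:, j] / lib[j], 0.75) for j in range(cm.n_samples)
        ])
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = list(cm.counts.columns).index(ref_sample)

    log2f = np.array([
        _tmm_pair(counts[:, j], counts[:, ref_j], lib[j], lib[ref_j])
        for j in range(cm.n_samples)
    ])
    factors = 2.0 ** log2f
    factors = factors / np.exp(np.mean(np.log(factors)))
    cols = cm.counts.columns
    return NormFactors(
        tmm_factor=pd.Series(factors, index=cols),
        library_size=pd.Series(lib.astype(np.int64), index=cols),
    )


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def fpkm(
    cm: CountMatrix,
    lengths: pd.Series,
    norm: NormFactors,
    use_tmm: bool = True,
) -> pd.DataFrame:
    """Fragments per kilobase per million effectively mapped reads.

    fpkm[g, i] = count[g, i] / (length_g / 1e3) / (effective_size_i / 1e6).
    Genes without a length are dropped with a warning.
    """
    missing = [g for g in cm.genes if g not in lengths.index or
               pd.isna(lengths.get(g))]
    if missing:
        warnings.warn(
            f"dropping {len(missing)} gene(s) without length "
            f"(first: {missing[0]!r})"
        )
    keep = [g for g in cm.genes if g not in set(missing)]
    counts = cm.counts.loc[keep].to_numpy(dtype=float)
    size = (norm.effective_size if use_tmm else norm.library_size)
    size = size.loc[cm.counts.columns].to_numpy(dtype=float)
    lens = lengths.loc[keep].to_numpy(dtype=float)
    vals = counts / (lens[:, None] / 1e3) / (size[None, :] / 1e6)
    return pd.DataFrame(vals, index=keep, columns=cm.counts.columns)


# ---------------------------------------------------------------------------
# length/GC capture offsets
# ---------------------------------------------------------------------------

def fit_length_gc_offset(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    norm: NormFactors,
    genes: list[str] | None = None,
    spline_df: int = 4,
) -> OffsetModel:
    """Fit the smooth capture effect f(length, gc) on the log scale.

    Regresses the per-gene mean of log((count + 0.5) / effective_size) on an
    additive cubic-regression-spline basis in log length and gc (``spline_df``
    degrees of freedom per covariate). Coefficients come from the supplied
    (typically expression-filtered) gene set; the smooth is then evaluated
    for every gene shared by the count matrix and the annotation, and the
    predictions, centered to mean zero over the fitting set, are the
    per-gene offsets o_g.
    """
    import statsmodels.api as sm
    from patsy import dmatrix

    fit_genes = list(genes) if genes is not None else cm.genes
    if len(fit_genes) < 50:
        raise ValidationError(
            f"need >= 50 genes to fit the length/GC smooth, got {len(fit_genes)}"
        )
    all_genes = [g for g in cm.genes if g in annotation.index]
    counts = cm.counts.loc[fit_genes].to_numpy(dtype=float)
    size = norm.effective_size.loc[cm.counts.columns].to_numpy(dtype=float)
    y = np.log((counts + 0.5) / size[None, :]).mean(axis=1)
    loglen = np.log(annotation.loc[all_genes, "length_bp"].to_numpy(dtype=float))
    gc = annotation.loc[all_genes, "gc"].to_numpy(dtype=float)
    if np.isnan(gc).all():
        gc = np.full_like(loglen, 0.5)

    def basis(x: np.ndarray) -> np.ndarray:
        # spline knots placed from all annotated genes; clamp to that range
        if np.ptp(x) < 1e-12:
            return np.zeros((x.size, 0))
        return np.asarray(dmatrix(
            "cr(x, df=df) - 1", {"x": x, "df": spline_df}, return_type="matrix"
        ))

    X_all = np.column_stack([np.ones(len(all_genes)), basis(loglen), basis(gc)])
    rows = pd.Index(all_genes).get_indexer(fit_genes)
    fit = sm.OLS(y, X_all[rows]).fit()
    pred = X_all @ fit.params
    center = pred[rows].mean()
    offsets = pd.Series(pred - center, index=all_genes)
    resid_sd = float(np.std(y - pred[rows], ddof=X_all.shape[1]))
    return OffsetModel(offsets=offsets, df_model=X_all.shape[1] - 1,
                       residual_sd=resid_sd)
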
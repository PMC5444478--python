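"""Bayesian gene-activity calling from a negative-binomial mixed model.

Per gene g the read count of sample i follows

    y_gi ~ NB(mean = exp(beta_g,cell(i) + u_lane(i) + offset_gi),
              Var = mu + phi_g mu^2)

with one fixed effect per genotype/stage cell, a sequencing-lane random
effect, and offsets combining the log TMM-effective library size with the
gene's length/GC capture offset. Cross-gene priors — beta_g,c ~ N(m_c, v_c)
independently per cell, log phi_g ~ N(m_phi, v_phi) — are estimated by an
empirical-Bayes moment-matching loop; the lane-effect precision carries a
fixed vague Gamma(0.5, 0.005) prior which is marginalized analytically
(a multivariate-t prior on the lane effects).

Each gene's joint posterior over (beta_1..C, u_1..L, log phi) is
approximated by a Laplace fit: the mode is found by damped Newton iteration
and the Gaussian covariance is the inverse Hessian at the mode. A gene is
called ACTIVE in a cell when the posterior probability that its fixed
effect exceeds a threshold T is strictly greater than one half:
P_gts(T) = 1 - Phi((T - mean)/sd) > 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CountMatrix, ValidationError
from .normalization import NormFactors, OffsetModel

__all__ = [
    "ActivityHyperparams",
    "GenePosteriors",
    "ActivityPosterior",
    "ActivitySummary",
    "fit_gene_posteriors",
    "estimate_hyperparams",
    "call_activity",
    "summarize_activity",
    "activity_analysis",
    "default_threshold",
]

LANE_GAMMA = (0.5, 0.005)    # fixed vague prior on lane-effect precision
SD_FLOOR = 1e-6
LOGPHI_BOUNDS = (math.log(1e-8), math.log(1e3))


@dataclass
class ActivityHyperparams:
    """Cross-gene priors: per-cell Normal on beta, Normal on log dispersion."""

    m_beta: np.ndarray          # (C,)
    v_beta: np.ndarray          # (C,), > 0
    m_logphi: float
    v_logphi: float
    lane_gamma: tuple[float, float] = LANE_GAMMA

    def validate(self) -> None:
        if (self.v_beta <= 0).any() or self.v_logphi <= 0:
            raise ValidationError("prior variances must be positive")
        if any(p <= 0 for p in self.lane_gamma):
            raise ValidationError("gamma prior parameters must be positive")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([
            self.m_beta, np.sqrt(self.v_beta),
            [self.m_logphi, math.sqrt(self.v_logphi)],
        ])


@dataclass
class GenePosteriors:
    """Laplace posterior summaries for every gene (arrays over genes)."""

    beta_mean: np.ndarray       # (G, C)
    beta_sd: np.ndarray         # (G, C)
    logphi_mean: np.ndarray     # (G,)
    logphi_sd: np.ndarray       # (G,)
    converged: np.ndarray       # (G,) bool
    theta: np.ndarray           # (G, p) full mode, for warm starts


@dataclass
class ActivityPosterior:
    """Per gene x cell posterior summaries, P_gts(T), and activity calls."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    p_active: pd.DataFrame
    call: pd.DataFrame
    threshold: float
    logphi: pd.DataFrame | None = None
    converged: pd.Series | None = None


@dataclass
class ActivitySummary:
    per_cell: pd.Series
    active_any: set[str]
    constitutive: set[str]
    exclusive: dict[str, set[str]]
    stage_pattern: pd.DataFrame


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

class _Problem:
    """Vectorized negative log posterior for a batch of genes."""

    def __init__(
        self,
        y: np.ndarray,            # (G, n)
        X: np.ndarray,            # (n, C)
        Z: np.ndarray | None,     # (n, L) or None
        offsets: np.ndarray,      # (G, n)
        hyper: ActivityHyperparams,
        fixed_logphi: float | None = None,
    ):
        self.y = y.astype(float)
        self.X = X
        self.Z = Z
        self.offsets = offsets
        self.hyper = hyper
        self.fixed_logphi = fixed_logphi
        self.G, self.n = y.shape
        self.C = X.shape[1]
        self.L = 0 if Z is None else Z.shape[1]
        self.fit_phi = fixed_logphi is None
        self.p = self.C + self.L + (1 if self.fit_phi else 0)
        self.gammaln_y = special.gammaln(self.y + 1.0)

    def split(self, theta: np.ndarray):
        beta = theta[:, : self.C]
        u = theta[:, self.C: self.C + self.L]
        if self.fit_phi:
            ell = theta[:, -1]
        else:
            ell = np.full(self.G, self.fixed_logphi)
        return beta, u, ell

    def _eta(self, beta, u):
        eta = beta @ self.X.T + self.offsets
        if self.L:
            eta = eta + u @ self.Z.T
        return eta

    def value(self, theta: np.ndarray) -> np.ndarray:
        beta, u, ell = self.split(theta)
        ell = np.clip(ell, *LOGPHI_BOUNDS)
        r = np.exp(-ell)[:, None]
        eta = self._eta(beta, u)
        mu = np.exp(np.clip(eta, -700, 700))
        nll = -(special.gammaln(self.y + r) - special.gammaln(r)
                - self.gammaln_y + r * (-ell[:, None]) + self.y * eta
                - (r + self.y) * np.log(r + mu))
        # near the Poisson limit the gammaln difference is numerically noisy;
        # use the exact limiting likelihood instead
        pois = (r[:, 0] > 1e6)
        if pois.any():
            nll[pois] = (mu[pois] - self.y[pois] * eta[pois]
                         + self.gammaln_y[pois])
        val = nll.sum(axis=1)
        h = self.hyper
        val += (0.5 * ((beta - h.m_beta) ** 2 / h.v_beta)).sum(axis=1)
        if self.L:
            a0, b0 = h.lane_gamma
            val += (a0 + self.L / 2) * np.log(b0 + 0.5 * (u ** 2).sum(axis=1))
        if self.fit_phi:
            val += 0.5 * (theta[:, -1] - h.m_logphi) ** 2 / h.v_logphi
        return val

    def grad(self, theta: np.ndarray) -> np.ndarray:
        beta, u, ell = self.split(theta)
        ell_c = np.clip(ell, *LOGPHI_BOUNDS)
        r = np.exp(-ell_c)[:, None]
        eta = self._eta(beta, u)
        mu = np.exp(np.clip(eta, -700, 700))
        g_eta = -self.y + (r + self.y) * mu / (r + mu)
        h = self.hyper
        g = np.empty((self.G, self.p))
        g[:, : self.C] = g_eta @ self.X + (beta - h.m_beta) / h.v_beta
        if self.L:
            a0, b0 = h.lane_gamma
            scale = (a0 + self.L / 2) / (b0 + 0.5 * (u ** 2).sum(axis=1))
            g[:, self.C: self.C + self.L] = g_eta @ self.Z + u * scale[:, None]
        if self.fit_phi:
            dnll_dr = (-special.digamma(self.y + r) + special.digamma(r)
                       + ell_c[:, None] - 1.0 + np.log(r + mu)
                       + (r + self.y) / (r + mu))
            g_ell = (-r * dnll_dr).sum(axis=1)
            g_ell += (theta[:, -1] - h.m_logphi) / h.v_logphi
            g[:, -1] = g_ell
        return g

    def hessian_fd(self, theta: np.ndarray) -> np.ndarray:
        """Central finite differences of the analytic gradient."""
        H = np.empty((self.G, self.p, self.p))
        for j in range(self.p):
            h = 1e-5 * (1.0 + np.abs(theta[:, j]))
            tp = theta.copy(); tp[:, j] += h
            tm = theta.copy(); tm[:, j] -= h
            H[:, :, j] = (self.grad(tp) - self.grad(tm)) / (2.0 * h[:, None])
        return 0.5 * (H + np.transpose(H, (0, 2, 1)))


def _batched_newton(
    prob: _Problem,
    theta0: np.ndarray,
    max_iter: int = 60,
    gtol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton mode search, vectorized over genes.

    Returns (theta at mode, converged mask). Steps that fail to decrease the
    objective are halved; genes whose gradient max-norm falls below ``gtol``
    (scaled by the data size) stop moving.
    """
    theta = theta0.copy()
    f = prob.value(theta)
    lam = np.full(prob.G, 1e-4)
    tol = gtol * max(1.0, prob.n)
    for _ in range(max_iter):
        g = prob.grad(theta)
        active = np.abs(g).max(axis=1) > tol
        if not active.any():
            break
        H = prob.hessian_fd(theta)
        eye = np.eye(prob.p)
        step = np.zeros_like(theta)
        Hd = H + lam[:, None, None] * eye
        try:
            step = -np.linalg.solve(Hd, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            for gi in range(prob.G):
                try:
                    step[gi] = -np.linalg.solve(Hd[gi], g[gi])
                except np.linalg.LinAlgError:
                    step[gi] = -g[gi] / (1.0 + lam[gi])
        # guard against wild steps
        norm = np.linalg.norm(step, axis=1)
        big = norm > 20.0
        step[big] *= (20.0 / norm[big])[:, None]

        alpha = np.ones(prob.G)
        improved = np.zeros(prob.G, dtype=bool)
        for _ in range(15):
            trial = theta + (alpha[:, None] * step) * active[:, None]
            f_trial = prob.value(trial)
            better = (f_trial <= f + 1e-12) & active & ~improved
            theta[better] = trial[better]
            f[better] = f_trial[better]
            improved |= better
            remaining = active & ~improved
            if not remaining.any():
                break
            alpha[remaining] *= 0.5
        lam[improved] = np.maximum(lam[improved] * 0.3, 1e-6)
        stuck = active & ~improved
        lam[stuck] = np.minimum(lam[stuck] * 10.0, 1e6)
    g = prob.grad(theta)
    converged = np.abs(g).max(axis=1) <= 10 * tol
    return theta, converged


def fit_gene_posteriors(
    counts: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None,
    offsets: np.ndarray,
    hyper: ActivityHyperparams,
    fixed_logphi: float | None = None,
    theta0: np.ndarray | None = None,
) -> GenePosteriors:
    """Laplace posterior for each gene; prior fallback for non-converged genes."""
    hyper.validate()
    prob = _Problem(counts, X, Z, offsets, hyper, fixed_logphi)
    if theta0 is None:
        theta0 = _initial_theta(prob)
    theta, converged = _batched_newton(prob, theta0)

    H = prob.hessian_fd(theta)
    beta_sd = np.empty((prob.G, prob.C))
    logphi_sd = np.zeros(prob.G)
    ok = converged.copy()
    cov = np.full((prob.G, prob.p, prob.p), np.nan)
    for gi in range(prob.G):
        try:
            c = np.linalg.inv(H[gi])
            d = np.diag(c)
            if (d <= 0).any() or not np.isfinite(d).all():
                raise np.linalg.LinAlgError
            cov[gi] = c
        except np.linalg.LinAlgError:
            ok[gi] = False
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} gene(s) did not yield a proper Laplace posterior; "
            "falling back to the prior for them"
        )
    beta_mean = theta[:, : prob.C].copy()
    diag = np.array([
        np.diag(cov[gi]) if ok[gi] else np.full(prob.p, np.nan)
        for gi in range(prob.G)
    ])
    beta_sd = np.sqrt(np.maximum(diag[:, : prob.C], SD_FLOOR**2))
    if prob.fit_phi:
        logphi_mean = theta[:, -1].copy()
        logphi_sd = np.sqrt(np.maximum(diag[:, -1], SD_FLOOR**2))
    else:
        logphi_mean = np.full(prob.G, fixed_logphi)
        logphi_sd = np.zeros(prob.G)
    # conservative fallback: posterior = prior
    bad = ~ok
    if bad.any():
        beta_mean[bad] = hyper.m_beta
        beta_sd[bad] = np.sqrt(hyper.v_beta)
        if prob.fit_phi:
            logphi_mean[bad] = hyper.m_logphi
            logphi_sd[bad] = math.sqrt(hyper.v_logphi)
    return GenePosteriors(
        beta_mean=beta_mean, beta_sd=beta_sd,
        logphi_mean=logphi_mean, logphi_sd=logphi_sd,
        converged=ok, theta=theta,
    )


def _initial_theta(prob: _Problem) -> np.ndarray:
    """Crude per-gene start: cell-wise offset-adjusted log means."""
    theta = np.zeros((prob.G, prob.p))
    w = np.exp(prob.offsets)
    for c in range(prob.C):
        cols = prob.X[:, c] > 0
        rate = (prob.y[:, cols] + 0.5) / w[:, cols]
        theta[:, c] = np.log(np.maximum(rate.mean(axis=1), 1e-12))
    if prob.fit_phi:
        theta[:, -1] = np.clip(prob.hyper.m_logphi, *LOGPHI_BOUNDS)
    return theta


def crude_hyperparams(
    counts: np.ndarray, X: np.ndarray, offsets: np.ndarray
) -> ActivityHyperparams:
    """Moment-based starting values for the empirical-Bayes loop."""
    G, n = counts.shape
    C = X.shape[1]
    w = np.exp(offsets)
    beta_hat = np.empty((G, C))
    phi_hat = np.full(G, 0.1)
    for c in range(C):
        cols = X[:, c] > 0
        rate = (counts[:, cols] + 0.5) / w[:, cols]
        beta_hat[:, c] = np.log(np.maximum(rate.mean(axis=1), 1e-12))
    # dispersion: method of moments on raw counts within cells
    ests = []
    for c in range(C):
        cols = X[:, c] > 0
        m = counts[:, cols].mean(axis=1)
        v = counts[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            est = (v - m) / np.maximum(m, 1e-12) ** 2
        ests.append(est)
    est = np.nanmedian(np.column_stack(ests), axis=1)
    good = np.isfinite(est) & (est > 0)
    phi_hat[good] = np.clip(est[good], 1e-3, 5.0)
    m_beta = beta_hat.mean(axis=0)
    v_beta = np.maximum(beta_hat.var(axis=0), 0.05)
    logphi = np.log(phi_hat)
    return ActivityHyperparams(
        m_beta=m_beta, v_beta=v_beta,
        m_logphi=float(logphi.mean()),
        v_logphi=float(max(logphi.var(), 0.05)),
    )


def estimate_hyperparams(
    counts: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None,
    offsets: np.ndarray,
    init: ActivityHyperparams | None = None,
    max_iter: int = 25,
    tol: float = 1e-3,
) -> tuple[ActivityHyperparams, GenePosteriors]:
    """Empirical-Bayes estimation of the cross-gene priors.

    Alternates (1) per-gene Laplace fits under the current priors with
    (2) moment-matching updates m_c = mean of posterior means and
    v_c = mean of (posterior mean - m_c)^2 + mean posterior variance (the
    EM update for a normal means hierarchy), identically for the log
    dispersion, until the relative change falls below ``tol`` (max
    ``max_iter`` sweeps). The lane-precision prior stays fixed and vague.
    """
    if counts.shape[0] < 200:
        raise ValidationError(
            f"empirical Bayes needs >= 200 genes, got {counts.shape[0]}"
        )
    hyper = init or crude_hyperparams(counts, X, offsets)
    theta = None
    fit = None
    for it in range(max_iter):
        fit = fit_gene_posteriors(counts, X, Z, offsets, hyper, theta0=theta)
        theta = fit.theta
        use = fit.converged if fit.converged.any() else np.ones(
            counts.shape[0], bool)
        b = fit.beta_mean[use]
        s2 = fit.beta_sd[use] ** 2
        m_new = b.mean(axis=0)
        v_new = np.maximum(((b - m_new) ** 2).mean(axis=0) + s2.mean(axis=0),
                           1e-6)
        lp, lps = fit.logphi_mean[use], fit.logphi_sd[use]
        m_phi = float(lp.mean())
        v_phi = float(max(((lp - m_phi) ** 2).mean() + (lps ** 2).mean(), 1e-6))
        new = ActivityHyperparams(m_beta=m_new, v_beta=v_new,
                                  m_logphi=m_phi, v_logphi=v_phi,
                                  lane_gamma=hyper.lane_gamma)
        delta = np.abs(new.as_vector() - hyper.as_vector())
        rel = delta / (np.abs(hyper.as_vector()) + 0.1)
        hyper = new
        if rel.max() < tol:
            break
    else:
        warnings.warn("empirical-Bayes loop did not converge; using last iterate")
    fit = fit_gene_posteriors(counts, X, Z, offsets, hyper, theta0=theta)
    return hyper, fit


# ---------------------------------------------------------------------------
# activity calls and summaries
# ---------------------------------------------------------------------------

def default_threshold(sample_offsets: np.ndarray, min_reads: float = 5.0) -> float:
    """Threshold T calibrated so exp(T + median sample offset) = min_reads."""
    return math.log(min_reads) - float(np.median(sample_offsets))


def call_activity(
    mean: pd.DataFrame, sd: pd.DataFrame, threshold: float
) -> ActivityPosterior:
    """P_gts(T) = 1 - Phi((T - mean)/sd); ACTIVE iff strictly > 0.5."""
    sd_arr = sd.to_numpy()
    if (sd_arr <= 0).any():
        raise ValidationError("posterior sd must be positive")
    z = (threshold - mean.to_numpy()) / sd_arr
    p = pd.DataFrame(stats.norm.sf(z), index=mean.index, columns=mean.columns)
    call = p > 0.5
    return ActivityPosterior(mean=mean, sd=sd, p_active=p, call=call,
                             threshold=threshold)


def summarize_activity(call: pd.DataFrame) -> ActivitySummary:
    """Per-cell totals, union, constitutive set, genotype-exclusive sets.

    Columns are cell labels "GENOTYPE:stage"; the stage-pattern table
    cross-tabulates, per genotype, the per-gene tuple of active stages.
    """
    genotypes = sorted({c.split(":")[0] for c in call.columns}, reverse=True)
    per_cell = call.sum(axis=0)
    active_any = set(call.index[call.any(axis=1)])
    constitutive = set(call.index[call.all(axis=1)])
    exclusive: dict[str, set[str]] = {}
    for g in genotypes:
        own = [c for c in call.columns if c.startswith(f"{g}:")]
        other = [c for c in call.columns if not c.startswith(f"{g}:")]
        mask = call[own].any(axis=1) & ~call[other].any(axis=1)
        exclusive[g] = set(call.index[mask])
    patterns = {}
    for g in genotypes:
        own = sorted([c for c in call.columns if c.startswith(f"{g}:")],
                     key=lambda c: int(c.split(":")[1]))
        patterns[g] = call[own].apply(
            lambda row: "".join("1" if v else "0" for v in row), axis=1
        )
    stage_pattern = pd.crosstab(patterns[genotypes[0]], patterns[genotypes[1]])
    stage_pattern.index.name = genotypes[0]
    stage_pattern.columns.name = genotypes[1]
    return ActivitySummary(
        per_cell=per_cell, active_any=active_any, constitutive=constitutive,
        exclusive=exclusive, stage_pattern=stage_pattern,
    )


def activity_analysis(
    cm: CountMatrix,
    norm: NormFactors,
    offset_model: OffsetModel | None = None,
    threshold: float | None = None,
    hyper: ActivityHyperparams | None = None,
    max_iter: int = 25,
) -> tuple[ActivityPosterior, ActivityHyperparams]:
    """Full activity pipeline on a count matrix.

    Offsets are log TMM-effective library sizes plus (when supplied) the
    per-gene capture offsets; T defaults to the 5-expected-read calibration
    against the median sample offset.
    """
    X, labels = _cell_design(cm)
    Z = _lane_design(cm)
    sample_off = norm.sample_offsets().loc[cm.counts.columns].to_numpy()
    gene_off = (offset_model.offsets.reindex(cm.genes).fillna(0.0).to_numpy()
                if offset_model is not None else np.zeros(cm.n_genes))
    offsets = gene_off[:, None] + sample_off[None, :]
    counts = cm.counts.to_numpy()
    if hyper is None:
        hyper, fit = estimate_hyperparams(counts, X, Z, offsets,
                                          max_iter=max_iter)
    else:
        fit = fit_gene_posteriors(counts, X, Z, offsets, hyper)
    if threshold is None:
        threshold = default_threshold(sample_off)
    mean = pd.DataFrame(fit.beta_mean, index=cm.genes, columns=labels)
    sd = pd.DataFrame(fit.beta_sd, index=cm.genes, columns=labels)
    post = call_activity(mean, sd, threshold)
    post.logphi = pd.DataFrame(
        {"mean": fit.logphi_mean, "sd": fit.logphi_sd}, index=cm.genes
    )
    post.converged = pd.Series(fit.converged, index=cm.genes)
    return post, hyper


def _cell_design(cm: CountMatrix) -> tuple[np.ndarray, list[str]]:
    cells = cm.cells()
    labels = [f"{g}:{s}" for g, s in cells]
    X = np.zeros((cm.n_samples, len(cells)))
    for i, s in enumerate(cm.samples):
        X[i, cells.index(s.cell)] = 1.0
    return X, labels


def _lane_design(cm: CountMatrix) -> np.ndarray | None:
    lanes = sorted({s.lane for s in cm.samples})
    if len(lanes) < 2:
        return None
    Z = np.zeros((cm.n_samples, len(lanes)))
    for i, s in enumerate(cm.samples):
        Z[i, lanes.index(s.lane)] = 1.0
    return Z
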
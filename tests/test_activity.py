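import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seminalseq import activity as act
from seminalseq import normalization as nz
from seminalseq.io import ValidationError


def _design(n_cells=1, reps=8, n_lanes=0):
    n = n_cells * reps
    X = np.zeros((n, n_cells))
    for i in range(n):
        X[i, i // reps] = 1.0
    Z = None
    if n_lanes:
        Z = np.zeros((n, n_lanes))
        for i in range(n):
            Z[i, i % n_lanes] = 1.0
    return X, Z


def _vague(n_cells, m=0.0, v=100.0):
    return act.ActivityHyperparams(
        m_beta=np.full(n_cells, m), v_beta=np.full(n_cells, v),
        m_logphi=math.log(0.1), v_logphi=1.0,
    )


def test_call_activity_boundary_is_inactive():
    """P = 0.5 exactly at mean == T: the strict rule says INACTIVE."""
    mean = pd.DataFrame({"WT:25": [0.0]}, index=["g1"])
    sd = pd.DataFrame({"WT:25": [1.0]}, index=["g1"])
    post = act.call_activity(mean, sd, threshold=0.0)
    assert post.p_active.iloc[0, 0] == pytest.approx(0.5)
    assert not post.call.iloc[0, 0]


def test_call_activity_one_sigma_above_threshold():
    mean = pd.DataFrame({"WT:25": [1.0]}, index=["g1"])
    sd = pd.DataFrame({"WT:25": [1.0]}, index=["g1"])
    post = act.call_activity(mean, sd, threshold=0.0)
    assert post.p_active.iloc[0, 0] == pytest.approx(stats.norm.cdf(1.0))
    assert post.call.iloc[0, 0]


def test_call_activity_rejects_nonpositive_sd():
    mean = pd.DataFrame({"c": [0.0]})
    sd = pd.DataFrame({"c": [0.0]})
    with pytest.raises(ValidationError):
        act.call_activity(mean, sd, 0.0)


def test_poisson_limit_matches_closed_form(rng):
    """Single cell, phi -> 0, flat prior: mode -> log(sum y / sum exp(o))."""
    X, Z = _design(1, reps=12)
    offsets = rng.normal(0.0, 0.3, (1, 12))
    mu = np.exp(1.3 + offsets)
    y = rng.poisson(mu)
    fit = act.fit_gene_posteriors(
        y, X, Z, offsets, _vague(1), fixed_logphi=math.log(1e-8)
    )
    closed = math.log(y.sum() / np.exp(offsets).sum())
    assert fit.beta_mean[0, 0] == pytest.approx(closed, abs=1e-3)


def test_tiny_dispersion_reproduces_poisson_glm(rng):
    """phi = 1e-8 gives the Poisson GLM posterior (statsmodels oracle)."""
    import statsmodels.api as sm

    X, _ = _design(2, reps=10)
    offsets = np.zeros((1, 20))
    y = rng.poisson([8.0] * 10 + [40.0] * 10)[None, :]
    fit = act.fit_gene_posteriors(
        y, X, None, offsets, _vague(2, v=1e8), fixed_logphi=math.log(1e-8)
    )
    glm = sm.GLM(y[0], X, family=sm.families.Poisson()).fit()
    assert np.allclose(fit.beta_mean[0], glm.params, atol=1e-3)
    assert np.allclose(fit.beta_sd[0], glm.bse, atol=1e-3)


def test_all_zero_counts_called_inactive():
    X, Z = _design(1, reps=8, n_lanes=4)
    y = np.zeros((1, 8), dtype=int)
    offsets = np.zeros((1, 8))
    hyper = _vague(1, m=-5.0, v=1.0)
    fit = act.fit_gene_posteriors(y, X, Z, offsets, hyper)
    mean = pd.DataFrame(fit.beta_mean, columns=["WT:25"])
    sd = pd.DataFrame(fit.beta_sd, columns=["WT:25"])
    post = act.call_activity(mean, sd, threshold=0.0)
    assert fit.beta_mean[0, 0] < -2.0
    assert post.p_active.iloc[0, 0] < 0.01
    assert not post.call.iloc[0, 0]


def test_posterior_shrinks_toward_prior_mean(rng):
    """Posterior means lie between the per-gene MLE and the prior mean."""
    X, _ = _design(1, reps=4)
    offsets = np.zeros((40, 4))
    mu_true = np.exp(rng.normal(2.0, 0.8, 40))
    y = rng.poisson(mu_true[:, None] * np.ones((1, 4))).astype(float)
    y = np.maximum(y, 1)  # keep the crude MLE finite
    hyper = act.ActivityHyperparams(
        m_beta=np.array([2.0]), v_beta=np.array([0.25]),
        m_logphi=math.log(0.05), v_logphi=0.5,
    )
    fit = act.fit_gene_posteriors(y.astype(int), X, None, offsets, hyper)
    mle = np.log(y.mean(axis=1))
    post = fit.beta_mean[:, 0]
    ok = fit.converged
    between = (post[ok] - mle[ok]) * (post[ok] - 2.0) <= 1e-6
    assert between.mean() > 0.95


def test_active_set_monotone_in_threshold(small_sim):
    cm = small_sim.counts
    norm = nz.tmm_factors(cm)
    post, hyper = act.activity_analysis(cm, norm, max_iter=8)
    sets = []
    for T in np.linspace(post.threshold - 2, post.threshold + 2, 7):
        called = act.call_activity(post.mean, post.sd, T).call
        sets.append(set(map(tuple, np.argwhere(called.to_numpy()))))
    for lo, hi in zip(sets[:-1], sets[1:]):
        assert hi <= lo


def test_hyperparam_floor_on_degenerate_spread(rng):
    """Identical genes shrink v toward its numerical floor."""
    X, Z = _design(2, reps=6, n_lanes=3)
    y_row = rng.poisson(20.0, 12)
    y = np.tile(y_row, (250, 1))
    offsets = np.zeros_like(y, dtype=float)
    hyper, fit = act.estimate_hyperparams(y, X, Z, offsets, max_iter=10)
    assert (hyper.v_beta < 0.05).all()
    assert (hyper.v_beta >= 1e-6).all()


def test_estimate_hyperparams_needs_enough_genes():
    X, _ = _design(1, reps=4)
    with pytest.raises(ValidationError, match="200"):
        act.estimate_hyperparams(np.ones((10, 4), int), X, None,
                                 np.zeros((10, 4)))


def test_offset_shift_equivariance(rng):
    """Adding log 2 to all offsets shifts every m_ts by -log 2."""
    X, Z = _design(3, reps=4, n_lanes=4)
    beta = rng.normal(1.5, 0.7, (300, 3))
    mu = np.exp(beta @ X.T)
    y = rng.poisson(mu * np.ones((300, 12)))
    off0 = np.zeros((300, 12))
    h0, _ = act.estimate_hyperparams(y, X, Z, off0, max_iter=10)
    h1, _ = act.estimate_hyperparams(y, X, Z, off0 + math.log(2), max_iter=10)
    assert np.allclose(h1.m_beta - h0.m_beta, -math.log(2), atol=0.02)
    assert np.allclose(h1.v_beta, h0.v_beta, atol=0.05)


def test_summarize_activity_sets_and_bruteforce(rng):
    cols = ["WT:25", "WT:30", "WT:35", "MUT:25", "MUT:30", "MUT:35"]
    call = pd.DataFrame(rng.random((120, 6)) < 0.6, columns=cols,
                        index=[f"g{i}" for i in range(120)])
    call.iloc[0] = True                      # constitutive
    call.iloc[1] = [True, False, False, False, False, False]  # WT@25 only
    s = act.summarize_activity(call)
    assert "g0" in s.constitutive
    assert "g1" in s.exclusive["WT"] and "g1" not in s.exclusive["MUT"]
    assert s.exclusive["WT"].isdisjoint(s.exclusive["MUT"])
    assert s.constitutive <= s.active_any
    arr = call.to_numpy()
    assert s.per_cell.tolist() == arr.sum(axis=0).tolist()
    wt_any = arr[:, :3].any(1)
    mut_any = arr[:, 3:].any(1)
    assert len(s.exclusive["WT"]) == int((wt_any & ~mut_any).sum())
    assert len(s.active_any) == int((wt_any | mut_any).sum())
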
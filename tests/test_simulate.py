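import numpy as np
import pandas as pd
import pytest

from seminalseq.simulate import (
    LBD_MOTIF,
    ConfigError,
    SimConfig,
    build_genome,
    pattern_label_from_beta,
    plant_motifs,
    simulate_experiment,
)


def test_same_seed_gives_identical_outputs():
    a = simulate_experiment(SimConfig(n_genes=80, seed=4))
    b = simulate_experiment(SimConfig(n_genes=80, seed=4))
    pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
    pd.testing.assert_frame_equal(a.truth.beta, b.truth.beta)
    assert a.promoters == b.promoters


def test_different_seed_differs():
    a = simulate_experiment(SimConfig(n_genes=50, seed=1, make_promoters=False))
    b = simulate_experiment(SimConfig(n_genes=50, seed=2, make_promoters=False))
    assert not a.counts.counts.equals(b.counts.counts)


def test_poisson_limit_variance_equals_mean():
    """With no lane noise and vanishing dispersion the counts are Poisson."""
    cfg = SimConfig(
        n_genes=500, seed=7, lane_sd=0.0, dispersion_logmean=np.log(1e-10),
        dispersion_logsd=0.0, baseline_logmean=(-10.0, 0.0),
        inactive_fraction=0.0, genotype_specific_fraction=0.0,
        de_fraction=0.0, pattern_fraction=0.0, libsize_logsd=0.0,
        capture_len_coef=0.0, capture_gc_coef=0.0, make_promoters=False,
    )
    sim = simulate_experiment(cfg)
    y = sim.counts.counts.to_numpy().ravel().astype(float)  # iid Poisson draws
    ratio = y.var() / y.mean()
    assert ratio == pytest.approx(1.0, abs=0.1)


def test_all_inactive_mean_matches_moment_oracle():
    """inactive_fraction=1: E[y] = exp(inactive_level + offsets), within 3 SE."""
    cfg = SimConfig(
        n_genes=800, seed=8, inactive_fraction=1.0, de_fraction=0.0,
        genotype_specific_fraction=0.0, pattern_fraction=0.0,
        lane_sd=0.0, libsize_logsd=0.0, capture_len_coef=0.0,
        capture_gc_coef=0.0, inactive_level=-11.0, activity_threshold=-10.0,
        make_promoters=False,
    )
    sim = simulate_experiment(cfg)
    mu = np.exp(cfg.inactive_level) * sim.truth.library_sizes.iloc[0]
    y = sim.counts.counts.to_numpy().astype(float)
    phi = sim.truth.gene["dispersion"].to_numpy()
    var = (mu + phi * mu**2).mean()
    se = np.sqrt(var / y.size)
    assert abs(y.mean() - mu) < 3 * se
    assert sim.truth.active.to_numpy().sum() == 0


def test_library_sizes_match_column_sum_expectation():
    cfg = SimConfig(n_genes=3000, seed=13, inactive_fraction=0.0,
                    genotype_specific_fraction=0.0, de_fraction=0.0,
                    pattern_fraction=0.0, make_promoters=False)
    sim = simulate_experiment(cfg)
    # expected column sum per sample from the generative law
    beta = sim.truth.beta
    cap = sim.truth.capture_offsets.to_numpy()
    for j, s in enumerate(sim.counts.samples[:4]):
        lane_u = sim.truth.lane_effects[s.lane]
        lib = sim.truth.library_sizes[s.sample_id]
        mu = np.exp(beta[f"{s.genotype}:{s.stage}"].to_numpy() + lane_u
                    + np.log(lib) + cap)
        obs = sim.counts.counts.iloc[:, j].sum()
        sd = np.sqrt((mu + sim.truth.gene["dispersion"].to_numpy() * mu**2).sum())
        assert abs(obs - mu.sum()) < 4 * sd


def test_truth_flags_consistent_with_parameters(small_sim):
    """DE flag <=> |delta beta|/ln2 >= 1; pattern label matches beta rule."""
    t = small_sim.truth
    for s in (25, 30, 35):
        lfc = (t.beta[f"WT:{s}"] - t.beta[f"MUT:{s}"]) / np.log(2)
        assert ((lfc.abs() >= 1.0) == t.gene[f"de_{s}"]).all()
        assert np.allclose(lfc, t.gene[f"lfc_{s}"])
    for g in t.beta.index[:50]:
        lab = pattern_label_from_beta(
            t.beta.loc[g, ["WT:25", "WT:30", "WT:35"]].to_numpy()
        )
        assert lab == t.gene.loc[g, "pattern_WT"]


def test_pattern_quota_exceeding_genes_rejected():
    with pytest.raises(ConfigError):
        SimConfig(n_genes=10, pattern_assignments={"UP-UP": 11}).validate()
    with pytest.raises(ConfigError):
        simulate_experiment(SimConfig(n_genes=100, de_fraction=1.0))


def test_plant_motifs_exact_counts_and_bounds():
    rng = np.random.default_rng(0)
    proms = {f"p{i}": "AT" * 500 for i in range(10)}
    out, pos = plant_motifs(proms, 0.0, rng)
    assert all(LBD_MOTIF not in s for s in out.values())
    out, pos = plant_motifs(proms, 1.0, rng)
    assert all(LBD_MOTIF in s for s in out.values())
    assert all(len(v) == 1 for v in pos.values())
    with pytest.raises(ConfigError):
        plant_motifs(proms, 1.5, rng)


def test_plant_motifs_fraction_037_of_131_gives_48():
    rng = np.random.default_rng(3)
    proms = {f"p{i}": "AT" * 500 for i in range(131)}
    out, pos = plant_motifs(proms, 0.37, rng)
    assert sum(LBD_MOTIF in s for s in out.values()) == 48


def test_genome_embedding_roundtrips_promoters(small_sim):
    genome, coords = build_genome(small_sim.promoters, seed=5)
    assert set(coords["strand"]) == {"+", "-"}
    from seminalseq.motifs import extract_promoters

    ann = small_sim.annotation.join(coords)
    proms = extract_promoters(ann, genome, promoter_len=1000)
    assert proms == small_sim.promoters
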
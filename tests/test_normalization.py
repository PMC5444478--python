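import numpy as np
import pandas as pd
import pytest

from seminalseq import normalization as nz
from seminalseq.io import CountMatrix, SampleMeta, ValidationError
from seminalseq.simulate import SimConfig, simulate_experiment


def _cm(counts, genotypes=None, stages=None, lanes=None):
    counts = np.asarray(counts)
    n = counts.shape[1]
    genotypes = genotypes or ["WT"] * n
    stages = stages or [25] * n
    lanes = lanes or [f"L{i+1}" for i in range(n)]
    reps = {}
    samples = []
    for i in range(n):
        key = (genotypes[i], stages[i])
        reps[key] = reps.get(key, 0) + 1
        samples.append(SampleMeta(f"s{i+1}", genotypes[i], stages[i],
                                  reps[key], lanes[i]))
    df = pd.DataFrame(counts, index=[f"g{i+1}" for i in range(counts.shape[0])],
                      columns=[s.sample_id for s in samples])
    return CountMatrix(df.astype(np.int64), samples)


# --------------------------------------------------------------------------
# expression filter
# --------------------------------------------------------------------------

def test_filter_boundary_all_replicates_at_five():
    """One cell with every replicate exactly at 5 reads passes the filter."""
    counts = np.zeros((1, 8), dtype=int)
    counts[0, :4] = 5
    cm = _cm(counts, genotypes=["WT"] * 4 + ["MUT"] * 4,
             stages=[30] * 8, lanes=[f"L{1 + i % 4}" for i in range(8)])
    assert nz.expression_filter(cm, 5) == ["g1"]


def test_filter_one_low_replicate_fails():
    counts = np.array([[4, 9, 9, 9]])
    cm = _cm(counts, genotypes=["WT"] * 4, lanes=["L1", "L2", "L3", "L4"])
    assert nz.expression_filter(cm, 5) == []


def test_filter_matches_bruteforce_over_cells(small_sim):
    cm = small_sim.counts
    got = set(nz.expression_filter(cm, 5))
    expect = set()
    for gi, gene in enumerate(cm.genes):
        row = cm.counts.iloc[gi]
        for cell, cols in cm.cell_columns().items():
            if all(row.iloc[j] >= 5 for j in cols):
                expect.add(gene)
                break
    assert got == expect


def test_filter_monotone_in_min_count(small_sim):
    prev = None
    for mc in (1, 5, 10, 50):
        cur = set(nz.expression_filter(small_sim.counts, mc))
        if prev is not None:
            assert cur <= prev
        prev = cur


# --------------------------------------------------------------------------
# TMM
# --------------------------------------------------------------------------

def _tmm_oracle(counts, ref_j):
    """Step-by-step doubly trimmed weighted mean, independent of the module."""
    counts = counts.astype(float)
    lib = counts.sum(axis=0)
    factors = []
    for j in range(counts.shape[1]):
        obs, ref = counts[:, j], counts[:, ref_j]
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        M = np.log2((o / lib[j]) / (r / lib[ref_j]))
        A = 0.5 * np.log2((o / lib[j]) * (r / lib[ref_j]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref_j] - r) / (lib[ref_j] * r)
        if np.allclose(M, M[0]):
            factors.append(1.0)
            continue
        n = len(M)
        loM, hiM = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        loA, hiA = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        k = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        f = np.sum(M[k] / w[k]) / np.sum(1.0 / w[k])
        factors.append(2.0 ** f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def test_tmm_identical_columns_give_unit_factors():
    col = np.array([10, 50, 3, 200, 8])
    cm = _cm(np.column_stack([col, col]))
    f = nz.tmm_factors(cm).tmm_factor
    assert np.allclose(f, 1.0)


def test_tmm_proportional_columns_give_unit_factors():
    col = np.array([10, 50, 3, 200, 8])
    cm = _cm(np.column_stack([col, 2 * col]))
    f = nz.tmm_factors(cm).tmm_factor
    assert np.allclose(f, 1.0)


def test_tmm_matches_stepwise_oracle(rng):
    counts = rng.negative_binomial(5, 0.05, size=(20, 3))
    cm = _cm(counts)
    norm = nz.tmm_factors(cm, ref_sample="s1")
    oracle = _tmm_oracle(counts, 0)
    assert np.allclose(norm.tmm_factor.to_numpy(), oracle, atol=1e-10)


def test_tmm_gene_order_permutation_invariant(rng):
    counts = rng.negative_binomial(5, 0.02, size=(40, 4))
    cm = _cm(counts)
    f1 = nz.tmm_factors(cm).tmm_factor.to_numpy()
    perm = rng.permutation(40)
    cm2 = _cm(counts[perm])
    f2 = nz.tmm_factors(cm2).tmm_factor.to_numpy()
    assert np.allclose(f1, f2)


def test_tmm_duplicate_columns_get_identical_factors(rng):
    a = rng.negative_binomial(5, 0.02, size=30)
    b = rng.negative_binomial(5, 0.01, size=30)
    cm = _cm(np.column_stack([a, a, b]))
    f = nz.tmm_factors(cm, ref_sample="s3").tmm_factor.to_numpy()
    assert f[0] == pytest.approx(f[1], rel=1e-12)


def test_tmm_all_zero_sample_rejected():
    cm = _cm(np.array([[0, 5], [0, 3]]))
    with pytest.raises(ValidationError, match="all-zero"):
        nz.tmm_factors(cm)


# --------------------------------------------------------------------------
# FPKM
# --------------------------------------------------------------------------

def test_fpkm_unit_denominators():
    cm = _cm(np.array([[10], [0]]), lanes=["L1"])
    lengths = pd.Series([1000, 500], index=["g1", "g2"])
    norm = nz.NormFactors(
        tmm_factor=pd.Series([1.0], index=["s1"]),
        library_size=pd.Series([10**6], index=["s1"]),
    )
    out = nz.fpkm(cm, lengths, norm)
    assert out.loc["g1", "s1"] == pytest.approx(10.0)
    assert out.loc["g2", "s1"] == 0.0


def test_fpkm_matches_elementwise_formula(small_sim, small_norm, rng):
    lengths = small_sim.annotation["length_bp"]
    out = nz.fpkm(small_sim.counts, lengths, small_norm)
    genes = rng.choice(small_sim.counts.genes, 20, replace=False)
    for g in genes:
        j = rng.integers(small_sim.counts.n_samples)
        s = small_sim.counts.counts.columns[j]
        expect = (small_sim.counts.counts.loc[g, s]
                  / (lengths[g] / 1e3)
                  / (small_norm.effective_size[s] / 1e6))
        assert out.loc[g, s] == pytest.approx(expect)


def test_fpkm_halving_length_doubles_value(small_sim, small_norm):
    lengths = small_sim.annotation["length_bp"]
    a = nz.fpkm(small_sim.counts, lengths, small_norm)
    b = nz.fpkm(small_sim.counts, lengths / 2, small_norm)
    assert np.allclose(b.to_numpy(), 2 * a.to_numpy())


def test_fpkm_missing_length_dropped_with_warning(small_sim, small_norm):
    lengths = small_sim.annotation["length_bp"].iloc[1:]
    with pytest.warns(UserWarning, match="without length"):
        out = nz.fpkm(small_sim.counts, lengths, small_norm)
    assert small_sim.counts.genes[0] not in out.index


# --------------------------------------------------------------------------
# length/GC offsets
# --------------------------------------------------------------------------

def test_offset_recovers_log_length_slope():
    """Counts generated with f = 1.0*log(len): fitted partial slope ~ 1."""
    cfg = SimConfig(n_genes=2000, seed=31, capture_len_coef=1.0,
                    capture_gc_coef=0.0, inactive_fraction=0.0,
                    genotype_specific_fraction=0.0, de_fraction=0.0,
                    pattern_fraction=0.0, make_promoters=False)
    sim = simulate_experiment(cfg)
    norm = nz.tmm_factors(sim.counts)
    om = nz.fit_length_gc_offset(sim.counts, sim.annotation, norm)
    loglen = np.log(sim.annotation["length_bp"].to_numpy(dtype=float))
    slope = np.polyfit(loglen, om.offsets.loc[sim.annotation.index], 1)[0]
    assert slope == pytest.approx(1.0, abs=0.1)


def test_offset_constant_covariates_give_zero(small_sim, small_norm):
    ann = small_sim.annotation.copy()
    ann["length_bp"] = 1000
    ann["gc"] = 0.5
    om = nz.fit_length_gc_offset(small_sim.counts, ann, small_norm)
    assert np.allclose(om.offsets.to_numpy(), 0.0, atol=1e-10)


def test_offset_scale_equivariance(small_sim, small_norm):
    """Multiplying all counts by 4 leaves centered offsets unchanged."""
    filt = nz.expression_filter(small_sim.counts)
    om1 = nz.fit_length_gc_offset(small_sim.counts, small_sim.annotation,
                                  small_norm, genes=filt)
    cm4 = CountMatrix(small_sim.counts.counts * 4,
                      list(small_sim.counts.samples))
    norm4 = nz.NormFactors(tmm_factor=small_norm.tmm_factor,
                           library_size=small_norm.library_size * 4)
    om4 = nz.fit_length_gc_offset(cm4, small_sim.annotation, norm4, genes=filt)
    # the 0.5 pseudocount breaks exactness where some cells have ~0 counts;
    # centered fits still agree to ~0.1 on the log scale
    assert np.allclose(om1.offsets, om4.offsets, atol=0.1)


def test_offset_refuses_tiny_gene_sets(small_sim, small_norm):
    with pytest.raises(ValidationError, match=">= 50"):
        nz.fit_length_gc_offset(small_sim.counts, small_sim.annotation,
                                small_norm, genes=small_sim.counts.genes[:10])
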
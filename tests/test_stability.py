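"""Unit and property tests for the four stability algorithms."""

import numpy as np
import pandas as pd
import pytest

from refstab.stability import (
    CtMatrix,
    bestkeeper,
    ct_to_quantity,
    delta_ct,
    genorm,
    normfinder,
    reduce_replicates,
)

from conftest import random_ct_matrix


def make_ct(values, genes=None, samples=None, **kw):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CtMatrix(pd.DataFrame(values, index=genes, columns=samples), **kw)


# ---------------------------------------------------------------- replicates

def test_reduce_replicates_means_triplicates():
    rows = []
    expected = {}
    for g in ["gA", "gB"]:
        for s in ["s1", "s2"]:
            reps = [20.0, 20.2, 20.4] if (g, s) == ("gA", "s1") else \
                np.round(np.random.default_rng(hash((g, s)) % 2**31).uniform(18, 30, 3), 2)
            expected[(g, s)] = float(np.mean(reps))
            rows += [{"sample": s, "gene": g, "replicate": r + 1, "ct": c}
                     for r, c in enumerate(reps)]
    ct = reduce_replicates(pd.DataFrame(rows))
    assert ct.values.shape == (2, 2)
    for (g, s), v in expected.items():
        assert ct.values.loc[g, s] == pytest.approx(v)
    assert ct.values.loc["gA", "s1"] == pytest.approx(20.2)


def test_reduce_replicates_single_replicate_is_identity():
    long = pd.DataFrame({"sample": ["s1"], "gene": ["g"], "replicate": [1], "ct": [25.5]})
    assert reduce_replicates(long).values.loc["g", "s1"] == 25.5


# ---------------------------------------------------------------- quantities

@pytest.mark.parametrize(
    "cts,eff,expected",
    [
        ([20.0, 21.0, 22.0], 2.0, [1.0, 0.5, 0.25]),
        ([25.0, 25.0, 25.0], 2.0, [1.0, 1.0, 1.0]),
        ([20.0, 21.0], 1.9, [1.0, 1 / 1.9]),
    ],
)
def test_ct_to_quantity(cts, eff, expected):
    ct = make_ct([cts], efficiency=pd.Series({"g0": eff}))
    np.testing.assert_allclose(ct_to_quantity(ct).to_numpy()[0], expected)


# ------------------------------------------------------------------- geNorm

def genorm_m_oracle(values: pd.DataFrame) -> pd.Series:
    """Brute-force double loop over the M definition (E = 2)."""
    y = np.log2(2.0) * (values.min(axis=1).to_numpy()[:, None] - values.to_numpy())
    genes = list(values.index)
    out = {}
    for i, gi in enumerate(genes):
        sds = []
        for j, gj in enumerate(genes):
            if i == j:
                continue
            a = y[i] - y[j]
            sds.append(np.std(a, ddof=1))
        out[gi] = np.mean(sds)
    return pd.Series(out)


def test_genorm_matches_bruteforce_oracle(ct_4x5):
    res = genorm(ct_4x5)
    oracle_m = genorm_m_oracle(ct_4x5.values)
    np.testing.assert_allclose(
        res.m_per_round[0].sort_index(), oracle_m.sort_index(), atol=1e-10
    )
    # elimination order reproduced by iterating the oracle
    remaining = list(ct_4x5.genes)
    order = []
    while len(remaining) > 2:
        m = genorm_m_oracle(ct_4x5.values.loc[remaining])
        worst = m.sort_index().idxmax()
        order.append(worst)
        remaining.remove(worst)
    assert res.elimination_order == order
    assert set(res.final_pair) == set(remaining)


def test_genorm_correlated_pair_has_zero_pair_sd():
    rng = np.random.default_rng(3)
    a = 20 + rng.standard_normal(6)
    ct = make_ct([a, a + 2.0, 20 + rng.standard_normal(6)], genes=["A", "B", "C"])
    res = genorm(ct)
    # A and B differ by a constant shift: SD of their log ratio is 0,
    # so they form the most stable pair
    assert set(res.final_pair) == {"A", "B"}
    y = np.log2(2.0) * (ct.values.min(axis=1).to_numpy()[:, None] - ct.values.to_numpy())
    assert np.std(y[0] - y[1], ddof=1) == pytest.approx(0.0, abs=1e-12)


def test_genorm_shift_invariance(ct_4x5):
    shifted = ct_4x5.values.copy()
    shifted.iloc[1] += 5.0
    res0 = genorm(ct_4x5)
    res1 = genorm(CtMatrix(shifted))
    np.testing.assert_allclose(
        res0.m_per_round[0].sort_index(), res1.m_per_round[0].sort_index(), atol=1e-10
    )


def test_genorm_final_pair_shares_rank_one(ct_4x5):
    res = genorm(ct_4x5)
    st = res.stability
    pair_ranks = st.ranks[list(res.final_pair)]
    assert (pair_ranks == 1.0).all()
    assert sorted(st.ranks) == [1.0, 1.0, 2.0, 3.0]


def test_genorm_max_m_never_increases_after_removal():
    ct = random_ct_matrix(6, 8, seed=11)
    res = genorm(ct)
    maxima = [m.max() for m in res.m_per_round]
    assert all(b <= a + 1e-12 for a, b in zip(maxima, maxima[1:]))


def test_genorm_pairwise_variation_series(ct_4x5):
    res = genorm(ct_4x5)
    assert list(res.pairwise_variation.index) == ["V2/3", "V3/4"]
    assert (res.pairwise_variation >= 0).all()


# ---------------------------------------------------------------- NormFinder

def test_normfinder_zero_variance_profiles():
    base = np.array([20.0, 21.0, 19.5, 22.0])
    ct = make_ct([base, base + 1, base + 2])
    st = normfinder(ct)
    np.testing.assert_allclose(st.values, 0.0, atol=1e-12)


def test_normfinder_shift_invariance(ct_4x6):
    shifted = ct_4x6.values.copy()
    shifted.iloc[2] += 7.5
    np.testing.assert_allclose(
        normfinder(ct_4x6).values, normfinder(CtMatrix(shifted)).values, atol=1e-10
    )


def test_normfinder_recovers_planted_variances():
    # Estimator unbiasedness at n=200: the per-gene variance estimate,
    # averaged over replicate panels to tame the ~10% sampling noise of a
    # single variance, lands within 25% of the generative value.
    k, n = 10, 200
    sigma = np.linspace(0.3, 1.2, k)
    estimates = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        ct = 25 + rng.uniform(-2, 2, size=(k, 1)) + rng.normal(size=(1, n)) \
            + sigma[:, None] * rng.standard_normal((k, n))
        estimates.append(normfinder(make_ct(ct)).values.to_numpy() ** 2)
    rel_err = np.abs(np.mean(estimates, axis=0) - sigma**2) / sigma**2
    assert (rel_err < 0.25).all()


def test_normfinder_requires_three_genes():
    with pytest.raises(ValueError, match="3 genes"):
        normfinder(random_ct_matrix(2, 5, seed=0))


def test_normfinder_grouped_runs_and_ranks():
    ct = random_ct_matrix(5, 8, seed=5)
    groups = pd.Series(["a"] * 4 + ["b"] * 4, index=ct.samples)
    st = normfinder(ct, groups=groups)
    assert (st.values >= 0).all()
    assert sorted(st.ranks)[0] == 1.0


# ---------------------------------------------------------------- BestKeeper

def test_bestkeeper_matches_hand_computation():
    vals = pd.DataFrame(
        [[20.0, 21.0, 20.5, 19.5], [30.0, 30.2, 29.8, 30.0], [25.0, 26.0, 24.0, 25.0]],
        index=["A", "B", "C"], columns=list("wxyz"),
    )
    res = bestkeeper(CtMatrix(vals))
    for g in vals.index:
        row = vals.loc[g].to_numpy()
        mad = np.mean(np.abs(row - row.mean()))
        assert res.descriptives.loc[g, "sd"] == pytest.approx(mad, abs=1e-10)
        assert res.descriptives.loc[g, "cv_percent"] == pytest.approx(
            100 * mad / row.mean(), abs=1e-10
        )
    index = np.array(
        [np.prod(vals[c]) ** (1 / 3) for c in vals.columns]
    )
    np.testing.assert_allclose(res.index.to_numpy(), index, atol=1e-10)
    for g in vals.index:
        r = np.corrcoef(vals.loc[g], index)[0, 1]
        assert res.descriptives.loc[g, "r_index"] == pytest.approx(r, abs=1e-10)


def test_bestkeeper_constant_gene_ranks_first():
    rng = np.random.default_rng(1)
    ct = make_ct([np.full(5, 24.0), 24 + rng.standard_normal(5), 30 + 2 * rng.standard_normal(5)])
    res = bestkeeper(ct)
    assert res.stability.values["g0"] == 0.0
    assert res.stability.ranks["g0"] == 1.0
    assert not res.descriptives.loc["g0", "inconsistent"]


def test_bestkeeper_identical_profiles_give_unit_correlations():
    base = np.array([20.0, 22.0, 21.0, 23.0])
    ct = make_ct([base, base, base])
    res = bestkeeper(ct)
    np.testing.assert_allclose(res.index.to_numpy(), base, atol=1e-10)
    np.testing.assert_allclose(res.descriptives["r_index"], 1.0)


def test_bestkeeper_flags_high_sd_genes():
    rng = np.random.default_rng(2)
    noisy = 25 + 5 * rng.standard_normal(12)
    quiet = 25 + 0.05 * rng.standard_normal(12)
    res = bestkeeper(make_ct([quiet, noisy], genes=["q", "n"]))
    assert res.descriptives.loc["n", "inconsistent"]
    assert not res.descriptives.loc["q", "inconsistent"]


# ------------------------------------------------------------------ delta-Ct

def deltact_oracle(values: pd.DataFrame) -> pd.Series:
    genes = list(values.index)
    out = {}
    for gi in genes:
        sds = [np.std(values.loc[gi] - values.loc[gj], ddof=1)
               for gj in genes if gj != gi]
        out[gi] = np.mean(sds)
    return pd.Series(out)


def test_deltact_matches_bruteforce_oracle(ct_4x6):
    st = delta_ct(ct_4x6)
    np.testing.assert_allclose(
        st.values.sort_index(), deltact_oracle(ct_4x6.values).sort_index(), atol=1e-12
    )


def test_deltact_constant_offset_pair_is_perfectly_stable():
    a = np.array([20.0, 21.0, 19.0, 22.0])
    st = delta_ct(make_ct([a, a + 3.0], genes=["A", "B"]))
    np.testing.assert_allclose(st.values, 0.0, atol=1e-12)


def test_deltact_permutation_equivariance(ct_4x6):
    st = delta_ct(ct_4x6)
    perm = list(ct_4x6.genes)[::-1]
    st_perm = delta_ct(ct_4x6.subset_genes(perm))
    np.testing.assert_allclose(
        st.values.sort_index(), st_perm.values.sort_index(), atol=1e-12
    )


def test_deltact_shift_invariance(ct_4x6):
    shifted = ct_4x6.values.copy()
    shifted.iloc[0] += 4.0
    np.testing.assert_allclose(
        delta_ct(ct_4x6).values, delta_ct(CtMatrix(shifted)).values, atol=1e-12
    )


# ------------------------------------------------------------------- shapes

def test_missing_cells_are_rejected():
    vals = pd.DataFrame([[20.0, np.nan], [21.0, 22.0], [23.0, 24.0]],
                        index=["a", "b", "c"], columns=["s1", "s2"])
    ct = CtMatrix(vals)
    for fn in (genorm, normfinder, bestkeeper, delta_ct):
        with pytest.raises(ValueError, match="complete"):
            fn(ct)
    complete = ct.dropna()
    assert list(complete.genes) == ["b", "c"]
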
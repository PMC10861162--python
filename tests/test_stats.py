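"""Node/edge test statistics, BH-FDR, and the Gaussian overlap coefficient."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from nbssni.stats import (
    bh_fdr,
    one_sample_ks_node_test,
    one_sample_node_test,
    ovl,
    two_sample_edge_test,
    two_sample_node_test,
)


# ------------------------------------------------------------------ one-sample t

def test_one_sample_t_null_column():
    values = np.full((5, 3), 2.0)
    values[:, 1] = [1.9, 2.0, 2.1, 2.0, 2.0]
    with pytest.warns(UserWarning):  # the two constant columns
        r = one_sample_node_test(values, mu0_mode="value", mu0_value=2.0,
                                 tail="greater")
    assert r.stat[1] == pytest.approx(0.0)
    assert r.pvalue[1] == pytest.approx(0.5)


def test_one_sample_t_hand_value():
    values = np.array([[1.0], [2.0], [3.0]])
    r = one_sample_node_test(values, mu0_mode="zero", tail="two_sided")
    assert r.stat[0] == pytest.approx(3.4641, abs=1e-4)
    assert r.pvalue[0] == pytest.approx(
        2 * sps.t.sf(3.4641016, df=2), abs=1e-6
    )


def test_one_sample_t_grand_mean_centers(rng):
    values = rng.normal(size=(20, 8))
    r = one_sample_node_test(values, mu0_mode="grand_mean")
    assert abs(r.stat.mean()) < 0.5  # exchangeable columns -> centered stats


def test_one_sample_t_zero_variance_warns():
    values = np.ones((4, 2))
    values[:, 1] = [0.0, 1.0, 2.0, 3.0]
    with pytest.warns(UserWarning):
        r = one_sample_node_test(values, mu0_mode="zero")
    assert r.stat[0] == 0.0 and r.pvalue[0] == 1.0


def test_one_sample_t_requires_two_subjects():
    with pytest.raises(ValueError):
        one_sample_node_test(np.ones((1, 3)), mu0_mode="zero")


# ------------------------------------------------------------------ KS test

def ks_dplus_oracle(sample, ref):
    """Brute force over every ECDF breakpoint."""
    best = -np.inf
    for x in np.concatenate([sample, ref]):
        f_s = np.mean(sample <= x)
        f_r = np.mean(ref <= x)
        best = max(best, f_r - f_s)
    return best


def test_ks_identical_sample_small_d(rng):
    pooled = rng.normal(size=(10, 5))
    r = one_sample_ks_node_test(pooled)
    assert np.all(r.stat <= 0.6)  # no column far from the pooled distribution


def test_ks_sample_above_maximum():
    values = np.zeros((4, 2))
    values[:, 0] = [0.1, 0.2, 0.3, 0.4]
    values[:, 1] = [10.0, 11.0, 12.0, 13.0]  # entirely above column 0
    r = one_sample_ks_node_test(values, tail="greater")
    # at x = 0.4 the pooled ECDF is 0.5 while the node ECDF is 0
    assert r.stat[1] == pytest.approx(0.5)


def test_ks_matches_breakpoint_enumeration(rng):
    values = rng.normal(size=(8, 6))
    r = one_sample_ks_node_test(values, tail="greater")
    pooled = values.ravel()
    for j in range(6):
        assert r.stat[j] == pytest.approx(
            ks_dplus_oracle(values[:, j], pooled), abs=1e-12
        )


def test_ks_constant_reference_rejected():
    with pytest.raises(ValueError):
        one_sample_ks_node_test(np.ones((5, 3)))


# ------------------------------------------------------------------ two-sample

def test_two_sample_node_identical_groups():
    v = np.arange(12.0).reshape(4, 3)
    r = two_sample_node_test(v, v)
    np.testing.assert_allclose(r.stat, 0.0)


def test_two_sample_node_hand_value():
    r = two_sample_node_test(np.array([[1.0], [2.0], [3.0]]),
                             np.array([[2.0], [3.0], [4.0]]),
                             tail="two_sided")
    assert r.stat[0] == pytest.approx(-1.2247, abs=1e-4)


def test_two_sample_node_separation_limit():
    eps = 1e-8
    a = np.array([[0.0], [eps], [-eps]])
    b = np.array([[1.0], [1 + eps], [1 - eps]])
    r = two_sample_node_test(a, b, tail="two_sided")
    assert abs(r.stat[0]) > 1e6
    assert r.pvalue[0] < 1e-10


def test_edge_test_identical_groups(rng):
    x = rng.normal(size=(4, 5, 5))
    x = (x + x.transpose(0, 2, 1)) / 2
    for m in x:
        np.fill_diagonal(m, 0.0)
    r = two_sample_edge_test(x, x)
    np.testing.assert_allclose(r.tstat, 0.0)


def test_edge_test_symmetry_and_diagonal(rng):
    def stack(k):
        x = rng.normal(size=(k, 6, 6))
        x = (x + x.transpose(0, 2, 1)) / 2
        for m in x:
            np.fill_diagonal(m, 0.0)
        return x

    r = two_sample_edge_test(stack(5), stack(7), tail="hypo")
    np.testing.assert_array_equal(r.tstat, r.tstat.T)
    np.testing.assert_array_equal(np.diag(r.tstat), 0.0)
    np.testing.assert_array_equal(np.diag(r.pvalue), 1.0)


def test_edge_test_expected_t_monte_carlo():
    # single edge, mu1 = 0.8 vs 0: E[t] ~ 0.8 / sqrt(2/30) = 3.098
    rng = np.random.default_rng(42)
    n_sims = 1000
    tvals = np.empty(n_sims)
    for s in range(n_sims):
        x1 = rng.normal(0.8, 1.0, 30)
        x2 = rng.normal(0.0, 1.0, 30)
        tvals[s] = sps.ttest_ind(x1, x2).statistic
    expected = 0.8 / np.sqrt(2 / 30)
    assert abs(tvals.mean() - expected) < 0.1

    # and the vectorized edge test agrees with scipy on one realization
    def to_stack(vals):
        out = np.zeros((vals.size, 2, 2))
        out[:, 0, 1] = out[:, 1, 0] = vals
        return out

    x1 = rng.normal(0.8, 1.0, 30)
    x2 = rng.normal(0.0, 1.0, 30)
    r = two_sample_edge_test(to_stack(x1), to_stack(x2), tail="hyper")
    assert r.tstat[0, 1] == pytest.approx(sps.ttest_ind(x1, x2).statistic)


def test_edge_test_permutation_equivariance(rng):
    def stack(k):
        x = rng.normal(size=(k, 6, 6))
        x = (x + x.transpose(0, 2, 1)) / 2
        for m in x:
            np.fill_diagonal(m, 0.0)
        return x

    x1, x2 = stack(5), stack(5)
    perm = rng.permutation(6)
    r = two_sample_edge_test(x1, x2)
    rp = two_sample_edge_test(x1[:, perm][:, :, perm], x2[:, perm][:, :, perm])
    np.testing.assert_allclose(rp.tstat, r.tstat[perm][:, perm], atol=1e-12)


def test_edge_test_null_calibration():
    # global null: suprathreshold fraction ~ one-tailed t tail probability
    rng = np.random.default_rng(2024)
    alpha = 0.05
    hits = total = 0
    for _ in range(30):
        x1 = rng.normal(size=(10, 6, 6))
        x2 = rng.normal(size=(10, 6, 6))
        x1 = (x1 + x1.transpose(0, 2, 1)) / 2
        x2 = (x2 + x2.transpose(0, 2, 1)) / 2
        r = two_sample_edge_test(x1, x2)
        iu, ju = np.triu_indices(6, k=1)
        hits += (r.pvalue[iu, ju] < alpha).sum()
        total += iu.size
    sd = np.sqrt(alpha * (1 - alpha) / total)
    assert abs(hits / total - alpha) < 3 * sd


# ------------------------------------------------------------------ BH-FDR

def bh_oracle(p, q):
    """Exhaustive search over all rejection cut ranks."""
    p = np.asarray(p)
    m = p.size
    order = np.argsort(p)
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            best_k = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:best_k]] = True
    return mask


def test_bh_all_rejected():
    mask = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert mask.all()


def test_bh_none_rejected():
    assert not bh_fdr([1.0, 1.0, 1.0], q=0.05).any()


def test_bh_matches_exhaustive_oracle(rng):
    for _ in range(50):
        m = int(rng.integers(1, 13))
        p = rng.random(m)
        q = float(rng.uniform(0.01, 0.5))
        np.testing.assert_array_equal(bh_fdr(p, q), bh_oracle(p, q))


def test_bh_monotone_in_q(rng):
    p = rng.random(40)
    r1 = bh_fdr(p, 0.05)
    r2 = bh_fdr(p, 0.2)
    assert np.all(r2[r1])  # rejections at q=0.05 are a subset of q=0.2


def test_bh_empty():
    assert bh_fdr([], 0.1).size == 0


# ------------------------------------------------------------------ OVL

def test_ovl_identical_means():
    assert ovl(1.3, 1.3, 2.0) == pytest.approx(1.0)


def test_ovl_hand_value():
    assert ovl(0.3, 0.0, 1.0) == pytest.approx(0.8808, abs=1e-4)


@pytest.mark.parametrize("mu", [0.2, 0.75, 1.5, 3.0])
def test_ovl_matches_quadrature(mu):
    f1 = sps.norm(0.0, 1.0).pdf
    f2 = sps.norm(mu, 1.0).pdf
    val, _ = quad(lambda x: min(f1(x), f2(x)), -10, 10 + mu)
    assert ovl(mu, 0.0, 1.0) == pytest.approx(val, abs=1e-6)


def test_ovl_requires_positive_sigma():
    with pytest.raises(ValueError):
        ovl(0.0, 1.0, 0.0)
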
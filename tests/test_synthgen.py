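"""Generative models: distance kernel, edge sampling, weight density,
functional contrasts, and the prebuilt planted scenarios."""

import numpy as np
import pytest

from nbssni.synthgen import (
    DistanceKernelParams,
    EdgeWeightSampler,
    FunctionalContrastSpec,
    StructuralGenParams,
    WeightParams,
    build_embedded_contrast_scenario,
    build_roc_scenario,
    distance_kernel,
    generate_cohort,
    sample_functional_network,
    sample_structural_network,
    structural_probability_matrix,
    synthetic_coords,
)


# ------------------------------------------------------------------ kernel

def test_kernel_short_range_value():
    # d = 10 mm: A1 * log(10 + 899.3) / (10 + 899.3)
    val = distance_kernel(10.0)
    expected = 133.49 * np.log(909.3) / 909.3
    assert val == pytest.approx(expected, rel=1e-12)
    assert val == pytest.approx(1.0001, abs=1e-3)


def test_kernel_positive_and_finite():
    d = np.linspace(0.5, 300.0, 2000)
    vals = distance_kernel(d)
    assert np.all(vals > 0)
    assert np.all(np.isfinite(vals))


def test_kernel_long_range_decays_by_default():
    lo, hi = distance_kernel(50.0), distance_kernel(200.0)
    assert hi < lo
    grow = DistanceKernelParams(printed_long_range_sign=True)
    assert distance_kernel(200.0, grow) > distance_kernel(50.0, grow)


def test_kernel_rejects_nonpositive_distance():
    with pytest.raises(ValueError):
        distance_kernel(0.0)


# ------------------------------------------------------------------ propensity

def _params(coords, **kw):
    defaults = dict(coords=coords, m_edges=100, n_c=frozenset({0, 1}),
                    mu_nc=1.5, sigma_nc=2.0)
    defaults.update(kw)
    return StructuralGenParams(**defaults)


def test_probability_noise_free_limit():
    coords = synthetic_coords(20)
    p = _params(coords, mu_nc=0.0, sigma_nc=1e-12)
    rng = np.random.default_rng(0)
    mat = structural_probability_matrix(p, rng)
    from scipy.spatial.distance import squareform, pdist

    expected = squareform(distance_kernel(pdist(coords)))
    np.testing.assert_allclose(mat, expected, rtol=1e-6)


def test_probability_central_rows_elevated():
    coords = synthetic_coords(30)
    p = _params(coords, n_c=frozenset({0, 1, 2}), mu_nc=1.5)
    rng = np.random.default_rng(1)
    acc = np.zeros((30, 30))
    for _ in range(100):
        acc += structural_probability_matrix(p, rng)
    base = structural_probability_matrix(_params(coords, mu_nc=0.0), rng)
    ratio_central = acc[:3].mean() / 100
    ratio_other = acc[3:, 3:].mean() / 100
    # touching rows scale by ~E*(1+mu_nc adj); compare against each other
    assert ratio_central > ratio_other


def test_probability_deterministic_and_symmetric():
    coords = synthetic_coords(15)
    p = _params(coords)
    m1 = structural_probability_matrix(p, np.random.default_rng(7))
    m2 = structural_probability_matrix(p, np.random.default_rng(7))
    np.testing.assert_array_equal(m1, m2)
    np.testing.assert_array_equal(m1, m1.T)
    np.testing.assert_array_equal(np.diag(m1), 0.0)
    assert np.all(m1 >= 0)


def test_probability_extra_noise_added():
    coords = synthetic_coords(15)
    base = _params(coords, mu_nc=0.0)
    noisy = _params(coords, mu_nc=0.0, extra_noise=(3.5, 2.0))
    m_noisy = structural_probability_matrix(noisy, np.random.default_rng(3))
    m_base = structural_probability_matrix(base, np.random.default_rng(3))
    iu = np.triu_indices(15, 1)
    assert m_noisy[iu].mean() > m_base[iu].mean() + 2.0


# ------------------------------------------------------------------ edge sampling

def test_sample_complete_graph():
    n = 6
    p = np.ones((n, n)) - np.eye(n)
    rng = np.random.default_rng(0)
    a = sample_structural_network(p, n * (n - 1) // 2,
                                  lambda k, r: np.ones(k), rng)
    assert (a[np.triu_indices(n, 1)] != 0).all()


def test_sample_exact_edge_count_and_determinism():
    coords = synthetic_coords(40)
    p = structural_probability_matrix(_params(coords, m_edges=150),
                                      np.random.default_rng(5))
    sampler = lambda k, r: r.uniform(1, 2, k)
    a1 = sample_structural_network(p, 150, sampler, np.random.default_rng(9))
    a2 = sample_structural_network(p, 150, sampler, np.random.default_rng(9))
    assert (a1[np.triu_indices(40, 1)] != 0).sum() == 150
    np.testing.assert_array_equal(a1, a2)
    assert np.all(a1 >= 0) and np.array_equal(a1, a1.T)


def test_sample_insufficient_support_errors():
    p = np.zeros((4, 4))
    p[0, 1] = p[1, 0] = 1.0
    with pytest.raises(ValueError):
        sample_structural_network(p, 3, lambda k, r: np.ones(k),
                                  np.random.default_rng(0))


@pytest.mark.parametrize("method", ["gumbel", "sequential"])
def test_uniform_inclusion_frequencies(method):
    # uniform propensities: every pair equally likely to be included
    n, m, reps = 10, 12, 2000
    p = np.ones((n, n)) - np.eye(n)
    rng = np.random.default_rng(11)
    n_pairs = n * (n - 1) // 2
    counts = np.zeros(n_pairs)
    iu, ju = np.triu_indices(n, 1)
    for _ in range(reps):
        a = sample_structural_network(p, m, lambda k, r: np.ones(k), rng,
                                      method=method)
        counts += a[iu, ju] != 0
    expect = m / n_pairs
    sd = np.sqrt(expect * (1 - expect) / reps)
    freq = counts / reps
    assert np.all(np.abs(freq - expect) < 4 * sd + 0.02)


def test_gumbel_matches_sequential_distribution():
    # nonuniform propensities: the two samplers draw the same distribution
    n, m, reps = 6, 4, 3000
    rng = np.random.default_rng(17)
    p = np.triu(rng.uniform(0.2, 3.0, (n, n)), 1)
    p = p + p.T
    iu, ju = np.triu_indices(n, 1)
    freqs = {}
    for method in ("gumbel", "sequential"):
        counts = np.zeros(iu.size)
        r = np.random.default_rng(23)
        for _ in range(reps):
            a = sample_structural_network(p, m, lambda k, g: np.ones(k), r,
                                          method=method)
            counts += a[iu, ju] != 0
        freqs[method] = counts / reps
    sd = np.sqrt(freqs["sequential"] * (1 - freqs["sequential"]) / reps)
    assert np.all(np.abs(freqs["gumbel"] - freqs["sequential"]) <
                  4 * sd + 0.03)


# ------------------------------------------------------------------ weights

def test_weight_sampler_matches_target_cdf():
    sampler = EdgeWeightSampler()
    rng = np.random.default_rng(0)
    draws = sampler(100_000, rng)
    # KS distance between the empirical CDF and the target CDF
    xs = np.sort(draws)
    ecdf = np.arange(1, xs.size + 1) / xs.size
    target = np.interp(xs, sampler.grid, sampler.cdf)
    assert np.max(np.abs(ecdf - target)) < 0.02
    assert draws.min() >= sampler.params.w_min
    assert draws.max() <= sampler.params.w_max


def test_weight_sampler_crossover_located():
    sampler = EdgeWeightSampler()
    p = sampler.params
    body = p.alpha * np.exp(p.k * sampler.w_c) / sampler.w_c + p.c
    tail = p.a_w * sampler.w_c ** (-p.eta_w)
    assert body == pytest.approx(tail, rel=1e-6)


def test_weight_sampler_all_mass_below_crossover():
    # crossover at the end of a shortened support: the tail branch is unused
    params = WeightParams(w_c=250.0, w_max=250.0)
    sampler = EdgeWeightSampler(params)
    draws = sampler(5000, np.random.default_rng(1))
    assert draws.max() <= 250.0


def test_weight_sampler_deterministic():
    s = EdgeWeightSampler()
    d1 = s(100, np.random.default_rng(5))
    d2 = s(100, np.random.default_rng(5))
    np.testing.assert_array_equal(d1, d2)


def test_weight_density_negative_rejected():
    with pytest.raises(ValueError):
        EdgeWeightSampler(WeightParams(alpha=0.0, c=-1.0, w_c=500.0))


# ------------------------------------------------------------------ functional

def test_functional_symmetry_zero_diagonal(rng):
    spec = FunctionalContrastSpec(contrasts=((frozenset({(0, 1)}), 0.5),))
    a = sample_functional_network(5, spec, True, rng)
    np.testing.assert_array_equal(a, a.T)
    np.testing.assert_array_equal(np.diag(a), 0.0)


def test_functional_planted_mean_clt():
    spec = FunctionalContrastSpec(contrasts=((frozenset({(0, 1)}), 0.7),))
    rng = np.random.default_rng(21)
    draws = np.array([sample_functional_network(4, spec, True, rng)[0, 1]
                      for _ in range(10_000)])
    assert abs(draws.mean() - 0.7) < 3 / np.sqrt(10_000)
    # CNR equals mu_e at sigma = 1
    assert abs(draws.std() - 1.0) < 0.05


def test_functional_noise_group_ignores_contrasts():
    spec = FunctionalContrastSpec(contrasts=((frozenset({(0, 1)}), 5.0),))
    rng = np.random.default_rng(2)
    draws = np.array([sample_functional_network(4, spec, False, rng)[0, 1]
                      for _ in range(2000)])
    assert abs(draws.mean()) < 0.1


def test_contrast_sets_must_be_disjoint():
    with pytest.raises(ValueError):
        FunctionalContrastSpec(
            contrasts=((frozenset({(0, 1)}), 0.5), (frozenset({(1, 0)}), 0.8))
        )


# ------------------------------------------------------------------ scenarios

def test_embedded_scenario_truth_structure():
    rng = np.random.default_rng(0)
    cohort, truth = build_embedded_contrast_scenario(rng, n_per_group=2)
    assert len(truth.n_c) == 5
    sub = truth.edges_at_cnr(0.6)
    con = truth.edges_at_cnr(0.8)
    assert len(sub) == 8 and len(con) == 11
    # every subcontrast edge touches a central node; contrast edges touch none
    for u, v in sub:
        assert u in truth.n_c or v in truth.n_c
    for u, v in con:
        assert u not in truth.n_c and v not in truth.n_c
    assert cohort.n == 264
    s = cohort.group1[0].structural
    assert (s[np.triu_indices(264, 1)] != 0).sum() == 3188


def test_embedded_scenario_control_group_null_at_planted_positions():
    rng = np.random.default_rng(4)
    cohort, truth = build_embedded_contrast_scenario(rng, n_per_group=3)
    vals = [s.functional[u, v] for s in cohort.group2
            for (u, v) in truth.all_edges]
    vals = np.array(vals)
    assert abs(vals.mean()) < 3 / np.sqrt(vals.size)
    assert 0.7 < vals.std() < 1.3


def test_embedded_scenario_seeded_reproducibility():
    c1, t1 = build_embedded_contrast_scenario(np.random.default_rng(8),
                                              n_per_group=2)
    c2, t2 = build_embedded_contrast_scenario(np.random.default_rng(8),
                                              n_per_group=2)
    assert t1 == t2
    np.testing.assert_array_equal(c1.group1[0].structural,
                                  c2.group1[0].structural)
    np.testing.assert_array_equal(c1.group2[1].functional,
                                  c2.group2[1].functional)


def test_roc_scenario_component():
    import networkx as nx

    rng = np.random.default_rng(3)
    cohort, truth = build_roc_scenario(mu_nc=1.0, mu_e=0.5, n_per_group=2,
                                       rng=rng)
    edges = truth.all_edges
    assert len(edges) == 20
    g = nx.Graph(list(edges))
    assert nx.is_connected(g)
    non_central = set(g.nodes) - truth.n_c
    assert len(non_central) == 2
    assert truth.n_c <= set(g.nodes)


def test_roc_scenario_seeded_reproducibility():
    a = build_roc_scenario(1.0, 0.5, 2, np.random.default_rng(9))
    b = build_roc_scenario(1.0, 0.5, 2, np.random.default_rng(9))
    assert a[1] == b[1]
    np.testing.assert_array_equal(a[0].group1[0].functional,
                                  b[0].group1[0].functional)


def test_generate_cohort_respects_group_sizes():
    coords = synthetic_coords(20)
    struct = StructuralGenParams(coords=coords, m_edges=60,
                                 n_c=frozenset({0}), mu_nc=1.0)
    spec = FunctionalContrastSpec()
    cohort = generate_cohort(struct, spec, 3, 4, np.random.default_rng(0))
    assert len(cohort.group1) == 3 and len(cohort.group2) == 4
    assert cohort.coords.shape == (20, 3)
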
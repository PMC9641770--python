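"""Inference engines: gaussianisation, penalised MLE, pcor, MCMC, trees."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from priorgraph import (
    BayesianStructureMCMC,
    OmicsDataset,
    PriorGraphicalLasso,
    PriorMatrix,
    ShrinkagePartialCorrelation,
    UndirectedNetwork,
    gaussianize,
    make_benchmark_prior,
    mcmc_structure_search,
    penalized_cv,
    penalized_mle,
    sample_graph_from_priors,
    scale_free_cutoff,
    select_posterior_network,
    shrinkage_pcor_network,
    simulate_gaussian,
    tree_ensemble_links,
)
from priorgraph.infer import RankedLinks, _correlation
from priorgraph._mcmc import graph_bic


def _dataset(x, cols=None):
    cols = cols or [f"x{i}" for i in range(x.shape[1])]
    return OmicsDataset(pd.DataFrame(x, columns=cols))


class TestGaussianize:
    def test_output_close_to_standard_normal(self, rng):
        x = rng.standard_normal((600, 2))
        g = gaussianize(_dataset(x))
        d, _ = stats.kstest(g.values["x0"], "norm")
        assert d < 0.05

    def test_dosage_column_three_levels_order_preserved(self, rng):
        d = rng.integers(0, 3, size=200).astype(float)
        d[:3] = [0, 1, 2]
        g = gaussianize(_dataset(d[:, None], ["snp"]))
        vals = g.values["snp"].to_numpy()
        assert len(np.unique(vals)) == 3
        assert vals[0] < vals[1] < vals[2]

    def test_invariant_to_monotone_distortion(self, rng):
        x = rng.uniform(1, 2, size=(100, 1))
        a = gaussianize(_dataset(x)).values.to_numpy()
        b = gaussianize(_dataset(np.exp(x ** 3))).values.to_numpy()
        assert np.allclose(a, b)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="x0"):
            gaussianize(_dataset(np.ones((10, 1))))


def kkt_residual(S, L, Theta):
    """Stationarity residual of the penalised covariance-selection problem."""
    Sig = np.linalg.inv(Theta)
    p = S.shape[0]
    res = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            if abs(Theta[i, j]) > 1e-8:
                res = max(res, abs(S[i, j] - Sig[i, j]
                                   + L[i, j] * np.sign(Theta[i, j])))
            else:
                res = max(res, abs(S[i, j] - Sig[i, j]) - L[i, j])
    return res


class TestPenalizedMle:
    def test_two_variable_soft_threshold_grid(self):
        # closed form: edge present iff |s12| > lambda12
        for s12 in [-0.7, -0.3, -0.05, 0.05, 0.3, 0.7]:
            for lam in [0.01, 0.1, 0.4, 0.8]:
                S = np.array([[1.0, s12], [s12, 1.0]])
                L = np.full((2, 2), lam)
                Theta, adj = penalized_mle(S, L)
                assert adj[0, 1] == (abs(s12) > lam)
                if adj[0, 1]:
                    Sig = np.linalg.inv(Theta)
                    assert Sig[0, 1] == pytest.approx(
                        s12 - lam * np.sign(s12), abs=1e-6)

    def test_full_shrinkage_gives_empty_graph(self, rng):
        x = rng.standard_normal((100, 6))
        S = _correlation(x)
        lam = np.abs(S - np.eye(6)).max() + 0.01
        _, adj = penalized_mle(S, np.full((6, 6), lam))
        assert not adj.any()

    def test_zero_penalty_equals_inverse(self, rng):
        x = rng.standard_normal((200, 5))
        S = np.cov(x, rowvar=False)
        Theta, _ = penalized_mle(S, np.zeros((5, 5)))
        assert np.abs(Theta - np.linalg.inv(S)).max() < 1e-6

    def test_kkt_stationarity_random_problems(self, rng):
        for _ in range(10):
            x = rng.standard_normal((80, 8))
            S = _correlation(x)
            L = rng.uniform(0.0, 0.3, size=(8, 8))
            L = 0.5 * (L + L.T)
            Theta, _ = penalized_mle(S, L)
            assert kkt_residual(S, L, Theta) < 1e-6

    def test_asymmetric_input_rejected(self):
        S = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError):
            penalized_mle(S, np.zeros((2, 2)))


OMEGA_GRID_SMALL = tuple(np.round(np.arange(0.01, 0.61, 0.02), 4))


class TestPenalizedCv:
    def test_pure_noise_few_spurious_edges(self, rng):
        counts = []
        for seed in range(3):
            x = np.random.default_rng(seed).standard_normal((300, 20))
            net = penalized_cv(_dataset(x), None, omega_grid=OMEGA_GRID_SMALL,
                               rng=seed)
            counts.append(net.n_edges)
        assert np.median(counts) <= 2

    def test_chain_recovery(self, rng):
        nodes = [f"n{i}" for i in range(6)]
        g = UndirectedNetwork(nodes, list(zip(nodes, nodes[1:])))
        data = simulate_gaussian(g, 600, rng)
        net = penalized_cv(data, None, omega_grid=OMEGA_GRID_SMALL, rng=0)
        from priorgraph import confusion, mcc

        assert g.edges <= net.edges or mcc(confusion(net, g)) >= 0.8

    def test_prior_on_true_edges_improves_mcc(self, rng):
        from priorgraph import confusion, mcc

        P = make_benchmark_prior(15, 25, rng=11)
        g = sample_graph_from_priors(P, rng)
        data = simulate_gaussian(g, 300, rng)
        hostile = None
        net_p = penalized_cv(data, P, omega_grid=OMEGA_GRID_SMALL, rng=5)
        net_0 = penalized_cv(data, hostile, omega_grid=OMEGA_GRID_SMALL, rng=5)
        assert mcc(confusion(net_p, g)) >= mcc(confusion(net_0, g))

    def test_estimator_api(self, rng):
        x = rng.standard_normal((60, 5))
        est = PriorGraphicalLasso(omega_grid=(0.1, 0.3), cv=3, random_state=0)
        est.fit(pd.DataFrame(x, columns=list("abcde")))
        assert hasattr(est, "network_") and hasattr(est, "omega_")
        params = est.get_params()
        assert params["cv"] == 3


class TestShrinkagePcor:
    def test_independent_columns_nearly_empty(self):
        counts = []
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal((500, 20))
            net = shrinkage_pcor_network(_dataset(x))
            counts.append(net.n_edges)
        assert np.median(counts) <= 1

    def test_shrinkage_intensity_in_unit_interval(self, rng):
        from priorgraph.infer import shrinkage_correlation

        for n in (10, 50, 200):
            x = rng.standard_normal((n, 6))
            _, lam = shrinkage_correlation(x)
            assert 0.0 <= lam <= 1.0

    def test_single_strong_edge_recovered(self, rng):
        nodes = [f"n{i}" for i in range(8)]
        g = UndirectedNetwork(nodes, [("n0", "n1")])
        data = simulate_gaussian(g, 600, rng)
        net = shrinkage_pcor_network(data)
        assert net.has_edge("n0", "n1")

    def test_too_few_columns(self, rng):
        with pytest.raises(ValueError):
            shrinkage_pcor_network(_dataset(rng.standard_normal((50, 2))))


class TestMcmc:
    def test_null_data_pseudo_prior_low_posteriors(self, rng):
        x = rng.standard_normal((400, 5))
        P = PriorMatrix([f"x{i}" for i in range(5)])  # all pseudo
        probs = mcmc_structure_search(_dataset(x), P, iter=4000, burnin=2000,
                                      rng=0)
        off = probs.probs[np.triu_indices(5, 1)]
        assert np.all(off < 0.5)

    def test_bivariate_strong_edge_posterior_one(self, rng):
        n = 600
        z = rng.standard_normal(n)
        x = np.column_stack([z, 0.9 * z + np.sqrt(1 - 0.81) *
                             rng.standard_normal(n),
                             rng.standard_normal(n)])
        probs = mcmc_structure_search(_dataset(x), None, iter=6000,
                                      burnin=3000, rng=1)
        assert probs.probs[0, 1] > 0.95

    def test_hostile_prior_lowers_posterior(self, rng):
        # moderate effect: the likelihood must not saturate the posterior in
        # both arms, or the strict inequality degenerates to a tie at 1
        n = 400
        z = rng.standard_normal(n)
        x = np.column_stack([z, 0.3 * z + np.sqrt(1 - 0.09) *
                             rng.standard_normal(n),
                             rng.standard_normal(n)])
        data = _dataset(x)
        nodes = ["x0", "x1", "x2"]
        hostile = PriorMatrix(nodes)  # pseudo = 1e-7 prior on the true edge
        flat = None
        p_hostile = mcmc_structure_search(data, hostile, iter=6000,
                                          burnin=3000, rng=2).probs[0, 1]
        p_flat = mcmc_structure_search(data, flat, iter=6000, burnin=3000,
                                       rng=2).probs[0, 1]
        assert p_hostile < p_flat

    def test_agrees_with_enumeration_three_nodes(self, rng):
        n = 250
        z = rng.standard_normal(n)
        x = np.column_stack([z, 0.5 * z + rng.standard_normal(n),
                             rng.standard_normal(n)])
        data = _dataset(x)
        S = _correlation(gaussianize(data).values.to_numpy())
        pairs = [(0, 1), (0, 2), (1, 2)]
        log_post = {}
        for bits in itertools.product([0, 1], repeat=3):
            A = np.zeros((3, 3))
            for b, (i, j) in zip(bits, pairs):
                A[i, j] = A[j, i] = b
            log_post[bits] = -graph_bic(S, A, n) / 2.0
        mx = max(log_post.values())
        Z = sum(np.exp(v - mx) for v in log_post.values())
        brute = [sum(np.exp(log_post[b] - mx) for b in log_post if b[k]) / Z
                 for k in range(3)]
        probs = mcmc_structure_search(data, None, iter=50_000, burnin=5_000,
                                      rng=3)
        got = [probs.probs[i, j] for i, j in pairs]
        assert np.abs(np.array(got) - np.array(brute)).max() < 0.05

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((150, 4))
        a = mcmc_structure_search(_dataset(x), None, iter=2000, burnin=1000,
                                  rng=9)
        b = mcmc_structure_search(_dataset(x), None, iter=2000, burnin=1000,
                                  rng=9)
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_select_posterior_network(self):
        probs_mat = np.array([[0, 0.95, 0.85], [0.95, 0, 0.2],
                              [0.85, 0.2, 0]])
        from priorgraph.infer import PosteriorEdgeProbs

        probs = PosteriorEdgeProbs(("a", "b", "c"), probs_mat, 0.2, 100, 50)
        net = select_posterior_network(probs, 0.9)
        assert net.edges == {("a", "b")}
        assert select_posterior_network(probs, 0.0).n_edges == 3


class TestTreesAndScaleFree:
    def test_planted_edge_ranks_first(self, rng):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            z = r.standard_normal(200)
            x = np.column_stack([z, z + 0.3 * r.standard_normal(200),
                                 r.standard_normal(200),
                                 r.standard_normal(200),
                                 r.standard_normal(200)])
            links = tree_ensemble_links(_dataset(x), n_estimators=50, rng=seed)
            a, b, _ = links.links[0]
            if {a, b} == {"x0", "x1"}:
                hits += 1
        assert hits >= 4

    def test_weights_nonnegative_and_symmetrised(self, rng):
        x = rng.standard_normal((100, 4))
        links = tree_ensemble_links(_dataset(x), n_estimators=20, rng=0)
        w = links.weights
        assert np.all(w >= 0) and np.all(np.isfinite(w))
        assert len(links.links) == 6  # all unordered pairs once

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((80, 4))
        l1 = tree_ensemble_links(_dataset(x), n_estimators=20, rng=7)
        l2 = tree_ensemble_links(_dataset(x), n_estimators=20, rng=7)
        assert l1.links == l2.links

    def test_scale_free_cutoff_on_preferential_attachment(self, rng):
        import networkx as nx

        g = nx.barabasi_albert_graph(120, 2, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
        true_edges = {tuple(sorted(e)) for e in g.edges}
        all_pairs = [(a, b) for i, a in enumerate(sorted(g.nodes))
                     for b in sorted(g.nodes)[i + 1:]]
        links = []
        for a, b in all_pairs:
            if (a, b) in true_edges:
                links.append((a, b, float(rng.uniform(0.5, 1.0))))
            else:
                links.append((a, b, float(rng.uniform(0.0, 0.4))))
        links.sort(key=lambda e: -e[2])
        net = scale_free_cutoff(RankedLinks(links))
        from priorgraph.infer import scale_free_fit_r2

        deg = np.array(list(net.degree().values()))
        r2, nb = scale_free_fit_r2(deg)
        assert r2 > 0.8 and nb >= 3

    def test_single_unique_weight(self):
        links = RankedLinks([("a", "b", 0.5), ("b", "c", 0.5)])
        net = scale_free_cutoff(links)
        assert net.n_edges == 2

    def test_empty_links(self):
        assert scale_free_cutoff(RankedLinks([])).n_edges == 0
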
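import numpy as np
import networkx as nx
import pytest
from scipy.integrate import cumulative_trapezoid

from photoqtl.network import (GeneNetwork, LOPBasis, QTLNetworkModel, adaptive_lasso_select,
                              assemble_network, classify_link, decompose_genetic_effect,
                              find_hubs, fit_qtl_ode, legendre_basis, network_stats,
                              rk4_integrate)


class TestLegendreBasis:
    def test_closed_form_values(self):
        basis, V = legendre_basis(2, np.array([-1.0, 0.0, 0.5, 1.0]), domain=(-1, 1))
        assert np.allclose(V[:, 0], 1.0)  # P0
        assert np.allclose(V[:, 1], [-1.0, 0.0, 0.5, 1.0])  # P1(x) = x
        assert V[2, 2] == pytest.approx((3 * 0.25 - 1) / 2)  # P2(0.5) = -0.125

    def test_all_orders_equal_one_at_right_endpoint(self):
        basis, V = legendre_basis(6, np.linspace(0, 5, 11), domain=(0, 5))
        assert np.allclose(V[-1], 1.0)

    def test_orthogonality_under_gauss_quadrature(self):
        x, w = np.polynomial.legendre.leggauss(40)
        basis = LOPBasis(order=5, lo=-1.0, hi=1.0)
        V = basis.evaluate(x)
        G = V.T @ (w[:, None] * V)
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-12

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError):
            LOPBasis(order=2, lo=1.0, hi=1.0)
        with pytest.raises(ValueError):
            LOPBasis(order=0, lo=0.0, hi=1.0)


@pytest.fixture(scope="module")
def sinusoids():
    fine = np.linspace(2.0, 7.9, 2901)
    grid = fine[::100]
    cand_f = {i: np.sin(0.3 * (i + 1) * fine + 0.5 * i) for i in range(6)}
    cand = {i: v[::100] for i, v in cand_f.items()}
    return fine, grid, cand_f, cand


class TestAdaptiveLasso:
    def test_single_planted_predictor_recovered(self, sinusoids):
        fine, grid, cand_f, cand = sinusoids
        target = np.concatenate([[0.0], cumulative_trapezoid(0.8 * cand_f[3], fine)])[::100]
        selected, info = adaptive_lasso_select(target, cand, grid)
        assert selected == [3]
        assert info["coef"][3] == pytest.approx(0.8, abs=0.05)

    def test_two_predictor_truth_matches_best_subset_search(self, sinusoids):
        fine, grid, cand_f, cand = sinusoids
        dtarget_f = 0.9 * cand_f[1] - 0.7 * cand_f[4]
        target = 0.1 + np.concatenate([[0.0], cumulative_trapezoid(dtarget_f, fine)])[::100]
        selected, _ = adaptive_lasso_select(target, cand, grid)

        # independent oracle: exhaustive least squares over all subsets of size <= 2
        from itertools import combinations
        from photoqtl.network import _empirical_derivative
        y = _empirical_derivative(target, grid)
        best = (np.inf, ())
        for k in (1, 2):
            for subset in combinations(range(6), k):
                A = np.column_stack([np.ones(grid.size)] + [cand[j] for j in subset])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                rss = float(np.sum((y - A @ coef) ** 2))
                if rss < best[0] * (1 - 1e-9):
                    best = (rss, subset)
        assert sorted(selected) == sorted(best[1]) == [1, 4]

    def test_total_shrinkage_empties_selection(self, sinusoids):
        fine, grid, cand_f, cand = sinusoids
        target = np.concatenate([[0.0], cumulative_trapezoid(0.8 * cand_f[2], fine)])[::100]
        selected, _ = adaptive_lasso_select(target, cand, grid,
                                            penalty_grid=np.array([1e12]))
        assert selected == []

    def test_all_zero_candidates_empty(self, sinusoids):
        fine, grid, cand_f, cand = sinusoids
        selected, info = adaptive_lasso_select(cand[0], {1: np.zeros(grid.size)}, grid)
        assert selected == []


class TestRK4:
    def test_exponential_decay_oracle(self):
        grid = np.linspace(0.0, 1.0, 11)  # step 0.1
        traj = rk4_integrate(lambda t, g: -g, 1.0, grid)
        assert abs(traj[-1] - np.exp(-1)) < 1e-6

    def test_zero_field_keeps_constant(self):
        traj = rk4_integrate(lambda t, g: 0.0, 3.5, np.linspace(0, 2, 21))
        assert np.allclose(traj, 3.5)

    def test_fourth_order_convergence_under_step_halving(self):
        errs = []
        for n in (11, 21):
            grid = np.linspace(0.0, 1.0, n)
            traj = rk4_integrate(lambda t, g: -g, 1.0, grid)
            errs.append(np.max(np.abs(traj - np.exp(-grid))))
        ratio = errs[0] / errs[1]
        assert 12.0 < ratio < 20.0  # ~16x for a fourth-order method

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError):
            rk4_integrate(lambda t, g: -g, 1.0, np.array([0.0, 0.1, 0.3]))

    def test_divergent_field_rejected(self):
        with pytest.raises(ValueError):
            rk4_integrate(lambda t, g: float("nan"), 1.0, np.linspace(0, 1, 11))


class TestODEFit:
    def test_self_consistent_recovery_without_predictors(self):
        """A trajectory generated from a known LOP self-field is re-fitted
        to numerical precision."""
        grid = np.linspace(2.0, 7.9, 30)
        basis = LOPBasis(order=3, lo=0.0, hi=2.0)
        phi_true = np.array([0.12, 0.08, -0.05, 0.02])
        truth = rk4_integrate(lambda t, g: float(basis.combine(g, phi_true)), 0.5, grid)
        fit = fit_qtl_ode(truth, grid, {}, lop_order=3, seed=0)
        assert fit.residual_norm < 1e-6
        assert np.allclose(fit.fitted, truth, atol=1e-6)
        assert np.allclose(fit.independent, fit.fitted, atol=1e-12)

    def test_constant_target_gives_null_fields(self):
        grid = np.linspace(2.0, 7.9, 30)
        fit = fit_qtl_ode(np.full(30, 1.4), grid, {}, lop_order=4, seed=0)
        assert fit.residual_norm < 1e-8
        assert np.allclose(np.diff(fit.fitted), 0.0, atol=1e-8)

    def test_planted_inhibitory_coupling_recovers_sign(self):
        fine = np.linspace(2.0, 7.9, 2901)
        gA_f = 0.5 + 0.2 * np.sin(1.2 * fine)
        gB_f = 1.5 + np.concatenate([[0.0], cumulative_trapezoid(-0.6 * gA_f, fine)])
        grid = fine[::100]
        fit = fit_qtl_ode(gB_f[::100], grid, {"A": gA_f[::100]}, seed=1)
        ind, deps = decompose_genetic_effect(fit)
        assert np.max(deps["A"]) <= 1e-8  # inhibitor stays non-positive
        sign, weight = classify_link(deps["A"])
        assert sign == -1 and weight > 0.5

    def test_decomposition_reproduces_fitted_curve(self, chain_curves):
        grid, curves = chain_curves
        fit = fit_qtl_ode(curves[3], grid, {2: curves[2]}, seed=2)
        ind, deps = decompose_genetic_effect(fit)
        total = ind + sum(deps.values())
        assert np.max(np.abs(total - fit.fitted)) < 1e-8


class TestNetworkAssembly:
    def _fit(self, dep_curves, observed=None):
        class F:  # minimal stand-in carrying the fields assemble_network reads
            pass

        f = F()
        n = 30
        f.independent = np.linspace(0, 1, n)
        f.dependent = dep_curves
        f.observed = observed if observed is not None else np.linspace(0, 2, n)
        return f

    def test_zero_curve_yields_no_edge(self):
        assert classify_link(np.zeros(30)) is None

    def test_positive_curve_is_activation(self):
        sign, weight = classify_link(np.linspace(0, 0.5, 30))
        assert sign == 1 and weight == pytest.approx(0.5)

    def test_sign_antisymmetry(self):
        c = np.sin(np.linspace(0, 3, 30)) + 0.2
        s1, w1 = classify_link(c)
        s2, w2 = classify_link(-c)
        assert s1 == -s2 and w1 == w2

    def test_empty_selections_give_zero_edges(self):
        fits = {i: self._fit({}) for i in range(4)}
        net = assemble_network(fits, trait="ETR")
        assert net.n_nodes == 4 and net.n_edges == 0
        assert find_hubs(net) == []

    def test_edge_count_conservation(self):
        fits = {1: self._fit({2: np.full(30, 0.3)}),
                2: self._fit({1: np.full(30, -0.4), 3: np.full(30, 0.2)}),
                3: self._fit({})}
        net = assemble_network(fits, trait="ETR")
        s = network_stats(net)
        assert sum(s["out_degree"].values()) == sum(s["in_degree"].values()) == net.n_edges == 3

    def test_below_threshold_links_dropped(self):
        fits = {1: self._fit({2: np.full(30, 1e-5)}, observed=np.full(30, 2.0)),
                2: self._fit({})}
        net = assemble_network(fits, trait="ETR", tau_fraction=0.01)
        assert net.n_edges == 0

    def test_duplicate_edge_is_a_construction_bug(self):
        fits = {1: self._fit({1: np.full(30, 0.3)})}
        with pytest.raises(ValueError):
            assemble_network(fits)


class TestNetworkStats:
    @pytest.mark.parametrize("N,E,expected", [(209, 865, 1.99), (216, 908, 1.96),
                                              (268, 1250, 1.75)])
    def test_density_from_printed_counts(self, N, E, expected):
        net = GeneNetwork(trait="t", graph=nx.gnm_random_graph(N, E, seed=1, directed=True))
        nx.set_edge_attributes(net.graph, 1, "sign")
        assert network_stats(net)["density_pct"] == expected

    def test_complete_digraph_has_full_density(self):
        g = nx.complete_graph(6, create_using=nx.DiGraph)
        nx.set_edge_attributes(g, 1, "sign")
        assert network_stats(GeneNetwork("t", g))["density_pct"] == 100.0

    def test_sign_shares(self):
        g = nx.DiGraph()
        g.add_edge(0, 1, sign=1)
        g.add_edge(1, 2, sign=1)
        g.add_edge(2, 0, sign=-1)
        s = network_stats(GeneNetwork("t", g))
        assert s["positive_pct"] == pytest.approx(66.67)
        assert s["negative_pct"] == pytest.approx(33.33)

    def test_hub_threshold_is_strict(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(10))
        for v in (1, 2, 3):
            g.add_edge(0, v, sign=1)  # out-degree 3 > 2 -> hub
        for v in (4, 5):
            g.add_edge(9, v, sign=1)  # out-degree 2, not > 2
        net = GeneNetwork("t", g)
        assert find_hubs(net, 0.2) == [0]

    def test_star_center_is_sole_hub(self):
        g = nx.DiGraph()
        for v in range(1, 8):
            g.add_edge(0, v, sign=1)
        assert find_hubs(GeneNetwork("t", g), 0.2) == [0]


def test_chain_network_recovered_exactly(chain_curves):
    """Noiseless 5-node chain with +0.8 couplings: the fitted network has
    exactly the chain's edges, all classified as activation."""
    grid, curves = chain_curves
    res = QTLNetworkModel(curves, grid, trait="ETR", seed=0).fit()
    expected = {(p, p + 1) for p in range(1, 5)}
    assert set(res.network.graph.edges()) == expected
    assert all(d["sign"] == 1 for _, _, d in res.network.graph.edges(data=True))
    s = res.stats()
    assert s["n_edges"] == 4 and s["n_nodes"] == 5


def test_selection_density_sparse_at_panel_scale():
    """On a 200-curve panel of independent smooth effect curves, the adaptive
    LASSO keeps the candidate graph sparse (edges are a subset of selections,
    so selection density bounds realized density).  Estimated from a 12-target
    subsample against the full 199-candidate pools."""
    from photoqtl.growth import HDEEParams, eval_hdee

    rng = np.random.default_rng(42)
    grid = np.linspace(1.98, 7.9, 30)
    N = 200
    curves = {}
    for i in range(N):
        K = rng.uniform(0.5, 3.0) * (1 if rng.random() < 0.7 else -1)
        p = HDEEParams(K=K, a=rng.uniform(2, 12), b=rng.uniform(0.5, 2.0),
                       c=rng.normal(0, 0.15), d=rng.uniform(-1, 1))
        curves[i] = 0.5 * eval_hdee("logistic", p, grid)
    targets = rng.choice(N, size=12, replace=False)
    sizes = []
    for t in targets:
        cand = {k: v for k, v in curves.items() if k != t}
        selected, _ = adaptive_lasso_select(curves[int(t)], cand, grid)
        sizes.append(len(selected))
    assert np.mean(sizes) / (N - 1) < 0.05
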
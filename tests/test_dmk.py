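"""DMK transport solver against exact oracles and regime behavior."""

import itertools
import warnings

import numpy as np
import pytest

from orcflow.benchmarks import random_local_problems
from orcflow.dmk import (
    DMKConfig,
    lp_transport_cost,
    sinkhorn_transport_cost,
    solve_dmk,
    solve_dmk_many,
    solve_dmk_network,
    wasserstein_cost,
)
from orcflow.ot_local import BipartiteOTProblem, build_local_ot_problem

from conftest import make_weighted


def make_problem(cost, source, sink):
    cost = np.asarray(cost, dtype=float)
    nL, nR = cost.shape
    return BipartiteOTProblem(
        left_nodes=list(range(nL)),
        right_nodes=list(range(100, 100 + nR)),
        cost=cost,
        source=np.asarray(source, dtype=float),
        sink=np.asarray(sink, dtype=float),
    )


def brute_force_transport(cost, a_units, b_units, denom):
    """Exhaustive minimum over integer transport tables with given margins."""
    cost = np.asarray(cost, dtype=float)
    nL, nR = cost.shape
    best = [np.inf]

    def rec(row, remaining_b, acc):
        if acc >= best[0]:
            return
        if row == nL:
            best[0] = acc
            return
        # enumerate compositions of a_units[row] into nR parts <= remaining_b
        def comp(col, left, partial):
            if col == nR - 1:
                if left <= remaining_b[col]:
                    remaining_b[col] -= left
                    rec(row + 1, remaining_b, partial + left * cost[row, col] / denom)
                    remaining_b[col] += left
                return
            for x in range(min(left, remaining_b[col]) + 1):
                remaining_b[col] -= x
                comp(col + 1, left - x, partial + x * cost[row, col] / denom)
                remaining_b[col] += x

        comp(0, a_units[row], acc)

    rec(0, list(b_units), 0.0)
    return best[0]


class TestLPOracle:
    def test_identical_distributions_cost_zero(self):
        p = make_problem(np.array([[0.0, 1.0], [1.0, 0.0]]), [0.5, 0.5], [0.5, 0.5])
        assert lp_transport_cost(p) == pytest.approx(0.0, abs=1e-12)

    def test_one_by_one(self):
        p = make_problem([[0.7]], [1.0], [1.0])
        assert lp_transport_cost(p) == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_3x3(self, seed):
        rng = np.random.default_rng(seed)
        denom = 8
        a_units = rng.multinomial(denom, [1 / 3] * 3)
        b_units = rng.multinomial(denom, [1 / 3] * 3)
        cost = rng.uniform(0.1, 1.0, size=(3, 3))
        p = make_problem(cost, a_units / denom, b_units / denom)
        expected = brute_force_transport(cost, list(a_units), list(b_units), denom)
        assert lp_transport_cost(p) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            p = make_problem([[1.0]], [1.0], [1.0])
            object.__setattr__(p, "sink", np.array([0.5]))
            lp_transport_cost(p)


class TestSolveDMK:
    def test_single_edge_forces_all_mass(self):
        """Conservation forces the unit mass across the weight-2 edge.

        (The copies of the endpoints give two equal-cost routes through the
        zero-cost pairs, so the flux may split between them, but every route
        crosses the weight-2 edge once: the cost is exactly 2.)
        """
        G = make_weighted([(1, 2, 2.0)])
        p = build_local_ot_problem(G, 1, 2)
        for beta in (0.7, 1.0, 1.3):
            r = solve_dmk(p, DMKConfig(beta=beta))
            assert r.cost == pytest.approx(2.0, rel=1e-4)
            assert r.residual < 1e-4

    def test_2x2_diagonal_optimum(self):
        p = make_problem([[1.0, 2.0], [2.0, 1.0]], [0.5, 0.5], [0.5, 0.5])
        r = solve_dmk(p, DMKConfig(beta=1.0))
        assert r.cost == pytest.approx(lp_transport_cost(p), rel=1e-3)
        assert r.cost == pytest.approx(1.0, rel=1e-3)

    def test_beta1_matches_lp_on_random_neighborhood_problems(self):
        problems = random_local_problems(30, seed=202)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            results = solve_dmk_many(problems, DMKConfig(beta=1.0))
        for r, p in zip(results, problems):
            lp = lp_transport_cost(p)
            assert r.cost == pytest.approx(lp, rel=1e-3, abs=1e-9)

    @pytest.mark.parametrize("beta", [0.1, 0.5, 1.5, 2.0])
    def test_wbeta_never_beats_lp(self, beta):
        """Feasible flux on metric costs cannot undercut the LP optimum."""
        problems = random_local_problems(20, seed=77)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            results = solve_dmk_many(problems, DMKConfig(beta=beta))
        for r, p in zip(results, problems):
            assert r.cost >= lp_transport_cost(p) - 1e-6

    def test_flux_conserves_forcing(self):
        problems = random_local_problems(10, seed=11)
        cfg = DMKConfig(beta=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            results = solve_dmk_many(problems, cfg)
        for r in results:
            assert r.residual < 10 * cfg.tol

    def test_mu_stationary_at_convergence_for_congested_regimes(self):
        problems = random_local_problems(15, seed=31)
        for beta in (0.5, 1.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                results = solve_dmk_many(problems, DMKConfig(beta=beta))
            for r in results:
                if r.converged:
                    assert np.max(np.abs(r.flux**beta - r.mu)) < 1e-4

    def test_cost_stationary_under_continued_integration(self):
        """Re-integrating from the returned state leaves the cost in place."""
        problems = random_local_problems(10, seed=47)
        for beta in (0.5, 1.5, 2.0):
            cfg = DMKConfig(beta=beta)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                first = solve_dmk_many(problems, cfg)
                again = solve_dmk_many(problems, cfg, mu_init=[r.mu for r in first])
            for r1, r2 in zip(first, again):
                assert r2.cost == pytest.approx(r1.cost, rel=2e-4, abs=1e-9)

    def test_batch_matches_single_solves(self):
        problems = random_local_problems(12, seed=5)
        cfg = DMKConfig(beta=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            batch = solve_dmk_many(problems, cfg)
            singles = [solve_dmk(p, cfg) for p in problems]
        for b, s in zip(batch, singles):
            assert b.cost == pytest.approx(s.cost, rel=1e-10, abs=1e-12)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 2\]"):
            DMKConfig(beta=3.0)
        with pytest.raises(ValueError, match=r"\(0, 2\]"):
            DMKConfig(beta=0.0)

    def test_dt_bounded(self):
        with pytest.raises(ValueError):
            DMKConfig(dt=0.8)


class TestRoutingRegimes:
    """Two parallel two-edge routes: cheap total 1.0 vs expensive 1.2."""

    def setup_method(self):
        self.G = make_weighted(
            [("s", "a", 0.5), ("a", "t", 0.5), ("s", "b", 0.6), ("b", "t", 0.6)]
        )
        self.forcing = {"s": 1.0, "t": -1.0}

    def test_congested_regime_spreads_over_both_routes(self):
        flux, cost, conv, _ = solve_dmk_network(self.G, self.forcing, DMKConfig(beta=0.5))
        assert conv
        assert flux[("a", "s")] >= 0.01
        assert flux[("b", "s")] >= 0.01

    def test_branched_regime_consolidates_on_cheap_route(self):
        flux, cost, conv, _ = solve_dmk_network(self.G, self.forcing, DMKConfig(beta=1.5))
        assert conv
        assert flux[("a", "s")] >= 0.99
        assert flux[("b", "s")] <= 0.01
        assert cost == pytest.approx(1.0, rel=1e-3)


class TestWassersteinCost:
    def test_zero_flux(self):
        p = make_problem([[0.4]], [1.0], [1.0])
        r = solve_dmk(p, DMKConfig())
        r.flux = np.zeros_like(r.flux)
        assert wasserstein_cost(r, p) == 0.0

    def test_unit_flux_single_pair(self):
        p = make_problem([[0.4]], [1.0], [1.0])
        r = solve_dmk(p, DMKConfig())
        assert wasserstein_cost(r, p) == pytest.approx(0.4, rel=1e-6)

    def test_identical_distributions_ship_for_free(self):
        cfg = DMKConfig(beta=1.0)
        p = make_problem(
            np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]]),
            [0.2, 0.5, 0.3],
            [0.2, 0.5, 0.3],
        )
        r = solve_dmk(p, cfg)
        # all mass rides the zero-cost diagonal; only the solver's epsilon remains
        assert wasserstein_cost(r, p) <= cfg.eps_cost * p.cost.max() * 10

    def test_mismatched_problem_rejected(self):
        p1 = make_problem([[0.4]], [1.0], [1.0])
        p2 = make_problem([[0.4, 1.0]], [1.0], [0.5, 0.5])
        r = solve_dmk(p1, DMKConfig())
        with pytest.raises(ValueError):
            wasserstein_cost(r, p2)


class TestSinkhorn:
    def test_identical_distributions_near_zero(self):
        p = make_problem(np.array([[0.0, 1.0], [1.0, 0.0]]), [0.5, 0.5], [0.5, 0.5])
        assert sinkhorn_transport_cost(p, reg=1e-3) <= 1e-2

    def test_2x2_approaches_lp(self):
        p = make_problem([[1.0, 2.0], [2.0, 1.0]], [0.5, 0.5], [0.5, 0.5])
        assert sinkhorn_transport_cost(p, reg=1e-3) == pytest.approx(1.0, abs=1e-2)

    def test_monotone_in_regularization(self):
        problems = random_local_problems(8, seed=19)
        for p in problems:
            lp = lp_transport_cost(p)
            hi = sinkhorn_transport_cost(p, reg=1e-1)
            lo = sinkhorn_transport_cost(p, reg=1e-3)
            assert hi >= lo - 1e-9
            assert lo >= lp - 1e-6

    def test_invalid_reg(self):
        p = make_problem([[1.0]], [1.0], [1.0])
        with pytest.raises(ValueError):
            sinkhorn_transport_cost(p, reg=0.0)
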
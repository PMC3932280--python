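"""Reaction-diffusion simulator: discrete Laplacian, invariant faces,
long-time bounds, and the extinction/permanence dichotomy."""

import math

import numpy as np
import pytest

import predprey_rd as pp
from predprey_rd.exceptions import DomainError, ParameterError

from conftest import CLEAN


@pytest.fixture(scope="module")
def grid():
    return pp.Grid1D(length=math.pi, n=201)


class TestGrid:
    def test_nodes_span_domain(self, grid):
        assert grid.x[0] == 0.0
        assert grid.x[-1] == pytest.approx(math.pi)
        assert grid.dx == pytest.approx(math.pi / 200)

    def test_rejects_tiny_grids(self):
        with pytest.raises(ParameterError):
            pp.Grid1D(length=1.0, n=8)

    def test_quadrature_weights_sum_to_length(self, grid):
        assert grid.quad_weights.sum() == pytest.approx(grid.length)


class TestLaplacian:
    def test_constant_maps_to_zero_exactly(self, grid):
        v = np.full(grid.n, 3.7)
        assert np.all(pp.laplacian_neumann(v, grid) == 0.0)

    @pytest.mark.parametrize("j", [1, 2, 3])
    def test_neumann_eigenfunction_action(self, j):
        # cos(j pi x / l) is an eigenfunction with eigenvalue -(j pi / l)^2
        g = pp.Grid1D(length=math.pi, n=801)
        v = np.cos(j * np.pi * g.x / g.length)
        lam = (j * np.pi / g.length) ** 2
        err = pp.laplacian_neumann(v, g) + lam * v
        assert np.max(np.abs(err)) < 5.0 * lam * g.dx**2

    def test_linear_field_interior_zero(self, grid):
        v = grid.x.copy()
        lap = pp.laplacian_neumann(v, grid)
        assert np.max(np.abs(lap[1:-1])) < 1e-10
        # boundary rows mirror the ghost node: nonzero, enforcing zero flux
        assert lap[0] != 0.0 and lap[-1] != 0.0

    def test_second_order_convergence(self):
        errs = []
        for n in (101, 201, 401):
            g = pp.Grid1D(length=math.pi, n=n)
            v = np.cos(2.0 * g.x)
            errs.append(np.max(np.abs(pp.laplacian_neumann(v, g) + 4.0 * v)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.15)


class TestSimulate:
    def test_converges_to_homogeneous_coexistence(self, clean_traj):
        N_end, P_end = clean_traj.N[-1], clean_traj.P[-1]
        assert N_end.max() - N_end.min() < 1e-3
        assert P_end.max() - P_end.min() < 1e-3
        assert N_end.mean() == pytest.approx(1.0, abs=1e-2)
        assert P_end.mean() == pytest.approx(1.0, abs=1e-2)

    def test_predator_free_face_invariant(self, clean_params, h2, grid):
        init = pp.random_init(grid, 5, (0.5, 1.0), 0.4)
        init = pp.FieldPair(init.N, np.zeros(grid.n))
        traj = pp.simulate(clean_params, h2, grid, init, 300.0)
        assert np.all(traj.P == 0.0)
        assert np.max(np.abs(traj.N[-1] - clean_params.K)) < 1e-6

    def test_prey_free_face_predator_decays(self, clean_params, h2, grid):
        init = pp.FieldPair(np.zeros(grid.n), np.full(grid.n, 2.0))
        traj = pp.simulate(clean_params, h2, grid, init, 300.0)
        assert np.all(traj.N == 0.0)
        assert traj.P[-1].max() < 1e-6

    def test_predation_free_logistic_limit(self, h2, grid):
        # a = 0 switches predation off; prey obeys the logistic equation
        p = pp.ModelParams(**{**CLEAN, "a": 0.0}, validate=False)
        init = pp.random_init(grid, 6, (0.3, 0.5), 0.5)
        traj = pp.simulate(p, h2, grid, init, 300.0)
        assert np.max(np.abs(traj.N[-1] - p.K)) < 1e-6

    def test_nonnegativity_across_regimes(self):
        for name in ("clean_stable", "extinction", "nonexistence_cert"):
            sc = pp.preset(name)
            for seed in (1, 2):
                traj = pp.simulate(sc.params, sc.response, sc.grid,
                                   sc.make_init(seed), 200.0)
                assert traj.N.min() >= 0.0 and traj.P.min() >= 0.0

    def test_diffusion_free_matches_ode(self, h2):
        p = pp.ModelParams(**{**CLEAN, "D1": 0.0, "D2": 0.0})
        g = pp.Grid1D(length=math.pi, n=21)
        traj = pp.simulate(p, h2, g, pp.FieldPair.constant(g, 0.5, 0.5),
                           200.0, rtol=1e-10, atol=1e-13)
        ode = pp.integrate_ode(p, h2, (0.5, 0.5), 200.0,
                               t_eval=traj.times)
        assert np.max(np.abs(traj.N - ode["N"].values[:, None])) < 1e-6
        assert np.max(np.abs(traj.P - ode["P"].values[:, None])) < 1e-6

    def test_summaries_consistent_with_snapshots(self, clean_traj):
        s = clean_traj.summaries
        i = len(clean_traj.times) // 2
        assert s["maxN"].iloc[i] == clean_traj.N[i].max()
        assert s["varP"].iloc[i] == pytest.approx(clean_traj.P[i].var())

    def test_rejects_negative_init(self, clean_params, h2, grid):
        bad = pp.FieldPair.constant(grid, 1.0, 1.0)
        bad.N[3] = -0.5
        with pytest.raises(DomainError):
            pp.simulate(clean_params, h2, grid, bad, 1.0)


class TestDiagnostics:
    def test_dissipativity_bound_value(self, clean_params, h2):
        # M0 = eps (K+1) / (a phi(K+1)) = 3 / 0.75 = 4
        assert pp.predator_bound_M0(clean_params, h2) == pytest.approx(4.0)

    def test_tail_enters_absorbing_box(self, clean_params, h2, grid):
        init = pp.random_init(grid, 9, (20.0, 8.0), 0.3)  # N starts at 10 K
        traj = pp.simulate(clean_params, h2, grid, init, 500.0)
        v = pp.dissipativity_check(traj, clean_params, h2)
        assert v.holds_N and v.holds_P
        assert v.tail_max_N <= clean_params.K + 1e-3
        assert v.tail_max_P <= v.M0 + 1e-3

    def test_margins_at_steady_state(self, clean_params, h2, grid):
        init = pp.FieldPair.constant(grid, 1.0, 1.0)
        traj = pp.simulate(clean_params, h2, grid, init, 100.0)
        q, Q, w, W = pp.persistence_margins(traj)
        assert q == pytest.approx(1.0, abs=1e-6)
        assert Q == pytest.approx(1.0, abs=1e-6)
        assert w == pytest.approx(1.0, abs=1e-6)
        assert W == pytest.approx(1.0, abs=1e-6)

    def test_too_short_trajectory_rejected(self, clean_params, h2, grid):
        init = pp.FieldPair.constant(grid, 1.0, 1.0)
        traj = pp.simulate(clean_params, h2, grid, init, 5.0)
        with pytest.raises(pp.DiagnosticsError):
            pp.persistence_margins(traj)


class TestRegime:
    def test_margin_values(self, clean_params, h2):
        v = pp.regime_check(clean_params, h2)
        assert v.regime == "permanent"
        assert v.margin == pytest.approx(-0.4 + 2.0 / 3.0)

    def test_extinction_side(self, h2):
        p = pp.ModelParams(**{**CLEAN, "gamma": 0.9, "delta": 1.2})
        v = pp.regime_check(p, h2)
        assert v.regime == "extinction"
        assert v.margin == pytest.approx(-0.9 + 2.0 / 3.0)

    def test_boundary_counts_as_extinction(self, h2):
        p = pp.ModelParams(**{**CLEAN, "gamma": 2.0 / 3.0, "delta": 1.0})
        assert pp.regime_check(p, h2).regime == "extinction"

    def test_verdict_ignores_diffusion(self, h2):
        for D in (0.0, 1.0, 50.0):
            p = pp.ModelParams(**{**CLEAN, "D1": D, "D2": D})
            assert pp.regime_check(p, h2).regime == "permanent"


def test_holling2_rhs_matches_rational_form():
    """With a Holling II response the assembled reaction terms equal the
    rational-form system eps(1-N/K)N - aPN/(beta+N), -M(P)P + bNP/(beta+N)
    term by term."""
    rng = np.random.default_rng(42)
    p = pp.ModelParams(eps=1.3, K=3.0, a=0.8, b=1.1, gamma=0.3, delta=0.9)
    beta = 2.0
    s = pp.holling2(beta)
    N = rng.uniform(0.0, 10.0, 10_000)
    P = rng.uniform(0.0, 10.0, 10_000)
    dN, dP = pp.ode_rhs(N, P, p, s)
    M = (p.gamma + p.delta * P) / (1.0 + P)
    dN_ref = p.eps * (1.0 - N / p.K) * N - p.a * P * N / (beta + N)
    dP_ref = -M * P + p.b * N * P / (beta + N)
    np.testing.assert_allclose(dN, dN_ref, rtol=0, atol=1e-14)
    np.testing.assert_allclose(dP, dP_ref, rtol=0, atol=1e-14)
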
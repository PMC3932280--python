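"""Reduced ODE model: mortality law, nullcline, equilibria, Jacobians,
classification and integration."""

import numpy as np
import pytest

import predprey_rd as pp
from predprey_rd.exceptions import DomainError, ParameterError

from conftest import CLEAN, random_response, random_valid_params


class TestModelParams:
    def test_rejects_gamma_ge_delta(self):
        with pytest.raises(ParameterError):
            pp.ModelParams(eps=1, K=1, a=1, b=1, gamma=0.5, delta=0.5)

    def test_rejects_nonpositive_core(self):
        with pytest.raises(ParameterError):
            pp.ModelParams(eps=0, K=1, a=1, b=1, gamma=0.1, delta=0.2)

    def test_unvalidated_escape_hatch(self):
        p = pp.ModelParams(eps=1, K=2, a=0.0, b=1, gamma=0.4, delta=0.6,
                           validate=False)
        assert p.a == 0.0


class TestMortality:
    def test_low_density_value(self, clean_params):
        assert pp.mortality(0.0, clean_params) == pytest.approx(0.4)

    def test_midpoint(self, clean_params):
        assert pp.mortality(1.0, clean_params) == pytest.approx(0.5)

    def test_approaches_delta_from_below(self, clean_params):
        vals = pp.mortality(np.array([10.0, 100.0, 1e6]), clean_params)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals < 0.6)
        assert vals[-1] == pytest.approx(0.6, abs=1e-5)

    def test_rejects_negative_density(self, clean_params):
        with pytest.raises(DomainError):
            pp.mortality(-0.1, clean_params)

    def test_derivative_positive_and_decreasing(self, clean_params):
        P = np.linspace(0.0, 10.0, 100)
        d = pp.mortality_prime(P, clean_params)
        assert np.all(d > 0) and np.all(np.diff(d) < 0)
        assert d[0] == pytest.approx(clean_params.delta - clean_params.gamma)


class TestPreyNullcline:
    def test_interior_value(self, clean_params, h2):
        assert pp.prey_nullcline_f(1.0, clean_params, h2) == pytest.approx(1.0)

    def test_vanishes_at_K(self, clean_params, h2):
        assert pp.prey_nullcline_f(2.0, clean_params, h2) == pytest.approx(0.0)

    def test_removable_singularity_at_zero(self, clean_params, h2):
        # limit eps / (a phi'(0)) with phi'(0) = 1
        assert pp.prey_nullcline_f(0.0, clean_params, h2) == pytest.approx(1.0)

    def test_fprime_matches_finite_differences(self, clean_params, h2):
        h = 1e-6
        for N in [0.3, 0.9, 1.5, 1.9]:
            fd = (pp.prey_nullcline_f(N + h, clean_params, h2)
                  - pp.prey_nullcline_f(N - h, clean_params, h2)) / (2 * h)
            an = pp.prey_nullcline_fprime(N, clean_params, h2)
            assert an == pytest.approx(fd, rel=1e-6, abs=1e-8)


class TestRhsAndEquilibria:
    def test_coexistence_point_is_root(self, clean_params, h2):
        assert pp.ode_rhs(1.0, 1.0, clean_params, h2) == (0.0, 0.0)

    def test_boundary_states_are_roots(self, clean_params, h2):
        assert pp.ode_rhs(0.0, 0.0, clean_params, h2) == (0.0, 0.0)
        assert pp.ode_rhs(2.0, 0.0, clean_params, h2) == (0.0, 0.0)

    def test_clean_set_equilibria(self, clean_params, h2):
        eqs = pp.find_equilibria(clean_params, h2)
        labels = [e.label for e in eqs]
        assert labels == ["E1", "E2", "E3"]
        e3 = eqs[2]
        assert e3.N0 == pytest.approx(1.0, abs=1e-10)
        assert e3.P0 == pytest.approx(1.0, abs=1e-10)

    def test_no_interior_without_persistence(self, h2):
        p = pp.ModelParams(**{**CLEAN, "gamma": 0.9, "delta": 1.2})
        eqs = pp.find_equilibria(p, h2)
        assert [e.label for e in eqs] == ["E1", "E2"]

    def test_residuals_over_random_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = random_valid_params(rng)
            s = random_response(rng, p)
            for eq in pp.find_equilibria(p, s):
                assert eq.residual < 1e-10

    def test_constant_mortality_limit(self, h2):
        # delta -> gamma+ : interior root approaches b phi(N) = gamma
        p = pp.ModelParams(**{**CLEAN, "delta": 0.4 + 1e-8})
        e3 = [e for e in pp.find_equilibria(p, h2) if e.label == "E3"][0]
        # b phi(N) = 0.4 => N/(1+N) = 0.4 => N = 2/3
        assert e3.N0 == pytest.approx(2.0 / 3.0, abs=1e-6)


class TestJacobianAndClassification:
    def test_origin_spectrum_closed_form(self, clean_params, h2):
        eqs = pp.find_equilibria(clean_params, h2)
        e1 = eqs[0]
        vals = sorted(z.real for z in e1.eigenvalues)
        assert vals == pytest.approx([-0.4, 1.0])
        assert e1.classification == "saddle"

    def test_prey_only_spectrum_closed_form(self, clean_params, h2):
        e2 = pp.find_equilibria(clean_params, h2)[1]
        vals = sorted(z.real for z in e2.eigenvalues)
        assert vals == pytest.approx([-1.0, 4.0 / 15.0])
        assert e2.classification == "saddle"

    def test_coexistence_matrix_entries(self, clean_e3):
        J = clean_e3.jac
        assert J == pytest.approx(np.array([[-0.25, -0.5], [0.25, -0.05]]),
                                  abs=1e-9)
        assert clean_e3.trace == pytest.approx(-0.3)
        assert clean_e3.det == pytest.approx(0.1375)
        assert clean_e3.classification == "stable-spiral"
        assert clean_e3.prop1_certificate  # N0 = 1 lies in [K/2, K] = [1, 2]

    def test_trace_det_eigenvalue_consistency(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = random_valid_params(rng)
            s = random_response(rng, p)
            for eq in pp.find_equilibria(p, s):
                lam1, lam2 = eq.eigenvalues
                assert (lam1 + lam2).real == pytest.approx(eq.trace, rel=1e-10,
                                                           abs=1e-12)
                assert (lam1 * lam2).real == pytest.approx(eq.det, rel=1e-10,
                                                           abs=1e-12)

    def test_prey_only_stability_flips_at_margin(self, h2):
        # b phi(K) = 2/3; crossing gamma through it flips E2's type
        for gamma, expected in [(0.5, "saddle"), (0.7, "stable-node")]:
            p = pp.ModelParams(**{**CLEAN, "gamma": gamma,
                                  "delta": gamma + 0.3})
            e2 = pp.find_equilibria(p, h2)[1]
            assert e2.classification == expected

    def test_stability_certificate_implies_stable(self):
        rng = np.random.default_rng(11)
        found = 0
        for _ in range(200):
            p = random_valid_params(rng)
            s = random_response(rng, p)
            for eq in pp.find_equilibria(p, s):
                if eq.prop1_certificate:
                    found += 1
                    assert eq.classification in ("stable-node",
                                                 "stable-spiral")
        assert found > 10


class TestOdeIntegration:
    def test_converges_to_coexistence(self, clean_params, h2):
        ts = pp.integrate_ode(clean_params, h2, (0.5, 0.5), 500.0)
        assert ts["N"].iloc[-1] == pytest.approx(1.0, abs=1e-3)
        assert ts["P"].iloc[-1] == pytest.approx(1.0, abs=1e-3)

    def test_predator_dies_out_below_margin(self, h2):
        p = pp.ModelParams(**{**CLEAN, "gamma": 0.9, "delta": 1.2})
        ts = pp.integrate_ode(p, h2, (0.5, 0.5), 500.0)
        assert ts["P"].iloc[-1] < 1e-6
        assert ts["N"].iloc[-1] == pytest.approx(2.0, abs=1e-3)

    def test_prey_axis_invariant(self, clean_params, h2):
        ts = pp.integrate_ode(clean_params, h2, (0.3, 0.0), 200.0)
        assert np.all(ts["P"] == 0.0)
        assert ts["N"].iloc[-1] == pytest.approx(2.0, abs=1e-6)
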
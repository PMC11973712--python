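"""Equilibrium solver against closed forms and an independent minimizer.

The network solver is cross-checked two ways: exact quadratic solutions
for single-edge systems, and direct numerical minimization of the convex
log-coordinate potential (scipy BFGS) for multi-edge systems — a fully
independent route to the same equilibrium.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from dimernet import (
    ConcentrationProfile,
    DimerizationNetwork,
    homodimer_equilibrium_closed_form,
    pair_equilibrium_closed_form,
    random_network,
    solve_equilibrium,
)
from dimernet.equilibrium import solve_equilibrium_free


def potential_minimizer_oracle(kmat, totals, x0_shift=0.0):
    """Independent equilibrium: scipy trust-region minimization of the
    convex potential (analytic gradient and Hessian)."""

    def phi(x):
        e = np.exp(x)
        pair = kmat * np.outer(e, e)
        return e.sum() + np.triu(pair, 1).sum() + np.diag(pair).sum() - totals @ x

    def grad(x):
        e = np.exp(x)
        pair = kmat * np.outer(e, e)
        return e + pair.sum(axis=1) + np.diag(pair) - totals

    def hess(x):
        e = np.exp(x)
        pair = kmat * np.outer(e, e)
        h = pair.copy()
        np.fill_diagonal(h, e + pair.sum(axis=1) + 3 * np.diag(pair))
        return h

    x0 = np.log(totals) + x0_shift
    res = minimize(phi, x0, jac=grad, hess=hess, method="trust-exact",
                   options={"gtol": 1e-13, "maxiter": 5000})
    x = res.x
    for _ in range(3):  # polish to machine precision
        x = x - np.linalg.solve(hess(x), grad(x))
    return np.exp(x)


class TestClosedForms:
    def test_pair_strong_binding_sequesters(self):
        fa, fb, d = pair_equilibrium_closed_form(1e7, 1e-3, 1e-3)
        assert fa == pytest.approx(9.950125e-6, rel=1e-6)
        assert d == pytest.approx(9.9005e-4, rel=1e-4)
        assert d / 1e-3 > 0.99  # >= 99% dimerized

    def test_pair_limits(self):
        fa, fb, d = pair_equilibrium_closed_form(5.0, 2.0, 0.0)
        assert (fa, fb, d) == (2.0, 0.0, 0.0)
        # weak-binding first-order limit D -> K Ta Tb
        _, _, d = pair_equilibrium_closed_form(1e-12, 3.0, 4.0)
        assert d == pytest.approx(1e-12 * 12.0, rel=1e-6)

    def test_homodimer_exact_and_limits(self):
        free, dimer = homodimer_equilibrium_closed_form(1.0, 1.0)
        assert free == pytest.approx(0.5) and dimer == pytest.approx(0.25)
        assert homodimer_equilibrium_closed_form(1.0, 0.0) == (0.0, 0.0)
        free, _ = homodimer_equilibrium_closed_form(1e-9, 1.0)
        assert free == pytest.approx(1.0 - 2e-9, rel=1e-12)


class TestSolverAgainstOracles:
    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        logk=st.floats(-7, 7),
        logta=st.floats(-3, 3),
        logtb=st.floats(-3, 3),
    )
    def test_pair_matches_closed_form(self, logk, logta, logtb):
        K, ta, tb = 10.0**logk, 10.0**logta, 10.0**logtb
        kmat = np.array([[0.0, K], [K, 0.0]])
        free = solve_equilibrium_free(kmat, np.array([ta, tb]))
        fa, fb, d = pair_equilibrium_closed_form(K, ta, tb)
        assert free[0] == pytest.approx(fa, rel=1e-8)
        assert free[1] == pytest.approx(fb, rel=1e-8)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(logk=st.floats(-7, 7), logt=st.floats(-3, 3))
    def test_homodimer_matches_closed_form(self, logk, logt):
        K, t = 10.0**logk, 10.0**logt
        free = solve_equilibrium_free(np.array([[K]]), np.array([t]))
        f_exact, _ = homodimer_equilibrium_closed_form(K, t)
        assert free[0] == pytest.approx(f_exact, rel=1e-8)

    @pytest.mark.parametrize("m", [2, 3, 4])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_networks_match_potential_minimizer(self, m, seed):
        net, prof = random_network(m, seed=seed)
        state = solve_equilibrium(net, prof)
        oracle = potential_minimizer_oracle(
            net.affinity_matrix(), prof.totals_array()
        )
        np.testing.assert_allclose(state.free, oracle, rtol=1e-6)


class TestEquilibriumInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_and_mass_action(self, seed):
        net, prof = random_network(5, seed=seed)
        state = solve_equilibrium(net, prof)
        assert state.residual_norm <= 1e-9
        for (i, j), k in zip(net.edges, net.K):
            assert state.dimers[(i, j)] == pytest.approx(
                k * state.free[i] * state.free[j], rel=1e-12
            )
        for i, t in enumerate(prof.totals):
            assert state.total_of(i, net) == pytest.approx(t, rel=1e-9)

    def test_zero_total_partner_absent(self):
        net = DimerizationNetwork(2, ((0, 1),), (5.0,))
        state = solve_equilibrium(net, ConcentrationProfile((2.0, 0.0), (0,)))
        assert state.free[0] == 2.0 and state.free[1] == 0.0
        assert state.dimers[(0, 1)] == 0.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_initialization_independence(self, seed):
        net, prof = random_network(4, seed=seed)
        kmat, totals = net.affinity_matrix(), prof.totals_array()
        base = solve_equilibrium_free(kmat, totals)
        rng = np.random.default_rng(seed)
        for _ in range(5):
            x0 = np.log(totals) + rng.uniform(-5, 5, size=totals.size)
            alt = solve_equilibrium_free(kmat, totals, x0=x0)
            np.testing.assert_allclose(alt, base, rtol=1e-8)

    def test_own_total_monotonicity(self):
        net, prof = random_network(4, seed=9)
        totals = prof.totals_array()
        kmat = net.affinity_matrix()
        for i in range(net.m):
            t_hi = totals.copy()
            t_hi[i] *= 1.01
            lo = solve_equilibrium_free(kmat, totals)
            hi = solve_equilibrium_free(kmat, t_hi)
            assert hi[i] > lo[i]

    @pytest.mark.parametrize("k_scale", [10.0, 0.01])
    def test_scale_covariance(self, k_scale):
        # totals x k and K / k leave the dimensionless system invariant:
        # all concentrations scale by k
        net, prof = random_network(5, seed=11)
        base = solve_equilibrium(net, prof)
        scaled_net = net.with_affinities(np.asarray(net.K) / k_scale)
        scaled_prof = prof.with_totals(prof.totals_array() * k_scale)
        scaled = solve_equilibrium(scaled_net, scaled_prof)
        np.testing.assert_allclose(scaled.free, base.free * k_scale, rtol=1e-8)
        for e in net.edges:
            assert scaled.dimers[e] == pytest.approx(
                base.dimers[e] * k_scale, rel=1e-8
            )

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            solve_equilibrium_free(np.array([[1.0]]), np.array([-1.0]))
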
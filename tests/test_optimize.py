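"""Losses, gate criterion, annealing and GA optimizers, versatility."""

import numpy as np
import pytest

from dimernet import (
    ConcentrationProfile,
    DimerizationNetwork,
    GAParams,
    TargetFunction,
    TitrationGrid,
    build_target_library,
    compute_loss,
    fit_network_dual_annealing,
    logic_gate_success,
    named_gate,
    optimize_accessories_ga,
    titrate,
    versatility_single_dimer,
)
from dimernet.optimize import gate_input_grid, gate_margin, named_two_input_targets


class TestLosses:
    def test_identity_gives_zero(self):
        F = np.array([0.0, 1.0, 2.0])
        for metric in ("sum_squares", "mse", "inf"):
            assert compute_loss(metric, F, F) == 0.0
        assert compute_loss("pearson", F, F) == pytest.approx(1.0)

    def test_worked_example(self):
        F, G = np.array([0.0, 1.0]), np.array([1.0, 3.0])
        assert compute_loss("inf", F, G) == 2.0
        assert compute_loss("mse", F, G) == 2.5
        assert compute_loss("sum_squares", F, G) == 5.0

    def test_pearson_affine_invariance(self):
        F = np.array([0.0, 0.5, 2.0, 3.0])
        assert compute_loss("pearson", F, 2 * F + 1) == pytest.approx(1.0)
        assert compute_loss("pearson", F, -F) == pytest.approx(-1.0)

    def test_pearson_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            compute_loss("pearson", np.zeros(3), np.arange(3.0))

    def test_loss_identities(self):
        rng = np.random.default_rng(0)
        F, G = rng.normal(size=20), rng.normal(size=20)
        ss = compute_loss("sum_squares", F, G)
        assert ss == pytest.approx(20 * compute_loss("mse", F, G))
        assert compute_loss("inf", F, G) <= np.sqrt(ss)


class TestGateCriterion:
    def test_grid_levels_and_patterns(self):
        pts, pats = gate_input_grid(2)
        assert pts.shape == (16, 2)
        assert pats.sum() == 16  # half of all input slots are "on"

    def test_strict_separation(self):
        tt = named_gate("AND")
        _, pats = gate_input_grid(2)
        on = np.array([tt(p) for p in pats])
        resp = np.where(on, 1.0, 1e-2)
        assert logic_gate_success(resp, tt)
        # boundary: off max == on min fails the strict rule
        resp_eq = np.where(on, 1e-2, 1e-2)
        assert not logic_gate_success(resp_eq, tt)

    def test_scale_invariance(self):
        tt = named_gate("NOR")
        _, pats = gate_input_grid(2)
        on = np.array([tt(p) for p in pats])
        resp = np.where(on, 5.0, 0.3)
        assert logic_gate_success(resp, tt) == logic_gate_success(100 * resp, tt)

    def test_named_gate_coverage(self):
        assert named_gate("XOR")((True, False)) is True
        assert named_gate("AT_LEAST_3", 4)((True, True, True, False)) is True
        assert named_gate("ANY_2_OR_NONE", 3)((False, False, False)) is True
        with pytest.raises(KeyError):
            named_gate("FROB")


class TestDualAnnealing:
    def test_self_recovery_small_network(self, grid1):
        # a target produced by a 2-monomer network is recoverable at m=2
        net = DimerizationNetwork(2, ((0, 1), (1, 1)), (1e6, 1e4))
        prof = ConcentrationProfile((1.0, 1.0), (0,))
        target_resp = titrate(net, prof, grid1)[net.edge_index()[(1, 1)]]
        target = TargetFunction(target_resp.log_values, grid1)
        res = fit_network_dual_annealing(target, 2, budget=2500, seed=0)
        assert res.success
        assert res.losses["inf"] <= 1.0
        assert res.network.m == 2

    def test_failed_runs_report_losses(self, grid1):
        # an impossible target (flat at the ceiling then the floor with a
        # one-point cliff) yields an honest failure with finite losses
        target = TargetFunction(np.where(np.arange(30) < 15, 3.0, -3.0), grid1)
        res = fit_network_dual_annealing(target, 2, budget=300, seed=1)
        assert not res.success
        assert np.isfinite(res.best_loss)


class TestGeneticAlgorithm:
    def test_self_recovery(self, grid1):
        from dimernet import random_network

        net, prof = random_network(3, seed=11)
        resp = titrate(net, prof, grid1)[0]
        target = TargetFunction(resp.log_values, grid1)
        a_star, losses = optimize_accessories_ga(
            net, target, dimer=resp.dimer,
            ga_params=GAParams(population=30, iterations=10), seed=5,
        )
        assert losses["inf"] <= 1.0
        assert a_star.shape == (2,)
        assert np.all((a_star >= 1e-3) & (a_star <= 1e3))

    def test_deterministic_given_seed(self, grid1):
        from dimernet import random_network

        net, prof = random_network(3, seed=2)
        resp = titrate(net, prof, grid1)[0]
        target = TargetFunction(resp.log_values, grid1)
        params = GAParams(population=12, iterations=4)
        out1 = optimize_accessories_ga(net, target, resp.dimer, ga_params=params, seed=9)
        out2 = optimize_accessories_ga(net, target, resp.dimer, ga_params=params, seed=9)
        np.testing.assert_array_equal(out1[0], out2[0])
        assert out1[1] == out2[1]


class TestVersatility:
    def test_own_response_always_achieved(self, grid1):
        from dimernet import random_network

        net, prof = random_network(3, seed=7)
        responses = titrate(net, prof, grid1)
        lib = build_target_library([responses[0]], m=3, grid=grid1)
        report = versatility_single_dimer(
            net, lib, gamma=1.0,
            ga_params=GAParams(population=25, iterations=8), seed=3,
            dimers=[responses[0].dimer],
        )
        assert report.per_dimer[responses[0].dimer] == 1.0
        assert report.any_dimer >= max(report.per_dimer.values())

    def test_empty_library_raises(self, grid1):
        from dimernet import random_network
        from dimernet.response import TargetLibrary

        net, _ = random_network(3, seed=7)
        empty = TargetLibrary(m=3, grid=grid1, codes=(), targets=())
        with pytest.raises(ValueError):
            versatility_single_dimer(net, empty, seed=0)


class TestTwoInputTargets:
    def test_named_set_complete(self, grid2):
        targets = named_two_input_targets(grid2)
        assert set(targets) == {
            "AND", "OR", "NAND", "NOR", "XOR", "XNOR", "NIMPLY",
            "ratiometric", "equality", "two_input_bump",
        }
        for t in targets.values():
            assert t.log_values.shape == grid2.shape

    def test_ratiometric_shape(self, grid2):
        t = named_two_input_targets(grid2)["ratiometric"]
        v = t.log_values
        assert v[-1, 0] == pytest.approx(1.0)   # x1 high, x2 low -> high
        assert v[0, -1] == pytest.approx(-2.0)  # x1 low, x2 high -> low
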
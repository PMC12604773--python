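import math

import numpy as np
import pytest

from tests.conftest import make_network, random_factors
from trifuse.objective import FactorSet, Hyperparameters, total_value
from trifuse.optimizer import (
    OptimizerState,
    _block_residuals,
    curvature_stepsize,
    curvature_stepsizes,
    extrapolate,
    fit,
    init_couplings,
    init_factors,
    ls1_step,
    ls2_step,
    project_topk,
    update_envelope,
    update_theta,
    update_weights,
)
from trifuse.synthetic import generate_planted_network


def make_initial_state(net, hp):
    """Replicate the solver's initialization into an explicit state."""
    G0 = init_factors(net, hp)
    S0 = init_couplings(net, G0)
    if hp.reweight:
        for key, w in update_weights(net, FactorSet(G=G0, S=S0), hp.eps_res).items():
            net.relations[key].weight = w
    c1 = total_value(net, FactorSet(G=G0, S=S0), hp)
    return OptimizerState(
        it=1, theta_prev=0.0, theta_cur=1.0, q=1.0, c=c1,
        G_cur=G0, G_prev={k: v.copy() for k, v in G0.items()},
        Z_cur={k: v.copy() for k, v in G0.items()},
        S_cur=S0, S_prev={k: v.copy() for k, v in S0.items()},
        l1=hp.l_init, l2=hp.l_init,
    )


class TestInitFactors:
    def test_deterministic(self, two_type_net):
        hp = Hyperparameters(seed=42, init="random")
        G1 = init_factors(two_type_net, hp)
        G2 = init_factors(two_type_net, hp)
        for name in G1:
            np.testing.assert_array_equal(G1[name], G2[name])

    @pytest.mark.parametrize("init", ["random", "svd"])
    def test_nonnegative_and_shaped(self, two_type_net, init):
        G = init_factors(two_type_net, Hyperparameters(seed=0, init=init))
        for t in two_type_net.types:
            assert G[t.name].shape == (t.n, t.rank)
            assert G[t.name].min() >= 0

    def test_isolated_type_still_initialized(self, rng):
        net = make_network(
            {"A": (4, 2), "B": (3, 2), "C": (6, 3)}, [("A", "B")], rng
        )
        G = init_factors(net, Hyperparameters(seed=0, init="svd"))
        assert G["C"].shape == (6, 3)
        assert G["C"].min() >= 0


class TestInitCouplings:
    def test_orthonormal_reduces_to_projection(self, rng):
        net = make_network({"A": (4, 2), "B": (3, 2)}, [("A", "B")], rng)
        Qa, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        Qb, _ = np.linalg.qr(rng.standard_normal((3, 2)))
        S = init_couplings(net, {"A": Qa, "B": Qb})
        R = net.relations[("A", "B")].matrix
        np.testing.assert_allclose(S[("A", "B")], Qa.T @ R @ Qb, atol=1e-10)

    def test_recovers_planted_coupling(self, rng):
        net = make_network({"A": (8, 3), "B": (6, 2)}, [("A", "B")], rng)
        Ga = rng.random((8, 3)) + 0.1
        Gb = rng.random((6, 2)) + 0.1
        S0 = rng.standard_normal((3, 2))
        net.relations[("A", "B")].matrix = Ga @ S0 @ Gb.T
        S = init_couplings(net, {"A": Ga, "B": Gb})
        np.testing.assert_allclose(S[("A", "B")], S0, atol=1e-8)

    def test_zero_matrix_gives_zero_coupling(self, rng):
        net = make_network({"A": (4, 2), "B": (3, 2)}, [("A", "B")], rng)
        net.relations[("A", "B")].matrix = np.zeros((4, 3))
        S = init_couplings(net, init_factors(net, Hyperparameters(seed=0)))
        np.testing.assert_allclose(S[("A", "B")], 0.0, atol=1e-12)


class TestExtrapolate:
    def test_first_iteration_fixed_point(self, two_type_net):
        hp = Hyperparameters(seed=0)
        st = make_initial_state(two_type_net.copy(), hp)
        Y = extrapolate(st)
        for name in Y:
            np.testing.assert_array_equal(Y[name], st.G_cur[name])

    def test_stationary_iterates_fixed_point(self, two_type_net, rng):
        hp = Hyperparameters(seed=0)
        st = make_initial_state(two_type_net.copy(), hp)
        st.theta_prev, st.theta_cur = 3.7, 5.1
        Y = extrapolate(st)
        for name in Y:
            np.testing.assert_allclose(Y[name], st.G_cur[name], atol=1e-12)

    def test_formula_transcription(self, two_type_net, rng):
        hp = Hyperparameters(seed=0)
        st = make_initial_state(two_type_net.copy(), hp)
        st.theta_prev, st.theta_cur = 2.0, 3.0
        for name in st.G_cur:
            st.G_prev[name] = rng.random(st.G_prev[name].shape)
            st.Z_cur[name] = rng.random(st.Z_cur[name].shape)
        Y = extrapolate(st)
        for name in Y:
            expect = (
                st.G_cur[name]
                + (2.0 / 3.0) * (st.Z_cur[name] - st.G_cur[name])
                + (1.0 / 3.0) * (st.G_cur[name] - st.G_prev[name])
            )
            np.testing.assert_allclose(Y[name], expect, atol=1e-12)

    def test_zero_theta_rejected(self, two_type_net):
        st = make_initial_state(two_type_net.copy(), Hyperparameters(seed=0))
        st.theta_cur = 0.0
        with pytest.raises(ZeroDivisionError):
            extrapolate(st)


class TestCurvatureStepsize:
    def test_quadratic_secant_exact(self, rng, hp):
        dx = rng.standard_normal(10)
        L = 7.5
        assert curvature_stepsize(dx, L * dx, hp) == pytest.approx(L)

    def test_zero_step_falls_back(self, hp):
        assert curvature_stepsize(np.zeros(5), np.ones(5), hp) == hp.l_init

    def test_negative_curvature_falls_back(self, rng, hp):
        dx = rng.standard_normal(8)
        assert curvature_stepsize(dx, -2.0 * dx, hp) == hp.l_init

    def test_clipped_into_bounds(self, hp):
        dx = np.ones(3)
        assert curvature_stepsize(dx, 1e20 * dx, hp) == hp.l_max

    def test_pair_wrapper(self, rng, hp):
        dx = rng.standard_normal(6)
        l1, l2 = curvature_stepsizes((dx, 2 * dx), (dx, 3 * dx), hp)
        assert (l1, l2) == (pytest.approx(2.0), pytest.approx(3.0))


class TestLineSearches:
    def test_ls1_prox_output_nonnegative(self, rng):
        net = make_network({"A": (5, 2), "B": (5, 2)}, [("A", "B")], rng)
        hp = Hyperparameters(seed=3, lam_g=0.1, k=4)
        st = make_initial_state(net, hp)
        Y = extrapolate(st)
        _, Z, _, _, _, _ = ls1_step(net, st, Y, hp)
        for z in Z.values():
            assert z.min() >= 0

    def test_ls1_descends_on_smooth_toy(self, rng):
        net = make_network({"A": (5, 2), "B": (5, 2)}, [("A", "B")], rng)
        hp = Hyperparameters(seed=5, lam=0.0, lam_g=0.0, delta=1e-8, reweight=False)
        st = make_initial_state(net, hp)
        # perturb away from the least-squares couplings so a descent exists
        for key in st.S_cur:
            st.S_cur[key] = st.S_cur[key] + 0.5
        st.c = total_value(net, FactorSet(G=st.G_cur, S=st.S_cur), hp)
        Y = extrapolate(st)
        S_new, Z_new, _, _, ok, _ = ls1_step(net, st, Y, hp)
        assert ok
        assert total_value(net, FactorSet(G=Z_new, S=S_new), hp) < st.c

    def test_ls1_flag_false_for_absurd_delta(self, rng):
        net = make_network({"A": (5, 2), "B": (5, 2)}, [("A", "B")], rng)
        hp = Hyperparameters(seed=3, delta=1e12)
        st = make_initial_state(net, hp)
        Y = extrapolate(st)
        _, _, l1, l2, ok, _ = ls1_step(net, st, Y, hp)
        assert not ok
        assert l1 == hp.l_max and l2 == hp.l_max

    def test_ls2_output_nonnegative_and_accepted(self, rng):
        net = make_network({"A": (5, 2), "B": (5, 2)}, [("A", "B")], rng)
        hp = Hyperparameters(seed=3, lam_g=0.1, k=4)
        st = make_initial_state(net, hp)
        S_new, V, _, _, ok, gap = ls2_step(net, st, hp)
        assert ok
        for v in V.values():
            assert v.min() >= 0
        # the accepted pair satisfies the Armijo inequality with margin >= 0
        F_new = total_value(net, FactorSet(G=V, S=S_new), hp)
        assert st.c - hp.delta * gap - F_new >= -1e-10

    def test_best_of_two_selection(self, rng):
        # with an absurd delta both searches fail; the main loop must pick
        # the candidate with the smaller objective
        net = make_network({"A": (5, 2), "B": (5, 2)}, [("A", "B")], rng)
        hp = Hyperparameters(seed=3, delta=1e12, max_iter=1)
        net2 = net.copy()  # replicate the solver's reweighted working copy
        st = make_initial_state(net2, hp)
        Y = extrapolate(st)
        S1, Z1, *_ = ls1_step(net2, st, Y, hp)
        S2, V2, *_ = ls2_step(net2, st, hp)
        Fz = total_value(net2, FactorSet(G=Z1, S=S1), hp)
        Fv = total_value(net2, FactorSet(G=V2, S=S2), hp)
        res = fit(net, hp)
        assert res.trace[0]["branch"] == ("LS2-Z" if Fz <= Fv else "LS2-V")
        chosen = Z1 if Fz <= Fv else V2
        for name in chosen:
            np.testing.assert_array_equal(res.factors.G[name], chosen[name])


class TestScalarUpdates:
    def test_theta_examples(self):
        assert update_theta(0.0) == pytest.approx(1.0)
        assert update_theta(1.0) == pytest.approx((math.sqrt(5) + 1) / 2)

    def test_theta_recurrence_identity(self, rng):
        for theta in rng.random(20) * 50:
            t2 = update_theta(theta)
            assert abs(t2 * t2 - t2 - theta * theta) <= 1e-12 * max(1.0, theta * theta)

    def test_envelope_example(self):
        q, c = update_envelope(1.0, 10.0, 8.0, 0.5)
        assert q == pytest.approx(1.5)
        assert c == pytest.approx(13.0 / 1.5)

    def test_envelope_tau_zero_limit(self):
        q, c = update_envelope(1.0, 10.0, 8.0, 1e-12)
        assert q == pytest.approx(1.0)
        assert c == pytest.approx(8.0)

    def test_envelope_never_increases_when_F_below_c(self, rng):
        for _ in range(50):
            q = 1.0 + 9 * rng.random()
            c = 10 * rng.random()
            F = c - 5 * rng.random()
            tau = 0.01 + 0.98 * rng.random()
            _, c_new = update_envelope(q, c, F, tau)
            assert c_new <= c + 1e-12


class TestUpdateWeights:
    def test_reciprocal_examples(self, rng):
        net = make_network({"A": (2, 1), "B": (2, 1)}, [("A", "B")], rng)
        fs = random_factors(net, rng)
        resid = _block_residuals(net, fs)[("A", "B")]
        w = update_weights(net, fs)[("A", "B")]
        assert w == pytest.approx(1.0 / (2.0 * resid))

    def test_exact_fit_hits_cap(self, rng):
        net = make_network({"A": (3, 2), "B": (3, 2)}, [("A", "B")], rng)
        fs = random_factors(net, rng)
        net.relations[("A", "B")].matrix = fs.G["A"] @ fs.S[("A", "B")] @ fs.G["B"].T
        w = update_weights(net, fs, eps_res=1e-12)[("A", "B")]
        assert w == pytest.approx(1.0 / (2e-12))


class TestProjectTopK:
    def test_keeps_k_largest(self):
        G = {"A": np.array([[0.5, 3.0], [1.0, 2.0]])}
        out = project_topk(G, 2)
        assert np.count_nonzero(out["A"]) == 2
        assert out["A"][0, 1] == 3.0 and out["A"][1, 1] == 2.0


class TestFit:
    def test_planted_exact_fit_recovery(self):
        pn = generate_planted_network(
            sizes=(15, 10, 15, 15, 8, 8), ranks=3, seed=7, binarize=False
        )
        # fixed unit weights: with lam = 0 the residual-normalizing weight
        # update rescales the objective away from the plain data fit
        hp = Hyperparameters(lam=0.0, lam_g=1e-6, seed=7, max_iter=100, reweight=False)
        G0 = init_factors(pn.network, hp)
        S0 = init_couplings(pn.network, G0)
        r0 = sum(_block_residuals(pn.network, FactorSet(G=G0, S=S0)).values())
        res = fit(pn.network, hp)
        rf = sum(res.trace[-1]["residuals"].values())
        assert rf <= 1e-3 * r0

    def test_trace_descent_invariants(self):
        pn = generate_planted_network(sizes=(15, 10, 15, 15, 8, 8), ranks=3, seed=3)
        hp = Hyperparameters(seed=3, reweight=False)
        res = fit(pn.network, hp)
        cs = [res.trace[0]["c_ref"]] + [r["c_next"] for r in res.trace]
        assert all(b <= a + 1e-9 for a, b in zip(cs, cs[1:]))
        for row in res.trace:
            assert row["ls_ok"]
            assert row["F"] <= row["c_ref"] - hp.delta * row["armijo_gap"] + 1e-9
            assert row["g_min"] >= 0

    def test_deterministic_traces(self):
        pn = generate_planted_network(sizes=(15, 10, 15, 15, 8, 8), ranks=3, seed=5)
        hp = Hyperparameters(seed=5)
        r1 = fit(pn.network, hp)
        r2 = fit(pn.network, hp)
        assert len(r1.trace) == len(r2.trace)
        for a, b in zip(r1.trace, r2.trace):
            assert a == b
        for name in r1.factors.G:
            np.testing.assert_array_equal(r1.factors.G[name], r2.factors.G[name])

    def test_input_network_not_mutated(self):
        pn = generate_planted_network(sizes=(15, 10, 15, 15, 8, 8), ranks=3, seed=5)
        before = {k: b.matrix.copy() for k, b in pn.network.relations.items()}
        weights = {k: b.weight for k, b in pn.network.relations.items()}
        fit(pn.network, Hyperparameters(seed=5, max_iter=5))
        for k, b in pn.network.relations.items():
            np.testing.assert_array_equal(b.matrix, before[k])
            assert b.weight == weights[k]

    def test_single_block_stationarity(self, rng):
        # at a stationary point with lam = lam_g = 0 the couplings solve the
        # least-squares normal equations for the final factors
        net = make_network({"A": (8, 2), "B": (7, 2)}, [("A", "B")], rng)
        hp = Hyperparameters(
            lam=0.0, lam_g=0.0, seed=2, max_iter=2000, tol=1e-14, reweight=False
        )
        res = fit(net, hp)
        S_ls = init_couplings(net, res.factors.G)
        diff = np.linalg.norm(res.factors.S[("A", "B")] - S_ls[("A", "B")])
        assert diff <= 1e-6 * max(1.0, np.linalg.norm(S_ls[("A", "B")]))

    def test_project_k_budget(self):
        pn = generate_planted_network(sizes=(15, 10, 15, 15, 8, 8), ranks=3, seed=5)
        hp = Hyperparameters(seed=5, k=10, lam_g=0.01, project_k=True, max_iter=20)
        res = fit(pn.network, hp)
        for G in res.factors.G.values():
            assert np.count_nonzero(G) <= 10

    def test_holdout_recovery_auc(self):
        # held-out positives of the target block outrank >= 95% of negatives
        from trifuse.evaluation import auc_aupr, reconstruct_scores
        from trifuse.synthetic import mask_holdout

        for seed in (0, 1, 2):
            pn = generate_planted_network(seed=seed)
            train, held = mask_holdout(pn, 0.2, seed=seed)
            res = fit(train, Hyperparameters(seed=seed))
            sm = reconstruct_scores(res.factors, pn.network.target)
            R = pn.network.target_block.matrix
            rows = sorted({r for r, _ in held})
            y = (R[rows, :] != 0).ravel().astype(int)
            auc, _ = auc_aupr(sm.scores[rows, :].ravel(), y)
            assert auc >= 0.95, (seed, auc)

    def test_stop_reason_tolerance(self):
        pn = generate_planted_network(sizes=(15, 10, 15, 15, 8, 8), ranks=3, seed=5)
        res = fit(pn.network, Hyperparameters(seed=5, tol=1e-3, max_iter=500))
        assert res.stop_reason == "tolerance"
        assert res.n_iter < 500
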
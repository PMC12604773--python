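"""Accelerated proximal difference-of-convex solver for the fused objective.

Each iteration builds a momentum point Y from the two most recent factor
iterates, takes a forward-backward step there (LS-1) with secant-based
step constants and a non-monotone Armijo test against the envelope value c,
and falls back to an anchored step at the current iterate (LS-2, with
best-of-two selection) when the extrapolated step fails.  Source weights,
the momentum scalar theta, and the (q, c) envelope are refreshed after
every accepted step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from trifuse.network import HeteroNetwork
from trifuse.objective import (
    FactorSet,
    GradientSet,
    Hyperparameters,
    grad_G,
    grad_S,
    total_value,
)
from trifuse.sparsity import prox_nonneg_linear, subgrad_sum_top_k

GDict = dict[str, np.ndarray]
SDict = dict[tuple[str, str], np.ndarray]


@dataclass
class OptimizerState:
    """Mutable per-iteration bookkeeping of the main loop."""

    it: int
    theta_prev: float
    theta_cur: float
    q: float
    c: float
    G_cur: GDict
    G_prev: GDict
    Z_cur: GDict
    S_cur: SDict
    S_prev: SDict
    l1: float
    l2: float
    trace: list[dict] = field(default_factory=list)


@dataclass
class FitResult:
    factors: FactorSet
    trace: list[dict]
    stop_reason: str
    n_iter: int

    def trace_tsv(self, path: str | Path) -> None:
        """Write the convergence trace as a TSV table."""
        if not self.trace:
            return
        res_keys = sorted(self.trace[0]["residuals"])
        cols = [
            "iter", "F", "F_plain", "c_ref", "c_next", "F_reweighted", "branch",
            "l1", "l2", "theta", "armijo_gap", "ls_ok", "g_min",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols + [f"res_{i}_{j}" for (i, j) in res_keys]) + "\n")
            for row in self.trace:
                vals = [repr(row[c]) if not isinstance(row[c], str) else row[c] for c in cols]
                vals += [repr(row["residuals"][k]) for k in res_keys]
                fh.write("\t".join(vals) + "\n")


def _copy_g(G: GDict) -> GDict:
    return {k: v.copy() for k, v in G.items()}


def _copy_s(S: SDict) -> SDict:
    return {k: v.copy() for k, v in S.items()}


def init_factors(net: HeteroNetwork, hp: Hyperparameters) -> GDict:
    """Seeded nonnegative initialization of every basis matrix G_i.

    The default draws uniform entries scaled so the reconstructed blocks
    roughly match the magnitude of the incident data; the "svd" variant
    takes absolute leading singular vectors of the horizontal concatenation
    of a type's incident blocks.
    """
    rng = np.random.default_rng(hp.seed)
    G: GDict = {}
    for t in net.types:
        incident: list[np.ndarray] = []
        for (i, j), blk in net.relations.items():
            if i == t.name:
                incident.append(blk.matrix)
            elif j == t.name:
                incident.append(blk.matrix.T)
        if incident:
            mean_abs = float(np.mean([np.mean(np.abs(m)) for m in incident]))
        else:
            mean_abs = 1.0
        scale = math.sqrt(max(mean_abs, 1e-12) / t.rank)
        if hp.init == "svd" and incident:
            M = np.hstack(incident)
            U, s, _ = np.linalg.svd(M, full_matrices=False)
            r = min(t.rank, U.shape[1])
            Gi = np.abs(U[:, :r]) * np.sqrt(np.maximum(s[:r], 1e-12))
            if r < t.rank:  # rank-deficient concatenation: pad with random columns
                pad = rng.random((t.n, t.rank - r)) * scale
                Gi = np.hstack([Gi, pad])
        else:
            Gi = rng.random((t.n, t.rank)) * scale
        G[t.name] = Gi
    return G


def init_couplings(net: HeteroNetwork, G: GDict) -> SDict:
    """Closed-form least-squares couplings S_ij for fixed factors.

    S_ij = (G_i^T G_i)^+ G_i^T R_ij G_j (G_j^T G_j)^+, the minimizer of
    ||R_ij - G_i S_ij G_j^T||_F^2 (pseudoinverses cover rank deficiency).
    """
    S: SDict = {}
    for (i, j), blk in net.relations.items():
        Gi, Gj = G[i], G[j]
        Pi = np.linalg.pinv(Gi.T @ Gi)
        Pj = np.linalg.pinv(Gj.T @ Gj)
        S[(i, j)] = Pi @ (Gi.T @ blk.matrix @ Gj) @ Pj
    return S


def extrapolate(state: OptimizerState) -> GDict:
    """Momentum point Y from current/previous factor and proximal iterates."""
    if state.theta_cur == 0:
        raise ZeroDivisionError("theta_cur must be nonzero")
    a = state.theta_prev / state.theta_cur
    b = (state.theta_prev - 1.0) / state.theta_cur
    return {
        name: G + a * (state.Z_cur[name] - G) + b * (G - state.G_prev[name])
        for name, G in state.G_cur.items()
    }


def _flat(arrays: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays]) if arrays else np.zeros(0)


def curvature_stepsize(
    dx: np.ndarray, dgrad: np.ndarray, hp: Hyperparameters
) -> float:
    """Secant curvature estimate <dx, dgrad> / <dx, dx>, clipped to bounds.

    Degenerate secants (zero step, nonpositive or vanishing curvature, as
    in locally concave regions) fall back to the configured ``l_init``.
    """
    den = float(dx @ dx)
    num = float(dx @ dgrad)
    if den <= 1e-30 or num <= 1e-30:
        l = hp.l_init
    else:
        l = num / den
    return float(min(max(l, hp.l_min), hp.l_max))


def curvature_stepsizes(
    s_pair: tuple[np.ndarray, np.ndarray],
    g_pair: tuple[np.ndarray, np.ndarray],
    hp: Hyperparameters,
) -> tuple[float, float]:
    """(l1, l2) from the S-space and G-space secant pairs."""
    return (
        curvature_stepsize(s_pair[0], s_pair[1], hp),
        curvature_stepsize(g_pair[0], g_pair[1], hp),
    )


def _grow(l: float, hp: Hyperparameters) -> float:
    return min(max(hp.l_min, hp.eta * l), hp.l_max)


def _dc_subgrad(G: GDict, net: HeteroNetwork, hp: Hyperparameters) -> GDict:
    """W(G): a subgradient of the concave part lam_g * sum_i s^(k)(vec(G_i))."""
    W: GDict = {}
    for t in net.types:
        v = G[t.name].ravel(order="F")
        k = v.size if hp.k is None else min(hp.k, v.size)
        z = subgrad_sum_top_k(v, k)
        W[t.name] = hp.lam_g * z.reshape(G[t.name].shape, order="F")
    return W


def _sq_gap_s(S_new: SDict, S_old: SDict) -> float:
    return sum(float(np.sum((S_new[k] - S_old[k]) ** 2)) for k in S_new)


def _sq_gap_g(G_new: GDict, G_old: GDict) -> float:
    return sum(float(np.sum((G_new[k] - G_old[k]) ** 2)) for k in G_new)


def _line_search(
    net: HeteroNetwork,
    hp: Hyperparameters,
    S_cur: SDict,
    anchor: GDict,
    dS: SDict,
    dG: GDict,
    l1: float,
    l2: float,
    c: float,
) -> tuple[SDict, GDict, float, float, bool, float]:
    """Shared backtracking loop of LS-1 / LS-2.

    Forward step on S, prox step on the factors from ``anchor``; grows both
    step constants until the non-monotone Armijo test passes or the trial
    cap / upper bound is hit.  Returns the last candidate either way.
    """
    W = _dc_subgrad(anchor, net, hp)
    skeys = list(net.relations)
    S_new: SDict = {}
    G_new: GDict = {}
    gap = 0.0
    for _ in range(max(1, hp.ls_max)):
        S_new = {k: S_cur[k] - (1.0 / l1) * dS[k] for k in skeys}
        a = hp.lam_g / l2
        G_new = {
            name: prox_nonneg_linear(
                anchor[name] - (1.0 / l2) * dG[name] + (1.0 / l2) * W[name], a
            )
            for name in anchor
        }
        F_new = total_value(net, FactorSet(G=G_new, S=S_new), hp)
        gap = _sq_gap_s(S_new, S_cur) + _sq_gap_g(G_new, anchor)
        if F_new <= c - hp.delta * gap:
            return S_new, G_new, l1, l2, True, gap
        if l1 >= hp.l_max and l2 >= hp.l_max:
            break
        l1, l2 = _grow(l1, hp), _grow(l2, hp)
    return S_new, G_new, l1, l2, False, gap


def ls1_step(
    net: HeteroNetwork, state: OptimizerState, Y: GDict, hp: Hyperparameters
) -> tuple[SDict, GDict, float, float, bool, float]:
    """Extrapolated forward-backward step with secant step constants.

    Gradients are taken at (S_cur, Y); the factor prox is anchored at Y.
    Returns (S_new, Z_new, l1, l2, accepted, squared step gap).
    """
    gS_cur = grad_S(net, FactorSet(G=Y, S=state.S_cur), hp).dS
    gS_prev = grad_S(net, FactorSet(G=Y, S=state.S_prev), hp).dS
    gG_Y = grad_G(net, FactorSet(G=Y, S=state.S_cur), hp).dG
    gG_prev = grad_G(net, FactorSet(G=state.G_prev, S=state.S_cur), hp).dG

    skeys = list(net.relations)
    tnames = [t.name for t in net.types]
    l1, l2 = curvature_stepsizes(
        (
            _flat([state.S_cur[k] - state.S_prev[k] for k in skeys]),
            _flat([gS_cur[k] - gS_prev[k] for k in skeys]),
        ),
        (
            _flat([Y[n] - state.G_prev[n] for n in tnames]),
            _flat([gG_Y[n] - gG_prev[n] for n in tnames]),
        ),
        hp,
    )
    return _line_search(net, hp, state.S_cur, Y, gS_cur, gG_Y, l1, l2, state.c)


def ls2_step(
    net: HeteroNetwork, state: OptimizerState, hp: Hyperparameters
) -> tuple[SDict, GDict, float, float, bool, float]:
    """Anchored fallback step at the (feasible) current iterate G_cur."""
    fs_cur = FactorSet(G=state.G_cur, S=state.S_cur)
    gS_cur = grad_S(net, fs_cur, hp).dS
    gS_prev = grad_S(net, FactorSet(G=state.G_cur, S=state.S_prev), hp).dS
    gG_cur = grad_G(net, fs_cur, hp).dG
    gG_prev = grad_G(net, FactorSet(G=state.G_prev, S=state.S_cur), hp).dG

    skeys = list(net.relations)
    tnames = [t.name for t in net.types]
    l1, l2 = curvature_stepsizes(
        (
            _flat([state.S_cur[k] - state.S_prev[k] for k in skeys]),
            _flat([gS_cur[k] - gS_prev[k] for k in skeys]),
        ),
        (
            _flat([state.G_cur[n] - state.G_prev[n] for n in tnames]),
            _flat([gG_cur[n] - gG_prev[n] for n in tnames]),
        ),
        hp,
    )
    return _line_search(net, hp, state.S_cur, state.G_cur, gS_cur, gG_cur, l1, l2, state.c)


def update_theta(theta: float) -> float:
    """Momentum recurrence theta' = (sqrt(4 theta^2 + 1) + 1) / 2."""
    return (math.sqrt(4.0 * theta * theta + 1.0) + 1.0) / 2.0


def update_envelope(q: float, c: float, F_new: float, tau: float) -> tuple[float, float]:
    """Non-monotone envelope update: q' = tau q + 1, c' = (tau q c + F_new)/q'."""
    q_new = tau * q + 1.0
    c_new = (tau * q * c + F_new) / q_new
    return q_new, c_new


def _block_residuals(net: HeteroNetwork, fs: FactorSet) -> dict[tuple[str, str], float]:
    out = {}
    for (i, j), blk in net.relations.items():
        resid = blk.matrix - fs.G[i] @ fs.S[(i, j)] @ fs.G[j].T
        out[(i, j)] = float(np.sum(resid * resid))
    return out


def update_weights(
    net: HeteroNetwork, fs: FactorSet, eps_res: float = 1e-12
) -> dict[tuple[str, str], float]:
    """Per-block weights 1 / (2 * max(residual, eps)); well-fit sources
    are up-weighted, unreliable ones down-weighted."""
    return {
        key: 1.0 / (2.0 * max(r2, eps_res))
        for key, r2 in _block_residuals(net, fs).items()
    }


def project_topk(G: GDict, k: int) -> GDict:
    """Zero all but the k largest entries of each factor matrix (stable ties)."""
    out: GDict = {}
    for name, Gi in G.items():
        v = Gi.ravel(order="F")
        kk = min(k, v.size)
        keep = np.argsort(-v, kind="stable")[:kk]
        w = np.zeros_like(v)
        w[keep] = v[keep]
        out[name] = w.reshape(Gi.shape, order="F")
    return out


def fit(net: HeteroNetwork, hp: Hyperparameters) -> FitResult:
    """Run the full accelerated proximal DC loop on ``net``.

    The input network is not mutated; source weights evolve on an internal
    copy.  Deterministic for a fixed seed and configuration.
    """
    net = net.copy()
    G0 = init_factors(net, hp)
    S0 = init_couplings(net, G0)
    fs0 = FactorSet(G=G0, S=S0)

    if hp.reweight:
        for key, w in update_weights(net, fs0, hp.eps_res).items():
            net.relations[key].weight = w
    c1 = total_value(net, fs0, hp)

    state = OptimizerState(
        it=1,
        theta_prev=0.0,
        theta_cur=1.0,
        q=1.0,
        c=c1,
        G_cur=G0,
        G_prev=_copy_g(G0),
        Z_cur=_copy_g(G0),
        S_cur=S0,
        S_prev=_copy_s(S0),
        l1=hp.l_init,
        l2=hp.l_init,
    )

    stop_reason = "max_iter"
    for _ in range(hp.max_iter):
        F_anchor = total_value(net, FactorSet(G=state.G_cur, S=state.S_cur), hp)
        Y = extrapolate(state)
        S1, Z1, l1, l2, ok1, gap1 = ls1_step(net, state, Y, hp)
        if ok1:
            S_sel, G_new, branch, gap, ls_ok = S1, Z1, "LS1", gap1, True
        else:
            S2, V2, l1b, l2b, ok2, gap2 = ls2_step(net, state, hp)
            Fz = total_value(net, FactorSet(G=Z1, S=S1), hp)
            Fv = total_value(net, FactorSet(G=V2, S=S2), hp)
            if Fz <= Fv:
                # best-of-two: the failed extrapolated pair still wins
                S_sel, G_new, branch, gap, ls_ok = S1, Z1, "LS2-Z", gap2, ok2
            else:
                S_sel, G_new, branch, gap, ls_ok = S2, V2, "LS2-V", gap2, ok2
                l1, l2 = l1b, l2b

        fs_new = FactorSet(G=G_new, S=S_sel)
        F_acc = total_value(net, fs_new, hp)
        residuals = _block_residuals(net, fs_new)
        # objective with unit source weights: scale-free convergence measure
        weighted = sum(net.relations[k].weight * residuals[k] for k in residuals)
        F_plain = sum(residuals.values()) + (F_acc - weighted)

        # Algorithm step order: reweight sources, then refresh theta and the
        # envelope with the objective under the new weights, so the next
        # iteration's anchor value never exceeds the envelope.
        if hp.reweight:
            for key, r2 in residuals.items():
                net.relations[key].weight = 1.0 / (2.0 * max(r2, hp.eps_res))
        theta_next = update_theta(state.theta_cur)
        F_rew = total_value(net, fs_new, hp)
        q_new, c_new = update_envelope(state.q, state.c, F_rew, hp.tau)

        state.trace.append(
            {
                "iter": state.it,
                "F": F_acc,
                "F_plain": F_plain,
                "c_ref": state.c,
                "c_next": c_new,
                "F_reweighted": F_rew,
                "branch": branch,
                "l1": l1,
                "l2": l2,
                "theta": state.theta_cur,
                "armijo_gap": gap,
                "ls_ok": ls_ok,
                "g_min": min(float(g.min()) for g in G_new.values()),
                "residuals": residuals,
            }
        )

        state.G_prev, state.G_cur = state.G_cur, G_new
        state.Z_cur = _copy_g(G_new)
        state.S_prev, state.S_cur = state.S_cur, S_sel
        state.theta_prev, state.theta_cur = state.theta_cur, theta_next
        state.q, state.c = q_new, c_new
        state.l1, state.l2 = l1, l2
        state.it += 1

        if abs(F_acc - F_anchor) / max(1.0, abs(F_anchor)) < hp.tol:
            stop_reason = "tolerance"
            break

    G_final = state.G_cur
    if hp.project_k and hp.k is not None:
        G_final = project_topk(G_final, hp.k)
    return FitResult(
        factors=FactorSet(G=G_final, S=state.S_cur),
        trace=state.trace,
        stop_reason=stop_reason,
        n_iter=state.it - 1,
    )
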
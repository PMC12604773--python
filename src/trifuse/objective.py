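"""Fused objective: smooth data-fit + regularizer, DC sparsity penalty, gradients.

The smooth part is

    f(S, G) = sum_(i,j) w_ij ||R_ij - G_i S_ij G_j^T||_F^2
              + lam * sum_i sum_r tr(G_i^T Theta_i^(r) G_i)

and the nonsmooth penalty is

    g(G) = I_{G >= 0}(G) + lam_g * sum_i ( e^T G_i e - s^(k)(vec(G_i)) )

which vanishes exactly on feasible factor sets with at most k nonzero
entries per G_i.  Gradients of f are closed-form.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field

import numpy as np

from trifuse.network import HeteroNetwork
from trifuse.sparsity import sum_top_k


@dataclass
class Hyperparameters:
    """Solver and model hyperparameters.

    ``k`` is a per-matrix nonzero budget applied to each ``vec(G_i)``; when
    ``None`` the budget equals the matrix size (penalty identically zero on
    the feasible cone).
    """

    lam: float = 1e-4          # intra-relation regularization weight
    lam_g: float = 1e-3        # DC sparsity penalty weight
    k: int | None = None       # nonzero budget per factor matrix
    delta: float = 1e-4        # Armijo sufficient-decrease constant
    tau: float = 0.5           # non-monotone envelope decay
    eta: float = 2.0           # step-constant growth factor in backtracking
    l_min: float = 1e-8
    l_max: float = 1e8
    l_init: float = 1.0        # fallback step constant when secants degenerate
    ls_max: int = 50           # backtracking trial cap per line search
    max_iter: int = 100
    tol: float = 1e-6          # relative objective-change stopping tolerance
    seed: int = 0
    init: str = "svd"          # factor initialization: "svd" | "random"
    eps_res: float = 1e-12     # residual floor in the source-weight update
    reweight: bool = True      # refresh source weights from residuals each iteration
    project_k: bool = False    # hard top-k projection of each G_i after fitting

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.lam_g < 0:
            raise ValueError("lam_g must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if self.eta <= 1:
            raise ValueError("eta must be > 1")
        if not 0 < self.l_min < self.l_max:
            raise ValueError("need 0 < l_min < l_max")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1 when given")
        if self.init not in ("random", "svd"):
            raise ValueError(f"unknown init scheme {self.init!r}")


@dataclass
class FactorSet:
    """Per-type basis matrices ``G`` and per-relation couplings ``S``."""

    G: dict[str, np.ndarray]
    S: dict[tuple[str, str], np.ndarray]

    def copy(self) -> "FactorSet":
        return FactorSet(
            G={k: v.copy() for k, v in self.G.items()},
            S={k: v.copy() for k, v in self.S.items()},
        )


@dataclass
class GradientSet:
    dS: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    dG: dict[str, np.ndarray] = field(default_factory=dict)


def _check_shapes(net: HeteroNetwork, fs: FactorSet) -> None:
    for t in net.types:
        G = fs.G.get(t.name)
        if G is None or G.shape != (t.n, t.rank):
            raise ValueError(
                f"factor for type {t.name!r} has shape "
                f"{None if G is None else G.shape}, expected ({t.n}, {t.rank})"
            )
    if set(fs.S) != set(net.relations):
        raise ValueError("coupling keys do not match the network's relation blocks")


def smooth_value(net: HeteroNetwork, fs: FactorSet, hp: Hyperparameters) -> float:
    """Weighted data-fit plus intra-relation trace regularizer."""
    _check_shapes(net, fs)
    val = 0.0
    for (i, j), blk in net.relations.items():
        resid = blk.matrix - fs.G[i] @ fs.S[(i, j)] @ fs.G[j].T
        val += blk.weight * float(np.sum(resid * resid))
    if hp.lam > 0:
        for tname, cms in net.constraints.items():
            G = fs.G[tname]
            for cm in cms:
                val += hp.lam * float(np.sum(G * (cm.matrix @ G)))
    return val


def penalty_value(fs: FactorSet, hp: Hyperparameters) -> float:
    """DC sparsity penalty; ``inf`` sentinel outside the nonnegative cone."""
    total = 0.0
    for G in fs.G.values():
        if np.any(G < 0):
            return math.inf
        if hp.lam_g == 0:
            continue
        v = G.ravel(order="F")
        k = v.size if hp.k is None else min(hp.k, v.size)
        total += hp.lam_g * (float(v.sum()) - sum_top_k(v, k))
    return total


def total_value(net: HeteroNetwork, fs: FactorSet, hp: Hyperparameters) -> float:
    return smooth_value(net, fs, hp) + penalty_value(fs, hp)


def grad_S(net: HeteroNetwork, fs: FactorSet, hp: Hyperparameters) -> GradientSet:
    """Exact gradient of :func:`smooth_value` with respect to every S_ij."""
    _check_shapes(net, fs)
    out = GradientSet()
    for (i, j), blk in net.relations.items():
        resid = blk.matrix - fs.G[i] @ fs.S[(i, j)] @ fs.G[j].T
        out.dS[(i, j)] = -2.0 * blk.weight * (fs.G[i].T @ resid @ fs.G[j])
    return out


def grad_G(net: HeteroNetwork, fs: FactorSet, hp: Hyperparameters) -> GradientSet:
    """Exact gradient of :func:`smooth_value` with respect to every G_i."""
    _check_shapes(net, fs)
    out = GradientSet()
    for t in net.types:
        out.dG[t.name] = np.zeros_like(fs.G[t.name])
    for (i, j), blk in net.relations.items():
        S = fs.S[(i, j)]
        resid = blk.matrix - fs.G[i] @ S @ fs.G[j].T
        out.dG[i] += -2.0 * blk.weight * (resid @ fs.G[j] @ S.T)
        out.dG[j] += -2.0 * blk.weight * (resid.T @ fs.G[i] @ S)
    if hp.lam > 0:
        for tname, cms in net.constraints.items():
            for cm in cms:
                # Theta stored symmetrized, so d/dG tr(G^T Theta G) = 2 Theta G
                out.dG[tname] += 2.0 * hp.lam * (cm.matrix @ fs.G[tname])
    return out


def gradients(net: HeteroNetwork, fs: FactorSet, hp: Hyperparameters) -> GradientSet:
    """Both gradient families in one :class:`GradientSet`."""
    gs = grad_S(net, fs, hp)
    gs.dG = grad_G(net, fs, hp).dG
    return gs
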
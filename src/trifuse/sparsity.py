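"""Cardinality machinery: top-k sums, largest-k norm, subgradients, prox.

The element-level sparsity constraint ``||x||_0 <= k`` is expressed exactly
through the gap between the full sum (or l1 norm) and the sum of the k
largest (absolute) entries; these primitives and the proximal operator of
the remaining convex part are what the solver needs.
"""

from __future__ import annotations

import numpy as np


def _check_k(x: np.ndarray, k: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not 1 <= int(k) <= x.size:
        raise ValueError(f"k must be in [1, {x.size}], got {k}")
    return x


def _topk_indices(values: np.ndarray, k: int) -> np.ndarray:
    # stable selection: among ties the lower flat index wins
    order = np.argsort(-values, kind="stable")
    return order[:k]


def sum_top_k(x: np.ndarray, k: int) -> float:
    """Sum of the ``k`` largest entries of ``x`` (no absolute values)."""
    x = _check_k(x, k)
    return float(x[_topk_indices(x, k)].sum())


def largest_k_norm(x: np.ndarray, k: int) -> float:
    """Sum of the ``k`` largest absolute values of ``x``.

    Coincides with :func:`sum_top_k` on nonnegative vectors; equals the l1
    norm at ``k = len(x)``.
    """
    x = _check_k(x, k)
    return float(np.abs(x)[_topk_indices(np.abs(x), k)].sum())


def subgrad_sum_top_k(x: np.ndarray, k: int) -> np.ndarray:
    """A subgradient of the sum-of-top-k function at ``x``.

    Returns the 0/1 indicator of the k selected positions, which satisfies
    the subdifferential membership conditions sum(z) = k, 0 <= z <= 1 and
    <x, z> = sum_top_k(x, k).  Ties are broken toward lower indices.
    """
    x = _check_k(x, k)
    z = np.zeros_like(x)
    z[_topk_indices(x, k)] = 1.0
    return z


def subgrad_largest_k(x: np.ndarray, k: int) -> np.ndarray:
    """A subgradient of the largest-k norm at ``x``: sign(x) on the k
    largest-magnitude positions, zero elsewhere."""
    x = _check_k(x, k)
    z = np.zeros_like(x)
    idx = _topk_indices(np.abs(x), k)
    z[idx] = np.sign(x[idx])
    # sign(0) = 0 would break sum(|z|) = k; any value in [-1, 1] is valid there
    z[idx] = np.where(z[idx] == 0.0, 1.0, z[idx])
    return z


def prox_nonneg_linear(X: np.ndarray, a: float) -> np.ndarray:
    """Prox of ``Z -> a * sum(Z)`` restricted to the nonnegative orthant.

    Solves ``argmin_{Z >= 0} a * sum(Z) + 0.5 * ||Z - X||_F^2`` in closed
    form: elementwise ``max(X - a, 0)``.  ``a`` is the penalty weight
    divided by the proximal step constant and must be nonnegative.
    """
    if a < 0:
        raise ValueError(f"threshold must be nonnegative, got {a}")
    return np.maximum(np.asarray(X, dtype=float) - a, 0.0)
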
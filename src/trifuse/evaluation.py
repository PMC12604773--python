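"""Target-block scoring, cross-validation, and ranking of novel pairs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from trifuse.network import HeteroNetwork
from trifuse.objective import FactorSet, Hyperparameters
from trifuse.optimizer import fit


@dataclass
class ScoreMatrix:
    """Dense reconstruction of the target relation block."""

    target: tuple[str, str]
    scores: np.ndarray
    provenance: str = "full-fit"


@dataclass
class CVResult:
    fold_auc: list[float]
    fold_aupr: list[float]
    pooled_auc: float
    pooled_aupr: float
    fold_assignments: np.ndarray
    seed: int
    split: str = "row"

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))


def reconstruct_scores(fs: FactorSet, target: tuple[str, str]) -> ScoreMatrix:
    """Scores for the target block: G_i S_ij G_j^T."""
    if target not in fs.S:
        raise KeyError(f"target {target} not among fitted couplings")
    i, j = target
    return ScoreMatrix(target=target, scores=fs.G[i] @ fs.S[target] @ fs.G[j].T)


def kfold_row_split(R: np.ndarray, folds: int, seed: int = 0) -> np.ndarray:
    """Deal shuffled target rows into ``folds`` near-equal groups.

    Returns an integer fold id per row.  Raises if any fold ends up with no
    positive entry (it would be unevaluable).
    """
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    n_rows = R.shape[0]
    if folds > n_rows:
        raise ValueError(f"cannot split {n_rows} rows into {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_rows)
    assign = np.empty(n_rows, dtype=int)
    # first (n_rows % folds) folds get one extra row
    sizes = [n_rows // folds + (1 if f < n_rows % folds else 0) for f in range(folds)]
    start = 0
    for f, sz in enumerate(sizes):
        assign[order[start : start + sz]] = f
        start += sz
    for f in range(folds):
        if np.count_nonzero(R[assign == f]) == 0:
            raise ValueError(f"fold {f} contains no positive entries")
    return assign


def auc_aupr(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Rank-based AUC (midrank ties) and step-interpolated AUPR."""
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def rank_pairs(
    sm: ScoreMatrix,
    training_positives,
    top_n: int,
    row: int | None = None,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Top-``top_n`` candidate pairs by descending score.

    Training positives are excluded; ties break deterministically by
    (score desc, row index, col index).  ``row`` restricts the ranking to a
    single source entity.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    S = sm.scores
    mask = np.zeros(S.shape, dtype=bool)
    for (r, c) in training_positives:
        mask[r, c] = True
    rows, cols = np.nonzero(~mask)
    if row is not None:
        keep = rows == row
        rows, cols = rows[keep], cols[keep]
    vals = S[rows, cols]
    order = np.lexsort((cols, rows, -vals))[:top_n]
    rows, cols, vals = rows[order], cols[order], vals[order]
    return pd.DataFrame(
        {
            "row_id": [row_ids[r] if row_ids else str(r) for r in rows],
            "col_id": [col_ids[c] if col_ids else str(c) for c in cols],
            "score": vals,
            "rank": np.arange(1, len(vals) + 1),
        }
    )


def _entry_split(R: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Positive entries dealt into folds (flat indices), row-stratified."""
    rng = np.random.default_rng(seed)
    flat = np.flatnonzero(R)
    flat = rng.permutation(flat)
    return [flat[f::folds] for f in range(folds)]


def run_cv(
    net: HeteroNetwork,
    hp: Hyperparameters,
    folds: int = 5,
    seed: int = 0,
    split: str = "row",
) -> CVResult:
    """K-fold cross-validation on the target block.

    With the default row split, each fold's test rows have all their
    positives zeroed in the training copy (every other block untouched);
    metrics are computed over all entries of the test rows.  The entry
    split instead holds out individual positive entries.
    """
    if split not in ("row", "entry"):
        raise ValueError(f"unknown split mode {split!r}")
    R = net.target_block.matrix
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    fold_auc: list[float] = []
    fold_aupr: list[float] = []

    if split == "row":
        assign = kfold_row_split(R, folds, seed)
        fold_iter = [(np.flatnonzero(assign == f), None) for f in range(folds)]
    else:
        assign = np.full(R.shape[0], -1)
        fold_iter = [(None, idx) for idx in _entry_split(R, folds, seed)]

    for f, (rows, flat) in enumerate(fold_iter):
        train = net.copy()
        if rows is not None:
            train.relations[net.target].matrix[rows, :] = 0.0
        else:
            train.relations[net.target].matrix.ravel()[flat] = 0.0
        res = fit(train, hp)
        sm = reconstruct_scores(res.factors, net.target)
        if rows is not None:
            s = sm.scores[rows, :].ravel()
            y = (R[rows, :] != 0).ravel().astype(int)
        else:
            # evaluate held-out positives against all true-negative entries
            neg = np.flatnonzero(R == 0)
            idx = np.concatenate([flat, neg])
            s = sm.scores.ravel()[idx]
            y = np.concatenate([np.ones(flat.size, dtype=int), np.zeros(neg.size, dtype=int)])
        a, p = auc_aupr(s, y)
        fold_auc.append(a)
        fold_aupr.append(p)
        pooled_scores.append(s)
        pooled_labels.append(y)

    pa, pp = auc_aupr(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return CVResult(
        fold_auc=fold_auc,
        fold_aupr=fold_aupr,
        pooled_auc=pa,
        pooled_aupr=pp,
        fold_assignments=assign,
        seed=seed,
        split=split,
    )
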
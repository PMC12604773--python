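"""Planted-structure heterogeneous networks for end-to-end testing.

The generator mirrors a six-type molecular topology (RBPs, miRNAs, genes,
AS events, diseases, drugs) with seven inter-relation blocks and two
intra-relation constraint matrices.  Observed associations derive from
planted nonnegative low-rank factors, binarized at a density quantile with
optional label noise, so recovery of held-out target entries is a
well-posed benchmark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.io import mmwrite

from trifuse.network import (
    ConstraintMatrix,
    HeteroNetwork,
    ObjectType,
    RelationBlock,
)

TYPE_NAMES = ("rbp", "mirna", "gene", "as_event", "disease", "drug")
DEFAULT_SIZES = (40, 30, 50, 40, 20, 20)
#: inter-relation topology: (src, dst) type-name pairs
RELATION_PAIRS = (
    ("rbp", "gene"),
    ("rbp", "as_event"),
    ("gene", "as_event"),
    ("mirna", "gene"),
    ("mirna", "disease"),
    ("gene", "disease"),
    ("gene", "drug"),
)
CONSTRAINT_TYPES = ("gene", "drug")
TARGET = ("rbp", "as_event")


@dataclass
class PlantedNetwork:
    network: HeteroNetwork
    G_true: dict[str, np.ndarray]
    S_true: dict[tuple[str, str], np.ndarray]
    density: float
    noise: float
    seed: int
    binarized: bool


def _planted_factor(rng: np.random.Generator, n: int, rank: int) -> np.ndarray:
    """Sparse nonnegative factor with one dominant latent block per row."""
    G = np.zeros((n, rank))
    clusters = rng.integers(0, rank, size=n)
    G[np.arange(n), clusters] = rng.uniform(0.8, 1.2, size=n)
    background = rng.random((n, rank)) < 0.2
    G[background] += rng.uniform(0.0, 0.05, size=int(background.sum()))
    return G


def _planted_coupling(rng: np.random.Generator, ki: int, kj: int) -> np.ndarray:
    """Cluster coupling with one strong partner per latent dimension."""
    S = 0.25 * rng.random((ki, kj)) ** 2
    cols = rng.permutation(kj) if kj >= ki else rng.integers(0, kj, size=ki)
    S[np.arange(ki), cols[:ki]] += 1.0
    return S


def _similarity_laplacian(G: np.ndarray) -> np.ndarray:
    """Laplacian of the row-cosine-similarity graph (positive semidefinite)."""
    norms = np.linalg.norm(G, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = G / norms
    W = U @ U.T
    np.fill_diagonal(W, 0.0)
    return np.diag(W.sum(axis=1)) - W


def generate_planted_network(
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    ranks: int | tuple[int, ...] = 5,
    density: float = 0.1,
    noise: float = 0.0,
    seed: int = 0,
    binarize: bool = True,
) -> PlantedNetwork:
    """Draw a seeded planted network.

    ``density`` controls, per block, the fraction of entries binarized to 1
    (via the corresponding upper quantile of the planted reconstruction);
    ``noise`` flips that fraction of entries after binarization (or, in
    real-valued mode, adds Gaussian noise of matching scale).
    """
    if len(sizes) != len(TYPE_NAMES):
        raise ValueError(f"expected {len(TYPE_NAMES)} type sizes, got {len(sizes)}")
    if not 0 < density < 1:
        raise ValueError(f"density must be in (0, 1), got {density}")
    if not 0 <= noise < 1:
        raise ValueError(f"noise must be in [0, 1), got {noise}")
    if isinstance(ranks, int):
        ranks = (ranks,) * len(sizes)

    rng = np.random.default_rng(seed)
    types = [
        ObjectType(index=idx + 1, name=name, n=int(n), rank=int(r))
        for idx, (name, n, r) in enumerate(zip(TYPE_NAMES, sizes, ranks))
    ]
    G_true = {t.name: _planted_factor(rng, t.n, t.rank) for t in types}
    by_name = {t.name: t for t in types}

    S_true: dict[tuple[str, str], np.ndarray] = {}
    relations: dict[tuple[str, str], RelationBlock] = {}
    for (i, j) in RELATION_PAIRS:
        S = _planted_coupling(rng, by_name[i].rank, by_name[j].rank)
        S_true[(i, j)] = S
        P = G_true[i] @ S @ G_true[j].T
        if binarize:
            thr = np.quantile(P, 1.0 - density)
            R = (P > thr).astype(float)
            if R.sum() == 0:
                raise ValueError(
                    f"density {density} yields zero positives in block {i}->{j}"
                )
            # every entity keeps at least its strongest association observed,
            # so no row or column is entirely uninformative
            for r in np.flatnonzero(R.sum(axis=1) == 0):
                R[r, np.argmax(P[r])] = 1.0
            for col in np.flatnonzero(R.sum(axis=0) == 0):
                R[np.argmax(P[:, col]), col] = 1.0
            if noise > 0:
                n_flip = int(noise * R.size)
                flat = rng.choice(R.size, size=n_flip, replace=False)
                R.ravel()[flat] = 1.0 - R.ravel()[flat]
        else:
            R = P.copy()
            if noise > 0:
                R = R + rng.normal(0.0, noise * float(P.std()), size=P.shape)
        relations[(i, j)] = RelationBlock(src=i, dst=j, matrix=R, weight=1.0)

    constraints = {
        name: [
            ConstraintMatrix(type_name=name, r=0, matrix=_similarity_laplacian(G_true[name]))
        ]
        for name in CONSTRAINT_TYPES
    }

    net = HeteroNetwork(
        types=types, relations=relations, constraints=constraints, target=TARGET
    )
    return PlantedNetwork(
        network=net,
        G_true=G_true,
        S_true=S_true,
        density=density,
        noise=noise,
        seed=seed,
        binarized=binarize,
    )


def mask_holdout(
    pn: PlantedNetwork, fraction: float, seed: int = 0
) -> tuple[HeteroNetwork, list[tuple[int, int]]]:
    """Hold out all positives of a ``fraction`` share of target-block rows.

    Returns the training network (held-out entries zeroed) and the list of
    held-out positive ``(row, col)`` coordinates.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    net = pn.network
    R = net.target_block.matrix
    n_pos = int(np.count_nonzero(R))
    if n_pos < 1.0 / fraction:
        raise ValueError("target block has too few positives for this fraction")
    rng = np.random.default_rng(seed)
    n_rows = R.shape[0]
    n_hold = max(1, round(fraction * n_rows))
    held_rows = np.sort(rng.permutation(n_rows)[:n_hold])

    train = net.copy()
    held: list[tuple[int, int]] = []
    for r in held_rows:
        for col in np.flatnonzero(R[r]):
            held.append((int(r), int(col)))
        train.relations[net.target].matrix[r, :] = 0.0
    return train, held


def write_network(pn: PlantedNetwork, outdir: str | Path) -> Path:
    """Serialize a planted network in the loader's TSV/MTX + YAML layout.

    Round-trips exactly through :func:`trifuse.network.load_network`.
    Returns the path of the written config file.
    """
    outdir = Path(outdir)
    (outdir / "ids").mkdir(parents=True, exist_ok=True)
    (outdir / "relations").mkdir(exist_ok=True)
    (outdir / "constraints").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    net = pn.network
    cfg: dict = {"types": [], "relations": [], "constraints": [], "target": None}
    for t in net.types:
        ids_path = outdir / "ids" / f"{t.name}.txt"
        ids_path.write_text("\n".join(t.ids) + "\n")
        cfg["types"].append(
            {"name": t.name, "n": t.n, "rank": t.rank, "ids_path": f"ids/{t.name}.txt"}
        )
    for (i, j), blk in net.relations.items():
        rel_path = outdir / "relations" / f"{i}__{j}.tsv"
        src_ids = net.type_by_name(i).ids
        dst_ids = net.type_by_name(j).ids
        with open(rel_path, "w") as fh:
            for r, col in zip(*np.nonzero(blk.matrix)):
                v = blk.matrix[r, col]
                if pn.binarized and v == 1.0:
                    fh.write(f"{src_ids[r]}\t{dst_ids[col]}\n")
                else:
                    fh.write(f"{src_ids[r]}\t{dst_ids[col]}\t{float(v)!r}\n")
        cfg["relations"].append(
            {"src": i, "dst": j, "path": f"relations/{i}__{j}.tsv", "weight": blk.weight}
        )
    for tname, cms in net.constraints.items():
        for cm in cms:
            cpath = outdir / "constraints" / f"{tname}_{cm.r}.mtx"
            mmwrite(str(cpath), cm.matrix, precision=17)
            cfg["constraints"].append({"type": tname, "path": f"constraints/{tname}_{cm.r}.mtx"})
    cfg["target"] = {"src": net.target[0], "dst": net.target[1]}

    for name, G in pn.G_true.items():
        np.savetxt(outdir / "truth" / f"G_{name}.tsv", G, delimiter="\t", fmt="%.17g")
    for (i, j), S in pn.S_true.items():
        np.savetxt(outdir / "truth" / f"S_{i}__{j}.tsv", S, delimiter="\t", fmt="%.17g")

    with open(outdir / "meta.json", "w") as fh:
        json.dump(
            {
                "density": pn.density,
                "noise": pn.noise,
                "seed": pn.seed,
                "binarized": pn.binarized,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    cfg_path = outdir / "network.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
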
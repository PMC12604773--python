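import numpy as np
import pytest

from trifuse.network import (
    ConstraintMatrix,
    HeteroNetwork,
    ObjectType,
    RelationBlock,
)
from trifuse.objective import FactorSet, Hyperparameters


def make_network(
    sizes: dict[str, tuple[int, int]],
    relation_pairs: list[tuple[str, str]],
    rng: np.random.Generator,
    n_constraints: dict[str, int] | None = None,
    target: tuple[str, str] | None = None,
    weights: dict[tuple[str, str], float] | None = None,
) -> HeteroNetwork:
    """Random dense network for unit tests.

    ``sizes`` maps type name -> (n, rank); constraint matrices are random
    symmetric PSD.
    """
    types = [
        ObjectType(index=i + 1, name=name, n=n, rank=r)
        for i, (name, (n, r)) in enumerate(sizes.items())
    ]
    by_name = {t.name: t for t in types}
    relations = {}
    for (i, j) in relation_pairs:
        R = rng.random((by_name[i].n, by_name[j].n))
        w = (weights or {}).get((i, j), 1.0)
        relations[(i, j)] = RelationBlock(src=i, dst=j, matrix=R, weight=w)
    constraints = {}
    for name, count in (n_constraints or {}).items():
        lst = []
        for r in range(count):
            n = by_name[name].n
            A = rng.random((n, n))
            lst.append(ConstraintMatrix(type_name=name, r=r, matrix=A @ A.T))
        constraints[name] = lst
    return HeteroNetwork(
        types=types,
        relations=relations,
        constraints=constraints,
        target=target or relation_pairs[0],
    )


def random_factors(net: HeteroNetwork, rng: np.random.Generator, signed: bool = False) -> FactorSet:
    G = {}
    for t in net.types:
        G[t.name] = rng.standard_normal((t.n, t.rank)) if signed else rng.random((t.n, t.rank))
    S = {key: rng.standard_normal((net.type_by_name(i).rank, net.type_by_name(j).rank))
         for key, (i, j) in zip(net.relations, net.relations)}
    return FactorSet(G=G, S=S)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_type_net(rng):
    return make_network({"A": (5, 2), "B": (4, 2)}, [("A", "B")], rng)


@pytest.fixture
def hp():
    return Hyperparameters()
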
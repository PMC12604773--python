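"""Multi-type relational network model and loaders.

A :class:`HeteroNetwork` bundles the typed entities, the inter-relation
blocks ``R_ij`` (with positive source weights), and optional symmetric
intra-relation constraint matrices per type.  One ordered pair of types is
designated as the prediction target.

Relation files are either 2/3-column TSV edge lists keyed by string entity
IDs, or Matrix Market coordinate/array files indexed positionally.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.io import mmread


class NetworkError(ValueError):
    """Raised for malformed network configurations or relation files."""


@dataclass
class ObjectType:
    """One entity type: ``n`` entities embedded with latent rank ``rank``."""

    index: int
    name: str
    n: int
    rank: int
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise NetworkError(f"type {self.name!r}: n must be >= 1, got {self.n}")
        if not 1 <= self.rank <= self.n:
            raise NetworkError(
                f"type {self.name!r}: rank must be in [1, {self.n}], got {self.rank}"
            )
        if not self.ids:
            self.ids = [f"{self.name}{t}" for t in range(self.n)]
        if len(self.ids) != self.n:
            raise NetworkError(
                f"type {self.name!r}: {len(self.ids)} ids declared for n={self.n}"
            )


@dataclass
class RelationBlock:
    """Observed inter-relation matrix between two entity types.

    ``matrix`` is an ``n_src x n_dst`` dense array (possibly asymmetric in
    role: rows are source entities, columns destination entities) and
    ``weight`` is the positive source weight applied to this block's
    residual in the fused objective.
    """

    src: str
    dst: str
    matrix: np.ndarray
    weight: float = 1.0

    @property
    def key(self) -> tuple[str, str]:
        return (self.src, self.dst)


@dataclass
class ConstraintMatrix:
    """Symmetric intra-relation matrix for one type (index ``r`` allows several)."""

    type_name: str
    r: int
    matrix: np.ndarray


@dataclass
class HeteroNetwork:
    types: list[ObjectType]
    relations: dict[tuple[str, str], RelationBlock]
    constraints: dict[str, list[ConstraintMatrix]]
    target: tuple[str, str]
    warnings: list[str] = field(default_factory=list)

    def type_by_name(self, name: str) -> ObjectType:
        for t in self.types:
            if t.name == name:
                return t
        raise NetworkError(f"unknown type {name!r}")

    @property
    def target_block(self) -> RelationBlock:
        return self.relations[self.target]

    def id_index(self, type_name: str) -> dict[str, int]:
        """String entity ID -> 0-based internal row/column index."""
        return {s: t for t, s in enumerate(self.type_by_name(type_name).ids)}

    def copy(self) -> "HeteroNetwork":
        return _copy.deepcopy(self)


def _read_edge_list(
    path: Path, row_ids: dict[str, int], col_ids: dict[str, int], shape: tuple[int, int]
) -> tuple[np.ndarray, list[str]]:
    """Parse a TSV edge list into a dense matrix, collapsing duplicates."""
    mat = np.zeros(shape)
    seen: set[tuple[int, int]] = set()
    warnings: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise NetworkError(f"{path}:{lineno}: expected 2 or 3 columns")
            src, dst = parts[0], parts[1]
            if src not in row_ids:
                raise NetworkError(f"{path}:{lineno}: unknown source entity {src!r}")
            if dst not in col_ids:
                raise NetworkError(f"{path}:{lineno}: unknown target entity {dst!r}")
            w = float(parts[2]) if len(parts) == 3 else 1.0
            i, j = row_ids[src], col_ids[dst]
            if (i, j) in seen:
                warnings.append(f"{path}:{lineno}: duplicate edge {src} -> {dst} collapsed")
            seen.add((i, j))
            mat[i, j] = w
    return mat, warnings


def _read_matrix(path: Path, shape: tuple[int, int]) -> np.ndarray:
    mat = mmread(str(path))
    if hasattr(mat, "toarray"):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if mat.shape != shape:
        raise NetworkError(f"{path}: shape {mat.shape} does not match declared {shape}")
    return mat


def _load_block(
    path: Path, row_ids: dict[str, int], col_ids: dict[str, int], shape: tuple[int, int]
) -> tuple[np.ndarray, list[str]]:
    if path.suffix == ".mtx":
        return _read_matrix(path, shape), []
    return _read_edge_list(path, row_ids, col_ids, shape)


def load_network(config_path: str | Path) -> HeteroNetwork:
    """Load and validate a :class:`HeteroNetwork` from a YAML config.

    The config declares ``types`` (name, n, rank, optional ids/ids_path),
    ``relations`` (src, dst, path, optional weight), optional ``constraints``
    (type, path) and the ``target`` pair.  Relative paths are resolved
    against the config file's directory.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise NetworkError(f"config file not found: {config_path}")
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    if not isinstance(cfg, dict) or "types" not in cfg or "relations" not in cfg:
        raise NetworkError(f"{config_path}: config must declare 'types' and 'relations'")

    types: list[ObjectType] = []
    for idx, spec in enumerate(cfg["types"], start=1):
        ids = spec.get("ids")
        if ids is None and "ids_path" in spec:
            ids = (base / spec["ids_path"]).read_text().split()
        types.append(
            ObjectType(
                index=idx,
                name=str(spec["name"]),
                n=int(spec["n"]),
                rank=int(spec["rank"]),
                ids=[str(s) for s in ids] if ids else [],
            )
        )
    names = [t.name for t in types]
    if len(set(names)) != len(names):
        raise NetworkError("duplicate type names in config")
    by_name = {t.name: t for t in types}
    id_maps = {t.name: {s: i for i, s in enumerate(t.ids)} for t in types}

    relations: dict[tuple[str, str], RelationBlock] = {}
    warnings: list[str] = []
    for spec in cfg["relations"]:
        src, dst = str(spec["src"]), str(spec["dst"])
        for nm in (src, dst):
            if nm not in by_name:
                raise NetworkError(f"relation {src}->{dst} references undeclared type {nm!r}")
        if (src, dst) in relations:
            raise NetworkError(f"relation {src}->{dst} declared twice")
        shape = (by_name[src].n, by_name[dst].n)
        path = base / spec["path"]
        if not path.exists():
            raise NetworkError(f"relation file not found: {path}")
        mat, warns = _load_block(path, id_maps[src], id_maps[dst], shape)
        warnings.extend(warns)
        weight = float(spec.get("weight", 1.0))
        if weight <= 0:
            raise NetworkError(f"relation {src}->{dst}: weight must be > 0, got {weight}")
        relations[(src, dst)] = RelationBlock(src=src, dst=dst, matrix=mat, weight=weight)

    constraints: dict[str, list[ConstraintMatrix]] = {}
    for spec in cfg.get("constraints", []) or []:
        tname = str(spec["type"])
        if tname not in by_name:
            raise NetworkError(f"constraint references undeclared type {tname!r}")
        n = by_name[tname].n
        path = base / spec["path"]
        if not path.exists():
            raise NetworkError(f"constraint file not found: {path}")
        mat, warns = _load_block(path, id_maps[tname], id_maps[tname], (n, n))
        warnings.extend(warns)
        # only the symmetric part enters tr(G^T Theta G); store it up front
        mat = 0.5 * (mat + mat.T)
        lst = constraints.setdefault(tname, [])
        lst.append(ConstraintMatrix(type_name=tname, r=len(lst), matrix=mat))

    tgt = cfg.get("target")
    if not tgt:
        raise NetworkError("config must declare a 'target' pair")
    target = (str(tgt["src"]), str(tgt["dst"]))
    if target not in relations:
        raise NetworkError(f"target pair {target} does not name a declared relation")

    net = HeteroNetwork(
        types=types,
        relations=relations,
        constraints=constraints,
        target=target,
        warnings=warnings,
    )
    diagnostics = [d for d in validate_network(net) if not d.startswith("warning:")]
    if diagnostics:
        raise NetworkError("; ".join(diagnostics))
    return net


def validate_network(net: HeteroNetwork) -> list[str]:
    """Return human-readable invariant violations (empty list when valid).

    Load-time duplicate-edge collapses are reported as ``warning:`` entries.
    """
    diags: list[str] = []
    declared = {t.name for t in net.types}
    for idx, t in enumerate(net.types, start=1):
        if t.index != idx:
            diags.append(f"type {t.name!r}: index {t.index} not contiguous (expected {idx})")
        if t.n < 1:
            diags.append(f"type {t.name!r}: n must be >= 1")
        if not 1 <= t.rank <= t.n:
            diags.append(f"type {t.name!r}: rank {t.rank} outside [1, {t.n}]")
    for key, blk in net.relations.items():
        if blk.src not in declared or blk.dst not in declared:
            diags.append(f"relation {key}: references undeclared type")
            continue
        shape = (net.type_by_name(blk.src).n, net.type_by_name(blk.dst).n)
        if blk.matrix.shape != shape:
            diags.append(f"relation {key}: matrix shape {blk.matrix.shape} != declared {shape}")
        if blk.weight <= 0:
            diags.append(f"relation {key}: weight must be positive, got {blk.weight}")
    for tname, lst in net.constraints.items():
        if tname not in declared:
            diags.append(f"constraint on undeclared type {tname!r}")
            continue
        n = net.type_by_name(tname).n
        for cm in lst:
            if cm.matrix.shape != (n, n):
                diags.append(
                    f"constraint for type {tname!r}: shape {cm.matrix.shape} != ({n}, {n})"
                )
    if net.target not in net.relations:
        diags.append(f"target pair {net.target} not among declared relations")
    diags.extend(f"warning: {w}" for w in net.warnings)
    return diags
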
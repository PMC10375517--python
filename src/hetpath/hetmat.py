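"""Disk-backed hetnet store (the HetMat directory convention).

A HetMat directory holds one hetnet::

    <dir>/
      metagraph.json            # schema
      nodes/<Metanode>.tsv      # one table per metanode, row order = position
      edges/<abbrev>.npy        # dense adjacency, or
      edges/<abbrev>.sparse.npz # sparse adjacency
      path-counts/              # cached DWPC / path-count matrices
      permutations/<i>.hetmat/  # permuted copies, each a full HetMat

Adjacency matrices bind to node-table row order and are loaded lazily, so
touching one metaedge never reads the others.  Matrices with density >= 0.7
are stored dense (``.npy``), sparser ones as compressed sparse (``.sparse.npz``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sparse

from .metagraph import Metaedge, Metagraph, Metanode, load_metagraph

DENSE_THRESHOLD = 0.7
NODE_TABLE_COMPRESSIONS = ("", ".gz", ".bz2", ".zip", ".xz")


class FormatError(ValueError):
    """Raised when a HetMat directory is structurally invalid."""


class ConsistencyError(ValueError):
    """Raised when matrices and node tables disagree."""


@dataclass(frozen=True)
class DegreeVector:
    """Per-node edge counts for one side of a metaedge."""

    metaedge: Metaedge
    side: str  # "source" or "target"
    values: np.ndarray

    def __post_init__(self):
        if self.side not in ("source", "target"):
            raise ValueError(f"side must be source|target, got {self.side!r}")


def _density(matrix) -> float:
    size = matrix.shape[0] * matrix.shape[1]
    if size == 0:
        return 0.0
    nnz = matrix.nnz if sparse.issparse(matrix) else np.count_nonzero(matrix)
    return nnz / size


def save_matrix(matrix, path_stub: Path) -> Path:
    """Persist a matrix using the density rule; returns the written path."""
    path_stub.parent.mkdir(parents=True, exist_ok=True)
    if _density(matrix) >= DENSE_THRESHOLD:
        path = path_stub.with_name(path_stub.name + ".npy")
        arr = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
        np.save(path, arr)
    else:
        path = path_stub.with_name(path_stub.name + ".sparse.npz")
        mat = matrix if sparse.issparse(matrix) else sparse.csr_matrix(matrix)
        sparse.save_npz(path, mat.tocsr())
    return path


def find_matrix_file(path_stub: Path) -> Path | None:
    for suffix in (".sparse.npz", ".npy"):
        candidate = path_stub.with_name(path_stub.name + suffix)
        if candidate.exists():
            return candidate
    return None


def load_matrix(path: Path):
    if path.name.endswith(".sparse.npz"):
        return sparse.load_npz(path)
    return np.load(path)


class HetMat:
    """A hetnet: metagraph + node orderings + one adjacency per metaedge.

    May be purely in-memory (``directory is None``) or disk-backed, in which
    case adjacency matrices load lazily on first access.
    """

    def __init__(
        self,
        metagraph: Metagraph,
        node_orderings: Mapping[str, list[str]],
        adjacency: Mapping[tuple, object] | None = None,
        directory: Path | None = None,
    ):
        self.metagraph = metagraph
        missing = set(metagraph.metanodes) - set(node_orderings)
        if missing:
            raise ConsistencyError(f"missing node orderings for metanodes {sorted(missing)}")
        self.node_orderings = {ab: list(ids) for ab, ids in node_orderings.items()}
        self._adjacency: dict[tuple, object] = {}
        if adjacency:
            for key, matrix in adjacency.items():
                self._set_adjacency(key, matrix)
        self.directory = Path(directory) if directory is not None else None

    # -- resolution ------------------------------------------------------

    def _resolve_metaedge(self, metaedge) -> Metaedge:
        if isinstance(metaedge, Metaedge):
            return metaedge
        if isinstance(metaedge, tuple):
            return self.metagraph.metaedges[metaedge]
        if isinstance(metaedge, str):
            for me in self.metagraph.metaedges.values():
                if me.abbreviation == metaedge:
                    return me
            raise KeyError(f"unknown metaedge {metaedge!r}")
        raise TypeError(f"cannot resolve metaedge from {metaedge!r}")

    def _resolve_metanode(self, metanode) -> Metanode:
        if isinstance(metanode, Metanode):
            return metanode
        return self.metagraph.metanode(metanode)

    # -- nodes -----------------------------------------------------------

    def nodes(self, metanode) -> list[str]:
        return self.node_orderings[self._resolve_metanode(metanode).abbreviation]

    def node_count(self, metanode) -> int:
        return len(self.nodes(metanode))

    def node_index(self, metanode) -> dict[str, int]:
        return {node: i for i, node in enumerate(self.nodes(metanode))}

    # -- adjacency -------------------------------------------------------

    def _validate_matrix(self, metaedge: Metaedge, matrix) -> None:
        n_rows = len(self.node_orderings[metaedge.source.abbreviation])
        n_cols = len(self.node_orderings[metaedge.target.abbreviation])
        if matrix.shape != (n_rows, n_cols):
            raise ConsistencyError(
                f"adjacency for {metaedge.abbreviation} has shape {matrix.shape}, "
                f"expected {(n_rows, n_cols)}"
            )
        if metaedge.is_self_loop:
            diagonal = matrix.diagonal()
            diag_nnz = diagonal.sum() if not sparse.issparse(matrix) else diagonal.sum()
            if diag_nnz:
                raise ConsistencyError(
                    f"self-edges are not allowed ({metaedge.abbreviation})"
                )
            if not metaedge.directed:
                difference = matrix - matrix.T
                asym = abs(difference).sum()
                if asym:
                    raise ConsistencyError(
                        f"undirected self metaedge {metaedge.abbreviation} must be symmetric"
                    )

    def _set_adjacency(self, key, matrix) -> None:
        metaedge = self._resolve_metaedge(key)
        if sparse.issparse(matrix):
            matrix = matrix.tocsr()
        else:
            matrix = np.asarray(matrix)
        self._validate_matrix(metaedge, matrix)
        self._adjacency[metaedge.key] = matrix

    def adjacency(self, metaedge, invert: bool = False):
        """The 0/1 adjacency matrix of a metaedge; ``invert`` transposes it
        (rows then follow the target metanode ordering)."""
        metaedge = self._resolve_metaedge(metaedge)
        matrix = self._adjacency.get(metaedge.key)
        if matrix is None:
            matrix = self._load_adjacency(metaedge)
            self._adjacency[metaedge.key] = matrix
        return matrix.T if invert else matrix

    def _load_adjacency(self, metaedge: Metaedge):
        if self.directory is None:
            raise KeyError(f"no adjacency stored for {metaedge.abbreviation}")
        stub = self.directory / "edges" / metaedge.abbreviation
        path = find_matrix_file(stub)
        if path is None:
            raise FileNotFoundError(
                f"missing adjacency matrix file for {metaedge.abbreviation}: "
                f"expected {stub}.npy or {stub}.sparse.npz"
            )
        matrix = load_matrix(path)
        self._validate_matrix(metaedge, matrix)
        return matrix

    def degrees(self, metaedge) -> tuple[DegreeVector, DegreeVector]:
        """Row and column sums of the adjacency matrix, as integers."""
        metaedge = self._resolve_metaedge(metaedge)
        matrix = self.adjacency(metaedge)
        row = np.asarray(matrix.sum(axis=1)).ravel().astype(np.int64)
        col = np.asarray(matrix.sum(axis=0)).ravel().astype(np.int64)
        return (
            DegreeVector(metaedge, "source", row),
            DegreeVector(metaedge, "target", col),
        )

    def edge_count(self, metaedge) -> int:
        metaedge = self._resolve_metaedge(metaedge)
        matrix = self.adjacency(metaedge)
        total = int(matrix.sum())
        if metaedge.is_self_loop and not metaedge.directed:
            return total // 2
        return total

    # -- generated-data layout ------------------------------------------

    @property
    def permutations_directory(self) -> Path:
        if self.directory is None:
            raise FormatError("in-memory HetMat has no permutations directory")
        return self.directory / "permutations"

    def path_counts_directory(self, w: float) -> Path:
        if self.directory is None:
            raise FormatError("in-memory HetMat has no path-counts directory")
        return self.directory / "path-counts" / f"dwpc-{w}"

    # -- IO --------------------------------------------------------------

    def write(self, directory) -> "HetMat":
        """Write this store as a HetMat directory and return the disk-backed
        copy.  Write-then-read round-trips exactly."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "metagraph.json").write_text(
            self.metagraph.to_json() + "\n", encoding="utf-8"
        )
        nodes_dir = directory / "nodes"
        nodes_dir.mkdir(exist_ok=True)
        for ab, ids in sorted(self.node_orderings.items()):
            metanode = self.metagraph.metanodes[ab]
            table = pd.DataFrame({"identifier": ids, "name": ids})
            table.to_csv(nodes_dir / f"{metanode.identifier}.tsv", sep="\t", index=False)
        for me in self.metagraph.metaedges.values():
            matrix = self._adjacency.get(me.key)
            if matrix is None and self.directory is not None:
                try:
                    matrix = self.adjacency(me)
                except FileNotFoundError:
                    matrix = None
            if matrix is not None:
                save_matrix(matrix, directory / "edges" / me.abbreviation)
        return HetMat.from_directory(directory)

    @classmethod
    def from_directory(cls, directory) -> "HetMat":
        directory = Path(directory)
        schema_path = directory / "metagraph.json"
        if not schema_path.exists():
            raise FormatError(f"not a HetMat directory: missing {schema_path}")
        metagraph = load_metagraph(schema_path)
        node_orderings = {}
        for metanode in metagraph.metanodes.values():
            stub = directory / "nodes" / metanode.identifier
            table_path = None
            for compression in NODE_TABLE_COMPRESSIONS:
                candidate = stub.with_name(f"{metanode.identifier}.tsv{compression}")
                if candidate.exists():
                    table_path = candidate
                    break
            if table_path is None:
                raise FormatError(f"missing node table for metanode {metanode.identifier}")
            table = pd.read_csv(table_path, sep="\t", dtype=str)
            if "identifier" not in table.columns:
                # positional contract: first column is the identifier
                table = table.rename(columns={table.columns[0]: "identifier"})
            node_orderings[metanode.abbreviation] = table["identifier"].tolist()
        return cls(metagraph, node_orderings, directory=directory)

    # -- construction helpers -------------------------------------------

    @classmethod
    def from_edge_lists(
        cls,
        metagraph: Metagraph,
        node_orderings: Mapping[str, list[str]],
        edges: Mapping[str, Iterable[tuple[str, str]]],
    ) -> "HetMat":
        """Build an in-memory store from {metaedge abbreviation: [(src_id,
        tgt_id), ...]}.  Undirected self metaedges are symmetrized."""
        store = cls(metagraph, node_orderings)
        indexes = {
            ab: {node: i for i, node in enumerate(ids)}
            for ab, ids in store.node_orderings.items()
        }
        by_abbrev = {me.abbreviation: me for me in metagraph.metaedges.values()}
        for abbrev, pairs in edges.items():
            me = by_abbrev[abbrev]
            src_index = indexes[me.source.abbreviation]
            tgt_index = indexes[me.target.abbreviation]
            matrix = np.zeros((len(src_index), len(tgt_index)), dtype=np.uint8)
            for src_id, tgt_id in pairs:
                i, j = src_index[src_id], tgt_index[tgt_id]
                matrix[i, j] = 1
                if me.is_self_loop and not me.directed:
                    matrix[j, i] = 1
            store._set_adjacency(me, matrix)
        return store

    def replace_adjacency(self, adjacency: Mapping[tuple, object]) -> "HetMat":
        """A new in-memory store with the same schema/nodes, new matrices."""
        return HetMat(self.metagraph, self.node_orderings, adjacency)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HetMat):
            return NotImplemented
        if self.metagraph != other.metagraph:
            return False
        if self.node_orderings != other.node_orderings:
            return False
        for me in self.metagraph.metaedges.values():
            try:
                a = self.adjacency(me)
            except (KeyError, FileNotFoundError):
                a = None
            try:
                b = other.adjacency(me)
            except (KeyError, FileNotFoundError):
                b = None
            if (a is None) != (b is None):
                return False
            if a is not None:
                a = a.toarray() if sparse.issparse(a) else a
                b = b.toarray() if sparse.issparse(b) else b
                if not np.array_equal(a, b):
                    return False
        return True

    def __repr__(self) -> str:
        nodes = sum(len(ids) for ids in self.node_orderings.values())
        return f"HetMat({self.metagraph!r}, {nodes} nodes, directory={self.directory})"
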
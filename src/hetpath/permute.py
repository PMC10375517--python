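"""Degree-preserving hetnet permutation via XSwap.

XSwap repeatedly picks two edges (a, b) and (c, d) and proposes the swap
(a, d), (c, b), rejecting proposals that would create a self-edge or a
duplicate edge.  Degrees are preserved exactly while edge identity is
destroyed, which is precisely the null needed for DWPC significance: the
permuted network retains degree effects but no biological signal.  A hetnet
is permuted by applying XSwap independently to each metaedge.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .hetmat import HetMat
from .metagraph import Metaedge

DEFAULT_MULTIPLIER = 10.0
DEFAULT_PERMUTATIONS = 200


@dataclass(frozen=True)
class PermutationReport:
    metaedge: Metaedge | None
    attempts: int
    completed_swaps: int
    fraction_edges_changed: float
    seed: int

    def __post_init__(self):
        if self.completed_swaps > self.attempts:
            raise ValueError("completed_swaps cannot exceed attempts")


def xswap(
    edges: list[tuple],
    directed: bool,
    multiplier: float = DEFAULT_MULTIPLIER,
    seed: int = 0,
    metaedge: Metaedge | None = None,
) -> tuple[list[tuple], PermutationReport]:
    """Randomize an edge list while preserving every node's degree.

    For undirected edges the endpoint roles of each drawn edge are flipped
    uniformly at random before proposing the swap, so both pairings
    {(a, d), (c, b)} and {(a, c), (b, d)} are reachable.  Rejected proposals
    count as attempts; reproducible for a given seed.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    _validate_edges(edges, directed)
    rng = np.random.default_rng(seed)
    norm = (lambda e: tuple(sorted(e))) if not directed else (lambda e: tuple(e))
    working = [norm(e) for e in edges]
    present = set(working)
    n_edges = len(working)
    attempts = int(round(multiplier * n_edges))
    completed = 0
    if n_edges >= 2:
        pair_draws = rng.integers(0, n_edges, size=(attempts, 2))
        flip_draws = rng.integers(0, 2, size=(attempts, 2))
        for (i, j), (flip_i, flip_j) in zip(pair_draws, flip_draws):
            if i == j:
                continue
            a, b = working[i]
            c, d = working[j]
            if not directed:
                if flip_i:
                    a, b = b, a
                if flip_j:
                    c, d = d, c
            new_one, new_two = norm((a, d)), norm((c, b))
            if a == d or c == b:
                continue
            if new_one in present or new_two in present or new_one == new_two:
                continue
            present.discard(working[i])
            present.discard(working[j])
            present.add(new_one)
            present.add(new_two)
            working[i] = new_one
            working[j] = new_two
            completed += 1
    original = {norm(e) for e in edges}
    changed = 1.0 - (len(original & present) / n_edges if n_edges else 1.0)
    report = PermutationReport(
        metaedge=metaedge,
        attempts=attempts if n_edges >= 2 else 0,
        completed_swaps=completed,
        fraction_edges_changed=changed,
        seed=seed,
    )
    return working, report


def _validate_edges(edges, directed: bool) -> None:
    norm = (lambda e: tuple(sorted(e))) if not directed else (lambda e: tuple(e))
    seen = set()
    for edge in edges:
        source, target = edge
        if source == target:
            raise ValueError(f"self-edge not allowed: {edge!r}")
        key = norm(edge)
        if key in seen:
            raise ValueError(f"duplicate edge not allowed: {edge!r}")
        seen.add(key)


def metaedge_seed(seed: int, metaedge: Metaedge) -> int:
    """Deterministic per-metaedge sub-seed, independent of iteration order."""
    digest = zlib.crc32(metaedge.abbreviation.encode())
    return int((seed * 1_000_003 + digest) % 2**31)


def extract_edges(store: HetMat, metaedge) -> list[tuple[int, int]]:
    """Adjacency → positional edge list; undirected self metaedges yield each
    unordered pair once (i < j) to avoid double representation."""
    metaedge = store._resolve_metaedge(metaedge)
    matrix = store.adjacency(metaedge)
    rows, cols = (
        matrix.nonzero() if hasattr(matrix, "nonzero") else np.nonzero(matrix)
    )
    pairs = list(zip(rows.tolist(), cols.tolist()))
    if metaedge.is_self_loop and not metaedge.directed:
        pairs = [(i, j) for i, j in pairs if i < j]
    return pairs


def permute_hetnet(
    store: HetMat,
    multiplier: float = DEFAULT_MULTIPLIER,
    seed: int = 0,
) -> tuple[HetMat, list[PermutationReport]]:
    """Permute every metaedge independently; node tables and the metagraph
    are untouched and per-metaedge degree vectors are preserved exactly."""
    adjacency = {}
    reports = []
    for key in sorted(store.metagraph.metaedges):
        metaedge = store.metagraph.metaedges[key]
        pairs = extract_edges(store, metaedge)
        sub_seed = metaedge_seed(seed, metaedge)
        undirected_self = metaedge.is_self_loop and not metaedge.directed
        n_rows = store.node_count(metaedge.source)
        if not metaedge.is_self_loop:
            # disjoint endpoint namespaces: a row index equal to a column
            # index is not a self-edge, so shift columns out of the way
            pairs = [(i, j + n_rows) for i, j in pairs]
        permuted, report = xswap(
            pairs,
            directed=not undirected_self,
            multiplier=multiplier,
            seed=sub_seed,
            metaedge=metaedge,
        )
        n_cols = store.node_count(metaedge.target)
        matrix = np.zeros((n_rows, n_cols), dtype=np.uint8)
        if not metaedge.is_self_loop:
            permuted = [(i, j - n_rows) for i, j in permuted]
        for i, j in permuted:
            matrix[i, j] = 1
            if undirected_self:
                matrix[j, i] = 1
        adjacency[key] = matrix
        reports.append(report)
    return store.replace_adjacency(adjacency), reports
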
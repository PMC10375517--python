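"""Path counting and degree-weighted path counts (DWPC) by matrix algebra.

The DWPC between a source and target node along a metapath is the sum over
all *duplicate-free* paths of the path degree product (PDP)

    PDP(path) = prod over edges (d_tail * d_head)^(-w)

where degrees are taken per metaedge and ``w`` is the damping exponent
(default 0.5; ``w = 0`` recovers the plain path count).  Naive matrix
multiplication counts walks, not paths, so products that revisit a node must
be corrected away.  Three building-block corrections cover most repeat
patterns:

* short repeats ``XaXbX``:   D = D(XaX) D(XbX) - diag(...)
* nested repeats ``XaYbYcX``: D = D(XaY) D(YbY) D(YcX) - diag(...)
* overlapping repeats ``XaYbXcY``:
    D = D1 D2 D3 - diag(D1 D2) D3 - D1 diag(D2 D3) + D1 ⊙ D2ᵀ ⊙ D3

Metapaths are categorized by their repeated-metanode pattern, segmented, and
each segment routed to a specialized routine; long (>=4) repeat runs and
unrecognized complex patterns fall back to exhaustive path enumeration
(:func:`dwpc_general`), which also serves as the correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import reduce
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sparse

from .hetmat import DENSE_THRESHOLD, HetMat, find_matrix_file, load_matrix, save_matrix
from .metagraph import Metapath, Step

DEFAULT_DAMPING = 0.5


@dataclass
class DwpcMatrix:
    """DWPC or path-count values for all (source, target) node pairs."""

    metapath: Metapath
    w: float
    values: np.ndarray
    kind: str = "dwpc"  # path_count | dwpc | dwpc_approx
    algorithm: str = "dispatch"

    def __post_init__(self):
        if self.kind not in ("path_count", "dwpc", "dwpc_approx"):
            raise ValueError(f"unknown DwpcMatrix kind {self.kind!r}")

    @property
    def transposed(self) -> "DwpcMatrix":
        return replace(self, metapath=self.metapath.reverse, values=self.values.T)

    def transformed(self, func) -> "DwpcMatrix":
        """Optional post-processing hook (e.g. a compacting transform such as
        ``np.arcsinh`` for cross-metapath comparability).  Never applied
        before significance testing — p-values always see raw DWPCs."""
        return replace(self, values=func(np.asarray(self.values, dtype=float)))


# ---------------------------------------------------------------------------
# degree weighting


def degree_weight(adjacency, source_degrees, target_degrees, w: float) -> np.ndarray:
    """Entry (i, j) becomes a_ij * d_i^(-w) * d_j^(-w); zero-degree rows and
    columns stay zero (such nodes lie on no path)."""
    if w < 0:
        raise ValueError(f"damping exponent must be nonnegative, got {w}")
    adjacency = _densify(adjacency)
    row = np.asarray(getattr(source_degrees, "values", source_degrees), dtype=float)
    col = np.asarray(getattr(target_degrees, "values", target_degrees), dtype=float)
    with np.errstate(divide="ignore"):
        row_w = np.where(row > 0, row**-w, 0.0)
        col_w = np.where(col > 0, col**-w, 0.0)
    return adjacency * row_w[:, np.newaxis] * col_w[np.newaxis, :]


def _densify(matrix) -> np.ndarray:
    if sparse.issparse(matrix):
        return matrix.toarray().astype(float)
    return np.asarray(matrix, dtype=float)


def step_weighted_matrix(store: HetMat, step: Step, w: float) -> np.ndarray:
    """Degree-weighted adjacency for one oriented metaedge traversal."""
    adjacency = _densify(store.adjacency(step.metaedge, invert=step.inverted))
    return degree_weight(adjacency, adjacency.sum(axis=1), adjacency.sum(axis=0), w)


# ---------------------------------------------------------------------------
# repeat-pattern categorization and segmentation


@dataclass(frozen=True)
class Segment:
    """A contiguous piece of a metapath with a solvable repeat pattern."""

    metapath: Metapath
    label: str
    children: tuple["Segment", ...] = ()

    def __str__(self) -> str:
        if self.children:
            inner = "".join(str(child) for child in self.children)
            return f"({self.metapath.abbreviation}:{self.label}[{inner}])"
        return f"({self.metapath.abbreviation}:{self.label})"


@dataclass(frozen=True)
class MetapathCategory:
    label: str
    segmentation: tuple[Segment, ...]


def _type_sequence(mp: Metapath) -> list[str]:
    return [mn.abbreviation for mn in mp.metanodes]


def _repeat_spans(types: Sequence[str]) -> list[tuple[int, int, frozenset]]:
    """Merged slot intervals covering all occurrences of repeated metanodes.

    Returns [(first_slot, last_slot, repeated_types)] in left-to-right order;
    intervals of different repeated types are merged when they overlap.
    """
    positions: dict[str, list[int]] = {}
    for slot, t in enumerate(types):
        positions.setdefault(t, []).append(slot)
    spans = sorted(
        (pos[0], pos[-1], t) for t, pos in positions.items() if len(pos) > 1
    )
    merged: list[tuple[int, int, set]] = []
    for start, end, t in spans:
        if merged and start < merged[-1][1]:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], end), prev[2] | {t})
        else:
            merged.append((start, end, {t}))
    return [(s, e, frozenset(ts)) for s, e, ts in merged]


def _classify_group(types: Sequence[str], start: int, end: int, reps: frozenset) -> str:
    occurrences = [types[slot] for slot in range(start, end + 1) if types[slot] in reps]
    slots = [slot for slot in range(start, end + 1) if types[slot] in reps]
    if len(reps) == 1:
        if len(occurrences) >= 4:
            return "long_repeat"
        if len(slots) == slots[-1] - slots[0] + 1:
            return "short_repeat"
        return "interleaved_nonrepeat"
    if occurrences[0] == occurrences[-1] and occurrences.count(occurrences[0]) == 2:
        return "nested"
    if occurrences == [occurrences[0], occurrences[1]] * 2 and occurrences[0] != occurrences[1]:
        return "overlapping"
    return "other_complex"


def _group_segment(mp: Metapath, start: int, end: int, reps: frozenset) -> Segment:
    types = _type_sequence(mp)
    label = _classify_group(types, start, end, reps)
    sub = mp[start:end]
    children: tuple[Segment, ...] = ()
    if label == "nested":
        inner_types = types[start : end + 1]
        outer = inner_types[0]
        inner_spans = _repeat_spans_excluding(inner_types, outer)
        children = tuple(
            _group_segment(sub, s, e, ts) for s, e, ts in inner_spans
        )
    return Segment(sub, label, children)


def _repeat_spans_excluding(types: Sequence[str], exclude: str):
    masked = [t if t != exclude else f"\x00{i}" for i, t in enumerate(types)]
    return _repeat_spans(masked)


def segment_metapath(mp: Metapath) -> list[Segment]:
    """Cover the metapath exactly once with repeat groups and plain flanks."""
    types = _type_sequence(mp)
    spans = _repeat_spans(types)
    segments: list[Segment] = []
    pos = 0
    for start, end, reps in spans:
        if pos < start:
            segments.append(Segment(mp[pos:start], "no_repeats"))
        segments.append(_group_segment(mp, start, end, reps))
        pos = end
    if pos < mp.length:
        segments.append(Segment(mp[pos : mp.length], "no_repeats"))
    return segments


def categorize_metapath(mp: Metapath) -> MetapathCategory:
    """Overall repeat-pattern label plus the segmentation that produced it."""
    segments = tuple(segment_metapath(mp))
    group_labels = [seg.label for seg in segments if seg.label != "no_repeats"]
    if not group_labels:
        label = "no_repeats"
    elif len(group_labels) == 1:
        label = group_labels[0]
    else:
        label = "disjoint"
    return MetapathCategory(label, segments)


# ---------------------------------------------------------------------------
# specialized matrix routines (public building blocks)


def _zero_diagonal(matrix: np.ndarray) -> np.ndarray:
    matrix = matrix.copy()
    np.fill_diagonal(matrix, 0.0)
    return matrix


def dwpc_short_repeat(*matrices: np.ndarray) -> np.ndarray:
    """Chain square X→X matrices, subtracting the main diagonal after every
    multiplication so no X node repeats (covers XaXbX and longer runs < 4)."""
    for matrix in matrices:
        if matrix.shape[0] != matrix.shape[1]:
            raise ValueError("short-repeat matrices must be square")
    result = _zero_diagonal(np.asarray(matrices[0], dtype=float))
    for matrix in matrices[1:]:
        result = _zero_diagonal(result @ _zero_diagonal(np.asarray(matrix, dtype=float)))
    return result


def dwpc_nested(outer_in: np.ndarray, inner: np.ndarray, outer_out: np.ndarray) -> np.ndarray:
    """Nested repeats XaYbYcX: inner YY resolved as a short repeat, then the
    outer XX closure removed by diagonal subtraction."""
    if inner.shape[0] != inner.shape[1]:
        raise ValueError("inner matrix must be square (Y→Y)")
    product = outer_in @ _zero_diagonal(np.asarray(inner, dtype=float)) @ outer_out
    if product.shape[0] != product.shape[1]:
        raise ValueError("outer chain must map X→X")
    return _zero_diagonal(product)


def dwpc_baba(d1: np.ndarray, d2: np.ndarray, d3: np.ndarray) -> np.ndarray:
    """Overlapping repeats XaYbXcY (e.g. CtDtCtD), by inclusion–exclusion:

    D = D1 D2 D3 - diag(D1 D2) D3 - D1 diag(D2 D3) + D1 ⊙ D2ᵀ ⊙ D3
    """
    d1, d2, d3 = (np.asarray(m, dtype=float) for m in (d1, d2, d3))
    if d1.shape[1] != d2.shape[0] or d2.shape[1] != d3.shape[0]:
        raise ValueError("matrices do not chain X→Y→X→Y")
    if d1.shape[0] != d2.shape[1] or d2.shape[0] != d3.shape[1]:
        raise ValueError("matrices do not chain X→Y→X→Y")
    walks = d1 @ d2 @ d3
    xx_closure = np.einsum("ij,ji->i", d1, d2)  # diag(D1 D2)
    yy_closure = np.einsum("ij,ji->i", d2, d3)  # diag(D2 D3)
    both = d1 * d2.T * d3
    return walks - xx_closure[:, np.newaxis] * d3 - d1 * yy_closure[np.newaxis, :] + both


# ---------------------------------------------------------------------------
# general (enumeration) method — exact for every pattern, and the oracle


def dwpc_general(store: HetMat, mp: Metapath, w: float = DEFAULT_DAMPING) -> DwpcMatrix:
    """Exact DWPC by explicit enumeration of duplicate-free paths.

    Slower than the matrix routines but valid for any metapath; the
    dispatcher falls back to it for long repeats and unrecognized patterns,
    and the test-suite uses it as the oracle for all specialized routines.
    """
    weights = [step_weighted_matrix(store, step, w) for step in mp]
    types = _type_sequence(mp)
    repeated = {t for t in types if types.count(t) > 1}
    neighbors = [
        [np.nonzero(row)[0] for row in matrix] for matrix in weights
    ]
    n_source = weights[0].shape[0]
    n_target = weights[-1].shape[1]
    values = np.zeros((n_source, n_target))
    visited: dict[str, set[int]] = {t: set() for t in repeated}

    def extend(depth: int, node: int, pdp: float) -> None:
        matrix = weights[depth]
        next_type = types[depth + 1]
        tracked = next_type in repeated
        for nxt in neighbors[depth][node]:
            if tracked and nxt in visited[next_type]:
                continue
            weight = pdp * matrix[node, nxt]
            if depth + 1 == len(types) - 1:
                values[start, nxt] += weight
            else:
                if tracked:
                    visited[next_type].add(nxt)
                extend(depth + 1, nxt, weight)
                if tracked:
                    visited[next_type].discard(nxt)

    source_tracked = types[0] in repeated
    for start in range(n_source):
        if source_tracked:
            visited[types[0]].add(start)
        extend(0, start, 1.0)
        if source_tracked:
            visited[types[0]].discard(start)
    return _finalize(mp, w, values, algorithm="general")


def _finalize(mp: Metapath, w: float, values: np.ndarray, algorithm: str, kind=None) -> DwpcMatrix:
    if kind is None:
        kind = "path_count" if w == 0 else "dwpc"
    if kind == "path_count":
        values = np.rint(values).astype(np.uint64)
    else:
        # correction algebra can leave tiny negative round-off
        values = np.where(np.abs(values) < 1e-12, 0.0, values)
        values = np.clip(values, 0.0, None) if values.min() > -1e-8 else values
    return DwpcMatrix(metapath=mp, w=w, values=values, kind=kind, algorithm=algorithm)


# ---------------------------------------------------------------------------
# dispatcher


class DwpcCache:
    """(abbreviation, w)-keyed cache of computed matrices, memory plus the
    ``path-counts/dwpc-<w>/`` directory of a disk-backed store."""

    def __init__(self, store: HetMat):
        self.store = store
        self.memory: dict[tuple[str, float], np.ndarray] = {}

    def get(self, mp: Metapath, w: float) -> np.ndarray | None:
        for candidate, transpose in ((mp, False), (mp.reverse, True)):
            hit = self.memory.get((candidate.abbreviation, w))
            if hit is None:
                hit = self._from_disk(candidate, w)
            if hit is not None:
                return hit.T if transpose else hit
        return None

    def _from_disk(self, mp: Metapath, w: float) -> np.ndarray | None:
        if self.store.directory is None:
            return None
        stub = self.store.path_counts_directory(w) / mp.abbreviation
        path = find_matrix_file(stub)
        if path is None:
            return None
        return _densify(load_matrix(path))

    def put(self, mp: Metapath, w: float, values: np.ndarray) -> None:
        self.memory[(mp.abbreviation, w)] = values

    def persist(self, mp: Metapath, w: float, values: np.ndarray) -> Path:
        stub = self.store.path_counts_directory(w) / mp.abbreviation
        existing = find_matrix_file(stub)
        if existing is not None:
            return existing
        matrix = values
        if _matrix_density(values) < DENSE_THRESHOLD:
            matrix = sparse.csr_matrix(values)
        return save_matrix(matrix, stub)


def _matrix_density(values: np.ndarray) -> float:
    if values.size == 0:
        return 0.0
    return np.count_nonzero(values) / values.size


def _get_cache(store: HetMat) -> DwpcCache:
    cache = getattr(store, "_dwpc_cache", None)
    if cache is None:
        cache = DwpcCache(store)
        store._dwpc_cache = cache
    return cache


def dwpc(
    store: HetMat,
    mp: Metapath,
    w: float = DEFAULT_DAMPING,
    dense_threshold: float = DENSE_THRESHOLD,
    use_cache: bool = True,
) -> DwpcMatrix:
    """Exact DWPC for any metapath via categorize → segment → route.

    Segment results are cached by (abbreviation, w) and reused across calls
    (including matrices previously persisted under ``path-counts/``); cached
    and fresh computations are value-identical.
    """
    if w < 0:
        raise ValueError("damping exponent must be nonnegative")
    if isinstance(mp, str):
        mp = store.metagraph.parse_metapath(mp)
    cache = _get_cache(store) if use_cache else None
    values = _dispatch(store, mp, w, cache)
    return _finalize(mp, w, values, algorithm="dispatch")


def path_count(store: HetMat, mp: Metapath, **kwargs) -> DwpcMatrix:
    """Duplicate-free path counts (DWPC at w = 0, unsigned 64-bit)."""
    return dwpc(store, mp, w=0.0, **kwargs)


def _dispatch(store: HetMat, mp: Metapath, w: float, cache: DwpcCache | None) -> np.ndarray:
    if cache is not None:
        hit = cache.get(mp, w)
        if hit is not None:
            return hit
    types = _type_sequence(mp)
    spans = _repeat_spans(types)
    factors: list[np.ndarray] = []
    pos = 0
    for start, end, reps in spans:
        if pos < start:
            factors.append(_chain(store, mp, pos, start, w))
        factors.append(_group_values(store, mp, start, end, reps, w, cache))
        pos = end
    if pos < mp.length:
        factors.append(_chain(store, mp, pos, mp.length, w))
    values = reduce(np.matmul, factors)
    if cache is not None:
        cache.put(mp, w, values)
    return values


def _chain(store: HetMat, mp: Metapath, start: int, end: int, w: float) -> np.ndarray:
    return reduce(
        np.matmul, (step_weighted_matrix(store, step, w) for step in mp[start:end])
    )


def _group_values(
    store: HetMat,
    mp: Metapath,
    start: int,
    end: int,
    reps: frozenset,
    w: float,
    cache: DwpcCache | None,
) -> np.ndarray:
    sub = mp[start:end]
    if cache is not None:
        hit = cache.get(sub, w)
        if hit is not None:
            return hit
    types = _type_sequence(mp)
    label = _classify_group(types, start, end, reps)
    if label in ("short_repeat", "interleaved_nonrepeat"):
        values = _short_repeat_values(store, mp, start, end, next(iter(reps)), w)
    elif label == "nested":
        values = _nested_values(store, mp, start, end, w, cache)
    elif label == "overlapping":
        values = _overlapping_values(store, mp, start, end, reps, w)
    else:  # long_repeat, other_complex → exact enumeration on the segment
        values = dwpc_general(store, sub, w).values.astype(float)
    if cache is not None:
        cache.put(sub, w, values)
    return values


def _short_repeat_values(store, mp, start, end, repeat_type, w) -> np.ndarray:
    types = _type_sequence(mp)
    occurrences = [s for s in range(start, end + 1) if types[s] == repeat_type]
    chains = [
        _chain(store, mp, a, b, w) for a, b in zip(occurrences, occurrences[1:])
    ]
    return dwpc_short_repeat(*chains)


def _nested_values(store, mp, start, end, w, cache) -> np.ndarray:
    types = _type_sequence(mp)
    outer = types[start]
    # spans of the remaining repeated types, strictly inside the group
    inner_types = types[start : end + 1]
    inner_spans = _repeat_spans_excluding(inner_types, outer)
    factors: list[np.ndarray] = []
    pos = start
    for s, e, ts in inner_spans:
        s, e = start + s, start + e
        if pos < s:
            factors.append(_chain(store, mp, pos, s, w))
        factors.append(_group_values(store, mp, s, e, ts, w, cache))
        pos = e
    if pos < end:
        factors.append(_chain(store, mp, pos, end, w))
    return _zero_diagonal(reduce(np.matmul, factors))


def _overlapping_values(store, mp, start, end, reps, w) -> np.ndarray:
    types = _type_sequence(mp)
    slots = [s for s in range(start, end + 1) if types[s] in reps]
    q0, q1, q2, q3 = slots
    d1 = _chain(store, mp, q0, q1, w)
    d2 = _chain(store, mp, q1, q2, w)
    d3 = _chain(store, mp, q2, q3, w)
    return dwpc_baba(d1, d2, d3)


# ---------------------------------------------------------------------------
# approximate variants (for comparison; the dispatcher never uses them)


def dwpc_approx(store: HetMat, mp: Metapath, w: float = DEFAULT_DAMPING) -> DwpcMatrix:
    """Approximate DWPC: exact on disjoint simple repeat patterns; for
    long/complex groups only the first repeat is corrected."""
    types = _type_sequence(mp)
    spans = _repeat_spans(types)
    factors: list[np.ndarray] = []
    pos = 0
    for start, end, reps in spans:
        if pos < start:
            factors.append(_chain(store, mp, pos, start, w))
        label = _classify_group(types, start, end, reps)
        if label in ("long_repeat", "other_complex"):
            factors.append(_first_repeat_corrected(store, mp, start, end, reps, w))
        else:
            factors.append(_group_values(store, mp, start, end, reps, w, None))
        pos = end
    if pos < mp.length:
        factors.append(_chain(store, mp, pos, mp.length, w))
    values = reduce(np.matmul, factors)
    return _finalize(mp, w, values, algorithm="approx", kind="dwpc_approx")


def _first_repeat_corrected(store, mp, start, end, reps, w) -> np.ndarray:
    types = _type_sequence(mp)
    first_type = next(t for t in types[start : end + 1] if t in reps)
    occurrences = [s for s in range(start, end + 1) if types[s] == first_type]
    qa, qb = occurrences[0], occurrences[1]
    factors = []
    if start < qa:
        factors.append(_chain(store, mp, start, qa, w))
    factors.append(_zero_diagonal(_chain(store, mp, qa, qb, w)))
    if qb < end:
        factors.append(_chain(store, mp, qb, end, w))
    return reduce(np.matmul, factors)


def dwpc_mayers(store: HetMat, mp: Metapath, w: float = DEFAULT_DAMPING) -> DwpcMatrix:
    """Alternative approximation that subtracts the main diagonal at every
    occurrence of the first repeated metanode (comparison only)."""
    types = _type_sequence(mp)
    repeated = [t for t in types if types.count(t) > 1]
    if not repeated:
        return _finalize(mp, w, _chain(store, mp, 0, mp.length, w), "mayers", "dwpc_approx")
    first_type = repeated[0]
    occurrences = [s for s, t in enumerate(types) if t == first_type]
    factors = []
    pos = 0
    if occurrences[0] > 0:
        factors.append(_chain(store, mp, 0, occurrences[0], w))
    running = None
    for a, b in zip(occurrences, occurrences[1:]):
        piece = _chain(store, mp, a, b, w)
        running = piece if running is None else running @ piece
        running = _zero_diagonal(running)
    factors.append(running)
    if occurrences[-1] < mp.length:
        factors.append(_chain(store, mp, occurrences[-1], mp.length, w))
    return _finalize(mp, w, reduce(np.matmul, factors), "mayers", "dwpc_approx")


# ---------------------------------------------------------------------------
# per-path decomposition


@dataclass(frozen=True)
class PathRecord:
    """One duplicate-free path with its PDP and share of the DWPC."""

    nodes: tuple[str, ...]
    metapath: Metapath
    path_degree_product: float
    percent_of_dwpc: float


def enumerate_paths(
    store: HetMat,
    mp: Metapath,
    source_node: str,
    target_node: str,
    w: float = DEFAULT_DAMPING,
    limit: int | None = None,
) -> list[PathRecord]:
    """All duplicate-free paths between two nodes along a metapath, sorted by
    descending PDP; ``percent_of_dwpc`` sums to 100 when the DWPC > 0."""
    if isinstance(mp, str):
        mp = store.metagraph.parse_metapath(mp)
    source_ids = store.nodes(mp.source)
    target_ids = store.nodes(mp.target)
    try:
        source_idx = source_ids.index(source_node)
        target_idx = target_ids.index(target_node)
    except ValueError as exc:
        raise TypeError(
            f"node not found with required metanode type for {mp.abbreviation}: {exc}"
        ) from None
    weights = [step_weighted_matrix(store, step, w) for step in mp]
    types = _type_sequence(mp)
    node_ids = [store.nodes(mn) for mn in mp.metanodes]
    found: list[tuple[tuple[str, ...], float]] = []
    visited = {(types[0], source_idx)}

    def extend(depth: int, node: int, pdp: float, trail: list[int]) -> None:
        matrix = weights[depth]
        next_type = types[depth + 1]
        last = depth + 1 == len(types) - 1
        for nxt in np.nonzero(matrix[node])[0]:
            key = (next_type, int(nxt))
            if key in visited:
                continue
            if last and nxt != target_idx:
                continue
            weight = pdp * matrix[node, nxt]
            if last:
                ids = tuple(
                    node_ids[d][i] for d, i in enumerate(trail + [int(nxt)])
                )
                found.append((ids, weight))
            else:
                visited.add(key)
                extend(depth + 1, int(nxt), weight, trail + [int(nxt)])
                visited.discard(key)

    extend(0, source_idx, 1.0, [source_idx])
    total = sum(pdp for _, pdp in found)
    found.sort(key=lambda item: (-item[1], item[0]))
    if limit is not None:
        found = found[:limit]
    return [
        PathRecord(
            nodes=ids,
            metapath=mp,
            path_degree_product=pdp,
            percent_of_dwpc=(100.0 * pdp / total) if total > 0 else 0.0,
        )
        for ids, pdp in found
    ]
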
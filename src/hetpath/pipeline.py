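"""End-to-end connectivity search: precompute, query tables, path ranking.

``precompute`` walks every metapath (canonical orientation only) up to a
length cap: DWPC and path-count matrices on the real network, degree-grouped
null summary statistics accumulated over permuted networks, and a table of
retained (prioritized) rows.  ``metapath_table`` answers a node-pair query
with one row per metapath; ``path_table`` ranks the individual paths behind
selected metapaths by path score

    path_score = (fraction of DWPC contributed by the path) · (−log10 p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nullmodel
from .dwpc import DEFAULT_DAMPING, _get_cache, dwpc, enumerate_paths, step_weighted_matrix
from .hetmat import HetMat
from .metagraph import Metanode, Metapath
from .permute import DEFAULT_MULTIPLIER, permute_hetnet

METAPATH_TABLE_COLUMNS = [
    "metapath",
    "source_id",
    "target_id",
    "path_count",
    "dwpc",
    "p_value",
    "p_adjusted",
    "source_degree",
    "target_degree",
    "n_dwpcs",
    "n_nonzero_dwpcs",
    "nonzero_mean",
    "nonzero_sd",
    "precomputed",
]


@dataclass
class PrecomputeResult:
    """Everything needed to answer queries: the store, null statistics per
    canonical metapath, retained rows, and the run parameters."""

    store: HetMat
    w: float
    max_length: int
    n_permutations: int
    seed: int
    metapaths: list[Metapath]
    stats: dict[str, dict[tuple[int, int], nullmodel.DegreeGroupStats]]
    rows: pd.DataFrame
    hurdle_weighted: bool = True
    _family_sizes: dict = field(default_factory=dict)

    def family_size(self, source: Metanode, target: Metanode, length: int) -> int:
        """Number of metapaths with the same source metanode, target
        metanode, and length (the Bonferroni family)."""
        key = (source.abbreviation, target.abbreviation, length)
        if key not in self._family_sizes:
            family = self.store.metagraph.enumerate_metapaths(
                length, source=source, target=target
            )
            self._family_sizes[key] = sum(1 for mp in family if mp.length == length)
        return self._family_sizes[key]


def metapath_degrees(store: HetMat, mp: Metapath) -> tuple[np.ndarray, np.ndarray]:
    """Node degrees for the metapath's first metaedge (source side) and last
    metaedge (target side), per the degree-grouping convention."""
    first = store.adjacency(mp.steps[0].metaedge, invert=mp.steps[0].inverted)
    last = store.adjacency(mp.steps[-1].metaedge, invert=mp.steps[-1].inverted)
    source_degrees = np.asarray(first.sum(axis=1)).ravel().astype(np.int64)
    target_degrees = np.asarray(last.sum(axis=0)).ravel().astype(np.int64)
    return source_degrees, target_degrees


def generate_permutations(
    store: HetMat,
    n_permutations: int,
    multiplier: float = DEFAULT_MULTIPLIER,
    seed: int = 0,
) -> list[HetMat]:
    """n permuted copies, seeded deterministically; disk-backed stores reuse
    permutations already present under ``permutations/``."""
    permuted_stores = []
    for index in range(n_permutations):
        perm_seed = seed + index
        if store.directory is not None:
            perm_dir = store.permutations_directory / f"{index + 1:03d}.hetmat"
            if (perm_dir / "metagraph.json").exists():
                permuted_stores.append(HetMat.from_directory(perm_dir))
                continue
            permuted, _ = permute_hetnet(store, multiplier=multiplier, seed=perm_seed)
            permuted_stores.append(permuted.write(perm_dir))
        else:
            permuted, _ = permute_hetnet(store, multiplier=multiplier, seed=perm_seed)
            permuted_stores.append(permuted)
    return permuted_stores


def accumulate_null_stats(
    store: HetMat,
    permuted_stores: list[HetMat],
    metapaths: list[Metapath],
    w: float = DEFAULT_DAMPING,
) -> dict[str, dict[tuple[int, int], nullmodel.DegreeGroupStats]]:
    """Degree-grouped running totals of null DWPCs, merged over permutations.

    Degrees are those of the unpermuted store; permutation preserves them,
    so groups are identical across permuted copies.
    """
    stats: dict[str, dict] = {}
    for mp in metapaths:
        source_degrees, target_degrees = metapath_degrees(store, mp)
        per_metapath: dict = {}
        for permuted in permuted_stores:
            null_matrix = dwpc(permuted, mp, w=w)
            new = nullmodel.degree_group_stats(
                null_matrix, source_degrees, target_degrees, metapath=mp.abbreviation
            )
            nullmodel.merge_stats_maps(per_metapath, new)
        stats[mp.abbreviation] = per_metapath
    return stats


def precompute(
    store: HetMat,
    max_length: int,
    w: float = DEFAULT_DAMPING,
    n_permutations: int = 20,
    seed: int = 0,
    multiplier: float = DEFAULT_MULTIPLIER,
    hurdle_weighted: bool = True,
) -> PrecomputeResult:
    """Full precomputation over every canonical metapath of length <= cap.

    Persists DWPC/path-count matrices (under ``path-counts/``) and null
    statistics (``null-stats/``) for disk-backed stores; completed metapaths
    found on disk are reused rather than recomputed, making an interrupted
    run resumable.
    """
    metagraph = store.metagraph
    metapaths = metagraph.enumerate_metapaths(max_length)
    permuted_stores = generate_permutations(store, n_permutations, multiplier, seed)
    cache = _get_cache(store)
    stats: dict[str, dict] = {}
    row_records = []
    for mp in metapaths:
        mp_stats = _load_stats(store, mp, w, n_permutations)
        if mp_stats is None:
            mp_stats = accumulate_null_stats(store, permuted_stores, [mp], w)[
                mp.abbreviation
            ]
            _save_stats(store, mp, w, mp_stats)
        stats[mp.abbreviation] = mp_stats
        dwpc_matrix = dwpc(store, mp, w=w)
        count_matrix = dwpc(store, mp, w=0.0)
        if store.directory is not None:
            cache.persist(mp, w, dwpc_matrix.values)
            cache.persist(mp, 0.0, count_matrix.values.astype(float))
        row_records.extend(
            _retained_rows(store, mp, dwpc_matrix, count_matrix, mp_stats, hurdle_weighted, metagraph, max_length)
        )
    rows = pd.DataFrame(row_records, columns=METAPATH_TABLE_COLUMNS[:-1])
    rows = rows.sort_values(["metapath", "source_id", "target_id"]).reset_index(drop=True)
    result = PrecomputeResult(
        store=store,
        w=w,
        max_length=max_length,
        n_permutations=n_permutations,
        seed=seed,
        metapaths=metapaths,
        stats=stats,
        rows=rows,
        hurdle_weighted=hurdle_weighted,
    )
    if store.directory is not None:
        rows_path = store.directory / "precompute" / f"rows-dwpc-{w}.tsv"
        rows_path.parent.mkdir(parents=True, exist_ok=True)
        rows.to_csv(rows_path, sep="\t", index=False)
    return result


def _stats_path(store: HetMat, mp: Metapath, w: float):
    return store.directory / "null-stats" / f"dwpc-{w}" / f"{mp.abbreviation}.tsv.gz"


def _load_stats(store, mp, w, n_permutations):
    if store.directory is None:
        return None
    path = _stats_path(store, mp, w)
    if not path.exists():
        return None
    loaded = nullmodel.read_stats(path)
    by_degree = {(s.source_degree, s.target_degree): s for s in loaded.values()}
    if any(s.n_perms != n_permutations for s in by_degree.values()):
        return None
    return by_degree


def _save_stats(store, mp, w, mp_stats):
    if store.directory is None:
        return
    nullmodel.write_stats(mp_stats, _stats_path(store, mp, w))


def _retained_rows(store, mp, dwpc_matrix, count_matrix, mp_stats, hurdle_weighted, metagraph, max_length):
    source_degrees, target_degrees = metapath_degrees(store, mp)
    n_source = len(store.nodes(mp.source))
    n_target = len(store.nodes(mp.target))
    threshold = nullmodel.storage_threshold(n_source, n_target, mp.length)
    family = _family_size(metagraph, mp)
    source_ids = store.nodes(mp.source)
    target_ids = store.nodes(mp.target)
    rows = []
    nonzero = np.argwhere(np.asarray(dwpc_matrix.values, dtype=float) > 0)
    for i, j in nonzero:
        t = float(dwpc_matrix.values[i, j])
        group = mp_stats.get((int(source_degrees[i]), int(target_degrees[j])))
        if group is None:
            continue
        significance = nullmodel.dwpc_pvalue(group, t, hurdle_weighted=hurdle_weighted)
        p_adjusted = nullmodel.adjust_pvalue(significance.p_value, family)
        if not nullmodel.keep_record(t, p_adjusted, threshold):
            continue
        rows.append(
            {
                "metapath": mp.abbreviation,
                "source_id": source_ids[i],
                "target_id": target_ids[j],
                "path_count": int(count_matrix.values[i, j]),
                "dwpc": t,
                "p_value": significance.p_value,
                "p_adjusted": p_adjusted,
                "source_degree": int(source_degrees[i]),
                "target_degree": int(target_degrees[j]),
                "n_dwpcs": group.N,
                "n_nonzero_dwpcs": group.n,
                "nonzero_mean": group.nonzero_mean,
                "nonzero_sd": group.nonzero_sd,
            }
        )
    return rows


def _family_size(metagraph, mp: Metapath) -> int:
    family = metagraph.enumerate_metapaths(mp.length, source=mp.source, target=mp.target)
    return sum(1 for other in family if other.length == mp.length)


# ---------------------------------------------------------------------------
# queries


def _locate_node(store: HetMat, node_id: str) -> tuple[Metanode, int]:
    hits = []
    for ab, ids in store.node_orderings.items():
        if node_id in ids:
            hits.append((store.metagraph.metanodes[ab], ids.index(node_id)))
    if not hits:
        raise KeyError(f"unknown node {node_id!r}")
    if len(hits) > 1:
        raise KeyError(f"node id {node_id!r} is ambiguous across metanodes")
    return hits[0]


def metapath_table(
    result: PrecomputeResult,
    source_id: str,
    target_id: str,
    max_length: int | None = None,
    precomputed_only: bool = False,
) -> pd.DataFrame:
    """One row per metapath between two nodes, sorted by adjusted p-value.

    Stored canonical orientations are reversed transparently; with
    ``precomputed_only=False`` rows absent from the retained set are computed
    on the fly with the identical code path.  A degree group absent from the
    null statistics yields a missing (NaN) p-value.
    """
    store = result.store
    if max_length is None:
        max_length = result.max_length
    source_mn, source_idx = _locate_node(store, source_id)
    target_mn, target_idx = _locate_node(store, target_id)
    metapaths = store.metagraph.enumerate_metapaths(
        max_length, source=source_mn, target=target_mn
    )
    retained = result.rows
    rows = []
    for mp in metapaths:
        canonical = mp if mp.is_canonical else mp.reverse
        oriented_reverse = canonical.abbreviation != mp.abbreviation
        mp_stats = result.stats.get(canonical.abbreviation, {})
        dwpc_matrix = dwpc(store, mp, w=result.w)
        count_matrix = dwpc(store, mp, w=0.0)
        t = float(dwpc_matrix.values[source_idx, target_idx])
        source_degrees, target_degrees = metapath_degrees(store, mp)
        sd = int(source_degrees[source_idx])
        td = int(target_degrees[target_idx])
        group_key = (td, sd) if oriented_reverse else (sd, td)
        group = mp_stats.get(group_key)
        family = result.family_size(source_mn, target_mn, mp.length)
        if group is None:
            p_value = p_adjusted = float("nan")
            n_dwpcs = n_nonzero = 0
            mean = sd_null = float("nan")
        else:
            significance = nullmodel.dwpc_pvalue(
                group, t, hurdle_weighted=result.hurdle_weighted
            )
            p_value = significance.p_value
            p_adjusted = nullmodel.adjust_pvalue(p_value, family)
            n_dwpcs, n_nonzero = group.N, group.n
            mean, sd_null = group.nonzero_mean, group.nonzero_sd
        key = (
            canonical.abbreviation,
            target_id if oriented_reverse else source_id,
            source_id if oriented_reverse else target_id,
        )
        precomputed = bool(
            (
                (retained["metapath"] == key[0])
                & (retained["source_id"] == key[1])
                & (retained["target_id"] == key[2])
            ).any()
        )
        rows.append(
            {
                "metapath": mp.abbreviation,
                "source_id": source_id,
                "target_id": target_id,
                "path_count": int(count_matrix.values[source_idx, target_idx]),
                "dwpc": t,
                "p_value": p_value,
                "p_adjusted": p_adjusted,
                "source_degree": sd,
                "target_degree": td,
                "n_dwpcs": n_dwpcs,
                "n_nonzero_dwpcs": n_nonzero,
                "nonzero_mean": mean,
                "nonzero_sd": sd_null,
                "precomputed": precomputed,
            }
        )
    table = pd.DataFrame(rows, columns=METAPATH_TABLE_COLUMNS)
    if precomputed_only:
        table = table[table["precomputed"]]
    table = table.sort_values(
        ["p_adjusted", "metapath"], na_position="last"
    ).reset_index(drop=True)
    return table


def path_table(
    result: PrecomputeResult,
    metapaths,
    source_id: str,
    target_id: str,
    per_metapath_limit: int = 100,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Individual paths for the selected metapaths, merged across metapaths
    and sorted by descending path score."""
    store = result.store
    table = metapath_table(result, source_id, target_id)
    p_column = "p_adjusted" if use_adjusted else "p_value"
    by_abbrev = table.set_index("metapath")[p_column].to_dict()
    rows = []
    for mp in metapaths:
        if isinstance(mp, str):
            mp = store.metagraph.parse_metapath(mp)
        p = by_abbrev.get(mp.abbreviation, float("nan"))
        records = enumerate_paths(
            store, mp, source_id, target_id, w=result.w, limit=per_metapath_limit
        )
        if p != p:  # missing p-value
            neg_log_p = float("nan")
        elif p <= 0:  # empirical zero: infinitely surprising
            neg_log_p = float("inf")
        else:
            neg_log_p = -math.log10(p)
        for record in records:
            rows.append(
                {
                    "path": "–".join(record.nodes),
                    "metapath": mp.abbreviation,
                    "percent_of_dwpc": record.percent_of_dwpc,
                    "path_score": record.percent_of_dwpc / 100.0 * neg_log_p,
                }
            )
    frame = pd.DataFrame(rows, columns=["path", "metapath", "percent_of_dwpc", "path_score"])
    return frame.sort_values(
        ["path_score", "metapath", "path"], ascending=[False, True, True]
    ).reset_index(drop=True)


def significant_metapath_counts(result: PrecomputeResult) -> pd.Series:
    """Retained-row count per node (both endpoints), a simple proxy for the
    node-search ranking."""
    counts = pd.concat([result.rows["source_id"], result.rows["target_id"]])
    return counts.value_counts()
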
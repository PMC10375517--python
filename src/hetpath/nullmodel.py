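"""Null distributions and significance for DWPCs.

Null DWPCs come from degree-preserving permuted hetnets.  Because
permutation preserves only degree, null values for all node pairs sharing a
(source degree, target degree) combination are exchangeable, so they are
pooled per degree group and summarized by running totals — total count N,
nonzero count n, sum, sum of squares, and the number of permuted hetnets —
which are additive across permutations and sufficient for significance.

The pooled nonzero values are modeled with a gamma-hurdle distribution:
probability 1 − λ of a zero, and with probability λ a Gamma(α, rate β) draw.
The right-tail probability of an observed DWPC t > 0 is

    p = λ · Q(α, β t)

with Q the regularized upper incomplete gamma function.  When the gamma part
cannot be fit (fewer than two nonzero nulls, or zero spread), an empirical
rule is used instead.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special


class FitUnavailable(ValueError):
    """Gamma-hurdle moments cannot be estimated; fall back to empirical."""


@dataclass(frozen=True)
class DegreeGroupStats:
    """Running-total null DWPC summary for one (metapath, degree pair)."""

    metapath: str
    source_degree: int
    target_degree: int
    N: int = 0
    n: int = 0
    sum: float = 0.0
    sum_sq: float = 0.0
    n_perms: int = 0

    def __post_init__(self):
        if not (0 <= self.n <= self.N):
            raise ValueError("need 0 <= n <= N")
        if self.sum < 0 or self.sum_sq < 0:
            raise ValueError("sums must be nonnegative")
        if self.n > 0 and self.sum**2 > self.n * self.sum_sq * (1 + 1e-9):
            raise ValueError("violates Cauchy–Schwarz: sum^2 > n * sum_sq")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.metapath, self.source_degree, self.target_degree)

    @property
    def nonzero_mean(self) -> float:
        return self.sum / self.n if self.n else float("nan")

    @property
    def nonzero_sd(self) -> float:
        if self.n < 2:
            return float("nan")
        var = (self.sum_sq - self.n * self.nonzero_mean**2) / (self.n - 1)
        return math.sqrt(max(var, 0.0))


def degree_group_stats(
    null_matrix,
    source_degrees,
    target_degrees,
    metapath: str | None = None,
) -> dict[tuple[int, int], DegreeGroupStats]:
    """Pool one permuted network's DWPC matrix by (source, target) degree.

    Every matrix cell lands in exactly one group; the returned stats carry
    ``n_perms = 1`` and add across permutations via :func:`merge_stats`.
    """
    values = np.asarray(getattr(null_matrix, "values", null_matrix), dtype=float)
    if metapath is None:
        mp = getattr(null_matrix, "metapath", None)
        metapath = mp.abbreviation if mp is not None else ""
    src = np.asarray(getattr(source_degrees, "values", source_degrees), dtype=np.int64)
    tgt = np.asarray(getattr(target_degrees, "values", target_degrees), dtype=np.int64)
    if values.shape != (src.size, tgt.size):
        raise ValueError(
            f"null matrix shape {values.shape} does not match degree vectors "
            f"({src.size}, {tgt.size})"
        )
    flat = values.ravel()
    keys_src = np.repeat(src, tgt.size)
    keys_tgt = np.tile(tgt, src.size)
    frame = pd.DataFrame(
        {
            "sd": keys_src,
            "td": keys_tgt,
            "value": flat,
            "nonzero": (flat > 0).astype(np.int64),
            "square": flat**2,
        }
    )
    grouped = frame.groupby(["sd", "td"], sort=True).agg(
        N=("value", "size"),
        n=("nonzero", "sum"),
        total=("value", "sum"),
        total_sq=("square", "sum"),
    )
    out = {}
    for (sd, td), row in grouped.iterrows():
        out[(int(sd), int(td))] = DegreeGroupStats(
            metapath=metapath,
            source_degree=int(sd),
            target_degree=int(td),
            N=int(row["N"]),
            n=int(row["n"]),
            sum=float(row["total"]),
            sum_sq=float(row["total_sq"]),
            n_perms=1,
        )
    return out


def merge_stats(a: DegreeGroupStats, b: DegreeGroupStats) -> DegreeGroupStats:
    """Fieldwise sum; commutative and associative with the all-zero identity."""
    if a.key != b.key and a.N and b.N:
        raise KeyError(f"cannot merge stats for different groups: {a.key} vs {b.key}")
    key = a.key if a.N else b.key
    return DegreeGroupStats(
        metapath=key[0],
        source_degree=key[1],
        target_degree=key[2],
        N=a.N + b.N,
        n=a.n + b.n,
        sum=a.sum + b.sum,
        sum_sq=a.sum_sq + b.sum_sq,
        n_perms=a.n_perms + b.n_perms,
    )


def merge_stats_maps(
    into: dict[tuple[int, int], DegreeGroupStats],
    new: dict[tuple[int, int], DegreeGroupStats],
) -> dict[tuple[int, int], DegreeGroupStats]:
    for key, stats in new.items():
        if key in into:
            into[key] = merge_stats(into[key], stats)
        else:
            into[key] = stats
    return into


# ---------------------------------------------------------------------------
# gamma-hurdle model


@dataclass(frozen=True)
class GammaHurdle:
    """Zero-inflated gamma: P(X=0) = 1-λ, X|X>0 ~ Gamma(shape α, rate β)."""

    lam: float
    alpha: float
    beta: float

    def __post_init__(self):
        if not 0 <= self.lam <= 1:
            raise ValueError("lambda must lie in [0, 1]")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


def fit_gamma_hurdle(stats: DegreeGroupStats) -> GammaHurdle:
    """Method-of-moments fit from summary statistics alone.

    λ̂ = n/N; with nonzero mean m = sum/n and Bessel-corrected variance
    v = (sum_sq − n·m²)/(n−1), the gamma part has shape α̂ = m²/v and rate
    β̂ = m/v (so that mean α/β = m and variance α/β² = v).
    """
    if stats.n < 2:
        raise FitUnavailable(f"need >= 2 nonzero null DWPCs, have {stats.n}")
    mean = stats.sum / stats.n
    var = (stats.sum_sq - stats.n * mean**2) / (stats.n - 1)
    if var <= 0:
        raise FitUnavailable("nonzero null DWPCs have zero spread")
    return GammaHurdle(lam=stats.n / stats.N, alpha=mean**2 / var, beta=mean / var)


def gamma_hurdle_pvalue(params: GammaHurdle, t: float, hurdle_weighted: bool = True) -> float:
    """Right-tail probability P(X >= t) for t > 0.

    ``hurdle_weighted=False`` returns the tail conditional on X > 0 (the
    bare gamma tail, without the λ factor).
    """
    if t <= 0:
        raise ValueError("gamma-hurdle p-value requires t > 0; route t <= 0 to empirical")
    tail = float(special.gammaincc(params.alpha, params.beta * t))
    return params.lam * tail if hurdle_weighted else tail


def empirical_pvalue(stats: DegreeGroupStats, t: float) -> float:
    """Fallback proportion-of-nulls-≥-t rules computable from summaries:
    t = 0 → 1; all nulls zero → 0; zero-spread nonzero nulls with common
    value v → 0 if t > v else n/N."""
    if t <= 0:
        return 1.0
    if stats.n == 0:
        return 0.0
    common = stats.sum / stats.n
    return 0.0 if t > common else stats.n / stats.N


@dataclass(frozen=True)
class SignificanceResult:
    dwpc: float
    p_value: float
    p_adjusted: float | None
    method: str  # gamma_hurdle | empirical
    stats_used: DegreeGroupStats

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p-value cannot be below raw p-value")


def dwpc_pvalue(
    stats: DegreeGroupStats,
    t: float,
    hurdle_weighted: bool = True,
) -> SignificanceResult:
    """Route to the gamma-hurdle fit when available, else empirical rules."""
    if stats.n_perms < 1:
        raise ValueError("need statistics from at least one permutation")
    if t <= 0:
        return SignificanceResult(t, 1.0, None, "empirical", stats)
    try:
        params = fit_gamma_hurdle(stats)
    except FitUnavailable:
        return SignificanceResult(t, empirical_pvalue(stats, t), None, "empirical", stats)
    p = gamma_hurdle_pvalue(params, t, hurdle_weighted=hurdle_weighted)
    return SignificanceResult(t, p, None, "gamma_hurdle", stats)


# ---------------------------------------------------------------------------
# multiple testing and storage prioritization


def adjust_pvalue(p: float, metapath_family_size: int) -> float:
    """Bonferroni over metapaths sharing source metanode, target metanode,
    and length: min(1, p × family size)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if metapath_family_size < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p * metapath_family_size)


def storage_threshold(n_source: int, n_target: int, length: int) -> float | None:
    """Adjusted-p cutoff for retaining a record in the precomputed database.

    Length-1 metapaths keep every nonzero DWPC (returns None: no p cutoff);
    longer metapaths keep adjusted p < 5·(n_source·n_target)^(−0.3), which
    penalizes metapaths with huge DWPC matrices.
    """
    if n_source < 1 or n_target < 1:
        raise ValueError("metanode sizes must be >= 1")
    if length < 1:
        raise ValueError("metapath length must be >= 1")
    if length == 1:
        return None
    return 5.0 * (n_source * n_target) ** -0.3


def keep_record(dwpc_value: float, p_adjusted: float | None, threshold: float | None) -> bool:
    if dwpc_value <= 0:
        return False
    if threshold is None:
        return True
    return p_adjusted is not None and p_adjusted < threshold


def node_pair_count(n_nodes: int) -> int:
    """Ordered (source, target) pairs over one metanode: n²."""
    if n_nodes < 0:
        raise ValueError("node count must be nonnegative")
    return n_nodes * n_nodes


def degree_pair_count(distinct_degrees: int) -> int:
    """Ordered (source degree, target degree) pairs: d²."""
    if distinct_degrees < 0:
        raise ValueError("degree count must be nonnegative")
    return distinct_degrees * distinct_degrees


# ---------------------------------------------------------------------------
# serialization

STATS_COLUMNS = [
    "metapath",
    "source_degree",
    "target_degree",
    "n_dwpcs",
    "n_nonzero_dwpcs",
    "sum",
    "sum_of_squares",
    "n_perms",
]


def stats_to_frame(stats_map: dict) -> pd.DataFrame:
    rows = [
        {
            "metapath": s.metapath,
            "source_degree": s.source_degree,
            "target_degree": s.target_degree,
            "n_dwpcs": s.N,
            "n_nonzero_dwpcs": s.n,
            "sum": s.sum,
            "sum_of_squares": s.sum_sq,
            "n_perms": s.n_perms,
        }
        for s in stats_map.values()
    ]
    frame = pd.DataFrame(rows, columns=STATS_COLUMNS)
    return frame.sort_values(["metapath", "source_degree", "target_degree"]).reset_index(
        drop=True
    )


def write_stats(stats_map: dict, path) -> Path:
    """Gzipped TSV, one row per (metapath, source degree, target degree)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = stats_to_frame(stats_map)
    with gzip.open(path, "wt") as handle:
        frame.to_csv(handle, sep="\t", index=False)
    return path


def read_stats(path) -> dict[tuple[str, int, int], DegreeGroupStats]:
    frame = pd.read_csv(path, sep="\t", compression="infer", float_precision="round_trip")
    out = {}
    for row in frame.itertuples(index=False):
        stats = DegreeGroupStats(
            metapath=row.metapath,
            source_degree=int(row.source_degree),
            target_degree=int(row.target_degree),
            N=int(row.n_dwpcs),
            n=int(row.n_nonzero_dwpcs),
            sum=float(row.sum),
            sum_sq=float(row.sum_of_squares),
            n_perms=int(row.n_perms),
        )
        out[stats.key] = stats
    return out
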
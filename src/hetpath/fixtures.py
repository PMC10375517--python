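"""Deterministic hetnet generators for testing and examples.

Provides hand-constructed toy hetnets with worked-out DWPC values, seeded
random hetnets for property sweeps, and the Hetionet v1.0 metagraph (schema
only — node/edge data are never required)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .hetmat import HetMat
from .metagraph import Metaedge, Metagraph, Metanode


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a random hetnet.

    ``metanodes`` maps identifier → abbreviation; ``metaedges`` is a list of
    (source_ab, target_ab, kind, kind_ab, directed); ``node_counts`` maps
    metanode abbreviation → node count; ``densities`` maps metaedge
    abbreviation → Bernoulli edge probability; ``degree_sequences`` maps a
    metaedge abbreviation to (source_degrees, target_degrees) for stub
    matching instead of density sampling.
    """

    metanodes: tuple[tuple[str, str], ...]
    metaedges: tuple[tuple[str, str, str, str, bool], ...]
    node_counts: dict[str, int] = field(default_factory=dict)
    densities: dict[str, float] = field(default_factory=dict)
    degree_sequences: dict[str, tuple] = field(default_factory=dict)
    seed: int = 0

    def build_metagraph(self) -> Metagraph:
        metanodes = {ab: Metanode(name, ab) for name, ab in self.metanodes}
        metaedges = [
            Metaedge(metanodes[src], metanodes[tgt], kind, kind_ab, directed)
            for src, tgt, kind, kind_ab, directed in self.metaedges
        ]
        return Metagraph(metanodes.values(), metaedges)


def generate_hetnet(spec: FixtureSpec) -> HetMat:
    """Reproducible random store: no self-edges, undirected self metaedges
    symmetric, densities as requested (realized within sampling noise)."""
    metagraph = spec.build_metagraph()
    rng = np.random.default_rng(spec.seed)
    node_orderings = {
        ab: [f"{ab.lower()}{i}" for i in range(spec.node_counts.get(ab, 10))]
        for ab in metagraph.metanodes
    }
    adjacency = {}
    for key in sorted(metagraph.metaedges):
        me = metagraph.metaedges[key]
        n = len(node_orderings[me.source.abbreviation])
        m = len(node_orderings[me.target.abbreviation])
        if me.abbreviation in spec.degree_sequences:
            matrix = _stub_match(rng, spec.degree_sequences[me.abbreviation], n, m, me)
        else:
            density = spec.densities.get(me.abbreviation, 0.1)
            if not 0 <= density <= 1:
                raise ValueError(f"density must lie in [0, 1], got {density}")
            matrix = (rng.random((n, m)) < density).astype(np.uint8)
            if me.is_self_loop:
                np.fill_diagonal(matrix, 0)
                if not me.directed:
                    upper = np.triu(matrix)
                    matrix = upper | upper.T
        adjacency[key] = matrix
    return HetMat(metagraph, node_orderings, adjacency)


def _stub_match(rng, sequences, n, m, me) -> np.ndarray:
    """Pair degree stubs at random, rejecting self and duplicate edges."""
    source_degrees, target_degrees = sequences
    src_stubs = np.repeat(np.arange(n), source_degrees)
    tgt_stubs = np.repeat(np.arange(m), target_degrees)
    if src_stubs.size != tgt_stubs.size:
        raise ValueError("degree sequences must have equal totals")
    matrix = np.zeros((n, m), dtype=np.uint8)
    for _ in range(100):
        matrix[:] = 0
        perm = rng.permutation(tgt_stubs)
        ok = True
        for i, j in zip(src_stubs, perm):
            if matrix[i, j] or (me.is_self_loop and i == j):
                ok = False
                break
            matrix[i, j] = 1
        if ok:
            break
    else:
        # accept the last attempt, dropping conflicting stub pairs
        matrix[:] = 0
        for i, j in zip(src_stubs, rng.permutation(tgt_stubs)):
            if not matrix[i, j] and not (me.is_self_loop and i == j):
                matrix[i, j] = 1
    if me.is_self_loop and not me.directed:
        upper = np.triu(matrix | matrix.T)
        np.fill_diagonal(upper, 0)
        matrix = upper | upper.T
    return matrix


def toy_fixtures() -> dict[str, HetMat]:
    """The two worked toy hetnets used throughout the documentation.

    toy-GiG: three genes g0–g1–g2 on Gene–interacts–Gene; the only GiGiG
    path g0–g1–g2 has PDP (1·2)^(−1/2)·(2·1)^(−1/2) = 0.5 at w = 0.5.

    toy-CD: compounds {c0, c1}, diseases {d0, d1}, treats edges c0–d0,
    c0–d1, c1–d0; the only duplicate-free CtDtCtD path c1–d0–c0–d1 has
    PDP 0.25 at w = 0.5, while every c0→d0 walk repeats a node.
    """
    gene = Metanode("Gene", "G")
    gig = Metaedge(gene, gene, "interacts", "i")
    toy_gig = HetMat.from_edge_lists(
        Metagraph([gene], [gig]),
        {"G": ["g0", "g1", "g2"]},
        {"GiG": [("g0", "g1"), ("g1", "g2")]},
    )
    compound = Metanode("Compound", "C")
    disease = Metanode("Disease", "D")
    ctd = Metaedge(compound, disease, "treats", "t")
    toy_cd = HetMat.from_edge_lists(
        Metagraph([compound, disease], [ctd]),
        {"C": ["c0", "c1"], "D": ["d0", "d1"]},
        {"CtD": [("c0", "d0"), ("c0", "d1"), ("c1", "d0")]},
    )
    return {"toy-GiG": toy_gig, "toy-CD": toy_cd}


def default_random_spec(
    seed: int = 0,
    n_nodes: int = 14,
    density: float = 0.2,
) -> FixtureSpec:
    """A small three-metanode metagraph exercising every repeat pattern
    class: an undirected self metaedge, a directed self metaedge, and
    bipartite metaedges forming cycles of types."""
    return FixtureSpec(
        metanodes=(("Gene", "G"), ("Compound", "C"), ("Disease", "D")),
        metaedges=(
            ("G", "G", "interacts", "i", False),
            ("G", "G", "regulates", "r", True),
            ("C", "G", "binds", "b", False),
            ("C", "D", "treats", "t", False),
            ("D", "G", "associates", "a", False),
        ),
        node_counts={"G": n_nodes, "C": max(n_nodes - 4, 2), "D": max(n_nodes - 4, 2)},
        densities={
            "GiG": density,
            "Gr>G": density * 0.75,
            "CbG": density,
            "CtD": density * 1.5,
            "DaG": density,
        },
        seed=seed,
    )


def hetionet_metagraph() -> Metagraph:
    """The Hetionet v1.0 schema: 11 metanodes, 24 metaedges."""
    text = resources.files("hetpath").joinpath("data/hetionet-v1.0-metagraph.json").read_text()
    return Metagraph.from_dict(json.loads(text))


# node counts from the Hetionet v1.0 release (metanode abbreviation → nodes)
HETIONET_NODE_COUNTS = {
    "A": 402,
    "BP": 11381,
    "CC": 1391,
    "C": 1552,
    "D": 137,
    "G": 20945,
    "MF": 2884,
    "PW": 1822,
    "PC": 345,
    "SE": 5734,
    "S": 438,
}
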
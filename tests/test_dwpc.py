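"""DWPC engine: weighting, categorization, corrections, and the oracle."""

import numpy as np
import pytest

import importlib

import hetpath

engine = importlib.import_module("hetpath.dwpc")
from hetpath.fixtures import FixtureSpec, default_random_spec, generate_hetnet
from hetpath.metagraph import Metaedge, Metagraph, Metanode

# metagraph carrying the repeat patterns discussed in the docs:
# disjoint DrDtCrC, overlapping DtCtDpC, nested CtDrDtC, long DrDaGaDrD
PATTERN_SPEC = FixtureSpec(
    metanodes=(("Disease", "D"), ("Compound", "C"), ("Gene", "G")),
    metaedges=(
        ("D", "D", "resembles", "r", False),
        ("C", "C", "resembles", "r", False),
        ("C", "D", "treats", "t", False),
        ("C", "D", "palliates", "p", False),
        ("D", "G", "associates", "a", False),
    ),
    node_counts={"D": 6, "C": 6, "G": 5},
    densities={"DrD": 0.4, "CrC": 0.4, "CtD": 0.4, "CpD": 0.3, "DaG": 0.4},
    seed=3,
)


@pytest.fixture(scope="module")
def pattern_store():
    return generate_hetnet(PATTERN_SPEC)


class TestDegreeWeight:
    def test_toy_gig_weighted_matrix(self, toy_gig):
        adjacency = toy_gig.adjacency("GiG")
        src, tgt = toy_gig.degrees("GiG")
        weighted = hetpath.degree_weight(adjacency, src, tgt, w=0.5)
        expected = [[0, 0.70711, 0], [0.70711, 0, 0.70711], [0, 0.70711, 0]]
        np.testing.assert_allclose(weighted, expected, atol=1e-5)

    def test_zero_damping_returns_adjacency(self, toy_cd):
        adjacency = np.asarray(toy_cd.adjacency("CtD"), dtype=float)
        src, tgt = toy_cd.degrees("CtD")
        np.testing.assert_array_equal(
            hetpath.degree_weight(adjacency, src, tgt, w=0.0), adjacency
        )

    def test_isolated_node_stays_zero(self):
        adjacency = np.array([[1, 0], [0, 0]])
        weighted = hetpath.degree_weight(adjacency, [1, 0], [1, 0], w=0.5)
        assert weighted[1].sum() == 0 and weighted[:, 1].sum() == 0

    def test_negative_damping_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            hetpath.degree_weight(np.eye(2), [1, 1], [1, 1], w=-0.5)


class TestCategorization:
    @pytest.mark.parametrize(
        "abbreviation, label",
        [
            ("DrDtCrC", "disjoint"),
            ("DtCtDpC", "overlapping"),
            ("CtDrDtC", "nested"),
            ("DrDaGaDrD", "long_repeat"),  # D appears 4 times
            ("CtDaG", "no_repeats"),
            ("DrDrD", "short_repeat"),
            ("DaGaDrD", "interleaved_nonrepeat"),
            ("DrDaGaD", "interleaved_nonrepeat"),
        ],
    )
    def test_category_labels(self, pattern_store, abbreviation, label):
        mp = pattern_store.metagraph.parse_metapath(abbreviation)
        assert hetpath.categorize_metapath(mp).label == label

    def test_segmentation_covers_metapath(self, pattern_store):
        mg = pattern_store.metagraph
        for abbrev in ["DrDtCrC", "DtCtDpC", "CtDrDtC", "CtDaG", "DrDaGaDrD"]:
            mp = mg.parse_metapath(abbrev)
            segments = hetpath.segment_metapath(mp)
            joined = segments[0].metapath
            for segment in segments[1:]:
                joined = joined + segment.metapath
            assert joined == mp

    def test_hierarchical_cbabac_xyz_segmentation(self):
        """A C(BABA)C-style head with a no-repeat tail segments as
        (nested [overlapping]) (no_repeats)."""
        metanodes = {ab: Metanode(name, ab) for name, ab in
                     [("Qoph", "Q"), ("Beta", "B"), ("Alpha", "A"),
                      ("Xi", "X"), ("Ypsilon", "Y"), ("Zeta", "Z")]}
        mg = Metagraph(
            metanodes.values(),
            [
                Metaedge(metanodes["Q"], metanodes["B"], "meets", "m"),
                Metaedge(metanodes["B"], metanodes["A"], "nears", "n"),
                Metaedge(metanodes["A"], metanodes["Q"], "orbits", "o"),
                Metaedge(metanodes["Q"], metanodes["X"], "passes", "p"),
                Metaedge(metanodes["X"], metanodes["Y"], "quotes", "q"),
                Metaedge(metanodes["Y"], metanodes["Z"], "rates", "s"),
            ],
        )
        mp = mg.parse_metapath("QmBnAnBnAoQpXqYsZ")
        segments = hetpath.segment_metapath(mp)
        assert [seg.label for seg in segments] == ["nested", "no_repeats"]
        assert [child.label for child in segments[0].children] == ["overlapping"]
        category = hetpath.categorize_metapath(mp)
        assert category.label == "nested"


class TestSpecializedRoutines:
    def test_short_repeat_path_counts(self, toy_gig):
        counts = hetpath.dwpc(toy_gig, "GiGiG", w=0.0)
        assert counts.kind == "path_count"
        assert counts.values.dtype == np.uint64
        np.testing.assert_array_equal(counts.values, [[0, 0, 1], [0, 0, 0], [1, 0, 0]])

    def test_short_repeat_dwpc_value(self, toy_gig):
        matrix = hetpath.dwpc(toy_gig, "GiGiG", w=0.5)
        assert matrix.values[0, 2] == pytest.approx(0.5)
        assert np.all(matrix.values.diagonal() == 0)

    def test_short_repeat_requires_square(self):
        with pytest.raises(ValueError, match="square"):
            hetpath.dwpc_short_repeat(np.ones((2, 3)), np.ones((3, 2)))

    def test_baba_corrections(self, toy_cd):
        matrix = hetpath.dwpc(toy_cd, "CtDtCtD", w=0.5)
        assert matrix.values[1, 1] == pytest.approx(0.25)
        # all c0→d0 walks revisit a node despite a nonzero walk count
        assert matrix.values[0, 0] == 0.0
        counts = hetpath.dwpc(toy_cd, "CtDtCtD", w=0.0)
        assert counts.values[1, 1] == 1

    def test_baba_annihilation(self):
        d = np.ones((3, 3))
        np.testing.assert_array_equal(hetpath.dwpc_baba(d, np.zeros((3, 3)), d), 0)

    def test_baba_shape_mismatch(self):
        with pytest.raises(ValueError, match="chain"):
            hetpath.dwpc_baba(np.ones((2, 3)), np.ones((3, 2)), np.ones((3, 3)))

    @pytest.mark.parametrize("w", [0.0, 0.5])
    def test_nested_matches_oracle(self, pattern_store, w):
        mp = pattern_store.metagraph.parse_metapath("CtDrDtC")
        fast = hetpath.dwpc(pattern_store, mp, w=w)
        oracle = hetpath.dwpc_general(pattern_store, mp, w=w)
        if w == 0:
            np.testing.assert_array_equal(fast.values, oracle.values)
        else:
            np.testing.assert_allclose(
                fast.values.astype(float), oracle.values, atol=1e-10
            )
        assert np.all(np.asarray(fast.values).diagonal() == 0)


class TestDispatcher:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_all_short_metapaths(self, seed):
        store = generate_hetnet(
            default_random_spec(seed=seed, n_nodes=10, density=0.25)
        )
        for mp in store.metagraph.enumerate_metapaths(3):
            fast = hetpath.dwpc(store, mp, w=0.5).values
            exact = hetpath.dwpc_general(store, mp, w=0.5).values
            np.testing.assert_allclose(fast, exact, rtol=1e-8, atol=1e-12, err_msg=str(mp))
            counts = hetpath.dwpc(store, mp, w=0.0).values
            oracle_counts = hetpath.dwpc_general(store, mp, w=0.0).values
            np.testing.assert_array_equal(counts, oracle_counts, err_msg=str(mp))

    def test_transpose_law(self, random_store):
        for abbrev in ["CbGiG", "CtDaG", "CbGr>G", "GiGiG", "CbGaDtC"]:
            mp = random_store.metagraph.parse_metapath(abbrev)
            forward = hetpath.dwpc(random_store, mp, w=0.5).values
            backward = hetpath.dwpc(random_store, mp.reverse, w=0.5).values
            np.testing.assert_allclose(backward, forward.T, atol=1e-12)

    def test_monotone_in_damping(self, random_store):
        mp = random_store.metagraph.parse_metapath("CbGiG")
        stack = [hetpath.dwpc(random_store, mp, w=w).values for w in (0.0, 0.25, 0.5, 1.0)]
        base = stack[0] > 0
        for lower, higher in zip(stack, stack[1:]):
            assert np.all(higher[base] <= lower[base] + 1e-12)

    def test_sum_decomposition(self, random_store):
        mp = random_store.metagraph.parse_metapath("GiGiG")
        matrix = hetpath.dwpc(random_store, mp, w=0.5).values
        genes = random_store.nodes("G")
        for i in [0, 3, 7]:
            for j in [1, 5]:
                records = hetpath.enumerate_paths(
                    random_store, mp, genes[i], genes[j], w=0.5
                )
                total = sum(r.path_degree_product for r in records)
                assert total == pytest.approx(matrix[i, j], abs=1e-8)

    def test_warm_cache_is_bit_identical(self, random_store):
        mp = random_store.metagraph.parse_metapath("CbGiG")
        cold = hetpath.dwpc(random_store, mp, w=0.5).values
        warm = hetpath.dwpc(random_store, mp, w=0.5).values
        np.testing.assert_array_equal(cold, warm)

    def test_disk_cache_reuse(self, tmp_path):
        store = generate_hetnet(default_random_spec(seed=5, n_nodes=8)).write(
            tmp_path / "c.hetmat"
        )
        mp = store.metagraph.parse_metapath("CbGiG")
        first = hetpath.dwpc(store, mp, w=0.5)
        engine._get_cache(store).persist(mp, 0.5, first.values)
        fresh = hetpath.HetMat.from_directory(store.directory)
        reloaded = hetpath.dwpc(fresh, mp, w=0.5)
        np.testing.assert_array_equal(reloaded.values, first.values)

    def test_sparse_and_dense_inputs_agree(self, tmp_path):
        import scipy.sparse as sparse

        store = generate_hetnet(default_random_spec(seed=6, n_nodes=8))
        sparse_store = store.replace_adjacency(
            {key: sparse.csr_matrix(store.adjacency(key)) for key in store.metagraph.metaedges}
        )
        mp = store.metagraph.parse_metapath("CbGiG")
        np.testing.assert_array_equal(
            hetpath.dwpc(store, mp, w=0.5).values,
            hetpath.dwpc(sparse_store, mp, w=0.5).values,
        )


class TestApproximations:
    def test_approx_exact_on_disjoint_and_simple(self, pattern_store, toy_gig):
        for store, abbrev in [(pattern_store, "DrDtCrC"), (toy_gig, "GiGiG")]:
            mp = store.metagraph.parse_metapath(abbrev)
            approx = hetpath.dwpc_approx(store, mp, w=0.5)
            exact = hetpath.dwpc(store, mp, w=0.5)
            assert approx.kind == "dwpc_approx"
            np.testing.assert_allclose(
                approx.values, exact.values.astype(float), atol=1e-12
            )

    def test_approx_flagged_on_complex_pattern(self, pattern_store):
        mp = pattern_store.metagraph.parse_metapath("DrDaGaDrD")
        approx = hetpath.dwpc_approx(pattern_store, mp, w=0.5)
        exact = hetpath.dwpc_general(pattern_store, mp, w=0.5)
        assert approx.kind == "dwpc_approx"
        # difference recorded, not asserted zero
        assert np.isfinite(approx.values - exact.values).all()

    def test_mayers_variant_runs_and_matches_simple(self, toy_gig):
        mp = toy_gig.metagraph.parse_metapath("GiGiG")
        mayers = hetpath.dwpc_mayers(toy_gig, mp, w=0.5)
        assert mayers.algorithm == "mayers"
        np.testing.assert_allclose(
            mayers.values, hetpath.dwpc(toy_gig, mp, w=0.5).values, atol=1e-12
        )


def test_transform_hook_does_not_mutate(toy_gig):
    matrix = hetpath.dwpc(toy_gig, "GiGiG", w=0.5)
    compacted = matrix.transformed(np.arcsinh)
    np.testing.assert_allclose(compacted.values, np.arcsinh(matrix.values))
    assert matrix.values[0, 2] == pytest.approx(0.5)  # original untouched


class TestGeneralAgainstNetworkx:
    def test_path_counts_match_networkx_simple_paths(self):
        networkx = pytest.importorskip("networkx")
        store = generate_hetnet(
            default_random_spec(seed=7, n_nodes=10, density=0.3)
        )
        matrix = np.asarray(store.adjacency("GiG"))
        graph = networkx.from_numpy_array(matrix)
        mp = store.metagraph.parse_metapath("GiGiGiG")
        counts = hetpath.dwpc_general(store, mp, w=0.0).values
        for s in range(10):
            for t in range(10):
                expected = sum(
                    1
                    for path in networkx.all_simple_paths(graph, s, t, cutoff=3)
                    if len(path) == 4
                )
                assert counts[s, t] == expected


class TestEnumeratePaths:
    def test_single_path_case(self, toy_cd):
        records = hetpath.enumerate_paths(toy_cd, "CtDtCtD", "c1", "d1", w=0.5)
        assert len(records) == 1
        record = records[0]
        assert record.nodes == ("c1", "d0", "c0", "d1")
        assert record.path_degree_product == pytest.approx(0.25)
        assert record.percent_of_dwpc == pytest.approx(100.0)

    def test_all_walks_repeat_nodes(self, toy_cd):
        assert hetpath.enumerate_paths(toy_cd, "CtDtCtD", "c0", "d0", w=0.5) == []

    def test_percent_sums_to_hundred(self, random_store):
        genes = random_store.nodes("G")
        records = hetpath.enumerate_paths(random_store, "GiGiG", genes[0], genes[5], w=0.5)
        if records:
            assert sum(r.percent_of_dwpc for r in records) == pytest.approx(100.0, abs=1e-6)

    def test_type_mismatch_is_type_error(self, toy_cd):
        with pytest.raises(TypeError):
            hetpath.enumerate_paths(toy_cd, "CtD", "d0", "d1", w=0.5)
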
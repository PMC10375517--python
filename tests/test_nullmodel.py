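"""Degree-grouped null statistics, gamma-hurdle fitting, and p-values."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, special

import hetpath
from hetpath.nullmodel import (
    DegreeGroupStats,
    FitUnavailable,
    keep_record,
    read_stats,
    stats_to_frame,
    write_stats,
)


def make_stats(values, N=None, metapath="GiGiG", sd=1, td=1, n_perms=1):
    values = np.asarray(values, dtype=float)
    nonzero = values[values > 0]
    total = N if N is not None else values.size
    return DegreeGroupStats(
        metapath=metapath,
        source_degree=sd,
        target_degree=td,
        N=total,
        n=nonzero.size,
        sum=float(nonzero.sum()),
        sum_sq=float((nonzero**2).sum()),
        n_perms=n_perms,
    )


class TestDegreeGroupStats:
    def test_toy_gig_grouping(self, toy_gig):
        mp = toy_gig.metagraph.parse_metapath("GiGiG")
        matrix = hetpath.dwpc(toy_gig, mp, w=0.5)
        src, tgt = toy_gig.degrees("GiG")
        groups = hetpath.degree_group_stats(matrix, src, tgt)
        assert {key: s.N for key, s in groups.items()} == {
            (1, 1): 4,
            (1, 2): 2,
            (2, 1): 2,
            (2, 2): 1,
        }
        assert sum(s.N for s in groups.values()) == 9

    def test_all_zero_matrix(self, toy_gig):
        src, tgt = toy_gig.degrees("GiG")
        groups = hetpath.degree_group_stats(np.zeros((3, 3)), src, tgt, metapath="GiGiG")
        assert all(s.n == 0 and s.sum == 0 for s in groups.values())

    def test_pooling_multiplier(self):
        """25 node pairs pooled over 200 permutations yield N = 5,000."""
        per_perm = make_stats(np.ones(25))
        pooled = per_perm
        for _ in range(199):
            pooled = hetpath.merge_stats(pooled, per_perm)
        assert pooled.N == 5_000
        assert pooled.n_perms == 200
        assert pooled.N // pooled.n_perms == 25

    def test_shape_mismatch(self, toy_gig):
        src, tgt = toy_gig.degrees("GiG")
        with pytest.raises(ValueError, match="shape"):
            hetpath.degree_group_stats(np.zeros((2, 2)), src, tgt, metapath="x")

    def test_summary_equals_raw(self, random_store):
        mp = random_store.metagraph.parse_metapath("CbGiG")
        matrix = hetpath.dwpc(random_store, mp, w=0.5)
        src = np.asarray(random_store.adjacency("CbG")).sum(axis=1).astype(int)
        tgt = np.asarray(random_store.adjacency("GiG")).sum(axis=0).astype(int)
        groups = hetpath.degree_group_stats(matrix, src, tgt)
        values = matrix.values
        for (sd, td), stats in groups.items():
            cell_values = values[np.ix_(src == sd, tgt == td)].ravel()
            nonzero = cell_values[cell_values > 0]
            assert stats.N == cell_values.size
            assert stats.n == nonzero.size
            assert stats.sum == pytest.approx(nonzero.sum(), abs=1e-12)
            assert stats.sum_sq == pytest.approx((nonzero**2).sum(), abs=1e-12)
            if stats.n >= 2:
                assert stats.nonzero_mean == pytest.approx(nonzero.mean(), rel=1e-10)
                assert stats.nonzero_sd == pytest.approx(nonzero.std(ddof=1), rel=1e-10)


class TestMergeStats:
    def test_merge_equals_union(self):
        a_vals, b_vals = [0, 1, 2], [3, 0, 4, 0]
        merged = hetpath.merge_stats(make_stats(a_vals), make_stats(b_vals))
        union = make_stats(a_vals + b_vals, n_perms=2)
        assert merged == union

    def test_identity_element(self):
        stats = make_stats([1, 2, 0])
        zero = DegreeGroupStats("GiGiG", 1, 1)
        assert hetpath.merge_stats(stats, zero) == stats
        assert hetpath.merge_stats(zero, stats) == stats

    def test_key_mismatch(self):
        with pytest.raises(KeyError):
            hetpath.merge_stats(make_stats([1], sd=1), make_stats([1], sd=2))

    @given(st.lists(st.lists(st.floats(0, 10), min_size=1, max_size=5), min_size=2, max_size=6))
    def test_fold_order_invariance(self, chunks):
        stats = [make_stats(chunk) for chunk in chunks]
        forward = stats[0]
        for s in stats[1:]:
            forward = hetpath.merge_stats(forward, s)
        backward = stats[-1]
        for s in reversed(stats[:-1]):
            backward = hetpath.merge_stats(backward, s)
        assert forward.N == backward.N and forward.n == backward.n
        assert forward.sum == pytest.approx(backward.sum, rel=1e-12)
        assert forward.sum_sq == pytest.approx(backward.sum_sq, rel=1e-12)


class TestGammaHurdleFit:
    def test_hand_worked_moments(self):
        stats = make_stats([1, 2, 3], N=6)
        fit = hetpath.fit_gamma_hurdle(stats)
        assert fit.lam == pytest.approx(0.5)
        assert fit.alpha == pytest.approx(4.0)
        assert fit.beta == pytest.approx(2.0)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(2024)
        lam, alpha, beta = 0.7, 3.0, 2.0
        n_draws = 100_000
        draws = np.where(
            rng.random(n_draws) < lam,
            rng.gamma(alpha, scale=1 / beta, size=n_draws),
            0.0,
        )
        fit = hetpath.fit_gamma_hurdle(make_stats(draws))
        assert fit.lam == pytest.approx(lam, abs=0.01)
        assert fit.alpha == pytest.approx(alpha, rel=0.05)
        assert fit.beta == pytest.approx(beta, rel=0.05)

    def test_insufficient_nonzero_values(self):
        with pytest.raises(FitUnavailable):
            hetpath.fit_gamma_hurdle(make_stats([5.0, 0.0]))

    def test_zero_spread_unavailable(self):
        with pytest.raises(FitUnavailable):
            hetpath.fit_gamma_hurdle(make_stats([2.0, 2.0, 2.0]))


class TestPvalues:
    def test_exponential_special_case(self):
        params = hetpath.GammaHurdle(0.5, 1.0, 1.0)
        assert hetpath.gamma_hurdle_pvalue(params, math.log(2)) == pytest.approx(0.25)

    def test_limit_small_t_approaches_lambda(self):
        params = hetpath.GammaHurdle(1.0, 2.3, 1.7)
        assert hetpath.gamma_hurdle_pvalue(params, 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_against_quadrature(self):
        params = hetpath.GammaHurdle(0.5, 4.0, 2.0)
        t = 2.0
        density = lambda x: (
            params.beta**params.alpha
            / special.gamma(params.alpha)
            * x ** (params.alpha - 1)
            * math.exp(-params.beta * x)
        )
        tail, _ = integrate.quad(density, t, np.inf)
        assert hetpath.gamma_hurdle_pvalue(params, t) == pytest.approx(
            0.5 * tail, abs=1e-8
        )

    def test_strictly_decreasing_in_t(self):
        params = hetpath.GammaHurdle(0.8, 2.0, 3.0)
        values = [hetpath.gamma_hurdle_pvalue(params, t) for t in np.linspace(0.01, 5, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert all(0 < v <= params.lam for v in values)

    def test_conditional_variant_drops_hurdle_weight(self):
        params = hetpath.GammaHurdle(0.5, 1.0, 1.0)
        weighted = hetpath.gamma_hurdle_pvalue(params, 1.0)
        conditional = hetpath.gamma_hurdle_pvalue(params, 1.0, hurdle_weighted=False)
        assert conditional == pytest.approx(2 * weighted)

    @pytest.mark.parametrize(
        "values, N, t, expected",
        [
            ([1, 2], None, 0.0, 1.0),  # observed DWPC zero
            ([0, 0, 0], None, 0.8, 0.0),  # all nulls zero, observed positive
            ([2.0] * 30, 100, 1.5, 0.3),  # zero-spread nulls, t below them
            ([2.0] * 30, 100, 2.5, 0.0),  # zero-spread nulls, t above them
        ],
    )
    def test_empirical_rules(self, values, N, t, expected):
        stats = make_stats(values, N=N)
        assert hetpath.empirical_pvalue(stats, t) == pytest.approx(expected)

    def test_routing(self):
        gamma_case = hetpath.dwpc_pvalue(make_stats([1, 2, 3], N=6), 2.0)
        assert gamma_case.method == "gamma_hurdle"
        zero_case = hetpath.dwpc_pvalue(make_stats([1, 2, 3], N=6), 0.0)
        assert zero_case.method == "empirical" and zero_case.p_value == 1.0
        spread_case = hetpath.dwpc_pvalue(make_stats([2.0, 2.0], N=4), 1.0)
        assert spread_case.method == "empirical"
        assert spread_case.p_value == pytest.approx(0.5)


class TestAdjustmentAndStorage:
    def test_bonferroni_worked_example(self):
        # a 5.9% p-value in a 3-metapath family adjusts to 17.8%
        assert hetpath.adjust_pvalue(0.0593, 3) == pytest.approx(0.178, abs=5e-4)

    def test_cap_and_identity(self):
        assert hetpath.adjust_pvalue(0.6, 3) == 1.0
        assert hetpath.adjust_pvalue(0.2, 1) == 0.2

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            hetpath.adjust_pvalue(0.2, 0)

    def test_length_one_keeps_all_nonzero(self):
        assert hetpath.storage_threshold(100, 100, 1) is None
        assert keep_record(0.5, 0.99, None)
        assert not keep_record(0.0, 0.0, None)

    def test_threshold_values(self):
        assert hetpath.storage_threshold(137, 1822, 2) == pytest.approx(0.1202, abs=2e-4)
        assert hetpath.storage_threshold(20945, 20945, 3) == pytest.approx(0.0128, abs=2e-4)

    def test_pair_counts(self):
        assert hetpath.node_pair_count(20945) == 438_693_025
        assert hetpath.degree_pair_count(302) == 91_204
        assert hetpath.node_pair_count(0) == 0


class TestSerialization:
    def test_stats_round_trip(self, tmp_path):
        stats_map = {
            (1, 2): make_stats([1.5, 0, 2.5], sd=1, td=2),
            (2, 2): make_stats([0.5], sd=2, td=2),
        }
        path = write_stats(stats_map, tmp_path / "GiGiG.tsv.gz")
        assert path.name.endswith(".tsv.gz")
        loaded = read_stats(path)
        for stats in stats_map.values():
            assert loaded[stats.key] == stats

    def test_frame_columns(self):
        frame = stats_to_frame({(1, 1): make_stats([1.0])})
        assert list(frame.columns) == [
            "metapath",
            "source_degree",
            "target_degree",
            "n_dwpcs",
            "n_nonzero_dwpcs",
            "sum",
            "sum_of_squares",
            "n_perms",
        ]
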
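"""Fold-change/t-test screening, top-k selection, and cluster ordering."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lncnet.diffexpr import (
    DERecord,
    de_table,
    differential_expression,
    hierarchical_cluster,
    select_top_k,
)
from tests.conftest import make_matrix


def rec(probe_id="P", p=0.01, fc=3.0, direction="up", significant=True):
    return DERecord(probe_id, 1.0, 1.0, fc, direction, p, significant)


class TestDifferentialExpression:
    def test_pooled_t_matches_closed_form(self):
        # log2 case [1,2,3] vs control [4,5,6]: pooled t = -3.674, df 4
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], scale="log2")
        r = differential_expression(m, fc_min=1.0)[0]
        t_expected = -3.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        assert abs(t_expected) == pytest.approx(3.674, abs=5e-4)
        assert r.p_value == pytest.approx(p_expected, rel=1e-9)
        assert r.p_value == pytest.approx(0.0213, abs=5e-4)
        assert r.direction == "down"

    def test_fold_change_is_linear_mean_ratio(self):
        m = make_matrix([[8.0, 8.0, 2.0, 2.0]])
        r = differential_expression(m)[0]
        assert r.fold_change == pytest.approx(4.0)
        assert r.direction == "up"

    def test_fc_gate_blocks_flat_probes(self):
        m = make_matrix([[5.0, 5.0, 5.0, 5.0, 5.0, 5.0]])
        r = differential_expression(m, fc_min=2.0)[0]
        assert r.fold_change == pytest.approx(1.0)
        assert not r.significant
        assert r.p_value == 1.0  # zero variance, equal means: no evidence

    def test_welch_differs_from_pooled_under_unequal_variance(self, rng):
        x = np.concatenate([rng.normal(5, 2, 3), rng.normal(5, 0.1, 3)])
        m = make_matrix([2.0 ** x])
        pooled = differential_expression(m)[0].p_value
        welch = differential_expression(m, welch=True)[0].p_value
        assert pooled != welch

    def test_group_swap_preserves_fc_and_flips_direction(self, rng):
        X = rng.lognormal(3, 1, size=(20, 6))
        m = make_matrix(X)
        swapped = make_matrix(X[:, [3, 4, 5, 0, 1, 2]])
        for a, b in zip(differential_expression(m), differential_expression(swapped)):
            assert a.fold_change == pytest.approx(b.fold_change, rel=1e-9)
            assert a.direction != b.direction or a.fold_change == pytest.approx(1.0)

    def test_bh_gate_is_more_conservative(self, rng):
        X = rng.lognormal(3, 1, size=(200, 6))
        m = make_matrix(X)
        raw = differential_expression(m, fc_min=1.0)
        adj = differential_expression(m, fc_min=1.0, bh=True)
        assert sum(r.significant for r in adj) <= sum(r.significant for r in raw)
        assert all(r.q_value >= r.p_value - 1e-15 for r in adj)

    def test_small_group_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]], n_case=1)
        with pytest.raises(ValueError, match="at least 2"):
            differential_expression(m)


class TestSelectTopK:
    def test_smallest_p_wins(self):
        recs = [rec(f"P{i}", p=0.01 * (i + 1)) for i in range(5)]
        up, down = select_top_k(recs, 3, 0)
        assert [r.probe_id for r in up] == ["P0", "P1", "P2"]
        assert down == []

    def test_tie_break_fc_then_id(self):
        recs = [
            rec("B", p=0.01, fc=2.0),
            rec("A", p=0.01, fc=2.0),
            rec("C", p=0.01, fc=5.0),
        ]
        up, _ = select_top_k(recs, 3, 0)
        assert [r.probe_id for r in up] == ["C", "A", "B"]

    def test_permutation_invariant(self, rng):
        recs = [rec(f"P{i}", p=float(p)) for i, p in enumerate(rng.uniform(size=30))]
        base_up, _ = select_top_k(recs, 10, 0)
        for _ in range(5):
            shuffled = list(recs)
            rng.shuffle(shuffled)
            up, _ = select_top_k(shuffled, 10, 0)
            assert [r.probe_id for r in up] == [r.probe_id for r in base_up]

    def test_shortfall_returns_available(self):
        recs = [rec("A"), rec("B", direction="down"), rec("C", significant=False)]
        up, down = select_top_k(recs, 5, 5)
        assert [r.probe_id for r in up] == ["A"]
        assert [r.probe_id for r in down] == ["B"]
        assert select_top_k(recs, 0, 0) == ([], [])


def _brute_force_average_linkage(D):
    """Independent average-linkage agglomeration on an explicit distance matrix.

    Returns one ({side_a, side_b}, height) entry per merge, where the sides
    are frozensets of original leaf indices.
    """
    clusters = {i: [i] for i in range(len(D))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i][j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append(({frozenset(clusters[a]), frozenset(clusters[b])}, d))
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return merges


def _replay_linkage(Z, n):
    """Expand a scipy linkage matrix into ({side_a, side_b}, height) merges."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, h, _) in enumerate(Z):
        sa, sb = members[int(a)], members[int(b)]
        merges.append(({sa, sb}, h))
        members[n + step] = sa | sb
    return merges


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        m = make_matrix([[1, 2, 3, 4], [1, 2, 3, 4], [9, 1, 4, 2]], scale="log2")
        order = hierarchical_cluster(m, ["P000", "P001", "P002"])
        assert order.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(order.linkage[0, :2].astype(int)) == {0, 1}

    def test_anticorrelated_row_joins_last_at_two(self):
        r1 = np.array([1.0, 2.0, 3.0, 4.0])
        m = make_matrix([r1, r1, -r1], scale="log2")
        order = hierarchical_cluster(m, ["P000", "P001", "P002"])
        assert order.linkage[-1, 2] == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("n_rows", [3, 4, 5])
    def test_merge_heights_match_exhaustive_oracle(self, n_rows, rng):
        X = rng.normal(size=(n_rows, 6))
        probes = [f"P{i:03d}" for i in range(n_rows)]
        order = hierarchical_cluster(make_matrix(X, scale="log2"), probes)
        D = 1 - np.corrcoef(X)
        oracle = _brute_force_average_linkage(D)
        got = _replay_linkage(order.linkage, n_rows)
        np.testing.assert_allclose(
            [h for _, h in got], [h for _, h in oracle], atol=1e-9
        )
        for (sides_got, _), (sides_oracle, _) in zip(got, oracle):
            assert sides_got == sides_oracle

    def test_constant_row_distance_defined(self):
        m = make_matrix([[5, 5, 5, 5], [1, 2, 3, 4]], scale="log2")
        order = hierarchical_cluster(m, ["P000", "P001"])
        assert order.linkage[0, 2] == pytest.approx(1.0)

    def test_ordering_is_permutation(self, rng):
        probes = [f"P{i:03d}" for i in range(10)]
        m = make_matrix(rng.normal(size=(10, 6)), scale="log2")
        order = hierarchical_cluster(m, probes)
        assert sorted(order.ordered_ids) == sorted(probes)
        assert order.linkage.shape[0] == 9

    def test_too_few_probes_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            hierarchical_cluster(small_matrix, ["P000"])


def test_de_table_layout(small_matrix):
    recs = [rec("A"), rec("B")]
    df = de_table(recs)
    assert list(df.columns)[:2] == ["probe_id", "mean_case"]
    assert len(df) == 2
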
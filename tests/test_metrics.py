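import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_snapshots
from cyclenet import (
    SnapshotSequence,
    baseline_scores,
    node_score_table,
    static_betweenness,
    tcn,
    tcr,
    temporal_betweenness,
    track,
    window_degrees,
)


class TestTcnTcr:
    def test_toy_tcn_vector(self, toy):
        inv = track(toy, max_len=3)
        got = [tcn(inv, v, (1, 3)) for v in (1, 2, 3, 4, 5)]
        assert got == [2.0, 4.0, 4.0, 2.0, 0.0]

    def test_unknown_node_rejected(self, toy):
        with pytest.raises(KeyError):
            tcn(track(toy, max_len=3), 99)

    def test_tcr_arithmetic(self):
        # pure Eq.-8 arithmetic on given numerator/denominator
        assert tcr(4.0, 7.0) == pytest.approx(4.0 / 7.0, abs=1e-6)
        assert round(tcr(4.0, 7.0), 2) == 0.57
        assert tcr(2.0, 5.0) == pytest.approx(0.40, abs=1e-6)
        assert tcr(0.0, 0.0) == 0.0  # isolated node guarded by epsilon

    def test_toy_tcr_column_from_snapshot_degrees(self, toy):
        """TCR re-derived from the fixture: degree sums (5,8,8,6,3) give
        (0.40, 0.50, 0.50, 0.33, 0.00) at two decimals."""
        table = node_score_table(toy, track(toy, max_len=3))
        assert list(table["degree_sum"]) == [5, 8, 8, 6, 3]
        assert [round(x, 2) for x in table["tcr"]] == [0.40, 0.50, 0.50, 0.33, 0.00]

    def test_tcn_matches_brute_force(self, rng):
        for _ in range(15):
            seq = random_snapshots(rng)
            inv = track(seq, max_len=4)
            table = node_score_table(seq, inv)
            expected = oracles.brute_tcn(seq, 4)
            for v in seq.nodes:
                assert table.loc[v, "tcn"] == pytest.approx(expected[v])

    def test_conservation_sum_tcn_equals_sum_tau_times_size(self, rng):
        for _ in range(15):
            seq = random_snapshots(rng)
            inv = track(seq, max_len=4)
            total = node_score_table(seq, inv)["tcn"].sum()
            assert total == pytest.approx(sum(r.tau * r.length for r in inv))

    def test_tcr_bounded_by_tcn_for_active_nodes(self, rng):
        seq = random_snapshots(rng)
        table = node_score_table(seq, track(seq, max_len=4))
        active = table[table["degree_sum"] >= 1]
        assert (active["tcr"] <= active["tcn"] + 1e-12).all()

    def test_scores_equivariant_under_relabeling(self, rng):
        seq = random_snapshots(rng, n_max=7, t_max=3)
        perm = {v: f"n{(v * 7 + 3) % seq.n_nodes}" for v in seq.nodes}
        relabeled = SnapshotSequence(
            nodes=tuple(sorted(perm.values())),
            edges=tuple(
                frozenset(tuple(sorted((perm[u], perm[v]))) for u, v in e_t)
                for e_t in seq.edges
            ),
            delta_t=seq.delta_t,
        )
        t1 = node_score_table(seq, track(seq, max_len=4))
        t2 = node_score_table(relabeled, track(relabeled, max_len=4))
        for v in seq.nodes:
            assert t2.loc[perm[v], "tcn"] == pytest.approx(t1.loc[v, "tcn"])
            assert t2.loc[perm[v], "tcr"] == pytest.approx(t1.loc[v, "tcr"])

    def test_interval_activity_uses_full_horizon_tau(self, toy):
        # triangle {1,2,3} is inactive in window 3, so an interval
        # restricted to window 3 credits only the other triangle
        inv = track(toy, max_len=3)
        assert tcn(inv, 1, (3, 3)) == 0.0
        assert tcn(inv, 4, (3, 3)) == 2.0  # full-horizon tau, not 1


class TestP2n:
    def test_perfect_matching_has_no_two_paths(self):
        seq = SnapshotSequence(
            nodes=(0, 1, 2, 3),
            edges=(frozenset({(0, 1), (2, 3)}),) * 3,
        )
        table = node_score_table(seq, twopath_inventory=track(seq, family="2paths"))
        assert (table["p2n"] == 0).all()

    def test_static_star_center_and_leaf_credits(self):
        star = frozenset({(0, 1), (0, 2), (0, 3)})
        T = 4
        seq = SnapshotSequence(nodes=(0, 1, 2, 3), edges=(star,) * T)
        table = node_score_table(seq, twopath_inventory=track(seq, family="2paths"))
        assert table.loc[0, "p2n"] == pytest.approx(3 * T)  # C(3,2) two-paths
        for leaf in (1, 2, 3):
            assert table.loc[leaf, "p2n"] == pytest.approx(2 * T)

    def test_center_only_credit_mode(self):
        star = frozenset({(0, 1), (0, 2), (0, 3)})
        seq = SnapshotSequence(nodes=(0, 1, 2, 3), edges=(star,))
        table = node_score_table(
            seq, twopath_inventory=track(seq, family="2paths"), credit="center"
        )
        assert table.loc[0, "p2n"] == 3.0
        assert (table.loc[[1, 2, 3], "p2n"] == 0).all()

    def test_p2n_matches_brute_force(self, rng):
        for _ in range(10):
            seq = random_snapshots(rng)
            table = node_score_table(
                seq, twopath_inventory=track(seq, family="2paths")
            )
            expected = oracles.brute_p2n(seq)
            for v in seq.nodes:
                assert table.loc[v, "p2n"] == pytest.approx(expected[v])


class TestBaselines:
    def test_static_path_graph_betweenness_peaks_at_middle(self):
        seq = SnapshotSequence(
            nodes=("a", "b", "c"), edges=(frozenset({("a", "b"), ("b", "c")}),) * 2
        )
        bc = static_betweenness(seq)
        assert bc["b"] > bc["a"] == bc["c"] == 0.0

    def test_single_window_temporal_betweenness_reduces_to_static(self, rng):
        seq = random_snapshots(rng, n_max=7, t_max=2)
        single = SnapshotSequence(nodes=seq.nodes, edges=(seq.edges[0],))
        tb = temporal_betweenness(single)
        # ordered-pair normalization matches networkx's normalized score
        sb = static_betweenness(single)
        for v in seq.nodes:
            assert tb[v] == pytest.approx(sb[v], abs=1e-9)

    def test_toy_temporal_betweenness_matches_exhaustive_oracle(self, toy):
        tb = temporal_betweenness(toy)
        expected = oracles.brute_temporal_betweenness(toy)
        for v in toy.nodes:
            assert tb[v] == pytest.approx(expected[v], abs=1e-9)

    def test_baseline_table_columns(self, toy):
        table = baseline_scores(toy)
        assert list(table.columns) == [
            "static_betweenness", "temporal_betweenness", "kcore",
        ]
        assert (table["kcore"] >= 1).all()

    def test_score_table_column_order(self, toy):
        table = node_score_table(
            toy, track(toy, max_len=3), track(toy, family="2paths")
        )
        assert list(table.columns) == ["tcn", "tcr", "p2n", "p2r", "degree_sum"]
        assert list(table.index) == [1, 2, 3, 4, 5]
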